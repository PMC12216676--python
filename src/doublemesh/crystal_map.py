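"""Segmentation of a mesh scan into individual-crystal regions.

A scored mesh scan is dissected into connected regions of grid cells that
diffract and whose diffraction patterns agree — cells illuminated by the
same crystal show the same spots in the same detector positions, while
neighbouring crystals give unrelated patterns.  Cells where two or more
patterns overlap are flagged by difference-vector statistics and excluded
(label 999 on the crystal map).  Regions are ranked by integrated
diffraction strength, get a score-weighted centroid and a recommended beam
aperture, and pool the reciprocal-space nodes of their member cells for
the downstream periodicity analysis.

Cross-scan pair candidates then follow from geometry alone: the grid axis
``u`` runs along the rotation axis, so a crystal keeps its ``u`` centroid
between the two scans of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    CrystalPosition3D,
    DetectorGeometry,
    spots_to_nodes,
    triangulate_centre,
)
from .io_meshscan import MeshScan
from .planes import PlanesConfig, find_planes

__all__ = [
    "SegmentationConfig",
    "CrystalRegion",
    "PairCandidate",
    "cell_score",
    "multipattern_flag",
    "cell_similarity",
    "multipattern_cells",
    "segment",
    "build_label_map",
    "pair_candidates",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of crystal-map construction; all config-overridable."""

    similarity_threshold: float = 0.4
    match_radius_px: float = 4.0
    min_spots_multipattern: int = 20
    flag_n_directions: int = 500
    flag_top_k: int = 4
    flag_refine_max_eval: int = 60
    flag_max_nodes: int = 200
    flag_outer_band: float = 0.25
    flag_outer_fraction: float = 0.1
    flag_min_nodes_unexplained: int = 120
    pairing_tolerance_cells: float = 1.5
    apertures_um: tuple[float, ...] = (10.0, 20.0, 30.0, 50.0)
    min_score: float = 0.0


@dataclass
class CrystalRegion:
    """A connected set of grid cells attributed to one crystal."""

    label: int
    cells: set[tuple[int, int]]
    centroid: tuple[float, float]  # (u, v) mm, score-weighted
    extents: tuple[float, float]  # (du, dv) mm
    integral_score: float
    nodes: np.ndarray  # pooled reciprocal-space nodes, (n, 3) Å⁻¹
    beam_size: float  # recommended aperture, µm


@dataclass
class PairCandidate:
    """A geometrically possible cross-scan crystal pair."""

    region_a: CrystalRegion
    region_b: CrystalRegion
    z_gap: float  # |u_a - u_b| mm along the rotation axis
    provisional_3d: CrystalPosition3D


def cell_score(spots: np.ndarray) -> float:
    """Background-weighted diffraction score of one image's spot list.

    Sum over spots of ``intensity / (background + 1)`` — a simple proxy
    for a per-image diffraction-signal estimate: linear in intensity and
    discounted where the local background is high.
    """
    spots = np.asarray(spots, dtype=float).reshape(-1, 4)
    if len(spots) == 0:
        return 0.0
    return float(np.sum(spots[:, 2] / (spots[:, 3] + 1.0)))


def multipattern_flag(
    spots: np.ndarray,
    det: DetectorGeometry,
    cfg: SegmentationConfig | None = None,
) -> bool:
    """Detect superimposed diffraction patterns in one image.

    The image's spots are back-projected to reciprocal-space nodes and a
    reduced plane search (``flag_n_directions`` directions) looks for
    periodic plane families.  For a single-lattice image some detected
    family phase-explains essentially every node: the projections onto the
    family normal sit close to integer multiples of the period, so almost
    no node falls in the outer phase band (further than ``flag_outer_band``
    periods from the nearest plane).  When two patterns are superimposed,
    the nodes of the other lattice are uniform in phase and at least
    ``~(1 - w)/2`` of them land in the outer band, whatever the mixing
    fraction ``w``.  Each family is also evaluated at twice its period, so
    that finding a half-period harmonic of the true family does not
    penalise a single-lattice image.  The image is flagged when the
    smallest outer-band fraction over all detected families exceeds
    ``flag_outer_fraction`` — or when a well-populated image
    (``flag_min_nodes_unexplained`` nodes or more) yields no accepted
    family at all, the signature of mutual dilution of two patterns.

    Images with fewer than ``min_spots_multipattern`` spots return False:
    too little evidence to call.
    """
    cfg = cfg or SegmentationConfig()
    spots = np.asarray(spots, dtype=float).reshape(-1, 4)
    if len(spots) < cfg.min_spots_multipattern:
        return False
    nodes = spots_to_nodes(spots[:, :2], det)
    if len(nodes) > cfg.flag_max_nodes:
        pick = np.linspace(0, len(nodes) - 1, cfg.flag_max_nodes).astype(int)
        nodes = nodes[pick]
    pcfg = PlanesConfig(
        n_directions=cfg.flag_n_directions,
        top_k=cfg.flag_top_k,
        refine_max_eval=cfg.flag_refine_max_eval,
        min_nodes=min(cfg.min_spots_multipattern, 20),
    )
    families = find_planes(nodes, pcfg)
    if not families:
        return len(nodes) >= cfg.flag_min_nodes_unexplained
    outer = 1.0
    for pv in families:
        proj = nodes @ pv.direction
        for period in (pv.frequency, 2.0 * pv.frequency):
            phase = proj * period
            err = np.abs(phase - np.round(phase))
            outer = min(outer, float(np.mean(err > cfg.flag_outer_band)))
    return outer > cfg.flag_outer_fraction


def cell_similarity(
    spots_a: np.ndarray, spots_b: np.ndarray, radius_px: float = 4.0
) -> float:
    """Fraction of the larger spot list matched one-to-one in the other.

    Matches are nearest-neighbour within ``radius_px``, assigned greedily
    by increasing distance so that each spot is used at most once.
    Normalising by the larger list makes the measure strict about
    asymmetric overlaps: an image whose spots are a union of one
    neighbour's pattern with a second, stronger pattern scores low against
    that neighbour, rather than trivially high because the neighbour's
    list happens to be the smaller one.
    """
    a = np.asarray(spots_a, dtype=float).reshape(-1, 4)[:, :2]
    b = np.asarray(spots_b, dtype=float).reshape(-1, 4)[:, :2]
    if len(a) == 0 or len(b) == 0:
        return 0.0
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    tree = cKDTree(large)
    dist, idx = tree.query(small, k=1, distance_upper_bound=radius_px)
    order = np.argsort(dist)
    used = set()
    matched = 0
    for s in order:
        if not np.isfinite(dist[s]):
            break
        if idx[s] in used:
            # nearest target taken; try the next neighbour within radius
            cands = tree.query_ball_point(small[s], radius_px)
            free = [c for c in cands if c not in used]
            if not free:
                continue
            d2 = np.linalg.norm(large[free] - small[s], axis=1)
            used.add(free[int(np.argmin(d2))])
        else:
            used.add(int(idx[s]))
        matched += 1
    return matched / len(large)


def multipattern_cells(
    scan: MeshScan, cfg: SegmentationConfig | None = None
) -> set[tuple[int, int]]:
    """Cells of a scan flagged as containing superimposed patterns."""
    cfg = cfg or SegmentationConfig()
    return {
        (c.iu, c.iv)
        for c in scan.cells
        if c.cell_score > cfg.min_score
        and multipattern_flag(c.spots, scan.detector, cfg)
    }


def segment(
    scan: MeshScan,
    cfg: SegmentationConfig | None = None,
    multipattern: set[tuple[int, int]] | None = None,
) -> list[CrystalRegion]:
    """Dissect a scored scan into ranked individual-crystal regions.

    Single-linkage agglomeration on the graph whose vertices are
    diffracting, single-pattern cells and whose edges connect 4-adjacent
    cells with pattern similarity at or above the threshold.  Each
    connected component becomes a region labelled 1..K in order of
    decreasing integrated score (ties broken by centroid position); the
    recommended aperture is the smallest available at least as large as
    the region's smaller extent.
    """
    cfg = cfg or SegmentationConfig()
    if multipattern is None:
        multipattern = multipattern_cells(scan, cfg)
    eligible = {
        (c.iu, c.iv): c
        for c in scan.cells
        if c.cell_score > cfg.min_score and (c.iu, c.iv) not in multipattern
    }
    # union-find over similarity-linked 4-adjacent cells
    parent = {k: k for k in eligible}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for (iu, iv), rec in eligible.items():
        for nb in ((iu + 1, iv), (iu, iv + 1)):
            other = eligible.get(nb)
            if other is None:
                continue
            sim = cell_similarity(rec.spots, other.spots, cfg.match_radius_px)
            if sim >= cfg.similarity_threshold:
                parent[find((iu, iv))] = find(nb)

    components: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for k in eligible:
        components.setdefault(find(k), []).append(k)

    geometry = scan.geometry
    step = geometry.step
    cell_by_index = {(c.iu, c.iv): c for c in scan.cells}
    raw = []
    for cells in components.values():
        recs = [eligible[c] for c in cells]
        # multi-pattern neighbours belong partly to this crystal: include
        # them in the centroid and extents at half weight so that a
        # crystal truncated by an overlap zone is not localised off-centre
        halo = set()
        for iu, iv in cells:
            for nb in ((iu + 1, iv), (iu - 1, iv), (iu, iv + 1), (iu, iv - 1)):
                if nb in multipattern:
                    halo.add(nb)
        pos_cells = list(cells) + sorted(halo)
        scores = np.concatenate(
            [
                [r.cell_score for r in recs],
                [0.5 * cell_by_index[c].cell_score for c in sorted(halo)],
            ]
        )
        total = float(sum(r.cell_score for r in recs))
        uu, vv = geometry.cell_centre(
            np.array([c[0] for c in pos_cells]), np.array([c[1] for c in pos_cells])
        )
        wsum = float(scores.sum())
        w = (
            scores / wsum
            if wsum > 0
            else np.full(len(pos_cells), 1.0 / len(pos_cells))
        )
        centroid = (float(uu @ w), float(vv @ w))
        ius = [c[0] for c in pos_cells]
        ivs = [c[1] for c in pos_cells]
        extents = (
            (max(ius) - min(ius) + 1) * step,
            (max(ivs) - min(ivs) + 1) * step,
        )
        all_spots = np.vstack([r.spots for r in recs if len(r.spots)] or [np.empty((0, 4))])
        # neighbouring cells of one crystal record the same reflections;
        # pool unique spot positions so duplicated reflections do not
        # inflate the projection histograms (and break the Rayleigh null)
        if len(all_spots):
            _, uniq_idx = np.unique(
                np.round(all_spots[:, :2]).astype(int), axis=0, return_index=True
            )
            nodes = spots_to_nodes(all_spots[uniq_idx, :2], scan.detector)
        else:
            nodes = np.empty((0, 3))
        min_extent_um = min(extents) * 1000.0
        fitting = [a for a in cfg.apertures_um if a >= min_extent_um]
        beam = min(fitting) if fitting else max(cfg.apertures_um)
        raw.append((set(cells), centroid, extents, total, nodes, beam))

    raw.sort(key=lambda r: (-r[3], r[1]))
    return [
        CrystalRegion(
            label=i + 1,
            cells=cells,
            centroid=centroid,
            extents=extents,
            integral_score=total,
            nodes=nodes,
            beam_size=beam,
        )
        for i, (cells, centroid, extents, total, nodes, beam) in enumerate(raw)
    ]


def build_label_map(
    scan: MeshScan,
    regions: list[CrystalRegion],
    multipattern: set[tuple[int, int]] = frozenset(),
) -> np.ndarray:
    """(n_v, n_u) integer label matrix: 0 / 999 / region labels."""
    labels = np.zeros((scan.geometry.n_v, scan.geometry.n_u), dtype=int)
    for iu, iv in multipattern:
        labels[iv, iu] = 999
    for r in regions:
        for iu, iv in r.cells:
            labels[iv, iu] = r.label
    return labels


def pair_candidates(
    regions1: list[CrystalRegion],
    regions2: list[CrystalRegion],
    omega: float,
    step: float,
    tol_cells: float | None = None,
    cfg: SegmentationConfig | None = None,
) -> list[PairCandidate]:
    """All cross-scan region pairs compatible along the rotation axis.

    The ``u`` (rotation-axis) centroid coordinate of a crystal is invariant
    between scans, so any pair whose ``u`` centroids agree within
    ``tol_cells * step`` is geometrically possible; each candidate carries
    a provisional triangulated 3D position.  ``omega`` is the rotation from
    scan 1 to scan 2 in degrees.
    """
    cfg = cfg or SegmentationConfig()
    if tol_cells is None:
        tol_cells = cfg.pairing_tolerance_cells
    tol = tol_cells * step
    out = []
    for ra in regions1:
        for rb in regions2:
            gap = abs(ra.centroid[0] - rb.centroid[0])
            if gap <= tol:
                pos = triangulate_centre(
                    (ra.centroid[1], ra.centroid[0]),
                    (rb.centroid[1], rb.centroid[0]),
                    omega,
                )
                out.append(
                    PairCandidate(
                        region_a=ra, region_b=rb, z_gap=gap, provisional_3d=pos
                    )
                )
    return out
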