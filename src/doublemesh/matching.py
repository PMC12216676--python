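"""Cross-scan crystal identity validation and the end-to-end pipeline.

A crystal's plane vectors (periodic plane-family normals scaled by the
family period) are fixed to its lattice, so between the two mesh scans of
a run they rotate exactly by the known goniometer angle difference.  The
``check()`` test therefore rotates a plane vector from one scan into the
frame of the other, projects the other region's reciprocal-space nodes
onto it, and asks whether the Fourier spectrum of the projection histogram
peaks at the spatial frequency the vector length dictates.  On the unit
Rayleigh scale of :mod:`doublemesh.planes`, a windowed peak above 5
(null tail ``exp(-25/2) ≈ 4e-6``) counts as a hit; a candidate pair is
declared the same crystal when the best score over all (plane vector,
pattern) combinations in both rotation directions clears that threshold.

Frame convention (see :mod:`doublemesh.geometry`): node sets observed at
goniometer angle ``omega`` are related by ``q2 = R(-alpha) q1`` with
``alpha = omega2 - omega1``, so "forward" rotation of scan-1 vectors into
the scan-2 frame applies ``R(-alpha)`` and the reverse applies ``R(+alpha)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crystal_map import (
    PairCandidate,
    SegmentationConfig,
    multipattern_cells,
    pair_candidates,
    segment,
)
from .geometry import CrystalPosition3D, rotate_about_axis
from .io_meshscan import MeshScan
from .planes import (
    PlanesConfig,
    PlaneVector,
    find_planes,
    make_histogram,
    project_nodes,
    spectrum,
)

__all__ = [
    "MatchingConfig",
    "MatchResult",
    "RunResult",
    "check",
    "match_pair",
    "run_doublemesh",
]


@dataclass(frozen=True)
class MatchingConfig:
    """Decision threshold and peak-search window for check()."""

    match_threshold: float = 5.0
    window_bins: float = 1.5


@dataclass
class MatchResult:
    """Outcome of cross-scan validation for one candidate pair."""

    pair: PairCandidate
    max_score: float
    matched: bool
    position: CrystalPosition3D
    integral_score: float  # combined diffraction strength of the two regions
    beam_size: float  # µm, conservative (smaller) of the two recommendations
    rank: int | None = None


@dataclass
class RunResult:
    """Everything the pipeline produced for one double mesh scan."""

    regions1: list
    regions2: list
    multipattern1: set
    multipattern2: set
    planes1: dict[int, list[PlaneVector]]
    planes2: dict[int, list[PlaneVector]]
    candidates: list[PairCandidate]
    results: list[MatchResult]

    @property
    def matches(self) -> list[MatchResult]:
        """Matched results in collection (rank) order."""
        return sorted(
            (m for m in self.results if m.matched), key=lambda m: m.rank
        )


def check(
    plane_vector: PlaneVector | np.ndarray,
    nodes: np.ndarray,
    planes_cfg: PlanesConfig | None = None,
    matching_cfg: MatchingConfig | None = None,
) -> float:
    """Score how well a (rotated) plane vector fits another node set.

    The nodes are projected onto the vector direction; the projection
    histogram (spanning this node set's own data range, so the frequency
    axis is aligned by physical units rather than reused bins) is
    normalised and Fourier transformed exactly as in the plane search, and
    the maximum unit-Rayleigh score within ``window_bins`` Fourier bins of
    the expected frequency ``|v|`` is returned.

    Raises ``ValueError`` if ``|v|`` exceeds the Nyquist period for the
    configured bin width.  Returns 0.0 when the node set is too small or
    the expected frequency falls in the masked low-frequency region.
    """
    pcfg = planes_cfg or PlanesConfig()
    mcfg = matching_cfg or MatchingConfig()
    v = plane_vector.v if isinstance(plane_vector, PlaneVector) else np.asarray(plane_vector, float)
    f_expected = float(np.linalg.norm(v))
    if f_expected <= 0:
        raise ValueError("plane vector has zero length")
    if f_expected > pcfg.nyquist_frequency:
        raise ValueError(
            f"expected frequency {f_expected:.1f} Å beyond the Nyquist bound "
            f"{pcfg.nyquist_frequency:.1f} Å for bin width {pcfg.bin_width}"
        )
    nodes = np.asarray(nodes, dtype=float)
    if len(nodes) < pcfg.min_nodes:
        return 0.0
    coords = project_nodes(nodes, v / f_expected)
    ph = make_histogram(coords, pcfg.bin_width, pcfg)
    spec = spectrum(ph, pcfg)
    n_bins = ph.n_bins
    k_expected = f_expected * n_bins * ph.bin_width
    k = np.arange(len(spec.score))
    window = spec.valid & (np.abs(k - k_expected) <= mcfg.window_bins)
    if not np.any(window):
        return 0.0
    return float(np.max(spec.score[window]))


def match_pair(
    candidate: PairCandidate,
    planes1: list[PlaneVector],
    planes2: list[PlaneVector],
    alpha: float,
    planes_cfg: PlanesConfig | None = None,
    matching_cfg: MatchingConfig | None = None,
) -> MatchResult:
    """Decide whether a candidate pair is the same crystal.

    Scan-1 plane vectors are rotated forward into the scan-2 frame and
    checked against the scan-2 region's nodes; scan-2 vectors are rotated
    backward and checked against scan-1.  The decision uses the maximum
    score over both directions; with no plane vectors on either side the
    score is 0 and the pair is unmatched.
    """
    mcfg = matching_cfg or MatchingConfig()
    pcfg = planes_cfg or PlanesConfig()
    nodes1 = candidate.region_a.nodes
    nodes2 = candidate.region_b.nodes
    scores = [0.0]
    for pv in planes1:
        if pv.frequency <= pcfg.nyquist_frequency:
            scores.append(
                check(rotate_about_axis(pv.v, -alpha), nodes2, pcfg, mcfg)
            )
    for pv in planes2:
        if pv.frequency <= pcfg.nyquist_frequency:
            scores.append(
                check(rotate_about_axis(pv.v, +alpha), nodes1, pcfg, mcfg)
            )
    max_score = float(max(scores))
    return MatchResult(
        pair=candidate,
        max_score=max_score,
        matched=max_score > mcfg.match_threshold,
        position=candidate.provisional_3d,
        integral_score=candidate.region_a.integral_score
        + candidate.region_b.integral_score,
        beam_size=min(candidate.region_a.beam_size, candidate.region_b.beam_size),
    )


def run_doublemesh(
    scan1: MeshScan,
    scan2: MeshScan,
    seg_cfg: SegmentationConfig | None = None,
    planes_cfg: PlanesConfig | None = None,
    matching_cfg: MatchingConfig | None = None,
) -> RunResult:
    """Full pipeline: segment → find planes → pair → validate → rank.

    The two scans must share grid dimensions and step.  Matched results
    are ranked (1 = best) by the combined integrated diffraction score of
    their two regions, the order in which data collection should visit
    the positions.
    """
    g1, g2 = scan1.geometry, scan2.geometry
    if (g1.n_u, g1.n_v, g1.step) != (g2.n_u, g2.n_v, g2.step):
        raise ValueError("the two scans of a run must share grid dims and step")
    seg_cfg = seg_cfg or SegmentationConfig()
    planes_cfg = planes_cfg or PlanesConfig()
    matching_cfg = matching_cfg or MatchingConfig()
    alpha = g2.omega - g1.omega

    mp1 = multipattern_cells(scan1, seg_cfg)
    mp2 = multipattern_cells(scan2, seg_cfg)
    regions1 = segment(scan1, seg_cfg, multipattern=mp1)
    regions2 = segment(scan2, seg_cfg, multipattern=mp2)
    planes1 = {r.label: find_planes(r.nodes, planes_cfg) for r in regions1}
    planes2 = {r.label: find_planes(r.nodes, planes_cfg) for r in regions2}
    candidates = pair_candidates(
        regions1, regions2, alpha, g1.step, cfg=seg_cfg
    )
    results = [
        match_pair(
            c,
            planes1[c.region_a.label],
            planes2[c.region_b.label],
            alpha,
            planes_cfg,
            matching_cfg,
        )
        for c in candidates
    ]
    matched = sorted(
        (m for m in results if m.matched), key=lambda m: -m.integral_score
    )
    for rank, m in enumerate(matched, start=1):
        m.rank = rank
    return RunResult(
        regions1=regions1,
        regions2=regions2,
        multipattern1=mp1,
        multipattern2=mp2,
        planes1=planes1,
        planes2=planes2,
        candidates=candidates,
        results=results,
    )
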