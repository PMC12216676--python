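"""Synthetic double-mesh-scan generator with exact ground truth.

A virtual sample holder contains several crystals with random unit cells,
orientations, sizes and 3D positions.  For each of the two goniometer
angles the generator:

* enumerates the reciprocal-lattice points of every crystal and keeps those
  whose distance from the Ewald sphere is within the excitation tolerance
  ``epsilon`` (a binary in/out stand-in for mosaicity and bandwidth on a
  still image);
* projects each excited node along its diffracted-beam direction onto the
  flat detector, recording crystal id and Miller indices per spot;
* rasterises the crystal's bounding box onto the scan grid — a grid cell
  receives the crystal's spot list when its centre falls inside the
  projected box — and merges spot lists where crystals overlap;
* adds uniform noise spots per cell, emulating salt/ice/background picks.

Everything is driven by one :class:`numpy.random.Generator` seed, making
scans byte-reproducible, and the returned :class:`GroundTruth` records the
seeded positions, per-cell contributors and true cross-scan pairs that the
segmentation, periodicity and matching stages are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import DetectorGeometry, ScanGeometry, rotate_about_axis
from .io_meshscan import GridCellRecord, MeshScan
from .crystal_map import cell_score

__all__ = [
    "SyntheticCrystal",
    "SimulationConfig",
    "GroundTruth",
    "reciprocal_basis",
    "diffracting_nodes",
    "random_crystals",
    "render_double_mesh",
]


@dataclass(frozen=True)
class SyntheticCrystal:
    """One virtual crystal: cell, orientation, position and size."""

    cell: tuple[float, float, float, float, float, float]  # a b c alpha beta gamma
    orientation: np.ndarray  # (3, 3) orthonormal
    position: np.ndarray  # (x, y, z) mm, goniometer-zero frame
    half_extents: np.ndarray  # (3,) mm
    intensity_scale: float = 100.0

    def __post_init__(self) -> None:
        a, b, c = self.cell[:3]
        if min(a, b, c) <= 0:
            raise ValueError(f"cell lengths must be > 0: {self.cell}")
        if np.any(np.asarray(self.half_extents) <= 0):
            raise ValueError(f"half_extents must be > 0: {self.half_extents}")
        R = np.asarray(self.orientation)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("orientation must be orthonormal")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic double mesh scan.

    Defaults emulate a typical multi-crystal mount: a 20x20 grid at 10 µm
    pitch, crystals of 10–30 µm with unit cells of 50–100 Å, an excitation
    tolerance of 0.002 Å⁻¹ and a handful of noise spots per image.
    """

    n_crystals: int = 5
    cell_length_range: tuple[float, float] = (50.0, 100.0)  # Å
    cell_angle_range: tuple[float, float] = (85.0, 95.0)  # degrees
    crystal_half_extent_range: tuple[float, float] = (0.005, 0.015)  # mm
    min_separation: float = 0.03  # mm between crystal centres
    epsilon: float = 0.002  # Å⁻¹ excitation tolerance
    d_min: float = 2.5  # Å resolution cutoff
    noise_spots_per_cell: int = 5
    background: float = 10.0
    omegas: tuple[float, float] = (0.0, 60.0)
    seed: int = 0
    detector: DetectorGeometry = field(
        default_factory=lambda: DetectorGeometry(
            wavelength=1.0,
            distance=150.0,
            beam_centre=(1024.0, 1024.0),
            pixel_size=0.075,
            detector_shape=(2048, 2048),
        )
    )
    # None centres the vertical grid axis on the rotation axis, so that
    # sample points remain inside the grid at every goniometer angle
    grid_origin: tuple[float, float] | None = None
    step: float = 0.01  # mm
    n_u: int = 32
    n_v: int = 28

    def __post_init__(self) -> None:
        if self.grid_origin is None:
            self.grid_origin = (0.0, -0.5 * (self.n_v - 1) * self.step)

    def scan_geometry(self, omega: float) -> ScanGeometry:
        return ScanGeometry(
            omega=omega,
            grid_origin=self.grid_origin,
            step=self.step,
            n_u=self.n_u,
            n_v=self.n_v,
        )


@dataclass
class GroundTruth:
    """Exact record of what the simulator put where."""

    crystals: list[SyntheticCrystal]
    # per scan: {crystal index: set of (iu, iv) footprint cells}
    footprints: list[dict[int, set[tuple[int, int]]]]
    # per scan: {(iu, iv): sorted crystal indices contributing spots}
    contributors: list[dict[tuple[int, int], list[int]]]
    # crystal indices visible (>= 1 cell) in both scans
    true_pairs: list[int]

    def to_jsonable(self) -> dict:
        return {
            "crystals": [
                {
                    "cell": list(map(float, c.cell)),
                    "position_mm": [float(x) for x in c.position],
                    "half_extents_mm": [float(x) for x in c.half_extents],
                }
                for c in self.crystals
            ],
            "footprints": [
                {str(k): sorted(map(list, v)) for k, v in fp.items()}
                for fp in self.footprints
            ],
            "true_pairs": list(self.true_pairs),
        }


def reciprocal_basis(cell: tuple[float, ...]) -> np.ndarray:
    """Reciprocal basis vectors (columns, Å⁻¹) of a unit cell."""
    uc = gemmi.UnitCell(*cell)
    ortho = np.array(uc.orth.mat.tolist())  # columns are a, b, c in cartesian
    return np.linalg.inv(ortho).T


def diffracting_nodes(
    crystal: SyntheticCrystal,
    omega: float,
    det: DetectorGeometry,
    epsilon: float,
    d_min: float = 2.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reciprocal-lattice points excited on a still at goniometer angle omega.

    Enumerates integer Miller triples inside the resolution sphere
    ``|q| <= 1/d_min``, rotates them into the scan's laboratory frame and
    keeps those within ``epsilon`` of the Ewald sphere whose diffracted
    beam actually hits the detector.

    Returns
    -------
    q : (n, 3) array — excited node vectors, laboratory frame of the scan
    hkl : (n, 3) int array — Miller indices
    xy_px : (n, 2) array — spot positions on the detector, pixels
    """
    lam = det.wavelength
    q_max = 1.0 / d_min
    B = reciprocal_basis(crystal.cell)
    A = rotate_about_axis(
        (np.asarray(crystal.orientation) @ B).T, -omega
    ).T  # columns = reciprocal basis in the scan frame
    a, b, c = crystal.cell[:3]
    hmax = [int(np.floor(l * q_max)) + 1 for l in (a, b, c)]
    hs = np.stack(
        np.meshgrid(
            np.arange(-hmax[0], hmax[0] + 1),
            np.arange(-hmax[1], hmax[1] + 1),
            np.arange(-hmax[2], hmax[2] + 1),
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)
    hs = hs[np.any(hs != 0, axis=1)]
    q = hs @ A.T
    qn = np.linalg.norm(q, axis=1)
    keep = qn <= q_max
    q, hs = q[keep], hs[keep]
    k_in = np.array([1.0 / lam, 0.0, 0.0])
    excite = np.abs(np.linalg.norm(q + k_in, axis=1) - 1.0 / lam) <= epsilon
    q, hs = q[excite], hs[excite]
    # diffracted-beam direction and detector intersection
    out = q + k_in
    out_norm = np.linalg.norm(out, axis=1, keepdims=True)
    u_hat = out / out_norm
    forward = u_hat[:, 0] > 0.05
    q, hs, u_hat = q[forward], hs[forward], u_hat[forward]
    t = det.distance / u_hat[:, 0]
    y_mm = t * u_hat[:, 1]
    z_mm = t * u_hat[:, 2]
    cx, cy = det.beam_centre
    x_px = cx + z_mm / det.pixel_size
    y_px = cy + y_mm / det.pixel_size
    nx, ny = det.detector_shape
    on_det = (x_px >= 0) & (x_px <= nx - 1) & (y_px >= 0) & (y_px <= ny - 1)
    return q[on_det], hs[on_det], np.column_stack([x_px, y_px])[on_det]


def random_crystals(cfg: SimulationConfig, rng: np.random.Generator) -> list[SyntheticCrystal]:
    """Draw crystals with rejection-sampled minimum 3D separation.

    The (x, y) position — depth along the beam and height — is sampled in
    a disc around the rotation axis small enough that the whole crystal
    footprint (not just its centre) stays inside the vertical extent of
    the grid at any goniometer angle; the rotation-axis coordinate z is
    uniform over the interior of the grid.
    """
    u0, _ = cfg.grid_origin
    z_lo, z_hi = u0 + cfg.step, u0 + (cfg.n_u - 2) * cfg.step
    margin = np.sqrt(2.0) * cfg.crystal_half_extent_range[1] + cfg.step
    r_max = 0.5 * (cfg.n_v - 1) * cfg.step - margin
    crystals: list[SyntheticCrystal] = []
    positions: list[np.ndarray] = []
    attempts = 0
    while len(crystals) < cfg.n_crystals and attempts < 200 * cfg.n_crystals:
        attempts += 1
        rho = r_max * np.sqrt(rng.uniform())
        ang = rng.uniform(0.0, 2.0 * np.pi)
        pos = np.array(
            [rho * np.cos(ang), rho * np.sin(ang), rng.uniform(z_lo, z_hi)]
        )
        if positions and np.min(
            np.linalg.norm(np.asarray(positions) - pos, axis=1)
        ) < cfg.min_separation:
            continue
        lengths = rng.uniform(*cfg.cell_length_range, size=3)
        angles = rng.uniform(*cfg.cell_angle_range, size=3)
        orientation = Rotation.random(random_state=rng).as_matrix()
        half = rng.uniform(*cfg.crystal_half_extent_range, size=3)
        crystals.append(
            SyntheticCrystal(
                cell=(*lengths, *angles),
                orientation=orientation,
                position=pos,
                half_extents=half,
                intensity_scale=float(rng.uniform(50.0, 200.0)),
            )
        )
        positions.append(pos)
    return crystals


def _footprint_cells(
    crystal: SyntheticCrystal, scan: ScanGeometry
) -> dict[tuple[int, int], float]:
    """Grid cells covered by the crystal's projected bounding box.

    A cell belongs to the footprint when any part of the projected box
    overlaps it — any illuminated sliver of crystal diffracts; its value
    is the fractional overlap area of the cell with the box, which grades
    the diffraction signal towards the crystal edge the way real
    mesh-scan heat maps fade out, and is what lets score-weighted region
    centroids localise a crystal to better than one grid step.
    """
    corners = crystal.position + np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    ) * crystal.half_extents
    lab = rotate_about_axis(corners, -scan.omega)
    y_lo, y_hi = lab[:, 1].min(), lab[:, 1].max()
    z_lo, z_hi = lab[:, 2].min(), lab[:, 2].max()
    u0, v0 = scan.grid_origin
    half = scan.step / 2.0
    cells: dict[tuple[int, int], float] = {}
    for iu in range(scan.n_u):
        zc = u0 + iu * scan.step
        oz = min(z_hi, zc + half) - max(z_lo, zc - half)
        if oz <= 0:
            continue
        for iv in range(scan.n_v):
            yc = v0 + iv * scan.step
            oy = min(y_hi, yc + half) - max(y_lo, yc - half)
            if oy <= 0:
                continue
            cells[(iu, iv)] = (oz * oy) / (scan.step * scan.step)
    return cells


def render_double_mesh(
    cfg: SimulationConfig,
    crystals: list[SyntheticCrystal] | None = None,
) -> tuple[MeshScan, MeshScan, GroundTruth]:
    """Simulate the two mesh scans of one run plus exact ground truth.

    ``crystals`` overrides the random sample, e.g. to rearrange or
    hand-craft the virtual holder.
    """
    rng = np.random.default_rng(cfg.seed)
    if crystals is None:
        crystals = random_crystals(cfg, rng)
    nx, ny = cfg.detector.detector_shape
    scans: list[MeshScan] = []
    footprints: list[dict[int, set[tuple[int, int]]]] = []
    contributors: list[dict[tuple[int, int], list[int]]] = []
    for omega in cfg.omegas:
        geometry = cfg.scan_geometry(omega)
        fp: dict[int, set[tuple[int, int]]] = {}
        per_cell: dict[tuple[int, int], list[np.ndarray]] = {}
        contrib: dict[tuple[int, int], list[int]] = {}
        for ci, crystal in enumerate(crystals):
            _, _, xy = diffracting_nodes(
                crystal, omega, cfg.detector, cfg.epsilon, cfg.d_min
            )
            if len(xy) == 0:
                continue
            cells = _footprint_cells(crystal, geometry)
            if not cells:
                continue
            intensities = crystal.intensity_scale * rng.exponential(1.0, size=len(xy))
            fp[ci] = set(cells)
            for cell, coverage in cells.items():
                spots = np.column_stack(
                    [xy, coverage * intensities, np.full(len(xy), cfg.background)]
                )
                per_cell.setdefault(cell, []).append(spots)
                contrib.setdefault(cell, []).append(ci)
        records = []
        for iu in range(geometry.n_u):
            for iv in range(geometry.n_v):
                parts = per_cell.get((iu, iv), [])
                n_noise = cfg.noise_spots_per_cell
                if n_noise > 0:
                    noise = np.column_stack(
                        [
                            rng.uniform(0, nx - 1, size=n_noise),
                            rng.uniform(0, ny - 1, size=n_noise),
                            rng.uniform(0.5, 3.0, size=n_noise) * cfg.background,
                            np.full(n_noise, cfg.background),
                        ]
                    )
                    parts = parts + [noise]
                spots = (
                    np.vstack(parts) if parts else np.empty((0, 4), dtype=float)
                )
                # cells containing no crystal pattern score 0: noise-only
                # images are below any sensible detection threshold
                score = cell_score(spots) if (iu, iv) in per_cell else 0.0
                records.append(
                    GridCellRecord(iu=iu, iv=iv, cell_score=score, spots=spots)
                )
        scans.append(
            MeshScan(geometry=geometry, detector=cfg.detector, cells=records)
        )
        footprints.append(fp)
        contributors.append({k: sorted(v) for k, v in contrib.items()})
    true_pairs = sorted(set(footprints[0]) & set(footprints[1]))
    truth = GroundTruth(
        crystals=crystals,
        footprints=footprints,
        contributors=contributors,
        true_pairs=true_pairs,
    )
    return scans[0], scans[1], truth
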