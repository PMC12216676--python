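"""Shared oracles and fixtures-in-code for the test suite."""

from __future__ import annotations

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from doublemesh.geometry import rotate_about_axis
from doublemesh.simulate import SyntheticCrystal


def make_crystal(
    seed: int,
    cell_length_range=(50.0, 100.0),
    cell_angle_range=(85.0, 95.0),
    position=(0.0, 0.0, 0.1),
    half_extents=(0.01, 0.01, 0.01),
) -> SyntheticCrystal:
    """One random crystal, reproducibly from a seed."""
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(*cell_length_range, size=3)
    angles = rng.uniform(*cell_angle_range, size=3)
    return SyntheticCrystal(
        cell=(*lengths, *angles),
        orientation=Rotation.random(random_state=rng).as_matrix(),
        position=np.asarray(position, dtype=float),
        half_extents=np.asarray(half_extents, dtype=float),
    )


def true_plane_families(
    crystal: SyntheticCrystal,
    omega: float,
    period_min: float = 25.0,
    period_max: float = 260.0,
    index_max: int = 3,
) -> list[tuple[np.ndarray, float]]:
    """Ground-truth plane families of a crystal's reciprocal-lattice subset.

    The families of parallel planes containing all reciprocal-lattice
    points have normals along *direct*-lattice vectors t = u a + v b + w c
    (q . t is integer for every node) and period |t| in Å.  Returns
    (unit normal in the scan's laboratory frame, period) for all primitive
    direct vectors with period inside the detectable band.
    """
    M = np.array(gemmi.UnitCell(*crystal.cell).orth.mat.tolist())
    A = rotate_about_axis((np.asarray(crystal.orientation) @ M).T, -omega).T
    out = []
    rng_idx = range(-index_max, index_max + 1)
    for u in rng_idx:
        for v in rng_idx:
            for w in rng_idx:
                if (u, v, w) == (0, 0, 0):
                    continue
                t = A @ np.array([u, v, w], dtype=float)
                L = float(np.linalg.norm(t))
                if period_min < L < period_max:
                    out.append((t / L, L))
    return out


def matches_true_family(plane_vector, families, angle_tol_deg=1.0, freq_tol=0.02) -> bool:
    """Whether a detected plane vector agrees with any ground-truth family."""
    for normal, period in families:
        cosang = abs(float(plane_vector.direction @ normal))
        ang = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
        if ang < angle_tol_deg and abs(plane_vector.frequency - period) / period < freq_tol:
            return True
    return False


def region_to_crystal(regions, contributors) -> dict[int, int | None]:
    """Map region labels to the simulator crystal that dominates them."""
    out: dict[int, int | None] = {}
    for region in regions:
        counts: dict[int, int] = {}
        for cell in region.cells:
            for ci in contributors.get(cell, []):
                counts[ci] = counts.get(ci, 0) + 1
        out[region.label] = max(counts, key=counts.get) if counts else None
    return out


def lattice_free_nodes(seed: int, n: int, detector) -> np.ndarray:
    """Nodes reconstructed from uniformly random detector positions.

    A lattice-free Ewald-sphere subset: the null model for the
    periodicity search.
    """
    rng = np.random.default_rng(seed)
    nx, ny = detector.detector_shape
    xy = np.column_stack(
        [rng.uniform(0, nx - 1, size=n), rng.uniform(0, ny - 1, size=n)]
    )
    from doublemesh.geometry import spots_to_nodes

    return spots_to_nodes(xy, detector)
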