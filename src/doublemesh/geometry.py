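"""Experimental coordinate frames and the geometry of double mesh scans.

Laboratory frame (right-handed)
-------------------------------
``x`` — incident beam direction of the *first* scan,
``y`` — laboratory vertical,
``z`` — goniometer rotation axis (horizontal).

A mesh scan rasters the sample holder over a 2D grid; the grid axis ``u``
runs along the rotation axis (lab ``z``) and the grid axis ``v`` along the
laboratory vertical (lab ``y``).  Between the two scans of a run the sample
is rotated about ``z`` by the angle difference of the two goniometer
settings, so the ``u``/``z`` coordinate of any sample point is invariant
between scans — which is what makes geometric pair candidates possible.

Convention: a point ``p`` given in the goniometer-zero (sample) frame is
observed, in a scan taken at goniometer angle ``omega``, at the laboratory
position ``R(-omega) @ p`` where ``R`` is :func:`rotate_about_axis`.  The
triangulation formula below is the exact inverse of this forward model and
is pinned against it by round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectorGeometry",
    "ScanGeometry",
    "Spot",
    "CrystalPosition3D",
    "GeometryError",
    "PairingError",
    "spot_to_node",
    "spots_to_nodes",
    "rotate_about_axis",
    "rotation_matrix",
    "scan_plane_coords",
    "triangulate_centre",
]


class GeometryError(ValueError):
    """Raised for invalid or degenerate experimental geometry."""


class PairingError(ValueError):
    """Raised when two 2D regions cannot represent the same 3D point."""


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat detector orthogonal to the beam, offset only by the beam centre.

    Parameters
    ----------
    wavelength : float
        X-ray wavelength in Å.
    distance : float
        Sample-to-detector distance in mm.
    beam_centre : tuple of float
        Direct-beam position ``(cx, cy)`` in pixels.
    pixel_size : float
        Pixel edge in mm (square pixels).
    detector_shape : tuple of int
        ``(nx, ny)`` pixel counts.  Pixel column ``x_px`` maps to lab ``z``
        (rotation axis) and pixel row ``y_px`` to lab ``y`` (vertical).
    """

    wavelength: float
    distance: float
    beam_centre: tuple[float, float]
    pixel_size: float
    detector_shape: tuple[int, int] = (2048, 2048)

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise GeometryError(f"wavelength must be > 0, got {self.wavelength}")
        if self.distance <= 0:
            raise GeometryError(f"distance must be > 0, got {self.distance}")
        if self.pixel_size <= 0:
            raise GeometryError(f"pixel_size must be > 0, got {self.pixel_size}")
        cx, cy = self.beam_centre
        nx, ny = self.detector_shape
        if not (0 <= cx < nx and 0 <= cy < ny):
            raise GeometryError(
                f"beam_centre {self.beam_centre} outside detector {self.detector_shape}"
            )


@dataclass(frozen=True)
class ScanGeometry:
    """One mesh scan: goniometer angle plus the raster grid.

    ``grid_origin`` is the physical position, in mm, of cell ``(0, 0)``;
    cell ``(iu, iv)`` is centred at ``grid_origin + (iu, iv) * step``.
    The step equals the beam size.  ``u`` is parallel to the rotation axis,
    ``v`` to the laboratory vertical.
    """

    omega: float  # degrees
    grid_origin: tuple[float, float] = (0.0, 0.0)  # (u0, v0) mm
    step: float = 0.01  # mm
    n_u: int = 20
    n_v: int = 20

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise GeometryError(f"step must be > 0, got {self.step}")
        if self.n_u < 1 or self.n_v < 1:
            raise GeometryError(f"grid dims must be >= 1, got {self.n_u}x{self.n_v}")

    def cell_centre(self, iu, iv) -> tuple[np.ndarray, np.ndarray]:
        """Physical (u, v) mm position of the centre of cell(s) (iu, iv)."""
        u0, v0 = self.grid_origin
        return u0 + np.asarray(iu) * self.step, v0 + np.asarray(iv) * self.step


@dataclass(frozen=True)
class Spot:
    """A diffraction spot found on one still image."""

    x_px: float
    y_px: float
    intensity: float = 1.0
    background: float = 0.0


@dataclass(frozen=True)
class CrystalPosition3D:
    """Crystal centring position in the frame of the first scan (mm).

    ``x`` lies along the beam of scan 1, ``y`` is vertical and ``z`` runs
    along the rotation axis.
    """

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def rotation_matrix(angle_deg: float) -> np.ndarray:
    """Right-handed rotation about the goniometer (z) axis.

    Positive angles rotate ``+x`` towards ``+y``.
    """
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotate_about_axis(v: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate 3-vector(s) about the goniometer axis; norm-preserving.

    ``v`` may be a single vector or an ``(n, 3)`` array.
    """
    v = np.asarray(v, dtype=float)
    return v @ rotation_matrix(angle_deg).T


def spots_to_nodes(xy_px: np.ndarray, det: DetectorGeometry) -> np.ndarray:
    """Back-project detector spots onto the Ewald sphere.

    For each spot the scattered-beam unit vector ``u_hat`` points from the
    sample to the spot's position on the detector plane; with the incident
    unit vector ``b_hat`` the reciprocal-space node is

        q = (u_hat - b_hat) / wavelength

    which by construction satisfies ``|q + k_in| = 1/wavelength`` (it lies on
    the Ewald sphere).  ``|q| = 2 sin(theta) / wavelength`` for scattering
    angle ``2 theta``.

    Parameters
    ----------
    xy_px : array, shape (n, 2)
        Spot positions in pixels.
    det : DetectorGeometry

    Returns
    -------
    array, shape (n, 3) — node vectors in Å⁻¹, laboratory frame of the scan.
    """
    xy = np.atleast_2d(np.asarray(xy_px, dtype=float))
    nx, ny = det.detector_shape
    if np.any(xy[:, 0] < 0) or np.any(xy[:, 0] > nx - 1) or np.any(
        xy[:, 1] < 0
    ) or np.any(xy[:, 1] > ny - 1):
        raise GeometryError("spot position outside detector")
    cx, cy = det.beam_centre
    # lab-frame position of the spot on the detector plane x = distance
    dy = (xy[:, 1] - cy) * det.pixel_size  # vertical (lab y)
    dz = (xy[:, 0] - cx) * det.pixel_size  # along rotation axis (lab z)
    pos = np.column_stack([np.full(len(xy), det.distance), dy, dz])
    u_hat = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    b_hat = np.array([1.0, 0.0, 0.0])
    return (u_hat - b_hat) / det.wavelength


def spot_to_node(spot: Spot, det: DetectorGeometry) -> np.ndarray:
    """Back-project a single :class:`Spot`; see :func:`spots_to_nodes`."""
    return spots_to_nodes(np.array([[spot.x_px, spot.y_px]]), det)[0]


def scan_plane_coords(position: np.ndarray, omega_deg: float) -> tuple[float, float]:
    """Forward model: where a sample point appears in a scan grid.

    Returns the ``(v, u)`` = (vertical, rotation-axis) mm coordinates at
    which the sample-frame point ``position`` sits during a scan taken at
    goniometer angle ``omega_deg``.
    """
    p = rotate_about_axis(np.asarray(position, dtype=float), -omega_deg)
    return float(p[..., 1]), float(p[..., 2])


def triangulate_centre(
    region1_centroid: tuple[float, float],
    region2_centroid: tuple[float, float],
    omega: float,
    z_tolerance: float | None = None,
) -> CrystalPosition3D:
    """Triangulate a 3D centring position from two 2D region centroids.

    Parameters
    ----------
    region1_centroid, region2_centroid : (y, z) in mm
        Score-weighted centroids of the candidate crystal region in scan 1
        and scan 2: ``y`` vertical, ``z`` along the rotation axis.
    omega : float
        Rotation-angle difference between the scans, degrees.
    z_tolerance : float, optional
        Maximum allowed |z1 - z2|; if exceeded a :class:`PairingError` is
        raised.  ``None`` disables the check.

    Returns
    -------
    CrystalPosition3D
        With ``y = y1``, ``x = (y1 cos Ω − y2) / sin Ω`` and
        ``z = (z1 + z2) / 2``.  This inverts the forward model of
        :func:`scan_plane_coords` exactly.
    """
    y1, z1 = region1_centroid
    y2, z2 = region2_centroid
    s = np.sin(np.deg2rad(omega))
    if abs(s) < 1e-9:
        raise GeometryError(
            f"rotation angle {omega} deg is degenerate (multiple of 180)"
        )
    if z_tolerance is not None and abs(z1 - z2) > z_tolerance:
        raise PairingError(
            f"rotation-axis coordinates differ by {abs(z1 - z2):.4f} mm "
            f"(> tolerance {z_tolerance:.4f})"
        )
    c = np.cos(np.deg2rad(omega))
    x = (y1 * c - y2) / s
    return CrystalPosition3D(x=float(x), y=float(y1), z=float((z1 + z2) / 2.0))
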