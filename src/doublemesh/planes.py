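"""Lattice-periodicity detection in reciprocal-lattice subsets.

A still diffraction image yields a subset of the crystal's reciprocal
lattice — the nodes lying on the Ewald sphere.  Following the 1D-FFT family
of indexing ideas, periodicity is searched direction by direction:

1.  an isotropic set of unit direction vectors covers a hemisphere;
2.  for each direction, all nodes are projected onto it and the projection
    coordinates are histogrammed;
3.  the histogram is normalised by subtracting a slowly moving average and
    dividing by its square root, so that without periodicity the bins are
    approximately zero-mean, unit-variance white noise;
4.  the FFT magnitudes of the normalised histogram, scaled by
    ``sqrt(2 / n_bins)``, then asymptotically follow a unit Rayleigh
    (chi, 2 dof) distribution under the no-periodicity null — an outlying
    peak indicates a family of parallel periodic planes perpendicular to
    the direction.

The unit-Rayleigh calibration gives the acceptance thresholds a concrete
meaning: a peak score above 7 corresponds to a null tail probability of
``exp(-49/2) ≈ 2e-11`` per (direction, frequency) cell, so a plane family
accepted at that level is essentially never a fluctuation even after the
multiple testing implied by scanning thousands of directions.

The best coarse directions are refined by derivative-free local
maximisation; each accepted direction is scaled by its peak frequency
(units Å — the direct-space spacing of the plane family) to give a *plane
vector*, the rotation-covariant fingerprint used for cross-scan matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize

__all__ = [
    "PlanesConfig",
    "DirectionSet",
    "ProjectionHistogram",
    "FourierScore",
    "Spectrum",
    "PlaneVector",
    "build_direction_set",
    "project_nodes",
    "make_histogram",
    "spectrum",
    "score_direction",
    "find_planes",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class PlanesConfig:
    """Tunable parameters of the periodicity search.

    Defaults are the operating point used throughout: 2500 directions,
    0.002 Å⁻¹ histogram bins, a Gaussian moving average of σ = 10 bins,
    and the Rayleigh-calibrated acceptance threshold 7.
    """

    n_directions: int = 2500
    bin_width: float = 0.002  # Å⁻¹
    smooth_sigma_bins: float = 10.0
    p_floor: float = 0.5  # bins with smoothed level below this carry no evidence
    mask_transfer: float = 0.002  # mask frequencies the moving average absorbs
    top_k: int = 10
    refine_step_deg: float = 0.5
    refine_max_eval: int = 40
    plane_threshold: float = 7.0
    min_nodes: int = 50
    dedup_angle_deg: float = 2.0
    dedup_freq_rel: float = 0.02
    chunk_elements: int = 20_000_000  # memory cap for the vectorised scan

    @property
    def nyquist_frequency(self) -> float:
        """Largest measurable direct-space period, Å."""
        return 1.0 / (2.0 * self.bin_width)


@dataclass(frozen=True)
class DirectionSet:
    """Quasi-uniform unit vectors covering one hemisphere (z >= 0)."""

    units: np.ndarray  # (n, 3)

    @property
    def n(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class ProjectionHistogram:
    """Histogram of node projections with its moving-average normalisation.

    ``normalized[i] = (counts[i] - smooth[i]) / sqrt(smooth[i])`` wherever
    the smoothed level exceeds the floor, else 0.
    """

    counts: np.ndarray
    smooth: np.ndarray
    normalized: np.ndarray
    bin_width: float
    origin: float
    smooth_sigma_bins: float

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class FourierScore:
    """One spectral component: unit-Rayleigh-scaled magnitude + period (Å)."""

    score: float
    frequency: float


@dataclass(frozen=True)
class Spectrum:
    """Scaled FFT magnitudes of a normalised histogram.

    ``score[k] = |DFT(h)[k]| * sqrt(2 / n_bins)`` so that under the
    no-periodicity null each unmasked component is unit Rayleigh.
    ``frequency[k]`` is the direct-space period in Å.  ``valid`` masks out
    the zero-frequency term, the Nyquist term and the low frequencies that
    the moving-average normalisation attenuates (sub-resolution).
    """

    score: np.ndarray
    frequency: np.ndarray
    valid: np.ndarray

    def peak(self) -> FourierScore:
        """Best valid component with sub-bin frequency interpolation.

        The peak period is refined by fitting a parabola through the
        magnitudes at the peak and its two neighbours, giving frequency
        accuracy well below the DFT bin spacing; the score is the raw
        bin magnitude.  Score 0 if nothing is valid.
        """
        if not np.any(self.valid):
            return FourierScore(0.0, 0.0)
        idx = np.flatnonzero(self.valid)
        k = int(idx[np.argmax(self.score[idx])])
        freq = self.frequency[k]
        if 0 < k < len(self.score) - 1:
            ym, y0, yp = self.score[k - 1 : k + 2]
            denom = ym - 2.0 * y0 + yp
            if denom < 0:  # concave; vertex well defined
                delta = 0.5 * (ym - yp) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
                df = self.frequency[1] - self.frequency[0]
                freq = self.frequency[k] + delta * df
        return FourierScore(float(self.score[k]), float(freq))

    def components(self) -> list[FourierScore]:
        return [
            FourierScore(float(s), float(f))
            for s, f, v in zip(self.score, self.frequency, self.valid)
            if v
        ]


@dataclass(frozen=True)
class PlaneVector:
    """Normal direction of a periodic plane family scaled by its period.

    ``v = frequency * unit_direction`` with ``|v|`` in Å equal to the
    direct-space spacing of the family.  Rotating the crystal rotates its
    plane vectors identically, which is what cross-scan matching exploits.
    """

    v: np.ndarray  # (3,), Å
    peak_score: float

    @property
    def frequency(self) -> float:
        return float(np.linalg.norm(self.v))

    @property
    def direction(self) -> np.ndarray:
        return self.v / self.frequency


def build_direction_set(n: int) -> DirectionSet:
    """Spherical-Fibonacci layout of ``n`` directions on the z >= 0 hemisphere.

    The Fibonacci lattice is quasi-uniform in solid angle and avoids the
    polar clustering of a regular (theta, phi) grid; restricting to one
    hemisphere removes antipodal duplicates (projections onto u and -u
    carry the same periodicity information).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * _GOLDEN_ANGLE
    r = np.sqrt(1.0 - z * z)
    units = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return DirectionSet(units=units)


def project_nodes(nodes: np.ndarray, unit: np.ndarray) -> np.ndarray:
    """Scalar projection coordinates (Å⁻¹) of nodes onto a direction."""
    return np.asarray(nodes, dtype=float) @ np.asarray(unit, dtype=float)


def _histogram_span(coords: np.ndarray, bin_width: float) -> tuple[float, int]:
    """Span = data range padded by 5%, at least one bin wide."""
    lo, hi = float(np.min(coords)), float(np.max(coords))
    rng = max(hi - lo, bin_width)
    lo -= 0.025 * rng
    n_bins = max(int(np.ceil(1.05 * rng / bin_width)), 16)
    return lo, n_bins


def make_histogram(
    coords: np.ndarray, bin_width: float, cfg: PlanesConfig | None = None
) -> ProjectionHistogram:
    """Bin projection coordinates and apply the moving-average normalisation.

    The smooth level ``p`` is a Gaussian moving average of the counts
    (σ = ``cfg.smooth_sigma_bins``, reflecting boundaries); the normalised
    histogram is ``(H - p) / sqrt(p)``, with bins where ``p`` falls below
    the evidence floor set to zero.  For Poisson counts this yields
    approximately zero-mean unit-variance bins — the premise of the
    Rayleigh null calibration.
    """
    cfg = cfg or PlanesConfig(bin_width=bin_width)
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("cannot histogram an empty coordinate set")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    lo, n_bins = _histogram_span(coords, bin_width)
    idx = np.clip(((coords - lo) / bin_width).astype(np.int64), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return _normalize_counts(counts, bin_width, lo, cfg)


def _normalize_counts(
    counts: np.ndarray, bin_width: float, origin: float, cfg: PlanesConfig
) -> ProjectionHistogram:
    smooth = gaussian_filter1d(counts, cfg.smooth_sigma_bins, mode="reflect")
    safe = np.maximum(smooth, cfg.p_floor)
    normalized = np.where(smooth > cfg.p_floor, (counts - smooth) / np.sqrt(safe), 0.0)
    return ProjectionHistogram(
        counts=counts,
        smooth=smooth,
        normalized=normalized,
        bin_width=bin_width,
        origin=origin,
        smooth_sigma_bins=cfg.smooth_sigma_bins,
    )


def _valid_mask(n_bins: int, n_freq: int, sigma: float, mask_transfer: float) -> np.ndarray:
    """Frequency mask: drop DC, Nyquist and moving-average-attenuated bins.

    The Gaussian moving average has transfer function
    ``G(k) = exp(-2 pi^2 sigma^2 (k/n)^2)``; fluctuations at frequencies
    where ``G`` is non-negligible are partly absorbed into the smooth level
    and their normalised amplitude is biased low, so those components are
    excluded rather than scored.
    """
    k = np.arange(n_freq)
    transfer = np.exp(-2.0 * np.pi**2 * sigma**2 * (k / n_bins) ** 2)
    valid = transfer <= mask_transfer
    valid[0] = False
    if n_bins % 2 == 0 and n_freq == n_bins // 2 + 1:
        valid[-1] = False  # real-only Nyquist term is not Rayleigh
    return valid


def spectrum(ph: ProjectionHistogram, cfg: PlanesConfig | None = None) -> Spectrum:
    """Unit-Rayleigh-scaled FFT magnitude spectrum of a normalised histogram."""
    cfg = cfg or PlanesConfig(bin_width=ph.bin_width)
    h = ph.normalized
    n = len(h)
    mag = np.abs(rfft(h))
    score = mag * np.sqrt(2.0 / n)
    k = np.arange(len(mag))
    frequency = k / (n * ph.bin_width)  # direct-space period, Å
    valid = _valid_mask(n, len(mag), ph.smooth_sigma_bins, cfg.mask_transfer)
    return Spectrum(score=score, frequency=frequency, valid=valid)


def score_direction(
    nodes: np.ndarray, unit: np.ndarray, cfg: PlanesConfig
) -> FourierScore:
    """Full single-direction pipeline: project → histogram → FFT peak."""
    coords = project_nodes(nodes, unit)
    ph = make_histogram(coords, cfg.bin_width, cfg)
    return spectrum(ph, cfg).peak()


def _coarse_scan(
    nodes: np.ndarray, units: np.ndarray, cfg: PlanesConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-direction peak scores and frequencies.

    All directions in a chunk share one FFT length (the largest span in the
    chunk); directions with a shorter span leave zero tail bins, which acts
    as zero padding — peak magnitudes are preserved and the per-direction
    Rayleigh scale uses each direction's own occupied bin count.
    """
    n_nodes = len(nodes)
    chunk = max(1, cfg.chunk_elements // max(n_nodes, 1))
    best_score = np.empty(len(units))
    best_freq = np.empty(len(units))
    for start in range(0, len(units), chunk):
        u = units[start : start + chunk]
        proj = nodes @ u.T  # (N, C)
        lo = proj.min(axis=0)
        rng = np.maximum(proj.max(axis=0) - lo, cfg.bin_width)
        lo = lo - 0.025 * rng
        nb_each = np.maximum(
            np.ceil(1.05 * rng / cfg.bin_width).astype(int), 16
        )
        nb = int(nb_each.max())
        idx = ((proj - lo[None, :]) / cfg.bin_width).astype(np.int64)
        np.clip(idx, 0, (nb_each - 1)[None, :], out=idx)
        keys = idx + np.arange(len(u))[None, :] * nb
        counts = np.bincount(keys.ravel(), minlength=len(u) * nb).astype(float)
        counts = counts.reshape(len(u), nb)
        smooth = gaussian_filter1d(counts, cfg.smooth_sigma_bins, axis=1, mode="reflect")
        safe = np.maximum(smooth, cfg.p_floor)
        h = np.where(smooth > cfg.p_floor, (counts - smooth) / np.sqrt(safe), 0.0)
        mag = np.abs(rfft(h, axis=1))
        score = mag * np.sqrt(2.0 / nb_each)[:, None]
        valid = _valid_mask(nb, mag.shape[1], cfg.smooth_sigma_bins, cfg.mask_transfer)
        score[:, ~valid] = 0.0
        kbest = np.argmax(score, axis=1)
        best_score[start : start + len(u)] = score[np.arange(len(u)), kbest]
        best_freq[start : start + len(u)] = kbest / (nb * cfg.bin_width)
    return best_score, best_freq


def _refine_direction(
    nodes: np.ndarray, unit: np.ndarray, cfg: PlanesConfig
) -> tuple[np.ndarray, FourierScore]:
    """Local maximisation of the peak score over direction (theta, phi).

    Derivative-free simplex search with an initial step of
    ``refine_step_deg`` and a hard evaluation budget; the score surface is
    piecewise constant at the histogram-bin scale, which Nelder-Mead
    tolerates.
    """
    theta0 = float(np.arccos(np.clip(unit[2], -1.0, 1.0)))
    phi0 = float(np.arctan2(unit[1], unit[0]))

    def to_unit(x: np.ndarray) -> np.ndarray:
        t, p = x
        return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])

    def neg(x: np.ndarray) -> float:
        return -score_direction(nodes, to_unit(x), cfg).score

    step = np.deg2rad(cfg.refine_step_deg)
    # widen the azimuth step near the pole where phi is ill-conditioned
    phi_step = step / max(np.sin(theta0), 0.1)
    x0 = np.array([theta0, phi0])
    simplex = np.array([x0, x0 + [step, 0.0], x0 + [0.0, phi_step]])
    res = minimize(
        neg,
        x0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "maxfev": cfg.refine_max_eval,
            "xatol": np.deg2rad(0.01),
            "fatol": 0.01,
        },
    )
    best = to_unit(res.x)
    best /= np.linalg.norm(best)
    return best, score_direction(nodes, best, cfg)


def polish_family(
    nodes: np.ndarray,
    unit: np.ndarray,
    period: float,
    n_iter: int = 4,
    inlier_phase: float = 0.3,
) -> tuple[np.ndarray, float]:
    """Least-squares polish of a plane family against the node set.

    Starting from an approximate normal direction and period (Å), performs
    a few Gauss-Newton steps minimising the wrapped phase residuals
    ``(q_i · u) * L - round(...)`` of the inlier nodes over the two
    direction angles and the relative period.  This sharpens a family
    located by the Fourier search to the accuracy supported by the nodes
    themselves, well beyond the histogram-bin and simplex-step scales.
    Falls back to the input when fewer than 10 nodes are inliers.
    """
    u = np.asarray(unit, dtype=float)
    u = u / np.linalg.norm(u)
    L = float(period)
    for _ in range(n_iter):
        # orthonormal frame completing u
        a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        proj = nodes @ u
        phase = proj * L
        resid = phase - np.round(phase)
        inl = np.abs(resid) < inlier_phase
        if inl.sum() < 10:
            return u, L
        # d(phase) = proj * dL + L * (nodes . e1) da1 + L * (nodes . e2) da2
        J = np.column_stack(
            [proj[inl], L * (nodes[inl] @ e1), L * (nodes[inl] @ e2)]
        )
        try:
            step, *_ = np.linalg.lstsq(J, -resid[inl], rcond=None)
        except np.linalg.LinAlgError:
            return u, L
        dL, da1, da2 = step
        L = L + float(dL)
        u = u + e1 * float(da1) + e2 * float(da2)
        u /= np.linalg.norm(u)
        if L <= 0:
            return np.asarray(unit, dtype=float), float(period)
    return u, L


def _dedup(planes: list[PlaneVector], cfg: PlanesConfig) -> list[PlaneVector]:
    """Keep one plane vector per distinct normal direction.

    Near-parallel detections are either re-detections of the same family
    (period within ``dedup_freq_rel``) or its harmonics (integer period
    ratios); distinct plane families of one lattice are never parallel.
    Either way a parallel duplicate adds no independent evidence, so only
    the highest-scoring representative of each direction is retained.
    """
    kept: list[PlaneVector] = []
    for pv in sorted(planes, key=lambda p: -p.peak_score):
        duplicate = False
        for other in kept:
            cosang = abs(float(np.dot(pv.direction, other.direction)))
            ang = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if ang < cfg.dedup_angle_deg:
                duplicate = True
                break
        if not duplicate:
            kept.append(pv)
    return kept


def find_planes(
    nodes: np.ndarray,
    cfg: PlanesConfig | None = None,
    directions: DirectionSet | None = None,
) -> list[PlaneVector]:
    """Detect families of parallel periodic planes in a node set.

    Coarse scan over the isotropic direction set, refinement of the
    ``top_k`` candidate directions, acceptance at the Rayleigh-calibrated
    threshold (default 7), conversion to plane vectors and deduplication of
    near-parallel results.

    Returns an empty list (not an error) when fewer than ``cfg.min_nodes``
    nodes are supplied or when no direction passes the threshold.
    """
    cfg = cfg or PlanesConfig()
    nodes = np.asarray(nodes, dtype=float)
    if len(nodes) < cfg.min_nodes:
        return []
    dirs = directions or build_direction_set(cfg.n_directions)
    scores, _ = _coarse_scan(nodes, dirs.units, cfg)
    order = np.argsort(scores)[::-1][: cfg.top_k]
    planes: list[PlaneVector] = []
    for i in order:
        unit, peak = _refine_direction(nodes, dirs.units[i], cfg)
        if peak.frequency > 0:
            # lattice-consistency polish sharpens direction and period
            # beyond the simplex-step and histogram-bin scales
            u2, L2 = polish_family(nodes, unit, peak.frequency)
            peak2 = score_direction(nodes, u2, cfg)
            if peak2.score > peak.score:
                unit = u2
                if abs(L2 - peak2.frequency) < 0.05 * peak2.frequency:
                    peak = FourierScore(peak2.score, L2)
                else:
                    peak = peak2
        if (
            peak.score > cfg.plane_threshold
            and 0 < peak.frequency <= cfg.nyquist_frequency
        ):
            if unit[2] < 0:  # canonical hemisphere for dedup stability
                unit = -unit
            planes.append(PlaneVector(v=peak.frequency * unit, peak_score=peak.score))
    return _dedup(planes, cfg)
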