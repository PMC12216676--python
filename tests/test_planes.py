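"""Direction sets, histogram normalisation, Rayleigh-scaled spectra and
plane-vector detection."""

import numpy as np
import pytest
from scipy.stats import kstest, rayleigh

from doublemesh.geometry import spots_to_nodes
from doublemesh.planes import (
    PlanesConfig,
    ProjectionHistogram,
    build_direction_set,
    find_planes,
    make_histogram,
    polish_family,
    project_nodes,
    score_direction,
    spectrum,
)
from doublemesh.planes import _normalize_counts
from doublemesh.simulate import diffracting_nodes

from helpers import (
    lattice_free_nodes,
    make_crystal,
    matches_true_family,
    true_plane_families,
)


class TestDirectionSet:
    def test_single_direction_is_unit(self):
        ds = build_direction_set(1)
        assert ds.n == 1
        assert np.linalg.norm(ds.units[0]) == pytest.approx(1.0, abs=1e-12)

    def test_all_unit_norm_upper_hemisphere(self):
        ds = build_direction_set(2500)
        assert np.allclose(np.linalg.norm(ds.units, axis=1), 1.0, atol=1e-12)
        assert np.all(ds.units[:, 2] >= 0)  # no antipodal duplicates

    def test_quasi_uniform_minimum_spacing(self):
        ds = build_direction_set(2500)
        gram = ds.units @ ds.units.T
        np.fill_diagonal(gram, -1.0)
        min_angle = np.arccos(np.clip(gram.max(), -1, 1))
        assert min_angle >= 0.6 * np.sqrt(2 * np.pi / 2500)


class TestProjection:
    def test_axis_projection(self):
        assert project_nodes(np.array([[0.1, 0.2, 0.3]]), [1.0, 0, 0])[0] == 0.1

    def test_flip_negates(self, rng):
        nodes = rng.normal(size=(20, 3))
        u = np.array([0.0, 1.0, 0.0])
        assert np.allclose(project_nodes(nodes, -u), -project_nodes(nodes, u))

    def test_lattice_projections_near_integer_multiples(self, detector):
        """Projections onto a true family normal sit at integer multiples
        of the reciprocal period, within the excitation tolerance."""
        crystal = make_crystal(3)
        q, _, _ = diffracting_nodes(crystal, 0.0, detector, 0.002, 2.5)
        normal, period = true_plane_families(crystal, 0.0)[0]
        phase = project_nodes(q, normal) * period
        assert np.max(np.abs(phase - np.round(phase))) < 1e-6  # exact lattice points


class TestHistogramNormalisation:
    def test_constant_counts_normalise_to_zero(self):
        cfg = PlanesConfig()
        ph = _normalize_counts(np.full(256, 50.0), 0.002, 0.0, cfg)
        assert np.allclose(ph.normalized, 0.0, atol=1e-9)

    def test_spike_on_flat_background_peaks_at_spike(self):
        cfg = PlanesConfig()
        counts = np.full(256, 20.0)
        counts[100] += 200.0
        ph = _normalize_counts(counts, 0.002, 0.0, cfg)
        assert int(np.argmax(ph.normalized)) == 100

    def test_counts_conserved(self, rng):
        coords = rng.normal(0.0, 0.1, size=500)
        ph = make_histogram(coords, 0.002)
        assert ph.counts.sum() == 500

    def test_poisson_null_magnitudes_are_unit_rayleigh(self):
        """Normalised white-count histograms give unit-Rayleigh FFT scores."""
        cfg = PlanesConfig()
        rejections = 0
        for seed in range(5):
            counts = np.random.default_rng(seed).poisson(100, 4096).astype(float)
            ph = _normalize_counts(counts, 0.002, 0.0, cfg)
            spec = spectrum(ph, cfg)
            pval = kstest(spec.score[spec.valid], rayleigh.cdf).pvalue
            rejections += pval < 0.01
        assert rejections <= 1


class TestSpectrum:
    def _wrap(self, h):
        n = len(h)
        return ProjectionHistogram(
            counts=h,
            smooth=np.zeros(n),
            normalized=h,
            bin_width=0.002,
            origin=0.0,
            smooth_sigma_bins=10.0,
        )

    def test_zero_histogram_scores_zero(self):
        spec = spectrum(self._wrap(np.zeros(128)))
        assert np.all(spec.score == 0)

    def test_pure_cosine_closed_form(self):
        # h_i = cos(2 pi k i / n) with n = 128 -> score sqrt(n/2) = 8 at k
        n, k = 128, 16
        h = np.cos(2 * np.pi * k * np.arange(n) / n)
        spec = spectrum(self._wrap(h))
        assert spec.valid[k]
        assert spec.score[k] == pytest.approx(np.sqrt(n / 2), rel=1e-9)

    def test_frequency_axis_in_angstrom(self):
        n = 500
        spec = spectrum(self._wrap(np.zeros(n)))
        # component k corresponds to a period of k / (n * bin_width) A
        assert spec.frequency[10] == pytest.approx(10 / (n * 0.002))

    def test_rayleigh_tail_calibration(self):
        # the acceptance thresholds on the unit-Rayleigh score scale
        assert rayleigh.sf(7.0) == pytest.approx(np.exp(-49 / 2), rel=1e-12)
        assert float(f"{rayleigh.sf(7.0):.0e}") == pytest.approx(2e-11)
        assert float(f"{rayleigh.sf(5.0):.0e}") == pytest.approx(4e-6)


class TestPolish:
    def test_recovers_true_family_from_offset_start(self, detector):
        crystal = make_crystal(5)
        q, _, _ = diffracting_nodes(crystal, 0.0, detector, 0.002, 2.5)
        # shortest-period family: phases wrap least, the regime polish
        # is used in after the Fourier search has located the family
        normal, period = min(true_plane_families(crystal, 0.0), key=lambda f: f[1])
        # perturb by ~1 degree and 1% in period
        perturbed = normal + 0.017 * np.array([0.6, -0.8, 0.0])
        perturbed /= np.linalg.norm(perturbed)
        u, L = polish_family(q, perturbed, period * 1.01)
        ang = np.degrees(np.arccos(np.clip(abs(u @ normal), 0, 1)))
        assert ang < 0.1
        assert L == pytest.approx(period, rel=1e-3)


class TestFindPlanes:
    def test_too_few_nodes_returns_empty(self, rng):
        assert find_planes(rng.normal(size=(10, 3))) == []

    def test_recovers_a_true_plane_family(self, detector):
        crystal = make_crystal(1)
        q, _, xy = diffracting_nodes(crystal, 0.0, detector, 0.002, 2.5)
        nodes = spots_to_nodes(xy, detector)
        planes = find_planes(nodes)
        families = true_plane_families(crystal, 0.0)
        assert any(matches_true_family(pv, families) for pv in planes)

    def test_all_scores_above_threshold(self, detector):
        crystal = make_crystal(2)
        _, _, xy = diffracting_nodes(crystal, 0.0, detector, 0.002, 2.5)
        planes = find_planes(spots_to_nodes(xy, detector))
        assert planes
        assert all(pv.peak_score > 7.0 for pv in planes)

    def test_no_near_parallel_duplicates(self, detector):
        crystal = make_crystal(4)
        _, _, xy = diffracting_nodes(crystal, 0.0, detector, 0.002, 2.5)
        planes = find_planes(spots_to_nodes(xy, detector))
        for i, a in enumerate(planes):
            for b in planes[i + 1 :]:
                cosang = abs(float(a.direction @ b.direction))
                ang = np.degrees(np.arccos(np.clip(cosang, 0, 1)))
                assert ang >= 2.0

    def test_lattice_free_nodes_yield_nothing(self, detector):
        for seed in range(3):
            nodes = lattice_free_nodes(seed, 600, detector)
            assert find_planes(nodes) == []
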