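"""check() scoring, pair decisions and the end-to-end pipeline."""

import numpy as np
import pytest

from doublemesh.crystal_map import CrystalRegion, PairCandidate
from doublemesh.geometry import CrystalPosition3D, rotate_about_axis, spots_to_nodes
from doublemesh.matching import MatchingConfig, check, match_pair, run_doublemesh
from doublemesh.planes import PlanesConfig, find_planes
from doublemesh.simulate import SimulationConfig, diffracting_nodes, render_double_mesh

from helpers import make_crystal, region_to_crystal


@pytest.fixture(scope="module")
def crystal_nodes(detector):
    """One crystal observed at 0 and 60 degrees, plus its plane vectors."""
    crystal = make_crystal(31)
    nodes0 = spots_to_nodes(diffracting_nodes(crystal, 0.0, detector, 0.002, 2.5)[2], detector)
    nodes60 = spots_to_nodes(diffracting_nodes(crystal, 60.0, detector, 0.002, 2.5)[2], detector)
    planes = find_planes(nodes0)
    assert planes
    return crystal, nodes0, nodes60, planes


class TestCheck:
    def test_own_vector_against_own_nodes(self, crystal_nodes):
        _, nodes0, _, planes = crystal_nodes
        best = max(check(pv, nodes0) for pv in planes)
        assert best > 7.0

    def test_rotated_vector_matches_other_orientation(self, crystal_nodes):
        _, _, nodes60, planes = crystal_nodes
        best = max(check(rotate_about_axis(pv.v, -60.0), nodes60) for pv in planes)
        assert best > 5.0

    def test_unrotated_vector_fails_other_orientation(self, crystal_nodes):
        """Without applying the known rotation the lattices disagree."""
        _, _, nodes60, planes = crystal_nodes
        best = max(check(pv.v, nodes60) for pv in planes)
        assert best <= 5.0

    def test_cross_crystal_vectors_score_low(self, detector, crystal_nodes):
        _, _, _, planes = crystal_nodes
        other = make_crystal(32)
        nodes = spots_to_nodes(
            diffracting_nodes(other, 60.0, detector, 0.002, 2.5)[2], detector
        )
        best = max(check(rotate_about_axis(pv.v, -60.0), nodes) for pv in planes)
        assert best <= 5.0

    def test_beyond_nyquist_frequency_rejected(self, crystal_nodes):
        _, nodes0, _, _ = crystal_nodes
        cfg = PlanesConfig()
        v = np.array([0.0, 0.0, 2.0 * cfg.nyquist_frequency])
        with pytest.raises(ValueError):
            check(v, nodes0)

    def test_too_few_nodes_scores_zero(self, crystal_nodes, rng):
        _, _, _, planes = crystal_nodes
        assert check(planes[0], rng.normal(size=(5, 3))) == 0.0


def _candidate(nodes_a, nodes_b):
    def region(label, nodes):
        return CrystalRegion(
            label=label, cells=set(), centroid=(0.1, 0.0), extents=(0.02, 0.02),
            integral_score=1.0, nodes=nodes, beam_size=20.0,
        )
    return PairCandidate(
        region_a=region(1, nodes_a),
        region_b=region(1, nodes_b),
        z_gap=0.0,
        provisional_3d=CrystalPosition3D(0.0, 0.0, 0.1),
    )


class TestMatchPair:
    def test_empty_plane_sets_unmatched(self, rng):
        cand = _candidate(rng.normal(size=(100, 3)), rng.normal(size=(100, 3)))
        result = match_pair(cand, [], [], 60.0)
        assert result.max_score == 0.0
        assert not result.matched

    def test_true_pair_matched(self, crystal_nodes):
        _, nodes0, nodes60, planes = crystal_nodes
        result = match_pair(_candidate(nodes0, nodes60), planes, [], 60.0)
        assert result.matched
        assert result.max_score > 5.0

    def test_decision_uses_threshold_five(self, crystal_nodes):
        _, nodes0, nodes60, planes = crystal_nodes
        strict = MatchingConfig(match_threshold=1e9)
        result = match_pair(
            _candidate(nodes0, nodes60), planes, [], 60.0, matching_cfg=strict
        )
        assert not result.matched


class TestRunDoubleMesh:
    def test_empty_holder_yields_no_matches(self):
        cfg = SimulationConfig(n_crystals=0, seed=0)
        s1, s2, _ = render_double_mesh(cfg)
        result = run_doublemesh(s1, s2)
        assert result.matches == []
        assert result.regions1 == [] and result.regions2 == []

    def test_small_multicrystal_run_recovers_all_pairs(self, small_sim):
        cfg, s1, s2, truth = small_sim
        result = run_doublemesh(s1, s2)
        m1 = region_to_crystal(result.regions1, truth.contributors[0])
        m2 = region_to_crystal(result.regions2, truth.contributors[1])
        matched = {(m1[m.pair.region_a.label], m2[m.pair.region_b.label])
                   for m in result.matches}
        assert {(c, c) for c in truth.true_pairs} <= matched
        # no cross-crystal matches
        assert all(a == b for a, b in matched)
        # positions within half a grid step of the seeded crystals
        for m in result.matches:
            ci = m1[m.pair.region_a.label]
            err = np.abs(m.position.as_array() - truth.crystals[ci].position)
            assert np.all(err <= cfg.step / 2)

    def test_matches_ranked_by_combined_score(self, small_sim):
        _, s1, s2, _ = small_sim
        result = run_doublemesh(s1, s2)
        scores = [m.integral_score for m in result.matches]
        assert scores == sorted(scores, reverse=True)
        assert [m.rank for m in result.matches] == list(range(1, len(scores) + 1))

    def test_swapping_scans_gives_same_pairs_and_scores(self, small_sim):
        _, s1, s2, _ = small_sim
        fwd = run_doublemesh(s1, s2)
        rev = run_doublemesh(s2, s1)
        fwd_pairs = {
            (m.pair.region_a.label, m.pair.region_b.label): m.max_score
            for m in fwd.matches
        }
        rev_pairs = {
            (m.pair.region_b.label, m.pair.region_a.label): m.max_score
            for m in rev.matches
        }
        assert set(fwd_pairs) == set(rev_pairs)
        for k in fwd_pairs:
            assert fwd_pairs[k] == pytest.approx(rev_pairs[k], rel=1e-9)

    def test_crystal_insertion_order_is_irrelevant(self):
        """Permuting the order crystals are placed in the holder leaves
        the matched positions unchanged."""
        cfg = SimulationConfig(n_crystals=3, seed=17, omegas=(0.0, 60.0))
        from doublemesh.simulate import random_crystals

        crystals = random_crystals(cfg, np.random.default_rng(cfg.seed))
        positions = []
        for order in (crystals, crystals[::-1]):
            s1, s2, _ = render_double_mesh(cfg, crystals=list(order))
            result = run_doublemesh(s1, s2)
            # intensities/noise draw from the RNG in a different order, so
            # compare positions at the micrometre level only
            positions.append(
                sorted(tuple(np.round(m.position.as_array(), 3)) for m in result.matches)
            )
        assert positions[0] == positions[1]

    def test_mismatched_grids_rejected(self, small_sim):
        _, s1, _, _ = small_sim
        other = render_double_mesh(SimulationConfig(n_crystals=1, seed=1, n_u=10, n_v=10))[0]
        with pytest.raises(ValueError):
            run_doublemesh(s1, other)
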