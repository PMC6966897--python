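import numpy as np
import pytest

from chromofold import (AnnotationTrack, LocusSpec, build_stratified_null,
                        call_specific_manybodies, coverage_fraction,
                        coverage_permutation_test, enumerate_3body,
                        enumerate_maximal, functional_landscape,
                        principal_loop_heatmap, sample_null_ensemble,
                        tally_frequencies)
from chromofold.manybody import ManyBodyCall, _spans
from chromofold.model_io import ClusterData

from _oracles import brute_force_3bodies, brute_force_maximal_cliques


def _triangle(side=50.0):
    """Three beads at an equilateral triangle plus two distant outliers."""
    h = side * np.sqrt(3) / 2
    return np.array([[0.0, 0.0, 0.0], [side, 0.0, 0.0], [side / 2, h, 0.0],
                     [500.0, 500.0, 0.0], [900.0, 0.0, 500.0]])


class TestEnumeration:
    def test_equilateral_triangle_is_one_3body(self):
        cx = enumerate_3body(_triangle(), threshold=80.0, min_separation=1,
                             bin_size=5000)
        assert [c.members for c in cx] == [(0, 1, 2)]
        assert cx[0].principal_span == 2 * 5000
        assert cx[0].minor_span == 5000
        assert cx[0].anchors == (0, 2)

    def test_fewer_than_three_bins_yields_nothing(self):
        assert enumerate_3body(np.zeros((2, 3))) == []
        assert enumerate_maximal(np.zeros((2, 3))) == []

    def test_four_mutually_close_beads_form_one_maximal_4clique(self):
        coords = np.array([[0, 0, 0], [40, 0, 0], [0, 40, 0], [0, 0, 40],
                           [700, 700, 700]], dtype=float)
        mx = enumerate_maximal(coords, threshold=80.0, min_separation=1)
        assert [c.members for c in mx] == [(0, 1, 2, 3)]
        assert mx[0].size == 4
        tri = enumerate_3body(coords, threshold=80.0, min_separation=1)
        assert len(tri) == 4  # all 4 triangles inside, none maximal

    @pytest.mark.parametrize("seed", range(8))
    def test_enumeration_matches_exhaustive_search(self, seed, loose_params):
        """3-body and maximal-clique enumeration agree with brute-force
        subset scans on random small conformations."""
        ens = sample_null_ensemble(loose_params, 12, 1, seed=seed)
        coords = ens.coords[0]
        got3 = sorted(c.members for c in enumerate_3body(coords, 80.0, 2))
        assert got3 == brute_force_3bodies(coords, 80.0, 2)
        gotm = sorted(c.members for c in enumerate_maximal(coords, 80.0, 2))
        assert gotm == brute_force_maximal_cliques(coords, 80.0, 2)

    def test_anchor_tie_break_is_lexicographic(self):
        span, minor, anchors = _spans((0, 3, 6), 5000)
        assert anchors == (0, 6)
        # two pairs tie at span 3: (0,3) and (3,6) -> smallest pair wins
        span2, minor2, anchors2 = _spans((0, 3), 5000)
        assert anchors2 == (0, 3)


@pytest.fixture(scope="module")
def null40(desk_params):
    return sample_null_ensemble(desk_params, 40, 300, seed=31)


@pytest.fixture(scope="module")
def null40_dist(null40):
    return build_stratified_null(null40, n_replicates=200, mode="3body",
                                 seed=1)


class TestStratifiedNull:
    def test_seed_determinism(self, null40):
        a = build_stratified_null(null40, 50, "3body", seed=9)
        b = build_stratified_null(null40, 50, "3body", seed=9)
        assert a.strata.keys() == b.strata.keys()
        assert all(np.array_equal(a.strata[k], b.strata[k]) for k in a.strata)

    def test_replicate_means_track_direct_tally(self, null40, null40_dist):
        freqs, strata = tally_frequencies(null40, "3body")
        # stratum-level: mean of pooled bootstrap frequencies approximates
        # the mean direct frequency of signatures in that stratum
        from collections import defaultdict
        direct = defaultdict(list)
        for sig, f in freqs.items():
            direct[strata[sig]].append(f)
        checked = 0
        for st, vals in direct.items():
            if len(vals) < 5 or st not in null40_dist.strata:
                continue
            pool = null40_dist.strata[st]
            assert abs(pool.mean() - np.mean(vals)) < 0.05
            checked += 1
        assert checked > 3


class TestCallSpecific:
    def test_self_null_calibration(self, null40, null40_dist, desk_params):
        """Scoring one random ensemble against a null built from another
        keeps the specific rate within the FDR budget."""
        other = sample_null_ensemble(desk_params, 40, 300, seed=77)
        calls = call_specific_manybodies(other, null40_dist)
        rate = np.mean([c.specific for c in calls])
        assert rate <= 0.05

    def test_planted_coactive_triple_is_recovered(self, desk_params,
                                                  null40_dist, null40):
        """Cells jointly constraining a triangle of contacts produce a
        3-body complex far beyond the random-folding null."""
        from chromofold import reconstruct
        a, b, c = 5, 20, 35
        contacts = [(a, b), (b, c), (a, c)]
        states = np.ones((20, 3), dtype=int)
        rec = reconstruct(states, contacts, desk_params, 40,
                          folds_per_cell=10, seed=3)
        calls = call_specific_manybodies(rec, null40_dist)
        by_sig = {cl.signature: cl for cl in calls}
        assert (a, b, c) in by_sig
        assert by_sig[(a, b, c)].specific

    def test_absent_complex_never_specific(self, null40, null40_dist):
        calls = call_specific_manybodies(null40, null40_dist)
        for cl in calls:
            if cl.frequency == 0:
                assert not cl.specific


class TestLandscape:
    @pytest.fixture()
    def annotations(self):
        locus = LocusSpec("c", 0, 200_000, 5000)  # 40 bins
        return AnnotationTrack([(25_000, 30_000, "SE"),   # bin 5
                                (100_000, 105_000, "SE"),  # bin 20
                                (175_000, 180_000, "P")],  # bin 35
                               locus)

    def _call(self, sig, specific):
        return ManyBodyCall(sig, 0.5, 0.01, 0.01, specific, (1, 1))

    def test_unannotated_bins_count_as_no_association(self):
        locus = LocusSpec("c", 0, 200_000, 5000)
        empty = AnnotationTrack([], locus)
        calls = [self._call((1, 8, 15), True), self._call((2, 9, 16), True)]
        table = functional_landscape(calls, empty)
        assert table.loc["specific", "no_functional"] == 1.0

    def test_hand_tallied_proportions(self, annotations):
        calls = [
            self._call((5, 20, 35), True),   # SE, SE, P -> 2 SE with P
            self._call((5, 20, 30), True),   # SE, SE, none
            self._call((1, 8, 15), True),    # none
            self._call((5, 10, 35), False),  # SE, none, P
        ]
        table = functional_landscape(calls, annotations)
        assert table.loc["specific", "n"] == 3
        assert table.loc["specific", "no_functional"] == pytest.approx(1 / 3)
        assert table.loc["specific", "ge2_SE_with_P"] == pytest.approx(1 / 3)
        assert table.loc["specific", "ge3_SE"] == 0.0
        assert table.loc["non_specific", "no_functional"] == 0.0


class TestCoverage:
    def test_complex_in_every_cluster_has_full_coverage(self):
        clusters = ClusterData([[1, 5, 9, 12], [5, 9, 30], [0, 5, 9]])
        assert coverage_fraction((5, 9), clusters) == 1.0
        assert coverage_fraction((5, 9, 12), clusters) == pytest.approx(1 / 3)

    def test_permutation_test_calibrated_under_label_exchange(self, rng):
        """Identical coverage distributions for both labels give a
        permutation p-value well away from significance."""
        clusters = ClusterData([sorted(rng.choice(40, size=8, replace=False))
                                for _ in range(60)])
        calls = []
        for k in range(40):
            i = int(rng.integers(0, 30))
            sig = (i, i + 3, i + 8)
            calls.append(ManyBodyCall(sig, 0.5, 0.01, 0.01,
                                      bool(k % 2), (1, 1)))
        res = coverage_permutation_test(calls, clusters, n_permutations=200,
                                        seed=5)
        assert res["p_value"] > 0.05

    def test_no_clusters_is_an_error(self):
        with pytest.raises(ValueError):
            coverage_fraction((1, 2), ClusterData([]))


class TestPrincipalLoopHeatmap:
    def test_symmetric_with_anchor_marginals(self, null40):
        hm = principal_loop_heatmap(null40, k=3, n_bins=40)
        assert np.allclose(hm, hm.T)
        freqs, _ = tally_frequencies(null40, "maximal")
        expect = np.zeros((40, 40))
        for (kk, (a, b)), f in freqs.items():
            if kk == 3:
                expect[a, b] += f
                expect[b, a] += f
        assert np.allclose(hm, expect)
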