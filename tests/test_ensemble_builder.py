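import numpy as np
import pytest

from chromofold import (boundary_strength, cell_distance_matrix,
                        distance_corrected_pearson, mean_distance_matrix,
                        overlap_coefficient, pearson, reconstruct,
                        sample_null_ensemble, simulated_hic)
from chromofold.polymer import pairwise_distances


@pytest.fixture(scope="module")
def recon(desk_params):
    states = np.array([[1, 0], [1, 1], [0, 0], [0, 1]])
    contacts = [(0, 25), (5, 18)]
    return reconstruct(states, contacts, desk_params, 30, folds_per_cell=6,
                       seed=99)


class TestReconstruct:
    def test_total_conformations_and_constraint_satisfaction(self, recon,
                                                             desk_params):
        assert len(recon) == 4 * 6
        states = {0: [(0, 25)], 1: [(0, 25), (5, 18)], 2: [], 3: [(5, 18)]}
        for cid, pairs in states.items():
            ens = recon.cells[cid]
            for conf in ens.conformations():
                conf.validate(desk_params, pairs)

    def test_all_zero_states_reduce_to_null_statistics(self, desk_params):
        states = np.zeros((3, 2), dtype=int)
        rec = reconstruct(states, [(0, 25), (5, 18)], desk_params, 30,
                          folds_per_cell=10, seed=4)
        freq = simulated_hic(rec)
        null = sample_null_ensemble(desk_params, 30, 30, seed=4)
        from chromofold import contact_frequency
        nf = contact_frequency(null)
        iu = np.triu_indices(30, 3)
        assert abs(freq[iu].mean() - nf[iu].mean()) < 0.1


class TestSimulatedHic:
    def test_matches_direct_tally_and_cell_permutation_invariance(self, recon,
                                                                  desk_params):
        freq = simulated_hic(recon)
        w = recon.cell_weights()
        coords = recon.all_coords()
        expect = np.zeros((30, 30))
        for k in range(len(coords)):
            d = pairwise_distances(coords[k])
            expect += w[k] * (d <= desk_params.contact_threshold)
        assert np.allclose(freq, expect)
        # permuting cell order leaves the aggregate unchanged
        from chromofold.ensemble_builder import ReconstructedEnsemble
        shuffled = ReconstructedEnsemble(
            {k: recon.cells[c] for k, c in enumerate([2, 0, 3, 1])},
            recon.params)
        assert np.allclose(simulated_hic(shuffled), freq)


class TestPearson:
    def test_identical_matrices_score_one(self, rng):
        m = rng.random((10, 10))
        m = m + m.T
        assert pearson(m, m, 2) == pytest.approx(1.0)

    def test_hand_computed_five_by_five(self):
        a = np.zeros((5, 5))
        b = np.zeros((5, 5))
        # entries with |i-j| > 2: (0,3), (0,4), (1,4)
        for (i, j), (x, y) in {(0, 3): (1.0, 2.0), (0, 4): (2.0, 3.0),
                               (1, 4): (4.0, 7.0)}.items():
            a[i, j] = a[j, i] = x
            b[i, j] = b[j, i] = y
        expect = np.corrcoef([1, 2, 4], [2, 3, 7])[0, 1]
        assert pearson(a, b, 2) == pytest.approx(expect)

    def test_exclusion_window_changes_entry_set(self, rng):
        m = rng.random((12, 12))
        m = m + m.T
        n = rng.random((12, 12))
        n = n + n.T
        assert pearson(m, n, 0) != pearson(m, n, 2)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson(np.ones((6, 6)), np.ones((6, 6)), 2)


class TestDistanceCorrectedPearson:
    def test_identical_matrices_score_one(self, rng):
        m = rng.random((12, 12))
        m = m + m.T
        assert distance_corrected_pearson(m, m) == pytest.approx(1.0)

    def test_per_stratum_constant_shift_is_removed(self, rng):
        m = rng.random((12, 12))
        m = m + m.T
        shifted = m.copy()
        for s in range(1, 12):
            shifted += np.diag(np.full(12 - s, s * 0.5), k=s)
            shifted += np.diag(np.full(12 - s, s * 0.5), k=-s)
        assert distance_corrected_pearson(m, shifted) == pytest.approx(1.0)

    def test_shared_decay_alone_scores_near_zero(self, desk_params):
        """Two independent random ensembles share only the distance decay:
        plain Pearson is high, the distance-corrected correlation is not."""
        from chromofold import contact_frequency
        a = contact_frequency(sample_null_ensemble(desk_params, 40, 400,
                                                   seed=1))
        b = contact_frequency(sample_null_ensemble(desk_params, 40, 400,
                                                   seed=2))
        assert pearson(a, b, 2) > 0.8
        assert abs(distance_corrected_pearson(a, b)) < 0.4


class TestDistanceMatrices:
    def test_mean_matches_brute_force_loop(self, recon):
        dm = mean_distance_matrix(recon)
        coords = recon.all_coords()
        w = recon.cell_weights()
        expect = np.zeros((30, 30))
        for k in range(len(coords)):
            expect += w[k] * pairwise_distances(coords[k])
        assert np.allclose(dm, expect)
        assert np.all(np.diag(dm) == 0)

    def test_bonded_pairs_at_bond_length(self, recon, desk_params):
        dm = mean_distance_matrix(recon)
        assert np.allclose(np.diagonal(dm, 1), desk_params.bond_length,
                           atol=1e-6)

    def test_unknown_cell_id_rejected(self, recon):
        with pytest.raises(KeyError):
            cell_distance_matrix(recon, 999)


class TestBoundaryStrength:
    def test_uniform_matrix_scores_one_everywhere_defined(self):
        d = np.full((30, 30), 50.0)
        prof = boundary_strength(d, window=5)
        inner = prof.strength[5:26]
        assert np.allclose(inner, 1.0)
        assert np.isnan(prof.strength[:5]).all()

    def test_two_domain_toy_peaks_exactly_at_junction(self):
        """Within-block distance 100, cross-block 300: the boundary score at
        the junction is exactly 3."""
        n, w = 20, 5
        d = np.full((n, n), 300.0)
        d[:10, :10] = 100.0
        d[10:, 10:] = 100.0
        np.fill_diagonal(d, 0.0)
        # keep within-block means exactly 100 by using off-diagonal pairs only
        prof = boundary_strength(d, window=w)
        assert prof.strength[10] == pytest.approx(3.0)
        assert np.nanargmax(prof.strength) == 10

    def test_profile_mirrors_under_locus_reversal(self, rng):
        d = rng.random((24, 24)) * 100
        d = d + d.T
        np.fill_diagonal(d, 0)
        w = 4
        fwd = boundary_strength(d, window=w).strength
        rev = boundary_strength(d[::-1, ::-1].copy(), window=w).strength
        for i in range(w, 24 - w + 1):
            assert fwd[i] == pytest.approx(rev[24 - i])

    def test_window_validation(self):
        d = np.zeros((10, 10))
        with pytest.raises(ValueError):
            boundary_strength(d, window=1)
        with pytest.raises(ValueError):
            boundary_strength(d, window=6)


class TestOverlapCoefficient:
    @pytest.mark.parametrize("a,b,expect", [
        ({(0, 5), (2, 9)}, {(0, 5), (2, 9)}, 1.0),
        ({(0, 5)}, {(2, 9)}, 0.0),
        ({(0, 5)}, {(0, 5), (2, 9), (4, 11)}, 1.0),  # subset
        ({(0, 5), (2, 9)}, {(2, 9), (7, 13)}, 0.5),
    ])
    def test_reference_cases(self, a, b, expect):
        assert overlap_coefficient(a, b) == expect

    def test_empty_set_undefined(self):
        with pytest.raises(ValueError):
            overlap_coefficient(set(), {(0, 5)})
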