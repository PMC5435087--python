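import numpy as np
import pytest

from phyloshift import asr, core_io, synth
from phyloshift.errors import DomainError, PairingError

from conftest import brute_force_marginals


class TestSubstitutionModel:
    def test_rows_sum_to_zero(self, lg_model):
        assert np.allclose(lg_model.rate_matrix.sum(axis=1), 0.0, atol=1e-12)

    def test_detailed_balance(self, lg_model):
        pi = lg_model.frequencies
        Q = lg_model.rate_matrix
        assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)

    def test_mean_rate_one(self, lg_model):
        pi = lg_model.frequencies
        assert abs(-np.dot(pi, np.diag(lg_model.rate_matrix)) - 1.0) < 1e-10

    def test_transition_matrix_stochastic(self, lg_gamma_model):
        for t in (0.0, 0.1, 1.0, 10.0, 50.0):
            P = lg_gamma_model.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(P >= 0)

    def test_long_time_reaches_equilibrium(self, lg_model):
        P = lg_model.transition_matrix(300.0)
        assert np.allclose(P, np.tile(lg_model.frequencies, (21, 1)),
                           atol=1e-7)

    def test_gamma_rates_mean_one(self):
        rates = asr.discrete_gamma_rates(0.5, 4)
        assert abs(rates.mean() - 1.0) < 1e-12
        assert np.all(np.diff(rates) > 0)

    def test_bad_alpha(self):
        with pytest.raises(DomainError):
            asr.SubstitutionModel.empirical("LG", alpha=-1.0)

    def test_gap_mode_missing_is_20_state(self):
        m = asr.SubstitutionModel.empirical("LG", gap_mode="missing")
        assert m.n_states == 20


class TestTreeLogLikelihood:
    def test_single_leaf_closed_form(self, lg_model):
        tree = core_io.read_tree("(a:0.0);")
        msa = core_io.MSA(["a"], ["A"])
        ll = asr.tree_log_likelihood(msa, tree, lg_model)
        expected = np.log(lg_model.frequencies[lg_model.state_index("A")])
        assert abs(ll - expected) < 1e-10

    def test_two_leaf_brute_force(self, lg_gamma_model):
        # oracle: direct summation over the single ancestral state
        model = lg_gamma_model
        tree = core_io.read_tree("(a:0.12,b:0.3);")
        msa = core_io.MSA(["a", "b"], ["H", "K"])
        i, j = model.state_index("H"), model.state_index("K")
        total = 0.0
        for rate in model.category_rates:
            P1 = model.transition_matrix(0.12 * rate)
            P2 = model.transition_matrix(0.3 * rate)
            total += float((model.frequencies * P1[:, i] * P2[:, j]).sum())
        expected = np.log(total / model.n_categories)
        ll = asr.tree_log_likelihood(msa, tree, model)
        assert abs(ll - expected) < 1e-12

    def test_zero_length_identical_leaves(self, lg_model):
        tree = core_io.read_tree("(a:0.0,b:0.0);")
        msa = core_io.MSA(["a", "b"], ["W", "W"])
        ll = asr.tree_log_likelihood(msa, tree, lg_model)
        expected = np.log(lg_model.frequencies[lg_model.state_index("W")])
        assert abs(ll - expected) < 1e-9

    def test_missing_leaf_sequence(self, lg_model, four_leaf_tree):
        msa = core_io.MSA(["a", "b", "c"], ["A", "A", "A"])
        with pytest.raises(PairingError):
            asr.tree_log_likelihood(msa, four_leaf_tree, lg_model)

    def test_rerooting_invariance(self, lg_gamma_model, four_leaf_tree):
        msa = core_io.MSA(["a", "b", "c", "d"],
                          ["HK-", "HRA", "QKA", "Q-A"])
        ref = asr.tree_log_likelihood(msa, four_leaf_tree, lg_gamma_model)
        for child in ("a", "c", "d"):
            rerooted = core_io.reroot_at_edge(four_leaf_tree, child, 0.3)
            ll = asr.tree_log_likelihood(msa, rerooted, lg_gamma_model)
            assert abs(ll - ref) < 1e-8


class TestMarginalASR:
    def test_matches_enumeration_four_leaves(self, lg_gamma_model,
                                             four_leaf_tree):
        msa = core_io.MSA(["a", "b", "c", "d"], ["HA", "H-", "QA", "KA"])
        recon = asr.marginal_asr(msa, four_leaf_tree, lg_gamma_model)
        oracle = brute_force_marginals(msa, four_leaf_tree, lg_gamma_model)
        for node_id, expected in oracle.items():
            assert np.abs(recon.posteriors[node_id] - expected).max() < 1e-9

    def test_matches_enumeration_five_leaves_three_sites(self, lg_model):
        tree = core_io.read_tree(
            "(((a:0.2,b:0.1):0.15,c:0.3):0.1,(d:0.25,e:0.05):0.2);")
        msa = core_io.MSA(["a", "b", "c", "d", "e"],
                          ["HKA", "HRA", "QK-", "QKA", "HKA"])
        recon = asr.marginal_asr(msa, tree, lg_model)
        oracle = brute_force_marginals(msa, tree, lg_model)
        for node_id, expected in oracle.items():
            assert np.abs(recon.posteriors[node_id] - expected).max() < 1e-9

    def test_posteriors_sum_to_one(self, lg_gamma_model, four_leaf_tree):
        msa = core_io.MSA(["a", "b", "c", "d"], ["HA", "HA", "QA", "KA"])
        recon = asr.marginal_asr(msa, four_leaf_tree, lg_gamma_model)
        for post in recon.posteriors.values():
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_leaves_give_identical_ml_state(self, lg_model):
        tree = core_io.read_tree("((a:2,b:2):2,(c:2,d:2):2);")
        msa = core_io.MSA(["a", "b", "c", "d"], ["H", "H", "H", "H"])
        recon = asr.marginal_asr(msa, tree, lg_model)
        assert set(recon.ml_sequences.values()) == {"H"}

    def test_long_terminal_branch_converges_to_no_information(self, lg_model):
        # as the leaf branch grows its influence decays toward the prior,
        # i.e. toward the reconstruction with that leaf marked missing
        msa_missing = core_io.MSA(["a", "b", "c"], ["X", "H", "Q"])
        distances = []
        for t in (1.0, 10.0, 100.0):
            tree = core_io.read_tree(f"((a:{t},b:0.1):0.2,c:0.1);")
            recon = asr.marginal_asr(
                core_io.MSA(["a", "b", "c"], ["W", "H", "Q"]), tree, lg_model)
            ref = asr.marginal_asr(msa_missing, tree, lg_model)
            distances.append(
                np.abs(recon.posteriors["N1"] - ref.posteriors["N1"]).sum())
        assert distances[0] > distances[1] > distances[2]
        assert distances[2] < 1e-6


class TestSampleAncestral:
    def test_default_twenty_draws(self, lg_model, four_leaf_tree):
        msa = core_io.MSA(["a", "b", "c", "d"], ["HA", "HA", "QA", "KA"])
        recon = asr.marginal_asr(msa, four_leaf_tree, lg_model)
        draws = asr.sample_ancestral(recon, "N0", 20, seed=7)
        assert len(draws) == 20
        assert all(len(d) == 2 for d in draws)

    def test_degenerate_posterior(self, lg_model, four_leaf_tree):
        msa = core_io.MSA(["a", "b", "c", "d"], ["HA", "HA", "QA", "KA"])
        recon = asr.marginal_asr(msa, four_leaf_tree, lg_model)
        recon.posteriors["N0"][:] = 0.0
        recon.posteriors["N0"][:, lg_model.state_index("H")] = 1.0
        draws = asr.sample_ancestral(recon, "N0", 50, seed=1)
        assert set(draws) == {"HH"}

    def test_reproducible(self, lg_model, four_leaf_tree):
        msa = core_io.MSA(["a", "b", "c", "d"], ["HA", "HA", "QA", "KA"])
        recon = asr.marginal_asr(msa, four_leaf_tree, lg_model)
        assert (asr.sample_ancestral(recon, "N1", 10, seed=3)
                == asr.sample_ancestral(recon, "N1", 10, seed=3))

    def test_frequencies_match_posterior(self, lg_model, four_leaf_tree):
        msa = core_io.MSA(["a", "b", "c", "d"], ["H", "H", "Q", "K"])
        recon = asr.marginal_asr(msa, four_leaf_tree, lg_model)
        n = 10_000
        draws = asr.sample_ancestral(recon, "N0", n, seed=11)
        post = recon.posteriors["N0"][0]
        for idx, state in enumerate(lg_model.states):
            p = post[idx]
            if p < 1e-4:
                continue
            observed = sum(d[0] == state for d in draws) / n
            se = np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) <= 3 * se + 1e-12

    def test_leaf_node_rejected(self, lg_model, four_leaf_tree):
        msa = core_io.MSA(["a", "b", "c", "d"], ["H", "H", "Q", "K"])
        recon = asr.marginal_asr(msa, four_leaf_tree, lg_model)
        with pytest.raises(DomainError):
            asr.sample_ancestral(recon, "a", 5, seed=1)


class TestNodeMeanPosterior:
    def _recon_with(self, lg_model, four_leaf_tree, values):
        msa = core_io.MSA(["a", "b", "c", "d"], ["HA", "HA", "QA", "KA"])
        recon = asr.marginal_asr(msa, four_leaf_tree, lg_model)
        post = np.zeros_like(recon.posteriors["N0"])
        n_states = post.shape[1]
        for i, v in enumerate(values):
            post[i, 0] = v
            post[i, 1:] = (1 - v) / (n_states - 1)
        recon.posteriors["N0"] = post
        recon.mean_posteriors["N0"] = float(
            post[np.arange(len(values)), post.argmax(axis=1)].mean())
        return recon

    def test_certainty(self, lg_model, four_leaf_tree):
        recon = self._recon_with(lg_model, four_leaf_tree, [1.0, 1.0])
        assert asr.node_mean_posterior(recon, "N0") == 1.0

    def test_arithmetic_mean(self, lg_model, four_leaf_tree):
        recon = self._recon_with(lg_model, four_leaf_tree, [0.8, 0.6])
        assert abs(asr.node_mean_posterior(recon, "N0") - 0.7) < 1e-12

    def test_uniform_posterior(self, lg_model, four_leaf_tree):
        msa = core_io.MSA(["a", "b", "c", "d"], ["HA", "HA", "QA", "KA"])
        recon = asr.marginal_asr(msa, four_leaf_tree, lg_model)
        recon.posteriors["N0"][:] = 1.0 / 21
        recon.mean_posteriors["N0"] = 1.0 / 21
        assert abs(asr.node_mean_posterior(recon, "N0") - 1 / 21) < 1e-12


class TestEstimateAlpha:
    def test_recovers_generating_alpha_roughly(self):
        model = asr.SubstitutionModel.empirical("LG", alpha=0.5,
                                                n_categories=4)
        tree = synth.birth_tree(12, seed=3)
        msa, _ = synth.simulate_alignment(tree, model, 300, seed=4)
        est = asr.estimate_alpha(msa, tree, "LG", n_categories=4)
        assert 0.25 < est < 1.0
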