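import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from phyloshift import bm_ratescan as bm
from phyloshift import core_io, synth
from phyloshift.errors import DomainError, PairingError


def dense_bm_loglik(tree, values, ses, state):
    """Independent oracle: explicit multivariate-normal density with the
    shared-path covariance (only feasible for small trees)."""
    flat = bm._FlatTree(tree)
    mult = flat.effective_multipliers(state.shifts)

    def path(i):
        out = []
        while flat.parent[i] >= 0:
            out.append(i)
            i = flat.parent[i]
        return set(out)

    idx = [i for i in range(len(flat.nodes)) if flat.ids[i] in values]
    n = len(idx)
    cov = np.zeros((n, n))
    for x, i in enumerate(idx):
        for y, j in enumerate(idx):
            shared = path(i) & path(j)
            cov[x, y] = state.sigma2 * sum(
                flat.length[k] * mult[k] for k in shared)
        se = ses.get(flat.ids[i], 0.0)
        cov[x, x] += se * se
    vec = [values[flat.ids[i]] for i in idx]
    return float(multivariate_normal.logpdf(
        vec, mean=[state.root_value] * n, cov=cov, allow_singular=True))


class TestBMLogLikelihood:
    def test_two_leaf_closed_form(self):
        tree = core_io.read_tree("(a:1,b:1);")
        state = bm.RateState(sigma2=1.0, root_value=0.0)
        ll = bm.bm_log_likelihood(tree, {"a": 0.5, "b": -0.3}, {}, state)
        ref = multivariate_normal.logpdf([0.5, -0.3], mean=[0, 0],
                                         cov=np.eye(2))
        assert abs(ll - ref) < 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_dense_mvn(self, seed):
        tree = synth.birth_tree(6, seed=seed)
        ses = {n.id: 0.05 for n in tree.preorder()}
        shifts = {} if seed % 2 else {"N2": 2.5}
        obs, _ = synth.simulate_bm_trait(tree, 0.6, shifts=shifts, ses=ses,
                                         seed=seed + 10)
        state = bm.RateState(sigma2=0.6, root_value=0.2, shifts=shifts)
        ll = bm.bm_log_likelihood(tree, obs, ses, state)
        assert abs(ll - dense_bm_loglik(tree, obs, ses, state)) < 1e-8

    def test_matches_dense_leaf_only(self):
        tree = synth.birth_tree(6, seed=9)
        obs, _ = synth.simulate_bm_trait(tree, 1.2, seed=5)
        leaf_obs = {n.id: obs[n.id] for n in tree.leaves()}
        state = bm.RateState(sigma2=1.2, root_value=-0.1)
        ll = bm.bm_log_likelihood(tree, leaf_obs, {}, state)
        assert abs(ll - dense_bm_loglik(tree, leaf_obs, {}, state)) < 1e-8

    def test_unit_multipliers_equal_no_shift_model(self):
        tree = synth.birth_tree(8, seed=2)
        obs, _ = synth.simulate_bm_trait(tree, 0.5, seed=3)
        leaf_obs = {n.id: obs[n.id] for n in tree.leaves()}
        base = bm.RateState(sigma2=0.5, root_value=0.0)
        trivial = bm.RateState(sigma2=0.5, root_value=0.0,
                               shifts={"N1": 1.0, "t1": 1.0})
        assert bm.bm_log_likelihood(tree, leaf_obs, {}, base) == \
            pytest.approx(bm.bm_log_likelihood(tree, leaf_obs, {}, trivial))

    def test_huge_se_makes_tip_uninformative(self):
        tree = core_io.read_tree("((a:1,b:1):1,c:1);")
        state = bm.RateState(sigma2=1.0, root_value=0.0)
        ses = {"c": 1e8}
        ll1 = bm.bm_log_likelihood(tree, {"a": 0.2, "b": 0.1, "c": 5.0},
                                   ses, state)
        ll2 = bm.bm_log_likelihood(tree, {"a": 0.2, "b": 0.1, "c": -7.0},
                                   ses, state)
        assert abs(ll1 - ll2) < 1e-6

    def test_nonpositive_sigma2(self):
        with pytest.raises(DomainError):
            bm.RateState(sigma2=0.0, root_value=0.0)

    def test_unknown_node(self):
        tree = core_io.read_tree("(a:1,b:1);")
        state = bm.RateState(sigma2=1.0, root_value=0.0)
        with pytest.raises(PairingError):
            bm.bm_log_likelihood(tree, {"zz": 1.0, "a": 0.0, "b": 0.0},
                                 {}, state)


class TestBMConfig:
    def test_chain_too_short(self):
        with pytest.raises(DomainError):
            bm.BMConfig(generations=500, thin=100)

    def test_bad_burnin(self):
        with pytest.raises(DomainError):
            bm.BMConfig(burnin=1.0)


class TestRJMCMC:
    def test_prior_only_matches_poisson(self):
        tree = synth.birth_tree(12, seed=1)
        cfg = bm.BMConfig(generations=40_000, thin=10, burnin=0.25,
                          chains=1, seed=42)
        post = bm.rjmcmc_run(tree, {}, {}, cfg, prior_only=True)
        counts = post.traces["n_shifts"].to_numpy()
        # Poisson(1) truncated far below the 22-node candidate cap
        mc_se = counts.std(ddof=1) / math.sqrt(len(counts) / 20)  # ~ESS guard
        assert abs(counts.mean() - 1.0) <= 3 * mc_se + 0.05
        assert abs(counts.var(ddof=1) - 1.0) < 0.35

    def test_star_tree_null_calibration(self):
        tree = core_io.read_tree(
            "(" + ",".join(f"t{i}:1" for i in range(8)) + ");")
        rng = np.random.default_rng(3)
        values = {f"t{i}": float(rng.normal(0, 1)) for i in range(8)}
        cfg = bm.BMConfig(generations=5000, thin=10, burnin=0.25,
                          chains=1, seed=11)
        post = bm.rjmcmc_run(tree, values, {}, cfg)
        prior_level = cfg.shift_rate_prior / len(post.node_ids)
        n_samples = (post.traces.shape[0])
        mc_se = math.sqrt(prior_level * (1 - prior_level) / (n_samples / 20))
        for node, p in post.p_shift.items():
            assert p < prior_level + 3 * mc_se + 0.1

    def test_recovers_planted_subtree_multiplier(self):
        tree = synth.birth_tree(24, seed=7)
        # pick an internal node with a mid-sized subtree
        target = next(
            n.id for n in tree.preorder()
            if n.parent is not None and not n.is_leaf
            and 5 <= len(tree.leafset(n)) <= 10)
        ses = {n.id: 0.02 for n in tree.preorder()}
        obs, _ = synth.simulate_bm_trait(tree, 0.05, shifts={target: 20.0},
                                         ses=ses, seed=8)
        cfg = bm.BMConfig(generations=10_000, thin=10, burnin=0.25,
                          chains=1, seed=9)
        post = bm.rjmcmc_run(tree, obs, ses, cfg)
        assert post.top_shift_node() == target
        # direction recovery: mean multiplier inside subtree exceeds outside
        inside = {n.id for n in tree.preorder()
                  if tree.leafset(n) <= tree.leafset(tree.node(target))}
        mean_in = np.mean([post.mean_multiplier[k] for k in post.node_ids
                           if k in inside])
        mean_out = np.mean([post.mean_multiplier[k] for k in post.node_ids
                            if k not in inside])
        assert mean_in > mean_out
        assert post.p_shift_up[target] > post.p_shift_down[target]

    def test_reproducible(self):
        tree = synth.birth_tree(8, seed=4)
        obs, _ = synth.simulate_bm_trait(tree, 0.2, seed=5)
        cfg = bm.BMConfig(generations=2000, thin=10, chains=1, seed=13)
        a = bm.rjmcmc_run(tree, obs, {}, cfg)
        b = bm.rjmcmc_run(tree, obs, {}, cfg)
        assert a.p_shift == b.p_shift

    def test_tips_only_mode_runs(self):
        tree = synth.birth_tree(8, seed=4)
        obs, _ = synth.simulate_bm_trait(tree, 0.2, seed=5)
        cfg = bm.BMConfig(generations=2000, thin=10, chains=1, seed=13,
                          use_ancestral_values=False)
        post = bm.rjmcmc_run(tree, obs, {}, cfg)
        assert set(post.p_shift) == {n.id for n in tree.preorder()
                                     if n.parent is not None}


class TestASDSF:
    def _posterior_with(self, tree, probs):
        node_ids = [n.id for n in tree.preorder() if n.parent is not None]
        import pandas as pd
        return bm.ShiftPosterior(
            tree=tree, node_ids=node_ids,
            p_shift_up={k: probs.get(k, 0.0) for k in node_ids},
            p_shift_down={k: 0.0 for k in node_ids},
            mean_multiplier={k: 1.0 for k in node_ids},
            mean_n_shifts=0.0, traces=pd.DataFrame())

    def test_identical_runs(self):
        tree = core_io.read_tree("(a:1,b:1);")
        runs = [self._posterior_with(tree, {"a": 0.3}) for _ in range(3)]
        assert bm.asdsf(runs) == 0.0

    def test_hand_computed_value(self):
        tree = core_io.read_tree("(a:1,b:1);")
        runs = [self._posterior_with(tree, {"a": 0.2, "b": 0.2}),
                self._posterior_with(tree, {"a": 0.4, "b": 0.2})]
        # sd({0.2, 0.4}, ddof=1) = 0.141421...; mean over nodes with b: 0
        expected = (np.std([0.2, 0.4], ddof=1) + 0.0) / 2
        assert bm.asdsf(runs) == pytest.approx(expected)
        assert np.std([0.2, 0.4], ddof=1) == pytest.approx(0.1414, abs=1e-4)

    def test_convergence_gate(self):
        tree = core_io.read_tree("(a:1,b:1);")
        tight = [self._posterior_with(tree, {"a": 0.300}),
                 self._posterior_with(tree, {"a": 0.301})]
        assert bm.asdsf(tight) < 0.01

    def test_single_run_rejected(self):
        tree = core_io.read_tree("(a:1,b:1);")
        with pytest.raises(DomainError):
            bm.asdsf([self._posterior_with(tree, {})])

    def test_mismatched_trees(self):
        t1 = core_io.read_tree("(a:1,b:1);")
        t2 = core_io.read_tree("(a:1,c:1);")
        with pytest.raises(PairingError):
            bm.asdsf([self._posterior_with(t1, {}),
                      self._posterior_with(t2, {})])
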