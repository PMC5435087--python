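"""Brownian-motion trait model with branch rate multipliers and rjMCMC.

The trait (pKd) evolves by Brownian motion whose per-branch variance is
sigma^2 * branch length * multiplier; multipliers come from discrete "shift"
nodes, each applying from the branch above the shift node downward until
overridden by a deeper shift.  Observation error (per-node SE) is folded
into the likelihood.  Shift configurations are sampled by reversible-jump
Metropolis-Hastings with birth/death/move/scale proposals.

Priors (documented substitutes for the unspecified reference defaults, all
configurable): number of shifts ~ Poisson(lambda); shift locations uniform
over non-root nodes; log multiplier ~ Normal(0, tau^2); log sigma^2 uniform
on [-20, 20]; root value ~ Normal(0, 10^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Tree
from .errors import DomainError, PairingError

__all__ = [
    "BMConfig",
    "RateState",
    "ShiftPosterior",
    "bm_log_likelihood",
    "rjmcmc_run",
    "asdsf",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class BMConfig:
    generations: int = 100_000
    thin: int = 100
    burnin: float = 0.25
    chains: int = 4
    seed: int = 0
    shift_rate_prior: float = 1.0     # Poisson mean on the number of shifts
    log_multiplier_sd: float = 1.0    # tau of the Normal(0, tau^2) prior
    use_ancestral_values: bool = True
    log_sigma2_bounds: tuple[float, float] = (-20.0, 20.0)
    root_prior_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.generations < self.thin:
            raise DomainError("generations must be >= thin")
        if self.generations < 10 * self.thin:
            raise DomainError("chain too short: need generations >= 10 * thin")
        if not 0.0 <= self.burnin < 1.0:
            raise DomainError("burnin fraction must be in [0, 1)")
        if self.chains < 1:
            raise DomainError("need at least one chain")


@dataclass
class RateState:
    """One point in the rjMCMC state space."""

    sigma2: float
    root_value: float
    shifts: dict[str, float] = field(default_factory=dict)  # node id -> multiplier

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise DomainError("sigma^2 must be > 0")
        if any(m <= 0 for m in self.shifts.values()):
            raise DomainError("multipliers must be > 0")


class _FlatTree:
    """Preorder-indexed arrays for fast repeated likelihood evaluation."""

    def __init__(self, tree: Tree):
        self.nodes = list(tree.preorder())
        self.index = {n.id: i for i, n in enumerate(self.nodes)}
        self.parent = [self.index[n.parent.id] if n.parent else -1
                       for n in self.nodes]
        self.length = [n.length for n in self.nodes]
        self.children = [[self.index[c.id] for c in n.children]
                         for n in self.nodes]
        self.postorder = list(range(len(self.nodes) - 1, -1, -1))
        self.is_leaf = [not n.children for n in self.nodes]
        self.ids = [n.id for n in self.nodes]

    def effective_multipliers(self, shifts: dict[str, float]) -> list[float]:
        """Per-node multiplier of the branch above each node: nearest shift
        at-or-above wins (a shift at a node governs its own branch)."""
        mult = [1.0] * len(self.nodes)
        shift_idx = {self.index[k]: v for k, v in shifts.items()}
        for i in range(len(self.nodes)):
            if i in shift_idx:
                mult[i] = shift_idx[i]
            elif self.parent[i] >= 0:
                mult[i] = mult[self.parent[i]]
        return mult


def _prune_loglik(flat: _FlatTree, values: dict[str, float],
                  ses: dict[str, float], sigma2: float, root_value: float,
                  mult: list[float]) -> float:
    """Felsenstein-style BM pruning with observation error.

    Each node carries (x, v): the conditional mean and variance of its state
    given data below.  Observed internal nodes contribute their value as a
    zero-length pseudo-child with variance se^2.
    """
    n = len(flat.nodes)
    xs = [0.0] * n
    vs = [0.0] * n
    loglik = 0.0
    for i in flat.postorder:
        node_id = flat.ids[i]
        parts = []  # (mean, variance) of independent estimates of this node
        for c in flat.children[i]:
            d = vs[c] + sigma2 * mult[c] * flat.length[c]
            parts.append((xs[c], d))
        if node_id in values:
            se = ses.get(node_id, 0.0)
            parts.append((values[node_id], se * se))
        elif flat.is_leaf[i]:
            raise PairingError(f"leaf {node_id!r} has no observed value")
        x0, v0 = parts[0]
        for x1, v1 in parts[1:]:
            tot = v0 + v1
            if tot <= 0.0:
                if x0 != x1:
                    return -math.inf
            else:
                diff = x0 - x1
                loglik += -0.5 * (_LOG_2PI + math.log(tot) + diff * diff / tot)
                prec0, prec1 = 1.0 / v0 if v0 > 0 else math.inf, 1.0 / v1 if v1 > 0 else math.inf
                if math.isinf(prec0) and math.isinf(prec1):
                    v_new, x_new = 0.0, 0.5 * (x0 + x1)
                elif math.isinf(prec0):
                    v_new, x_new = 0.0, x0
                elif math.isinf(prec1):
                    v_new, x_new = 0.0, x1
                else:
                    v_new = 1.0 / (prec0 + prec1)
                    x_new = v_new * (x0 * prec0 + x1 * prec1)
                x0, v0 = x_new, v_new
        xs[i], vs[i] = x0, v0
    # root against the root-value parameter
    tot = vs[0]
    diff = xs[0] - root_value
    if tot <= 0.0:
        return -math.inf if diff != 0.0 else loglik
    loglik += -0.5 * (_LOG_2PI + math.log(tot) + diff * diff / tot)
    return loglik


def bm_log_likelihood(tree: Tree, values: dict[str, float],
                      ses: dict[str, float], state: RateState) -> float:
    """Gaussian log-density of the observed trait values under ``state``.

    Covariance between observations is sigma^2 times the multiplier-weighted
    shared path length from the root, plus se^2 on the diagonal; computed by
    pruning, never by dense matrix inversion.
    """
    if state.sigma2 <= 0:
        raise DomainError("sigma^2 must be > 0")
    flat = _FlatTree(tree)
    for k in list(values) :
        if k not in flat.index:
            raise PairingError(f"observed node {k!r} not in tree")
    mult = flat.effective_multipliers(state.shifts)
    return _prune_loglik(flat, values, ses, state.sigma2, state.root_value, mult)


@dataclass
class ShiftPosterior:
    """Posterior summaries from one chain or a pool of chains."""

    tree: Tree
    node_ids: list[str]
    p_shift_up: dict[str, float]
    p_shift_down: dict[str, float]
    mean_multiplier: dict[str, float]    # per branch (node id = child end)
    mean_n_shifts: float
    traces: pd.DataFrame
    chains: list["ShiftPosterior"] = field(default_factory=list)

    @property
    def p_shift(self) -> dict[str, float]:
        return {k: self.p_shift_up[k] + self.p_shift_down[k]
                for k in self.node_ids}

    def top_shift_node(self) -> str:
        return max(self.node_ids, key=lambda k: self.p_shift[k])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": self.node_ids,
            "p_shift_up": [self.p_shift_up[k] for k in self.node_ids],
            "p_shift_down": [self.p_shift_down[k] for k in self.node_ids],
            "mean_multiplier": [self.mean_multiplier[k] for k in self.node_ids],
        })


def _run_single_chain(flat, values, ses, config, rng, prior_only):
    n_nodes = len(flat.nodes)
    candidates = [i for i in range(n_nodes) if flat.parent[i] >= 0]
    n_cand = len(candidates)
    lam = config.shift_rate_prior
    tau = config.log_multiplier_sd
    lo_s2, hi_s2 = config.log_sigma2_bounds

    # initial state
    log_sigma2 = 0.0
    root_value = float(np.mean(list(values.values())))
    shifts: dict[int, float] = {}

    def loglik(log_s2, mu, sh):
        if prior_only:
            return 0.0
        mult = [1.0] * n_nodes
        for i in range(n_nodes):
            if i in sh:
                mult[i] = sh[i]
            elif flat.parent[i] >= 0:
                mult[i] = mult[flat.parent[i]]
        return _prune_loglik(flat, values, ses, math.exp(log_s2), mu, mult)

    def log_prior_multiplier(m):
        lm = math.log(m)
        return -0.5 * (_LOG_2PI + 2 * math.log(tau) + (lm / tau) ** 2) - lm

    # birth/death proposal for the new multiplier: lognormal, deliberately
    # wider than the prior so large planted multipliers are reachable
    s_birth = max(2.0, tau)

    def log_q_multiplier(m):
        lm = math.log(m)
        return (-0.5 * (_LOG_2PI + 2 * math.log(s_birth)
                        + (lm / s_birth) ** 2) - lm)

    cur_ll = loglik(log_sigma2, root_value, shifts)
    n_keep = config.generations // config.thin
    samples = []
    for gen in range(1, config.generations + 1):
        move = rng.integers(4)
        k = len(shifts)
        if move == 0 and k < n_cand:  # birth
            free = [i for i in candidates if i not in shifts]
            node = free[rng.integers(len(free))]
            m = math.exp(rng.normal(0.0, s_birth))
            new = dict(shifts)
            new[node] = m
            new_ll = loglik(log_sigma2, root_value, new)
            # location-prior and location-proposal terms cancel, leaving the
            # Poisson count ratio and the prior/proposal ratio for m
            log_alpha = (new_ll - cur_ll) + math.log(lam / (k + 1)) \
                + log_prior_multiplier(m) - log_q_multiplier(m)
            if math.log(rng.random()) < log_alpha:
                shifts, cur_ll = new, new_ll
        elif move == 1 and k > 0:  # death
            keys = list(shifts)
            node = keys[rng.integers(len(keys))]
            new = dict(shifts)
            m_gone = shifts[node]
            del new[node]
            new_ll = loglik(log_sigma2, root_value, new)
            log_alpha = (new_ll - cur_ll) + math.log(k / lam) \
                - log_prior_multiplier(m_gone) + log_q_multiplier(m_gone)
            if math.log(rng.random()) < log_alpha:
                shifts, cur_ll = new, new_ll
        elif move == 2 and k > 0:  # move a shift to a free node
            keys = list(shifts)
            node = keys[rng.integers(len(keys))]
            free = [i for i in candidates if i not in shifts]
            if free:
                target = free[rng.integers(len(free))]
                new = dict(shifts)
                new[target] = new.pop(node)
                new_ll = loglik(log_sigma2, root_value, new)
                if math.log(rng.random()) < new_ll - cur_ll:
                    shifts, cur_ll = new, new_ll
        elif move == 3:  # scale sigma^2, a multiplier, the root value, or
            # jointly rescale (sigma^2 up, all multipliers down) to traverse
            # the sigma^2/multiplier ridge between equivalent explanations
            which = rng.integers(4)
            if which == 0:
                prop = log_sigma2 + rng.normal(0.0, 0.3)
                if lo_s2 <= prop <= hi_s2:
                    new_ll = loglik(prop, root_value, shifts)
                    if math.log(rng.random()) < new_ll - cur_ll:
                        log_sigma2, cur_ll = prop, new_ll
            elif which == 1 and k > 0:
                keys = list(shifts)
                node = keys[rng.integers(len(keys))]
                old_m = shifts[node]
                new_m = math.exp(math.log(old_m) + rng.normal(0.0, 0.7))
                new = dict(shifts)
                new[node] = new_m
                new_ll = loglik(log_sigma2, root_value, new)
                # log-scale random walk: Hastings ratio new_m/old_m
                log_alpha = (new_ll - cur_ll)
                log_alpha += log_prior_multiplier(new_m) - log_prior_multiplier(old_m)
                log_alpha += math.log(new_m / old_m)
                if math.log(rng.random()) < log_alpha:
                    shifts, cur_ll = new, new_ll
            elif which == 2:
                prop = root_value + rng.normal(0.0, 0.3)
                new_ll = loglik(log_sigma2, prop, shifts)
                log_alpha = (new_ll - cur_ll) + 0.5 * (
                    root_value ** 2 - prop ** 2) / config.root_prior_sd ** 2
                if math.log(rng.random()) < log_alpha:
                    root_value, cur_ll = prop, new_ll
            elif which == 3:
                u = rng.normal(0.0, 1.0)
                prop_s2 = log_sigma2 + u
                if lo_s2 <= prop_s2 <= hi_s2:
                    new = {i: m * math.exp(-u) for i, m in shifts.items()}
                    new_ll = loglik(prop_s2, root_value, new)
                    # state is (log sigma^2, multipliers): the log-sigma^2
                    # part is an additive move under its uniform prior; each
                    # multiplier map m -> m e^{-u} carries Jacobian e^{-u}
                    log_alpha = (new_ll - cur_ll) - k * u
                    for i in shifts:
                        log_alpha += (log_prior_multiplier(new[i])
                                      - log_prior_multiplier(shifts[i]))
                    if math.log(rng.random()) < log_alpha:
                        log_sigma2, shifts, cur_ll = prop_s2, new, new_ll
        if gen % config.thin == 0:
            samples.append((gen, math.exp(log_sigma2), root_value,
                            cur_ll, dict(shifts)))
    return samples


def _summarize(flat, samples, burnin, config) -> ShiftPosterior:
    keep = samples[int(math.ceil(len(samples) * burnin)):]
    n_nodes = len(flat.nodes)
    node_ids = [flat.ids[i] for i in range(n_nodes) if flat.parent[i] >= 0]
    up = {k: 0 for k in node_ids}
    down = {k: 0 for k in node_ids}
    mult_sum = {k: 0.0 for k in node_ids}
    n_shift_sum = 0.0
    trace_rows = []
    for gen, s2, mu, ll, shifts in keep:
        mult = [1.0] * n_nodes
        parent_eff = [1.0] * n_nodes
        for i in range(n_nodes):
            p = flat.parent[i]
            parent_eff[i] = mult[p] if p >= 0 else 1.0
            mult[i] = shifts.get(i, parent_eff[i])
        for i, m in shifts.items():
            nid = flat.ids[i]
            if m > parent_eff[i]:
                up[nid] += 1
            else:
                down[nid] += 1
        for i in range(n_nodes):
            if flat.parent[i] >= 0:
                mult_sum[flat.ids[i]] += mult[i]
        n_shift_sum += len(shifts)
        trace_rows.append({
            "generation": gen, "sigma2": s2, "root_value": mu,
            "loglik": ll, "n_shifts": len(shifts),
            "shifts": ";".join(f"{flat.ids[i]}:{m:.6g}"
                               for i, m in sorted(shifts.items())),
        })
    n = max(len(keep), 1)
    return ShiftPosterior(
        tree=None,  # set by caller
        node_ids=node_ids,
        p_shift_up={k: up[k] / n for k in node_ids},
        p_shift_down={k: down[k] / n for k in node_ids},
        mean_multiplier={k: mult_sum[k] / n for k in node_ids},
        mean_n_shifts=n_shift_sum / n,
        traces=pd.DataFrame(trace_rows),
    )


def rjmcmc_run(tree: Tree, values: dict[str, float], ses: dict[str, float],
               config: BMConfig, prior_only: bool = False) -> ShiftPosterior:
    """Sample shift configurations; returns pooled posterior (chains kept).

    ``prior_only`` disables the likelihood, turning the sampler into a prior
    simulator (used to validate reversible-jump correctness).
    """
    if not prior_only and len(values) < 3:
        raise DomainError("need at least 3 observed values")
    if not config.use_ancestral_values:
        leaf_ids = {n.id for n in tree.leaves()}
        values = {k: v for k, v in values.items() if k in leaf_ids}
        ses = {k: v for k, v in ses.items() if k in leaf_ids}
    flat = _FlatTree(tree)
    for k in values:
        if k not in flat.index:
            raise PairingError(f"observed node {k!r} not in tree")
    if prior_only and not values:
        values = {n.id: 0.0 for n in tree.leaves()}
    seed_seq = np.random.SeedSequence(config.seed)
    chain_posteriors = []
    all_samples = []
    for child_seq in seed_seq.spawn(config.chains):
        rng = np.random.default_rng(child_seq)
        samples = _run_single_chain(flat, values, ses, config, rng, prior_only)
        post = _summarize(flat, samples, config.burnin, config)
        post.tree = tree
        chain_posteriors.append(post)
        all_samples.extend(samples[int(math.ceil(len(samples) * config.burnin)):])
    pooled = _summarize(flat, all_samples, 0.0, config)
    pooled.tree = tree
    pooled.chains = chain_posteriors
    return pooled


def asdsf(runs: list[ShiftPosterior]) -> float:
    """Average (over nodes) standard deviation (ddof=1, across runs) of the
    per-node shift posterior probabilities.  Convergence gate: < 0.01."""
    if len(runs) < 2:
        raise DomainError("need >= 2 runs")
    ids = runs[0].node_ids
    for r in runs[1:]:
        if r.node_ids != ids:
            raise PairingError("runs come from different trees")
    mat = np.array([[r.p_shift[k] for k in ids] for r in runs])
    return float(mat.std(axis=0, ddof=1).mean())
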