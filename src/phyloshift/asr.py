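"""Marginal ancestral sequence reconstruction under empirical AA models.

Implements the pruning algorithm for tree likelihoods, the up/down pass for
per-node per-site marginal posteriors, posterior sampling of ancestral
sequences, and discrete-gamma rate variation.

Gaps are modeled as a 21st character state by default (uniform
exchangeability with every amino acid, frequency estimated from the
alignment), which makes ancestral insertion/deletion states first-class;
``gap_mode="missing"`` instead treats gaps (and 'X') as missing data under
the plain 20-state model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._aa_models import AA_ORDER, EMPIRICAL_MODELS
from .core_io import AMBIGUOUS, GAP, MSA, Node, Tree
from .errors import DomainError, PairingError

__all__ = [
    "SubstitutionModel",
    "AncestralReconstruction",
    "tree_log_likelihood",
    "marginal_asr",
    "sample_ancestral",
    "node_mean_posterior",
    "estimate_alpha",
]


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability discrete-gamma categories,
    normalized to mean 1 (the usual quantile-slice construction)."""
    if alpha <= 0:
        raise DomainError(f"gamma shape must be > 0, got {alpha}")
    if k < 1:
        raise DomainError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], bounds * alpha, [np.inf]])
    # mean of X over a slice of Gamma(alpha, 1): uses regularized gammainc
    upper = gammainc(alpha + 1.0, edges[1:])
    lower = gammainc(alpha + 1.0, edges[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Time-reversible amino-acid model, optionally with a gap state.

    The rate matrix is built as ``Q_ij = s_ij * pi_j``, diagonal set so rows
    sum to zero, then scaled so the mean rate is 1 substitution/site.
    Transition matrices use the symmetric eigendecomposition of the
    pi-rescaled matrix for numerical stability at large t.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float = 1.0
    n_categories: int = 4
    states: str = AA_ORDER
    name: str = "custom"

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        n = len(self.states)
        if S.shape != (n, n) or not np.allclose(S, S.T):
            raise DomainError("exchangeability matrix must be symmetric")
        if pi.shape != (n,) or abs(pi.sum() - 1.0) > 1e-8 or np.any(pi <= 0):
            raise DomainError("frequencies must be positive and sum to 1")
        if self.alpha <= 0:
            raise DomainError(f"gamma shape must be > 0, got {self.alpha}")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(pi, np.diag(Q))
        Q /= scale
        self.frequencies = pi
        self.rate_matrix = Q
        # symmetric form B = D^{1/2} Q D^{-1/2}
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)
        self._eigvals, self._eigvecs = np.linalg.eigh(B)
        self._left = self._eigvecs / sq[:, None]   # D^{-1/2} U
        self._right = self._eigvecs * sq[:, None]  # D^{1/2} U -> use transpose
        self.category_rates = discrete_gamma_rates(self.alpha, self.n_categories)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise DomainError("branch length must be >= 0")
        expd = np.exp(self._eigvals * t)
        P = (self._left * expd[None, :]) @ self._right.T
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def state_index(self, symbol: str) -> int:
        return self.states.index(symbol)

    def encode(self, sequence: str) -> np.ndarray:
        """Per-site likelihood vectors for one sequence (handles '-'/'X')."""
        n = self.n_states
        out = np.zeros((len(sequence), n))
        for i, ch in enumerate(sequence):
            if ch == AMBIGUOUS or (ch == GAP and GAP not in self.states):
                out[i, :] = 1.0
            else:
                out[i, self.states.index(ch)] = 1.0
        return out

    @classmethod
    def empirical(
        cls,
        name: str = "LG",
        alpha: float = 1.0,
        n_categories: int = 4,
        gap_mode: str = "state",
        gap_frequency: float = 0.05,
        msa: "MSA | None" = None,
    ) -> "SubstitutionModel":
        """Build LG/WAG/JTT, optionally extended with a 21st gap state.

        With ``gap_mode="state"`` the gap exchangeability to every amino acid
        is uniform (1.0) and the gap frequency comes from ``msa`` when given,
        else ``gap_frequency``.
        """
        key = name.upper()
        if key not in EMPIRICAL_MODELS:
            raise DomainError(f"unknown empirical model {name!r}")
        S20, pi20 = EMPIRICAL_MODELS[key]
        if gap_mode == "missing":
            return cls(S20.copy(), pi20.copy(), alpha=alpha,
                       n_categories=n_categories, states=AA_ORDER, name=key)
        if gap_mode != "state":
            raise DomainError("gap_mode must be 'state' or 'missing'")
        if msa is not None:
            total = sum(len(r) for r in msa.rows)
            gaps = sum(r.count(GAP) for r in msa.rows)
            gap_frequency = max(gaps / total, 1e-4)
        if not 0 < gap_frequency < 1:
            raise DomainError("gap frequency must be in (0, 1)")
        n = 21
        S = np.zeros((n, n))
        S[:20, :20] = S20
        S[20, :20] = S[:20, 20] = 1.0
        pi = np.empty(n)
        pi[:20] = pi20 * (1.0 - gap_frequency)
        pi[20] = gap_frequency
        return cls(S, pi, alpha=alpha, n_categories=n_categories,
                   states=AA_ORDER + GAP, name=key + "+gap")


# ---------------------------------------------------------------------------
# pruning machinery
# ---------------------------------------------------------------------------

def _check_pairing(msa: MSA, tree: Tree) -> None:
    missing = set(tree.leaf_names) - set(msa.names)
    if missing:
        raise PairingError(f"leaves without sequences: {sorted(missing)}")


def _upward_partials(msa, tree, model, rate):
    """Conditional (below-subtree) likelihoods per node for one rate class.

    Returns dict node_id -> (n_sites, n_states) array, plus the per-edge
    transition matrices used.
    """
    P = {}
    for node in tree.preorder():
        if node.parent is not None:
            P[node.id] = model.transition_matrix(node.length * rate)
    up = {}
    for node in tree.postorder():
        if node.is_leaf:
            up[node.id] = model.encode(msa.sequence(node.label))
        else:
            acc = None
            for child in node.children:
                contrib = up[child.id] @ P[child.id].T
                acc = contrib if acc is None else acc * contrib
            up[node.id] = acc
    return up, P


def tree_log_likelihood(msa: MSA, tree: Tree, model: SubstitutionModel) -> float:
    """Log-likelihood of the alignment: summed over ancestral states by
    pruning, averaged over gamma categories with equal weights."""
    _check_pairing(msa, tree)
    n_sites = msa.length
    site_lik = np.zeros(n_sites)
    pi = model.frequencies
    for rate in model.category_rates:
        up, _ = _upward_partials(msa, tree, model, rate)
        site_lik += up[tree.root.id] @ pi
    site_lik /= model.n_categories
    if np.any(site_lik <= 0):
        return -np.inf
    return float(np.log(site_lik).sum())


def estimate_alpha(
    msa: MSA,
    tree: Tree,
    model_name: str = "LG",
    n_categories: int = 4,
    gap_mode: str = "state",
    bounds: tuple[float, float] = (0.05, 20.0),
    tol: float = 1e-4,
) -> float:
    """Estimate the gamma shape by 1-D likelihood maximization
    (golden-section / Brent on log alpha, tolerance 1e-4)."""

    def neg(log_alpha: float) -> float:
        model = SubstitutionModel.empirical(
            model_name, alpha=math.exp(log_alpha),
            n_categories=n_categories, gap_mode=gap_mode, msa=msa)
        return -tree_log_likelihood(msa, tree, model)

    res = minimize_scalar(
        neg, bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded", options={"xatol": tol})
    return float(math.exp(res.x))


@dataclass
class AncestralReconstruction:
    """Per-node, per-site marginal posteriors with ML and sampling access."""

    tree: Tree
    model: SubstitutionModel
    posteriors: dict[str, np.ndarray]         # node id -> (n_sites, n_states)
    ml_sequences: dict[str, str]
    mean_posteriors: dict[str, float]
    log_likelihood: float
    sampled_sequences: dict[str, list[str]] = field(default_factory=dict)

    @property
    def states(self) -> str:
        return self.model.states

    def internal_ids(self) -> list[str]:
        return [n.id for n in self.tree.internal_nodes()]

    def export_posteriors(self, path) -> None:
        import pandas as pd

        rows = []
        for node_id, post in sorted(self.posteriors.items()):
            for site in range(post.shape[0]):
                rows.append([node_id, site] + list(post[site]))
        cols = ["node", "site"] + [f"p_{s}" for s in self.states]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)

    def export_sequences(self, path) -> None:
        with open(path, "w") as fh:
            for node_id, seq in sorted(self.ml_sequences.items()):
                fh.write(f">{node_id}\n{seq}\n")


def marginal_asr(msa: MSA, tree: Tree, model: SubstitutionModel) -> AncestralReconstruction:
    """Marginal reconstruction at every internal node.

    The posterior at node v, site i, state x is proportional to the product
    of below-subtree and outside partial likelihoods (the outside pass
    carries the root prior), mixed over gamma categories weighted by each
    category's site likelihood.  Argmax ties break alphabetically.
    """
    _check_pairing(msa, tree)
    if len(tree.root.children) == 0:
        raise DomainError("tree must have at least one internal node")
    n_sites = msa.length
    n_states = model.n_states
    pi = model.frequencies
    internal = [n for n in tree.internal_nodes()]

    joint_sum = {n.id: np.zeros((n_sites, n_states)) for n in internal}
    site_lik_sum = np.zeros(n_sites)

    for rate in model.category_rates:
        up, P = _upward_partials(msa, tree, model, rate)
        out = {tree.root.id: np.tile(pi, (n_sites, 1))}
        for node in tree.preorder():
            for child in node.children:
                if child.is_leaf:
                    continue
                sib = out[node.id].copy()
                for other in node.children:
                    if other is not child:
                        sib *= up[other.id] @ P[other.id].T
                out[child.id] = sib @ P[child.id]
        cat_site_lik = up[tree.root.id] @ pi
        site_lik_sum += cat_site_lik
        for node in internal:
            joint_sum[node.id] += up[node.id] * out[node.id]

    site_lik = site_lik_sum / model.n_categories
    if np.any(site_lik <= 0):
        raise DomainError("zero site likelihood; check inputs")

    posteriors = {}
    ml_sequences = {}
    mean_posteriors = {}
    state_arr = np.array(list(model.states))
    order = np.argsort(state_arr, kind="stable")  # alphabetical tie-break
    for node in internal:
        post = joint_sum[node.id] / site_lik_sum[:, None]
        post /= post.sum(axis=1, keepdims=True)
        posteriors[node.id] = post
        sorted_post = post[:, order]
        best = np.argmax(sorted_post, axis=1)  # first max = alphabetical min
        ml_idx = order[best]
        ml_sequences[node.id] = "".join(state_arr[ml_idx])
        mean_posteriors[node.id] = float(post[np.arange(n_sites), ml_idx].mean())

    return AncestralReconstruction(
        tree=tree,
        model=model,
        posteriors=posteriors,
        ml_sequences=ml_sequences,
        mean_posteriors=mean_posteriors,
        log_likelihood=float(np.log(site_lik).sum()),
    )


def sample_ancestral(
    recon: AncestralReconstruction, node: str, n: int, seed: int
) -> list[str]:
    """Draw ``n`` ancestral sequences at an internal node, each site drawn
    independently from its marginal posterior; reproducible given seed."""
    if n < 1:
        raise DomainError("need n >= 1 draws")
    if node not in recon.posteriors:
        raise DomainError(f"{node!r} is not an internal node with posteriors")
    post = recon.posteriors[node]
    rng = np.random.default_rng(seed)
    states = np.array(list(recon.states))
    n_sites = post.shape[0]
    draws = []
    cum = np.cumsum(post, axis=1)
    cum[:, -1] = 1.0
    for _ in range(n):
        u = rng.random(n_sites)
        idx = (u[:, None] > cum).sum(axis=1)
        draws.append("".join(states[idx]))
    recon.sampled_sequences.setdefault(node, []).extend(draws)
    return draws


def node_mean_posterior(recon: AncestralReconstruction, node: str) -> float:
    """Mean over alignment columns of the ML state's posterior probability."""
    if node not in recon.mean_posteriors:
        raise DomainError(f"{node!r} is not a reconstructed internal node")
    return recon.mean_posteriors[node]
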