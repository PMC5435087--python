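"""Synthetic-data generators with machine-readable ground truth.

Every downstream stage has a generator here that produces its exact input
format: alignments evolved on a tree under the ASR substitution model,
replicate affinity profiles driven by a site-weight motif score, BM traits
with injected branch rate multipliers, and 1:1 Langmuir sensorgrams.
All generators are seed-deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .affinity import AffinityProfile, SyntheticPredictor
from .asr import SubstitutionModel
from .core_io import MSA, Node, Tree
from .errors import DomainError
from .kinetics import Sensorgram

__all__ = [
    "SimulationTruth",
    "birth_tree",
    "simulate_alignment",
    "constant_truth",
    "inject_substitution",
    "simulate_affinity_profiles",
    "simulate_bm_trait",
    "simulate_sensorgram",
    "DEFAULT_MOTIF_WEIGHTS",
]

# two-site motif: a "contact histidine" analog and a "basic patch" analog
DEFAULT_MOTIF_WEIGHTS = {10: {"H": 0.7}, 40: {"K": 0.3}}


@dataclass
class SimulationTruth:
    """Ground truth emitted next to every synthetic data set."""

    tree: Tree
    sequences: dict[str, str] = field(default_factory=dict)     # node -> seq
    affinities: dict[str, float] = field(default_factory=dict)  # node -> pKd
    shift_branches: dict[str, float] = field(default_factory=dict)  # child -> delta
    rate_multipliers: dict[str, float] = field(default_factory=dict)
    trait_values: dict[str, float] = field(default_factory=dict)
    kinetics: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def write_json(self, path) -> None:
        payload = {
            "newick": self.tree.to_newick() if self.tree is not None else None,
            "sequences": self.sequences,
            "affinities": self.affinities,
            "shift_branches": self.shift_branches,
            "rate_multipliers": self.rate_multipliers,
            "trait_values": self.trait_values,
            "kinetics": self.kinetics,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def birth_tree(n_leaves: int = 32, seed: int = 0,
               length_range: tuple[float, float] = (0.05, 0.5)) -> Tree:
    """Pure-birth topology with U(length_range) branch lengths."""
    if n_leaves < 2:
        raise DomainError("need >= 2 leaves")
    rng = np.random.default_rng(seed)
    lo, hi = length_range

    def draw() -> float:
        return float(rng.uniform(lo, hi))

    root = Node()
    tips = []
    for _ in range(2):
        tips.append(root.add_child(Node(length=draw())))
    while len(tips) < n_leaves:
        tip = tips.pop(rng.integers(len(tips)))
        for _ in range(2):
            tips.append(tip.add_child(Node(length=draw())))
    leaves = [n for n in _preorder(root) if not n.children]
    for i, leaf in enumerate(leaves):
        leaf.label = f"t{i + 1}"
    return Tree(root)


def _preorder(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


def simulate_alignment(tree: Tree, model: SubstitutionModel, n_sites: int,
                       seed: int = 0) -> tuple[MSA, SimulationTruth]:
    """Evolve sequences down the tree: root from the equilibrium
    frequencies, each branch via P(branch length * site rate).

    Per-site rate categories are drawn uniformly from the model's discrete
    gamma categories, matching the likelihood's assumptions.
    """
    if n_sites < 1:
        raise DomainError("need n_sites >= 1")
    rng = np.random.default_rng(seed)
    states = np.array(list(model.states))
    n_states = model.n_states
    site_rates = model.category_rates[
        rng.integers(model.n_categories, size=n_sites)]
    seqs: dict[str, np.ndarray] = {}
    root_states = rng.choice(n_states, size=n_sites, p=model.frequencies)
    seqs[tree.root.id] = root_states
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = seqs[node.parent.id]
        child_states = np.empty(n_sites, dtype=int)
        for rate in np.unique(site_rates):
            mask = site_rates == rate
            P = model.transition_matrix(node.length * rate)
            cum = np.cumsum(P, axis=1)
            u = rng.random(mask.sum())
            rows = cum[parent_states[mask]]
            child_states[mask] = (u[:, None] > rows).sum(axis=1)
        seqs[node.id] = child_states
    sequences = {k: "".join(states[v]) for k, v in seqs.items()}
    truth = SimulationTruth(tree=tree, sequences=sequences, seed=seed)
    leaves = tree.leaf_names
    msa = MSA(leaves, [sequences[name] for name in leaves])
    return msa, truth


def constant_truth(tree: Tree, sequence: str) -> SimulationTruth:
    """Truth object with the same sequence at every node (a blank canvas for
    :func:`inject_substitution`)."""
    sequences = {n.id: sequence for n in tree.preorder()}
    return SimulationTruth(tree=tree, sequences=sequences)


def inject_substitution(truth: SimulationTruth, node_id: str, site: int,
                        residue: str) -> SimulationTruth:
    """Force ``residue`` at ``site`` in ``node_id`` and all its descendants,
    modeling a substitution on the branch above ``node_id``."""
    node = truth.tree.node(node_id)
    if site < 0 or site >= len(next(iter(truth.sequences.values()))):
        raise DomainError(f"site {site} out of range")
    stack = [node]
    while stack:
        n = stack.pop()
        seq = truth.sequences[n.id]
        truth.sequences[n.id] = seq[:site] + residue + seq[site + 1:]
        stack.extend(n.children)
    return truth


def simulate_affinity_profiles(
    truth: SimulationTruth,
    weights: dict[int, dict[str, float]] = None,
    baseline: float = 4.3,
    noise_sd: float = 0.1,
    n_reps: int = 5,
    seed: int = 0,
) -> dict[str, AffinityProfile]:
    """Replicate pKd profiles for every node from its TRUE sequence.

    Records each node's noiseless motif score in ``truth.affinities`` and
    every branch with a nonzero score change in ``truth.shift_branches``.
    """
    if weights is None:
        weights = DEFAULT_MOTIF_WEIGHTS
    predictor = SyntheticPredictor(weights, baseline, noise_sd)
    seed_seq = np.random.SeedSequence(seed)
    nodes = [n.id for n in truth.tree.preorder()]
    child_seeds = seed_seq.spawn(len(nodes))
    profiles = {}
    for node_id, child_seq in zip(nodes, child_seeds):
        node_seed = int(child_seq.generate_state(1)[0])
        reps = predictor.predict(truth.sequences[node_id], n_reps, node_seed)
        profiles[node_id] = AffinityProfile(node_id, reps, source="ml")
        truth.affinities[node_id] = predictor.score(truth.sequences[node_id])
    truth.shift_branches = {}
    for node in truth.tree.preorder():
        if node.parent is None:
            continue
        delta = truth.affinities[node.id] - truth.affinities[node.parent.id]
        if delta != 0.0:
            truth.shift_branches[node.id] = delta
    return profiles


def simulate_bm_trait(
    tree: Tree,
    sigma2: float,
    shifts: dict[str, float] = None,
    ses: dict[str, float] = None,
    seed: int = 0,
    root_value: float = 0.0,
) -> tuple[dict[str, float], SimulationTruth]:
    """Brownian trait down the tree with branch rate multipliers.

    child = parent + N(0, sigma2 * multiplier * branch length); observed
    values add N(0, se^2) noise.  Returns (observed values, truth); the
    truth carries noiseless node values and the effective multipliers.
    """
    shifts = shifts or {}
    ses = ses or {}
    if any(m <= 0 for m in shifts.values()):
        raise DomainError("multipliers must be > 0")
    if sigma2 < 0:
        raise DomainError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    true_vals: dict[str, float] = {tree.root.id: root_value}
    mult: dict[str, float] = {}
    for node in tree.preorder():
        if node.parent is None:
            mult[node.id] = 1.0
            continue
        mult[node.id] = shifts.get(node.id, mult[node.parent.id])
        var = sigma2 * mult[node.id] * node.length
        step = rng.normal(0.0, math.sqrt(var)) if var > 0 else 0.0
        true_vals[node.id] = true_vals[node.parent.id] + step
    observed = {}
    for node_id, val in true_vals.items():
        se = ses.get(node_id, 0.0)
        observed[node_id] = val + (rng.normal(0.0, se) if se > 0 else 0.0)
    truth = SimulationTruth(tree=tree, trait_values=true_vals,
                            rate_multipliers=mult, seed=seed)
    return observed, truth


def simulate_sensorgram(
    kd: float,
    kon: float,
    concs,
    times=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    rmax: float = 1.0,
    association_s: float = 360.0,
    dissociation_s: float = 240.0,
    n_controls: int = 2,
) -> tuple[Sensorgram, SimulationTruth]:
    """1:1 Langmuir sensorgram at a concentration series.

    Association R(t) = Rmax*C/(C+Kd) * (1 - exp(-(kon*C + koff) t)) with
    koff = kon*Kd; dissociation decays from the association endpoint at
    rate koff.  Control probes are emitted as noise-only series.
    """
    if kd <= 0 or kon <= 0:
        raise DomainError("kd and kon must be > 0")
    koff = kon * kd
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.arange(0.0, association_s, 1.0)
    times = np.asarray(times, dtype=float)
    t_dis = times[times <= dissociation_s]
    rows = []
    for i, conc in enumerate(concs):
        pid = f"probe_{i + 1}"
        plateau = rmax * conc / (conc + kd)
        kobs = kon * conc + koff
        assoc = plateau * (1.0 - np.exp(-kobs * times))
        assoc_noisy = assoc + rng.normal(0.0, noise_sd, size=times.size)
        end = assoc[-1]
        dis = end * np.exp(-koff * t_dis)
        dis_noisy = dis + rng.normal(0.0, noise_sd, size=t_dis.size)
        for t, r in zip(times, assoc_noisy):
            rows.append((t, conc, r, pid, "association"))
        for t, r in zip(t_dis, dis_noisy):
            rows.append((t, conc, r, pid, "dissociation"))
    for j in range(n_controls):
        pid = f"control_{j + 1}"
        for t in times:
            rows.append((t, 0.0, float(rng.normal(0.0, noise_sd)), pid,
                         "association"))
        for t in t_dis:
            rows.append((t, 0.0, float(rng.normal(0.0, noise_sd)), pid,
                         "dissociation"))
    df = pd.DataFrame(
        rows, columns=["time_s", "conc_M", "response", "probe_id", "phase"])
    sensorgram = Sensorgram(df)
    truth = SimulationTruth(
        tree=None, kinetics={"kd": kd, "kon": kon, "koff": koff, "rmax": rmax},
        seed=seed)
    return sensorgram, truth
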