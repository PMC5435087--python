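"""pKd algebra, replicate aggregation, and the pluggable predictor contract.

Kd is carried in molar units internally; micromolar appears only at I/O
boundaries.  pKd = -log10(Kd [M]).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "pkd_from_kd",
    "kd_from_pkd",
    "fold_change",
    "aggregate_replicates",
    "AffinityProfile",
    "PredictorContract",
    "SyntheticPredictor",
    "synthetic_predictor",
    "read_profiles",
    "write_profiles",
]


def pkd_from_kd(kd: float) -> float:
    """-log10 of a dissociation constant given in molar."""
    if kd <= 0:
        raise DomainError(f"Kd must be > 0 M, got {kd}")
    return -math.log10(kd)


def kd_from_pkd(pkd: float) -> float:
    """Inverse of :func:`pkd_from_kd`; returns molar."""
    if not math.isfinite(pkd):
        raise DomainError("pKd must be finite")
    return 10.0 ** (-pkd)


def fold_change(kd_a: float, kd_b: float) -> float:
    """Ratio of the larger to the smaller Kd (always >= 1)."""
    if kd_a <= 0 or kd_b <= 0:
        raise DomainError("Kd values must be > 0")
    hi, lo = max(kd_a, kd_b), min(kd_a, kd_b)
    return hi / lo


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sd with ddof=1 over sqrt n) of replicates."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DomainError("no replicates to aggregate")
    mean = float(arr.mean())
    if arr.size == 1:
        warnings.warn("single replicate: SE reported as 0", stacklevel=2)
        return mean, 0.0
    se = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, se


@dataclass
class AffinityProfile:
    """Replicate pKd values for one node with derived mean and SE."""

    node_id: str
    replicates: list[float]
    source: str = "ml"  # ml | sampled | experimental
    mean: float = field(init=False)
    se: float = field(init=False)

    def __post_init__(self) -> None:
        if self.source not in ("ml", "sampled", "experimental"):
            raise DomainError(f"unknown source tag {self.source!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.mean, self.se = aggregate_replicates(self.replicates)

    @property
    def n(self) -> int:
        return len(self.replicates)


class PredictorContract(Protocol):
    """Callable surface every affinity predictor must provide."""

    def predict(self, sequence: str, n_replicates: int, seed: int) -> list[float]:
        ...


class SyntheticPredictor:
    """Additive site-weight predictor with Gaussian replicate noise.

    predict(seq, n, seed) = baseline + sum of per-site residue weights
    + iid N(0, noise_sd) per replicate.  Deterministic in (sequence, seed).
    """

    def __init__(
        self,
        weights: dict[int, dict[str, float]],
        baseline: float,
        noise_sd: float = 0.0,
    ):
        if noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        self.weights = {int(k): dict(v) for k, v in weights.items()}
        self.baseline = float(baseline)
        self.noise_sd = float(noise_sd)

    def score(self, sequence: str) -> float:
        total = self.baseline
        for site, table in self.weights.items():
            if site < 0 or site >= len(sequence):
                raise DomainError(
                    f"weight site {site} out of range for sequence of "
                    f"length {len(sequence)}")
            total += table.get(sequence[site], 0.0)
        return total

    def predict(self, sequence: str, n_replicates: int, seed: int) -> list[float]:
        if n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")
        base = self.score(sequence)
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, self.noise_sd, size=n_replicates)
        return [base + float(x) for x in noise]


def synthetic_predictor(
    weights: dict[int, dict[str, float]], baseline: float, noise_sd: float = 0.0
) -> SyntheticPredictor:
    """Factory matching the predictor contract; see :class:`SyntheticPredictor`."""
    return SyntheticPredictor(weights, baseline, noise_sd)


# ---------------------------------------------------------------------------
# TSV I/O: node_id, source, rep_1..rep_n, mean, se
# ---------------------------------------------------------------------------

def write_profiles(profiles: dict[str, AffinityProfile], path) -> None:
    n_max = max(p.n for p in profiles.values())
    rows = []
    for node_id in sorted(profiles):
        p = profiles[node_id]
        reps = list(p.replicates) + [math.nan] * (n_max - p.n)
        rows.append([p.node_id, p.source] + reps + [p.mean, p.se])
    cols = (["node_id", "source"] + [f"rep_{i + 1}" for i in range(n_max)]
            + ["mean", "se"])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> dict[str, AffinityProfile]:
    df = pd.read_csv(path, sep="\t")
    rep_cols = [c for c in df.columns if c.startswith("rep_")]
    if not rep_cols or "node_id" not in df.columns:
        raise DomainError("profile TSV needs node_id and rep_* columns")
    out = {}
    for _, row in df.iterrows():
        reps = [float(row[c]) for c in rep_cols if not pd.isna(row[c])]
        source = str(row.get("source", "ml"))
        out[str(row["node_id"])] = AffinityProfile(
            str(row["node_id"]), reps, source=source)
    return out
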