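"""Binding-kinetics curve fitting from label-free sensorgram data.

Steady-state Kd comes from a one-site binding curve fit to plateau responses
across the concentration series; Km comes from a hyperbolic fit to initial
association rates extracted from single-exponential fits of each
association phase.  Comparisons between constants happen on the -log10
scale with unequal-variance t tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .affinity import aggregate_replicates
from .errors import DomainError, FitError
from .shift_scan import welch_t

__all__ = [
    "Sensorgram",
    "BindingFit",
    "subtract_reference",
    "steady_state_fit",
    "association_kinetics",
    "association_rates",
    "rate_constants",
    "steady_state_rates",
    "km_fit",
    "compare_affinities",
    "fit_sensorgram",
]

ASSOCIATION_SECONDS = 360.0   # 6 min association phase
DISSOCIATION_SECONDS = 240.0  # 4 min dissociation phase
SAMPLE_INTERVAL = 0.003       # 3 ms default sampling


@dataclass
class Sensorgram:
    """Long-format time-course table: time_s, conc_M, response, probe_id, phase.

    Analysis probes carry one concentration each; control probes (probe_id
    beginning with "control") track instrument drift and are subtracted by
    :func:`subtract_reference`.
    """

    data: pd.DataFrame

    REQUIRED = ("time_s", "conc_M", "response", "probe_id", "phase")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise DomainError(f"sensorgram table missing columns {missing}")
        for pid, grp in self.data.groupby("probe_id"):
            for phase, pgrp in grp.groupby("phase"):
                t = pgrp["time_s"].to_numpy()
                if np.any(np.diff(t) <= 0):
                    raise DomainError(
                        f"times not strictly increasing for probe {pid!r}")

    @property
    def concentrations(self) -> list[float]:
        mask = ~self.data["probe_id"].str.startswith("control")
        return sorted(self.data.loc[mask, "conc_M"].unique())

    def analysis_probes(self) -> list[str]:
        return sorted(
            p for p in self.data["probe_id"].unique()
            if not p.startswith("control"))

    def control_probes(self) -> list[str]:
        return sorted(
            p for p in self.data["probe_id"].unique()
            if p.startswith("control"))

    def phase(self, probe_id: str, phase: str) -> pd.DataFrame:
        out = self.data[(self.data["probe_id"] == probe_id)
                        & (self.data["phase"] == phase)]
        return out.sort_values("time_s")

    @classmethod
    def read_tsv(cls, path) -> "Sensorgram":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class BindingFit:
    """Replicate-aggregated binding constants (molar) with pKd-scale SEs."""

    kd: float
    kd_se: float
    km: float
    km_se: float
    rmax: float
    residual_rms: float = math.nan
    kd_replicates: list[float] = field(default_factory=list)
    km_replicates: list[float] = field(default_factory=list)


def subtract_reference(sensorgram: Sensorgram) -> Sensorgram:
    """Subtract the pointwise mean of all control probes from every analysis
    probe (matching on phase and time grid)."""
    controls = sensorgram.control_probes()
    if not controls:
        raise DomainError("no control probes present")
    df = sensorgram.data
    ctrl = (df[df["probe_id"].isin(controls)]
            .groupby(["phase", "time_s"])["response"].mean())
    rows = []
    for pid in sensorgram.analysis_probes():
        probe = df[df["probe_id"] == pid].copy()
        key = list(zip(probe["phase"], probe["time_s"]))
        try:
            baseline = ctrl.loc[key].to_numpy()
        except KeyError as exc:
            raise DomainError(
                f"control grid misaligned with probe {pid!r}") from exc
        probe["response"] = probe["response"].to_numpy() - baseline
        rows.append(probe)
    return Sensorgram(pd.concat(rows, ignore_index=True))


def _one_site(conc, rmax, kd):
    return rmax * conc / (kd + conc)


def _hyperbolic_fit(x, y, label: str) -> tuple[float, float]:
    """Shared multi-start least-squares for R = Rmax*C/(K + C)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise DomainError(f"{label}: need >= 4 points")
    if np.ptp(y) == 0:
        raise FitError(f"{label}: responses are constant (unidentifiable)")
    pos = x[x > 0]
    half = y.max() / 2.0
    k_inits = [float(np.exp(np.mean(np.log(pos)))),
               float(pos[np.argmin(np.abs(y[x > 0] - half))])]
    best = None
    for k0 in k_inits:
        try:
            popt, _ = curve_fit(
                _one_site, x, y, p0=[y.max(), k0],
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(((y - _one_site(x, *popt)) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise FitError(f"{label}: nonlinear fit failed to converge "
                       f"(inits tried: {k_inits})")
    rss, (rmax, k) = best
    if k <= 0:
        raise FitError(f"{label}: fitted constant non-positive")
    return float(k), float(rmax)


def steady_state_fit(concs, plateaus) -> tuple[float, float]:
    """Fit R = Rmax*C/(Kd + C) to steady-state responses; returns (Kd, Rmax)."""
    kd, rmax = _hyperbolic_fit(concs, plateaus, "steady-state fit")
    return kd, rmax


def _association_curve(t, req, kobs):
    return req * (1.0 - np.exp(-kobs * t))


def association_kinetics(sensorgram: Sensorgram) -> list[tuple[float, float, float]]:
    """Per-concentration (conc, Req, kobs) from single-exponential fits of
    each association phase.  Under 1:1 kinetics kobs = kon*C + koff."""
    out = []
    for pid in sensorgram.analysis_probes():
        assoc = sensorgram.phase(pid, "association")
        if assoc.empty:
            raise DomainError(f"probe {pid!r} has no association phase")
        conc = float(assoc["conc_M"].iloc[0])
        t = assoc["time_s"].to_numpy()
        r = assoc["response"].to_numpy()
        t = t - t[0]
        if conc == 0.0 or np.ptp(r) == 0:
            out.append((conc, 0.0, 0.0))
            continue
        # flag grossly non-monotone early phases (beyond noise) and skip
        head = r[: max(4, len(r) // 5)]
        noise = np.std(np.diff(r)) + 1e-30
        if head.size >= 4 and (head[-1] - head[0]) < -5 * noise:
            warnings.warn(
                f"non-monotone association phase for probe {pid!r}; excluded",
                stacklevel=2)
            continue
        try:
            popt, _ = curve_fit(
                _association_curve, t, r, p0=[r.max(), 1.0 / max(t[-1], 1e-9)],
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000)
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"association fit failed for probe {pid!r}") from exc
        req, kobs = popt
        out.append((conc, float(req), float(kobs)))
    return sorted(out)


def association_rates(sensorgram: Sensorgram) -> list[tuple[float, float]]:
    """Initial binding rate per concentration: rate = Req * kobs, the fitted
    association curve's slope at t = 0.

    Note: under ideal 1:1 kinetics this quantity is exactly linear in
    concentration (Rmax * kon * C); see :func:`steady_state_rates` for the
    saturating rate readout used to estimate Km.
    """
    return [(conc, req * kobs)
            for conc, req, kobs in association_kinetics(sensorgram)]


def rate_constants(kin: list[tuple[float, float, float]]) -> tuple[float, float]:
    """(kon, koff) by linear regression of kobs on concentration."""
    pts = [(c, kobs) for c, _, kobs in kin if c > 0]
    if len(pts) < 2:
        raise DomainError("need >= 2 nonzero concentrations for kobs fit")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    kon, koff = np.polyfit(x, y, 1)
    if kon <= 0:
        raise FitError("fitted kon is non-positive")
    return float(kon), float(max(koff, 0.0))


def steady_state_rates(sensorgram: Sensorgram) -> list[tuple[float, float]]:
    """Equilibrium binding-flux readout per concentration: Req * koff.

    At steady state association and dissociation fluxes balance, so this
    saturates hyperbolically with half-max at Kd and is the rate series fed
    to :func:`km_fit` by the full pipeline.
    """
    kin = association_kinetics(sensorgram)
    _, koff = rate_constants(kin)
    return [(conc, req * koff) for conc, req, _ in kin]


def km_fit(rates, method: str = "fit") -> float:
    """Half-saturation constant of rate = Vmax*C/(Km + C).

    ``method="fit"`` does the hyperbolic least-squares fit;
    ``method="interpolate"`` linearly interpolates the concentration at half
    the maximum observed rate.
    """
    concs = [c for c, _ in rates]
    vals = [v for _, v in rates]
    if method == "interpolate":
        order = np.argsort(vals)
        half = max(vals) / 2.0
        return float(np.interp(half, np.asarray(vals)[order],
                               np.asarray(concs)[order]))
    if method != "fit":
        raise DomainError("method must be 'fit' or 'interpolate'")
    km, _ = _hyperbolic_fit(concs, vals, "Km fit")
    return km


def compare_affinities(reps_a, reps_b) -> float:
    """Welch p-value comparing two replicate sets of binding constants on the
    -log10 (pKd) scale."""
    a = [-math.log10(v) for v in reps_a]
    b = [-math.log10(v) for v in reps_b]
    _, p = welch_t(a, b)
    return p


def fit_sensorgram(sensorgram: Sensorgram,
                   subtract_controls: bool = True) -> dict[str, float]:
    """Full single-experiment pipeline: reference subtraction, steady-state
    Kd, association rates, and Km."""
    if subtract_controls and sensorgram.control_probes():
        sensorgram = subtract_reference(sensorgram)
    concs, plateaus = [], []
    for pid in sensorgram.analysis_probes():
        assoc = sensorgram.phase(pid, "association")
        conc = float(assoc["conc_M"].iloc[0])
        tail = assoc["response"].to_numpy()[-max(3, len(assoc) // 10):]
        concs.append(conc)
        plateaus.append(float(tail.mean()))
    kd, rmax = steady_state_fit(concs, plateaus)
    kin = association_kinetics(sensorgram)
    kon, koff = rate_constants(kin)
    km = km_fit([(c, req * koff) for c, req, _ in kin])
    return {"kd": kd, "km": km, "rmax": rmax, "kon": kon, "koff": koff}


def aggregate_fits(fits: list[dict[str, float]]) -> BindingFit:
    """Combine >= 1 replicate experiments; SEs computed on the pKd scale."""
    kds = [f["kd"] for f in fits]
    kms = [f["km"] for f in fits]
    pkd_mean, pkd_se = aggregate_replicates([-math.log10(k) for k in kds])
    pkm_mean, pkm_se = aggregate_replicates([-math.log10(k) for k in kms])
    return BindingFit(
        kd=10 ** (-pkd_mean), kd_se=pkd_se,
        km=10 ** (-pkm_mean), km_se=pkm_se,
        rmax=float(np.mean([f["rmax"] for f in fits])),
        kd_replicates=kds, km_replicates=kms,
    )
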