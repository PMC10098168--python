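"""Convergence checks and calibration diagnostics.

Convergence follows the two-chain protocol: per-variable effective size
(Geyer initial-positive-sequence estimator) and between-chain discrepancy
|mean1 - mean2| / pooled SD, with pass thresholds ESS >= 50 and d <= 0.30.

Calibration cross-validation scores each calibration by how well dating
runs that include it recover the fossil intervals of the *other*
calibrated clades; the duplicate-calibration variance compares posterior
mean ages across clades that share one calibration (lower variance =
more internally consistent clock model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from phyloclock.dating import ChainTrace, GridResult, RootPrior

__all__ = [
    "effective_size",
    "chain_discrepancy",
    "ConvergenceReport",
    "convergence_report",
    "prior_boundary_check",
    "CVReport",
    "calibration_cross_validation",
    "duplicate_calibration_variance",
]


def effective_size(series) -> float:
    """Effective sample size ``n / (1 + 2*sum(rho_k))``.

    Autocorrelations are truncated with Geyer's initial positive sequence
    (sum consecutive lag pairs while their sum stays positive).  A constant
    series carries no autocorrelation evidence and returns n.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("series too short for ESS (need >= 10)")
    if np.ptp(x) == 0:
        return float(n)
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / var

    tau = 1.0
    k = 1
    while k + 1 < n:
        gamma = rho[k] + rho[k + 1]
        if gamma <= 0:
            break
        tau += 2.0 * gamma
        k += 2
    tau = max(tau, 1.0)
    return float(n / tau)


def chain_discrepancy(series_1, series_2) -> float:
    """|mean1 - mean2| in pooled-SD units (tracecomp convention)."""
    a = np.asarray(series_1, dtype=float)
    b = np.asarray(series_2, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both series must be non-empty")
    va = float(a.var(ddof=1)) if len(a) > 1 else 0.0
    vb = float(b.var(ddof=1)) if len(b) > 1 else 0.0
    diff = abs(float(a.mean()) - float(b.mean()))
    pooled = math.sqrt(0.5 * (va + vb))
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return diff / pooled


@dataclass
class ConvergenceReport:
    """Per-variable ESS and between-chain discrepancy with pass thresholds."""

    ess: Dict[str, float]
    discrepancy: Dict[str, float]
    min_ess: float = 50.0
    max_discrepancy: float = 0.30

    @property
    def passed(self) -> bool:
        return all(v >= self.min_ess for v in self.ess.values()) and all(
            d <= self.max_discrepancy for d in self.discrepancy.values()
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": v,
                "ess": self.ess[v],
                "discrepancy": self.discrepancy.get(v, float("nan")),
            }
            for v in self.ess
        ]
        return pd.DataFrame(rows)


def _trace_variables(trace: ChainTrace) -> Dict[str, np.ndarray]:
    out = {}
    ages = trace.retained_ages()
    for j, label in enumerate(trace.age_labels):
        out[f"age_{label}"] = ages[:, j]
    params = trace.retained_params()
    for col in params.columns:
        if col != "logpost":
            out[col] = params[col].to_numpy()
    return out


def convergence_report(
    traces: Sequence[ChainTrace],
    min_ess: float = 50.0,
    max_discrepancy: float = 0.30,
) -> ConvergenceReport:
    """Assess convergence across chains (ESS = min over chains)."""
    if not traces:
        raise ValueError("no traces")
    per_chain = [_trace_variables(t) for t in traces]
    variables = per_chain[0].keys()
    ess = {
        v: min(effective_size(chain[v]) for chain in per_chain) for v in variables
    }
    discrepancy = {}
    if len(per_chain) >= 2:
        for v in variables:
            discrepancy[v] = max(
                chain_discrepancy(per_chain[i][v], per_chain[j][v])
                for i in range(len(per_chain))
                for j in range(i + 1, len(per_chain))
            )
    return ConvergenceReport(
        ess=ess, discrepancy=discrepancy, min_ess=min_ess, max_discrepancy=max_discrepancy
    )


def prior_boundary_check(
    root_ages,
    root_prior: RootPrior,
    eps: float = 0.01,
    flag_fraction: float = 0.05,
) -> Tuple[bool, float]:
    """Detect posterior piling against the stated root-prior bounds.

    Returns (flag, fraction): fraction of samples within ``eps`` of the
    prior span of either bound; flagged when it exceeds ``flag_fraction``.
    Mirrors the relax-the-bound-and-rerun procedure: a flagged run should
    be repeated with a wider prior.
    """
    x = np.asarray(root_ages, dtype=float)
    if len(x) == 0:
        raise ValueError("empty trace")
    span = root_prior.old_bound - root_prior.young_bound
    tol = eps * span
    near = (np.abs(x - root_prior.old_bound) <= tol) | (
        np.abs(x - root_prior.young_bound) <= tol
    )
    fraction = float(near.mean())
    return fraction > flag_fraction, fraction


# ------------------------------------------------------------------- CV


@dataclass
class CVReport:
    """Held-out fossil-recovery table plus per-calibration recovery rates."""

    rows: pd.DataFrame  # model, subset, clade, mean, lo95, hi95, fossil bounds, status
    informativeness: pd.DataFrame  # calibration -> recovery rate when active

    def recovered_fraction(self) -> float:
        evaluated = self.rows[self.rows["status"] != "missing"]
        if len(evaluated) == 0:
            return float("nan")
        return float((evaluated["status"] == "recovered").mean())


def _status(mean: float, lo: float, hi: float) -> str:
    if mean < lo:
        return "underestimate"
    if mean > hi:
        return "overestimate"
    return "recovered"


def calibration_cross_validation(
    grid: GridResult,
    fossil_intervals: Dict[str, Tuple[float, float]],
    clade_groups: Dict[str, str],
) -> CVReport:
    """Score calibrations by held-out fossil recovery.

    ``fossil_intervals`` maps clade (= calibration) names to (min, max)
    ages; ``clade_groups`` maps each clade name to its calibration group.
    A clade is evaluated only in cells where its own calibration is
    inactive (self-exclusion).
    """
    rows: List[dict] = []
    for cell in grid.cells:
        for clade, (lo, hi) in fossil_intervals.items():
            if clade_groups.get(clade) in cell.subset:
                continue  # self-exclusion: its calibration is active here
            entry = cell.summaries.get(clade) if not cell.error else None
            if entry is None:
                status, mean, mlo, mhi = "missing", np.nan, np.nan, np.nan
            else:
                mean, mlo, mhi = entry["mean"], entry["lo95"], entry["hi95"]
                status = _status(mean, lo, hi)
            rows.append(
                {
                    "model": cell.model,
                    "subset": "+".join(cell.subset) if cell.subset else "none",
                    "clade": clade,
                    "mean_age": mean,
                    "lo95": mlo,
                    "hi95": mhi,
                    "fossil_min": lo,
                    "fossil_max": hi,
                    "status": status,
                }
            )
    table = pd.DataFrame(rows)

    groups = sorted({g for g in clade_groups.values() if g})
    info_rows = []
    for group in groups:
        mask = table["subset"].str.split("+", regex=False).apply(lambda s: group in s)
        evaluated = table[mask & (table["status"] != "missing")]
        rate = (
            float((evaluated["status"] == "recovered").mean())
            if len(evaluated)
            else float("nan")
        )
        info_rows.append({"calibration": group, "recovery_rate": rate, "n": len(evaluated)})
    return CVReport(rows=table, informativeness=pd.DataFrame(info_rows))


def duplicate_calibration_variance(mean_ages: Sequence[float]) -> Tuple[float, float]:
    """Population variance and SD of posterior mean ages across clades that
    share one calibration; lower = more internally consistent model."""
    x = np.asarray(mean_ages, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 co-calibrated clades")
    var = float(np.mean((x - x.mean()) ** 2))
    return var, math.sqrt(var)
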