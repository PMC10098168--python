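"""Branch-rate processes: uncorrelated gamma (UGAM), autocorrelated
lognormal (LN, geometric Brownian motion with mean-preserving drift) and
the mean-reverting square-root process (CIR).

All three are parameterized as mean-1 multipliers of a separate global
rate ``mu``, so chronogram expectations are directly comparable between
models.  The effective rate of a branch is the arithmetic mean of its
endpoint rates for the autocorrelated models (a standard discretization),
and the branch multiplier itself for UGAM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import ive

from phyloclock.trees import PhyloTree

__all__ = [
    "RateModelParams",
    "RateAssignment",
    "simulate_rates",
    "branch_log_density",
    "stationary_moments",
    "MODELS",
]

MODELS = ("UGAM", "LN", "CIR")
_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class RateModelParams:
    """Parameters of one branch-rate model.

    UGAM uses ``nu`` (variance of the unit-mean gamma multiplier); LN uses
    ``sigma2`` (Brownian variance of log-rate per Ma); CIR uses reversion
    strength ``theta`` and diffusion ``sigma`` with the Feller condition
    2*theta > sigma**2 enforced.  ``mu`` is the global rate in
    substitutions/site/Ma.
    """

    model: str
    nu: Optional[float] = None
    sigma2: Optional[float] = None
    theta: Optional[float] = None
    sigma: Optional[float] = None
    mu: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.model == "UGAM":
            if self.nu is None or self.nu <= 0:
                raise ValueError("UGAM requires nu > 0")
        elif self.model == "LN":
            if self.sigma2 is None or self.sigma2 < 0:
                raise ValueError("LN requires sigma2 >= 0")
        else:  # CIR
            if self.theta is None or self.theta <= 0:
                raise ValueError("CIR requires theta > 0")
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("CIR requires sigma > 0")
            if 2.0 * self.theta <= self.sigma**2:
                raise ValueError(
                    "CIR parameters violate the Feller condition 2*theta > sigma**2"
                )


@dataclass
class RateAssignment:
    """Simulated rates on a chronogram.

    ``node_rates`` maps tip/internal labels (node key) to instantaneous
    rates for the autocorrelated models; ``branch_rates`` maps the child
    endpoint of each branch to the branch effective rate.  All values are
    dimensionless multipliers of ``mu``; the root rate is 1 by convention.
    """

    model: str
    node_rates: Dict[int, float] = field(default_factory=dict)
    branch_rates: Dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in list(self.node_rates.values()) + list(self.branch_rates.values()):
            if r <= 0:
                raise ValueError("rates must be strictly positive")

    def to_frame(self, tree: PhyloTree) -> pd.DataFrame:
        rows = []
        for i, node in enumerate(tree.postorder()):
            if node.parent is None:
                continue
            rows.append(
                {
                    "branch": node.label if node.is_tip else f"node{i}",
                    "r_parent": self.node_rates.get(id(node.parent), float("nan")),
                    "r_child": self.node_rates.get(id(node), float("nan")),
                    "r_branch": self.branch_rates[id(node)],
                }
            )
        return pd.DataFrame(rows)


def _cir_transition_params(theta: float, sigma: float, dt: float) -> Tuple[float, float]:
    """(c, df) of the exact CIR transition: Y = 2c*r(dt) ~ ncx2(df, lam)."""
    c = 2.0 * theta / (sigma**2 * (1.0 - math.exp(-theta * dt)))
    df = 4.0 * theta / sigma**2
    return c, df


def sample_cir_transition(
    r_parent, params: RateModelParams, dt: float, rng: np.random.Generator
):
    """Exact CIR transition draw(s) after elapsed time ``dt``."""
    c, df = _cir_transition_params(params.theta, params.sigma, dt)
    lam = 2.0 * c * np.asarray(r_parent) * math.exp(-params.theta * dt)
    y = rng.noncentral_chisquare(df, lam)
    return y / (2.0 * c)


def simulate_rates(
    chronogram: PhyloTree, params: RateModelParams, seed=None
) -> RateAssignment:
    """Draw per-branch rates on an ultrametric tree.

    UGAM branches are i.i.d. Gamma(1/nu, nu) multipliers.  LN log-rates
    follow Brownian motion with drift -sigma2*dt/2 (so the rate itself is
    a martingale).  CIR rates follow the exact noncentral-chi-square
    transition of dr = theta*(1-r)dt + sigma*sqrt(r)dW.
    """
    chronogram.validate_ages()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    node_rates: Dict[int, float] = {id(chronogram.root): 1.0}
    branch_rates: Dict[int, float] = {}

    for node in chronogram.preorder():
        if node.parent is None:
            continue
        dt = node.parent.age - node.age
        if params.model == "UGAM":
            r_b = float(rng.gamma(1.0 / params.nu, params.nu))
            branch_rates[id(node)] = max(r_b, 1e-300)
            continue
        r_p = node_rates[id(node.parent)]
        if params.model == "LN":
            if params.sigma2 == 0.0 or dt == 0.0:
                r_c = r_p
            else:
                s2 = params.sigma2 * dt
                r_c = float(
                    np.exp(rng.normal(math.log(r_p) - 0.5 * s2, math.sqrt(s2)))
                )
        else:  # CIR
            if dt == 0.0:
                r_c = r_p
            else:
                r_c = float(sample_cir_transition(r_p, params, dt, rng))
                r_c = max(r_c, 1e-300)
        node_rates[id(node)] = r_c
        branch_rates[id(node)] = 0.5 * (r_p + r_c)

    return RateAssignment(model=params.model, node_rates=node_rates, branch_rates=branch_rates)


# ----------------------------------------------------------------- densities


def _gamma_logpdf(x, shape: float, scale: float):
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        (shape - 1.0) * np.log(np.where(x > 0, x, 1.0))
        - x / scale
        - shape * math.log(scale)
        - math.lgamma(shape),
        -np.inf,
    )
    return out


def _ncx2_logpdf(x, df: float, nc: float):
    """Log-density of the noncentral chi-square (stable via exp-scaled Iv)."""
    x = np.asarray(x, dtype=float)
    v = 0.5 * df - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.sqrt(nc * x)
        log_iv = np.log(ive(v, z)) + z
        out = (
            -math.log(2.0)
            - 0.5 * (x + nc)
            + 0.5 * v * (np.log(x) - math.log(nc))
            + log_iv
        )
    return np.where(x > 0, out, -np.inf)


def branch_log_density(
    params: RateModelParams,
    r_child,
    r_parent: Optional[float] = None,
    dt: Optional[float] = None,
):
    """Log transition density (LN, CIR) or marginal density (UGAM).

    Returns -inf (not an exception) for non-positive rates.  Vectorized
    over ``r_child``.
    """
    r_child = np.asarray(r_child, dtype=float)
    scalar = r_child.ndim == 0
    r_child = np.atleast_1d(r_child)

    if params.model == "UGAM":
        out = _gamma_logpdf(r_child, 1.0 / params.nu, params.nu)
    else:
        if r_parent is None or dt is None:
            raise ValueError(f"{params.model} transition density needs r_parent and dt")
        if dt <= 0:
            raise ValueError("dt must be > 0 for autocorrelated models")
        if r_parent <= 0:
            out = np.full(r_child.shape, -np.inf)
        elif params.model == "LN":
            s2 = params.sigma2 * dt
            if s2 == 0:
                raise ValueError("LN transition density undefined for sigma2 == 0")
            m = math.log(r_parent) - 0.5 * s2
            with np.errstate(divide="ignore", invalid="ignore"):
                lx = np.log(np.where(r_child > 0, r_child, 1.0))
                out = np.where(
                    r_child > 0,
                    -lx - 0.5 * math.log(2.0 * math.pi * s2) - (lx - m) ** 2 / (2.0 * s2),
                    -np.inf,
                )
        else:  # CIR
            c, df = _cir_transition_params(params.theta, params.sigma, dt)
            nc = 2.0 * c * r_parent * math.exp(-params.theta * dt)
            out = _ncx2_logpdf(2.0 * c * r_child, df, nc) + math.log(2.0 * c)

    return float(out[0]) if scalar else out


def stationary_moments(params: RateModelParams) -> Tuple[float, Optional[float]]:
    """(mean, variance) of the stationary rate law.

    LN (geometric Brownian motion) has no stationary law: variance is
    returned as None.  CIR is stationary Gamma(2*theta/sigma**2, same rate),
    i.e. mean 1 and variance sigma**2/(2*theta).
    """
    if params.model == "UGAM":
        return 1.0, params.nu
    if params.model == "LN":
        return 1.0, None
    return 1.0, params.sigma**2 / (2.0 * params.theta)
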