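"""Disproportionality statistics: ROR with Wald CI, and the BCPNN
information component with Bayesian shrinkage.

Reporting odds ratio (ROR)
    ROR = (a*d)/(b*c) on the fourfold table, with a Wald interval on the
    natural-log scale: exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)),
    z = 1.96 by default.  When b, c or d is zero the Haldane-Anscombe
    correction (add 0.5 to every cell) is applied and flagged.  Signal
    threshold: a >= 3 and CI lower bound > 1.

BCPNN information component (IC)
    IC = log2 of the observed-to-expected co-reporting probability,
    shrunk toward 0 under a conjugate Beta model.  With hyperparameters
    alpha1 = beta1 = gamma11 = 1, alpha = beta = 2 and the data-dependent
    joint prior count

        gamma = gamma11 * (N+alpha)(N+beta) / ((a+b+alpha1)(a+c+beta1)),

    the posterior expectation and variance of IC are

        E(IC) = log2[ (a+gamma11)(N+alpha)(N+beta)
                      / ((N+gamma)(a+b+alpha1)(a+c+beta1)) ]
        V(IC) = (1/ln 2)^2 * [ (N-a+gamma-gamma11)/((a+gamma11)(1+N+gamma))
                             + (N-(a+b)+alpha-alpha1)/((a+b+alpha1)(1+N+alpha))
                             + (N-(a+c)+beta-beta1)/((a+c+beta1)(1+N+beta)) ]

    and the signal criterion is IC025 = E(IC) - 2*sqrt(V(IC)) > 0.
    A Monte-Carlo posterior quantile (:func:`mc_ic_quantile`) is provided
    as an independent check on this delta approximation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contingency import ContingencyTable
from .exceptions import ConfigError, InvalidTableError

DEFAULT_Z = 1.96
DEFAULT_MIN_COUNT = 3


@dataclass(frozen=True)
class BcpnnHyperparams:
    """Prior counts of the conjugate Beta model (all strictly positive)."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self):
        for name in ("alpha1", "beta1", "alpha", "beta", "gamma11"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"BCPNN hyperparameter {name} must be > 0")


@dataclass(frozen=True)
class RorResult:
    ror: float
    ln_ror: float
    se_ln_ror: float
    ci_lower: float
    ci_upper: float
    zero_corrected: bool
    meets_threshold: bool


@dataclass(frozen=True)
class BcpnnResult:
    ic_raw: float
    e_ic: float
    v_ic: float
    sd_ic: float
    ic025: float
    meets_threshold: bool


def _require_a(table: ContingencyTable) -> None:
    if table.a < 1:
        raise InvalidTableError(
            f"table for PT {table.pt_name!r} has a={table.a}; statistics need a >= 1"
        )


def compute_ror(
    table: ContingencyTable,
    z: float = DEFAULT_Z,
    min_count: int = DEFAULT_MIN_COUNT,
) -> RorResult:
    """ROR with Wald 95% CI; threshold = (a >= min_count) and CI lower > 1.

    The threshold is always evaluated on the uncorrected ``a``.
    """
    _require_a(table)
    a, b, c, d = table.cells
    zero_corrected = min(b, c, d) == 0
    if zero_corrected:
        fa, fb, fc, fd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        fa, fb, fc, fd = float(a), float(b), float(c), float(d)
    ror = (fa * fd) / (fb * fc)
    ln_ror = math.log(ror)
    se = math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
    ci_lower = math.exp(ln_ror - z * se)
    ci_upper = math.exp(ln_ror + z * se)
    return RorResult(
        ror=ror,
        ln_ror=ln_ror,
        se_ln_ror=se,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        zero_corrected=zero_corrected,
        meets_threshold=(a >= min_count and ci_lower > 1.0),
    )


def compute_bcpnn(
    table: ContingencyTable, h: BcpnnHyperparams | None = None
) -> BcpnnResult:
    """Shrunken information component E(IC), its variance and IC025."""
    _require_a(table)
    h = h or BcpnnHyperparams()
    a, b, c, _ = table.cells
    n = float(table.n_total)
    ab = float(a + b)
    ac = float(a + c)

    ic_raw = math.log2(a * n / (ab * ac)) if ab and ac else float("nan")
    gamma = h.gamma11 * (n + h.alpha) * (n + h.beta) / ((ab + h.alpha1) * (ac + h.beta1))
    e_ic = math.log2(
        (a + h.gamma11)
        * (n + h.alpha)
        * (n + h.beta)
        / ((n + gamma) * (ab + h.alpha1) * (ac + h.beta1))
    )
    v_ic = (1 / math.log(2)) ** 2 * (
        (n - a + gamma - h.gamma11) / ((a + h.gamma11) * (1 + n + gamma))
        + (n - ab + h.alpha - h.alpha1) / ((ab + h.alpha1) * (1 + n + h.alpha))
        + (n - ac + h.beta - h.beta1) / ((ac + h.beta1) * (1 + n + h.beta))
    )
    sd_ic = math.sqrt(v_ic)
    ic025 = e_ic - 2 * sd_ic
    return BcpnnResult(
        ic_raw=ic_raw,
        e_ic=e_ic,
        v_ic=v_ic,
        sd_ic=sd_ic,
        ic025=ic025,
        meets_threshold=ic025 > 0.0,
    )


def mc_ic_quantile(
    table: ContingencyTable,
    h: BcpnnHyperparams | None = None,
    n_samples: int = 100_000,
    seed: int = 0,
    q: float = 0.025,
) -> float:
    """Monte-Carlo posterior quantile of IC under the conjugate Beta model.

    Draws the joint and marginal reporting probabilities from their Beta
    posteriors, forms IC = log2(p11 / (p1. * p.1)) per draw, and returns
    the ``q`` quantile.  Independent check on the delta approximation in
    :func:`compute_bcpnn`; deterministic under ``seed``.
    """
    _require_a(table)
    if n_samples < 1000:
        raise ConfigError("mc_ic_quantile needs n_samples >= 1000")
    h = h or BcpnnHyperparams()
    a, b, c, _ = table.cells
    n = float(table.n_total)
    ab, ac = float(a + b), float(a + c)
    gamma = h.gamma11 * (n + h.alpha) * (n + h.beta) / ((ab + h.alpha1) * (ac + h.beta1))

    rng = np.random.default_rng(seed)
    p11 = rng.beta(a + h.gamma11, n - a + gamma - h.gamma11, size=n_samples)
    p1 = rng.beta(ab + h.alpha1, n - ab + h.alpha - h.alpha1, size=n_samples)
    p2 = rng.beta(ac + h.beta1, n - ac + h.beta - h.beta1, size=n_samples)
    ic = np.log2(p11 / (p1 * p2))
    return float(np.quantile(ic, q))
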