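"""The four disproportionality estimators and their positivity thresholds.

For a 2x2 table (a, b, c, d) with N = a+b+c+d and expected count
E = (a+b)(a+c)/N:

* **ROR** (reporting odds ratio): ``ad / bc`` with a Wald interval on the
  log-odds scale; positive when ``a >= 3`` and the 95% CI lower bound > 1.
* **PRR** (proportional reporting ratio): ``[a/(a+b)] / [c/(c+d)]`` paired
  with the Pearson chi-square (no continuity correction); positive when
  ``a >= 3``, ``PRR >= 2`` and ``chi2 >= 4``.
* **IC** (information component): the additive-shrinkage form
  ``log2((a + 1/2) / (E + 1/2))``; its lower 2.5% credible bound IC025 comes
  from the Gamma(a + 1/2, rate E + 1/2) posterior of the relative reporting
  rate; positive when ``IC025 > 0``.
* **EBGM** (empirical Bayes geometric mean): posterior geometric mean of the
  relative reporting rate under a two-component gamma-Poisson mixture prior
  fitted to the whole table collection by marginal maximum likelihood
  (each observed count is marginally a mixture of negative binomials);
  positive when the 5% posterior quantile EB05 > 2.

Undefined statistics (zero margins etc.) propagate as NaN / inf markers with
the positivity flag forced False, never as silent zeros.  All estimators
exist in a scalar form operating on :class:`ContingencyTable` and a
vectorized batch form operating on numpy arrays; the batch form is what the
pipeline runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, special, stats

from adcvigil.stratify_contingency import ContingencyTable

log = logging.getLogger(__name__)

__all__ = [
    "GammaPoissonPrior",
    "AlgorithmConfig",
    "ConvergenceError",
    "RorStats",
    "PrrStats",
    "IcStats",
    "EbgmStats",
    "compute_ror",
    "compute_prr",
    "compute_ic",
    "compute_ebgm",
    "fit_ebgm_prior",
    "ror_stats",
    "prr_stats",
    "ic_stats",
    "ebgm_stats",
]


class ConvergenceError(RuntimeError):
    """Mixture fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: "GammaPoissonPrior"):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class GammaPoissonPrior:
    """Two-component gamma mixture prior on the relative reporting rate
    lambda: with probability ``p`` lambda ~ Gamma(alpha1, rate beta1), else
    Gamma(alpha2, rate beta2).  Defaults are the classical gamma-Poisson
    shrinker starting values."""

    alpha1: float = 0.2
    beta1: float = 0.1
    alpha2: float = 2.0
    beta2: float = 4.0
    p: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("prior shape/rate parameters must be positive")
        if not (0 <= self.p <= 1):
            raise ValueError("mixture weight p must lie in [0, 1]")

    def mean(self) -> float:
        return self.p * self.alpha1 / self.beta1 + (1 - self.p) * self.alpha2 / self.beta2

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.alpha1, self.beta1, self.alpha2, self.beta2, self.p)


@dataclass(frozen=True)
class AlgorithmConfig:
    """Thresholds and numerical settings for the four estimators.

    Defaults are the canonical published criteria for each method; every
    value is overridable."""

    ror_min_count: int = 3
    z: float = 1.959964          # two-sided 95% normal quantile
    prr_min: float = 2.0
    prr_chi2_min: float = 4.0
    prr_min_count: int = 3
    yates: bool = False
    ic_shrinkage: float = 0.5    # additive constant in IC = log2((a+s)/(E+s))
    ic025_min: float = 0.0
    ebgm_prior: GammaPoissonPrior = field(default_factory=GammaPoissonPrior)
    eb05_min: float = 2.0
    em_tol: float = 1e-8
    em_max_iter: int = 10_000
    min_prior_tables: int = 50   # fall back to the default prior below this


class RorStats(NamedTuple):
    ror: float
    lo: float
    hi: float
    flag: bool


class PrrStats(NamedTuple):
    prr: float
    chi2: float
    flag: bool
    unstable: bool


class IcStats(NamedTuple):
    ic: float
    ic025: float
    flag: bool


class EbgmStats(NamedTuple):
    ebgm: float
    eb05: float
    flag: bool


# --------------------------------------------------------------------------
# vectorized estimators


def _as_float_arrays(a, b, c, d):
    return (np.asarray(a, dtype=float), np.asarray(b, dtype=float),
            np.asarray(c, dtype=float), np.asarray(d, dtype=float))


def ror_stats(a, b, c, d, cfg: AlgorithmConfig = AlgorithmConfig()) -> dict[str, np.ndarray]:
    """Vectorized ROR with Wald log-scale CI and positivity flags."""
    a, b, c, d = _as_float_arrays(a, b, c, d)
    ror = np.full(a.shape, np.nan)
    lo = np.full(a.shape, np.nan)
    hi = np.full(a.shape, np.nan)

    zero_a = a == 0
    zero_other = (b == 0) | (c == 0) | (d == 0)
    ok = ~zero_a & ~zero_other

    ror[zero_a] = 0.0
    ror[~zero_a & zero_other] = np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        ror[ok] = a[ok] * d[ok] / (b[ok] * c[ok])
        se = np.sqrt(1 / a[ok] + 1 / b[ok] + 1 / c[ok] + 1 / d[ok])
        lnror = np.log(ror[ok])
        lo[ok] = np.exp(lnror - cfg.z * se)
        hi[ok] = np.exp(lnror + cfg.z * se)
    flag = ok & (a >= cfg.ror_min_count) & (lo > 1)
    flag = np.where(np.isnan(lo), False, flag)
    return {"ror": ror, "ror_lo": lo, "ror_hi": hi, "flag_ror": flag.astype(bool)}


def pearson_chi2(a, b, c, d, yates: bool = False) -> np.ndarray:
    """Pearson chi-square for 2x2 tables, closed form; NaN on a zero margin."""
    a, b, c, d = _as_float_arrays(a, b, c, d)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    diff = np.abs(a * d - b * c)
    if yates:
        diff = np.maximum(diff - n / 2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * diff**2 / denom
    return np.where(denom > 0, chi2, np.nan)


def prr_stats(a, b, c, d, cfg: AlgorithmConfig = AlgorithmConfig()) -> dict[str, np.ndarray]:
    """Vectorized PRR + chi-square with positivity flags.

    ``c = 0`` (event absent from comparator) makes the PRR infinite; the flag
    can still fire when the other conditions hold but the pair is marked
    unstable."""
    a, b, c, d = _as_float_arrays(a, b, c, d)
    prr = np.full(a.shape, np.nan)
    row1 = a + b
    row2 = c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(row1 > 0, a / row1, np.nan)
        p2 = np.where(row2 > 0, c / row2, np.nan)
        prr = p1 / p2
    prr = np.where((c == 0) & (a > 0) & (row1 > 0) & (row2 > 0), np.inf, prr)
    prr = np.where((a == 0) & (row1 > 0) & (p2 > 0), 0.0, prr)
    chi2 = pearson_chi2(a, b, c, d, yates=cfg.yates)
    with np.errstate(invalid="ignore"):
        flag = (
            (a >= cfg.prr_min_count)
            & np.where(np.isnan(prr), False, prr >= cfg.prr_min)
            & np.where(np.isnan(chi2), False, chi2 >= cfg.prr_chi2_min)
        )
    unstable = np.isinf(prr)
    return {"prr": prr, "chi2": chi2, "flag_prr": flag.astype(bool), "unstable_prr": unstable}


def ic_stats(a, expected, cfg: AlgorithmConfig = AlgorithmConfig()) -> dict[str, np.ndarray]:
    """Vectorized information component with Gamma-posterior credible bound.

    IC = log2((a+s)/(E+s)); IC025 = log2 of the 2.5% quantile of
    Gamma(a+s, rate E+s).  E = 0 (event absent from the data) is undefined.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(expected, dtype=float)
    s = cfg.ic_shrinkage
    ic = np.full(a.shape, np.nan)
    ic025 = np.full(a.shape, np.nan)
    ok = e > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ic[ok] = np.log2((a[ok] + s) / (e[ok] + s))
        q = stats.gamma.ppf(0.025, a[ok] + s, scale=1.0 / (e[ok] + s))
        ic025[ok] = np.log2(q)
    flag = np.where(np.isnan(ic025), False, ic025 > cfg.ic025_min)
    return {"ic": ic, "ic025": ic025, "flag_ic": flag.astype(bool)}


# --------------------------------------------------------------------------
# EBGM: two-component gamma-Poisson mixture


def _mixture_logpmf(a: np.ndarray, e: np.ndarray, prior: GammaPoissonPrior) -> np.ndarray:
    """Marginal log P(a | E) under the mixture of negative binomials."""
    p1 = prior.beta1 / (prior.beta1 + e)
    p2 = prior.beta2 / (prior.beta2 + e)
    lg1 = stats.nbinom.logpmf(a, prior.alpha1, p1)
    lg2 = stats.nbinom.logpmf(a, prior.alpha2, p2)
    if prior.p == 1.0:
        return lg1
    if prior.p == 0.0:
        return lg2
    return np.logaddexp(np.log(prior.p) + lg1, np.log1p(-prior.p) + lg2)


def _theta_to_prior(theta: np.ndarray) -> GammaPoissonPrior:
    return GammaPoissonPrior(
        alpha1=float(np.exp(theta[0])),
        beta1=float(np.exp(theta[1])),
        alpha2=float(np.exp(theta[2])),
        beta2=float(np.exp(theta[3])),
        p=float(special.expit(theta[4])),
    )


def fit_ebgm_prior(
    a: Sequence[float] | np.ndarray,
    expected: Sequence[float] | np.ndarray,
    cfg: AlgorithmConfig = AlgorithmConfig(),
) -> GammaPoissonPrior:
    """Fit the mixture prior by maximizing the marginal likelihood of the
    observed counts over all tables with E > 0.

    Optimization is quasi-Newton on log/logit-transformed parameters.  With
    fewer than ``cfg.min_prior_tables`` usable tables the configured default
    prior is returned with a logged warning.  Non-convergence raises
    :class:`ConvergenceError` carrying the last iterate.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(expected, dtype=float)
    mask = e > 0
    a, e = a[mask], e[mask]
    if a.size < cfg.min_prior_tables:
        log.warning(
            "only %d tables with E>0 (< %d): using default prior",
            a.size,
            cfg.min_prior_tables,
        )
        return cfg.ebgm_prior

    def nll(theta: np.ndarray) -> float:
        try:
            prior = _theta_to_prior(theta)
        except (ValueError, OverflowError):
            return np.inf
        with np.errstate(over="ignore", invalid="ignore"):
            ll = _mixture_logpmf(a, e, prior)
        if not np.all(np.isfinite(ll)):
            return np.inf
        return -float(ll.sum())

    start = cfg.ebgm_prior
    theta0 = np.array(
        [
            np.log(start.alpha1),
            np.log(start.beta1),
            np.log(start.alpha2),
            np.log(start.beta2),
            special.logit(np.clip(start.p, 1e-6, 1 - 1e-6)),
        ]
    )
    res = optimize.minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=[(-12, 12)] * 4 + [(-15, 15)],
        options={"maxiter": cfg.em_max_iter, "ftol": cfg.em_tol, "maxfun": 10 * cfg.em_max_iter},
    )
    prior = _theta_to_prior(res.x)
    if not res.success and "ITERATIONS" in str(res.message).upper():
        raise ConvergenceError(f"mixture fit did not converge: {res.message}", prior)
    if not res.success:
        log.warning("mixture fit stopped early (%s); using last iterate", res.message)
    return prior


def _posterior_weights(a: np.ndarray, e: np.ndarray, prior: GammaPoissonPrior) -> np.ndarray:
    """Posterior probability Q1 of the first mixture component."""
    if prior.p == 1.0:
        return np.ones_like(a, dtype=float)
    if prior.p == 0.0:
        return np.zeros_like(a, dtype=float)
    lg1 = np.log(prior.p) + stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    lg2 = np.log1p(-prior.p) + stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    return special.expit(lg1 - lg2)


def posterior_cdf(x: np.ndarray, a: np.ndarray, e: np.ndarray, prior: GammaPoissonPrior) -> np.ndarray:
    """CDF of the posterior mixture Q1 Gamma(a1+a, rate b1+E) + Q2 Gamma(a2+a, rate b2+E)."""
    q1 = _posterior_weights(a, e, prior)
    c1 = stats.gamma.cdf(x, prior.alpha1 + a, scale=1.0 / (prior.beta1 + e))
    c2 = stats.gamma.cdf(x, prior.alpha2 + a, scale=1.0 / (prior.beta2 + e))
    return q1 * c1 + (1 - q1) * c2


def ebgm_stats(
    a,
    expected,
    prior: GammaPoissonPrior,
    cfg: AlgorithmConfig = AlgorithmConfig(),
    quantile: float = 0.05,
) -> dict[str, np.ndarray]:
    """Vectorized EBGM / EB05.

    EBGM is the exponentiated posterior mean of ln(lambda):
    ``exp(sum_j Qj (psi(alpha_j + a) - ln(beta_j + E)))``; EB05 is the 5%
    posterior quantile found by bisection on the mixture CDF.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(expected, dtype=float)
    ebgm = np.full(a.shape, np.nan)
    eb05 = np.full(a.shape, np.nan)
    ok = e > 0
    if ok.any():
        ao, eo = a[ok], e[ok]
        q1 = _posterior_weights(ao, eo, prior)
        m1 = special.digamma(prior.alpha1 + ao) - np.log(prior.beta1 + eo)
        m2 = special.digamma(prior.alpha2 + ao) - np.log(prior.beta2 + eo)
        ebgm[ok] = np.exp(q1 * m1 + (1 - q1) * m2)

        lo = np.full(ao.shape, 1e-8)
        hi = np.maximum(ao / eo, prior.mean()) * 10 + 1.0
        # widen until the bracket certainly contains the quantile
        for _ in range(60):
            bad = posterior_cdf(hi, ao, eo, prior) < quantile
            if not bad.any():
                break
            hi[bad] *= 10
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            below = posterior_cdf(mid, ao, eo, prior) < quantile
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        eb05[ok] = 0.5 * (lo + hi)
    flag = np.where(np.isnan(eb05), False, eb05 > cfg.eb05_min)
    return {"ebgm": ebgm, "eb05": eb05, "flag_ebgm": flag.astype(bool)}


# --------------------------------------------------------------------------
# scalar facades


def compute_ror(t: ContingencyTable, cfg: AlgorithmConfig = AlgorithmConfig()) -> RorStats:
    out = ror_stats([t.a], [t.b], [t.c], [t.d], cfg)
    return RorStats(float(out["ror"][0]), float(out["ror_lo"][0]), float(out["ror_hi"][0]), bool(out["flag_ror"][0]))


def compute_prr(t: ContingencyTable, cfg: AlgorithmConfig = AlgorithmConfig()) -> PrrStats:
    out = prr_stats([t.a], [t.b], [t.c], [t.d], cfg)
    return PrrStats(float(out["prr"][0]), float(out["chi2"][0]), bool(out["flag_prr"][0]), bool(out["unstable_prr"][0]))


def compute_ic(t: ContingencyTable, cfg: AlgorithmConfig = AlgorithmConfig()) -> IcStats:
    out = ic_stats([t.a], [t.expected], cfg)
    return IcStats(float(out["ic"][0]), float(out["ic025"][0]), bool(out["flag_ic"][0]))


def compute_ebgm(
    t: ContingencyTable,
    prior: GammaPoissonPrior | None = None,
    cfg: AlgorithmConfig = AlgorithmConfig(),
) -> EbgmStats:
    prior = prior if prior is not None else cfg.ebgm_prior
    out = ebgm_stats([t.a], [t.expected], prior, cfg)
    return EbgmStats(float(out["ebgm"][0]), float(out["eb05"][0]), bool(out["flag_ebgm"][0]))
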