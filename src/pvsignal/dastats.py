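"""The four disproportionality statistics and the combined signal gate.

Given a 2x2 table (a, b, c, d) of drug-event co-reporting:

* **ROR** — reporting odds ratio ``ad/(bc)`` with a Wald 95% CI on the log
  scale.  A Haldane-Anscombe +0.5 correction on all cells is applied when
  (and only when) a zero cell occurs.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]``, paired
  with the Pearson chi-square statistic of independence (no continuity
  correction by default).
* **BCPNN IC** — the information component ``log2`` of the shrunk
  observed-to-expected ratio.  The default is the closed-form credibility
  formula ``IC = log2((a+0.5)/(E+0.5))`` with lower bound
  ``IC025 = IC - 3.3(a+0.5)^(-1/2) - 2(a+0.5)^(-3/2)``, where
  ``E = (a+b)(a+c)/N``.  The original Dirichlet-prior posterior
  approximation is available as ``ic_method="bate"``.
* **MGPS EBGM** — the DuMouchel gamma-Poisson shrinker.  Counts are modelled
  as ``a ~ Poisson(lambda * E)`` with a two-component gamma mixture prior on
  the relative reporting rate ``lambda``; the prior is fitted by maximizing
  the negative-binomial marginal likelihood over all cells, the posterior is
  again a gamma mixture, EBGM is the posterior geometric mean
  ``exp(E[ln lambda | a])`` and EBGM05 its 5th percentile.

A drug-event pair is a *signal* when it passes all four method thresholds
simultaneously (defaults: N >= 3 reports, ROR lower CI > 1, PRR >= 2 with
chi-square >= 4, IC025 > 0, EBGM05 > 2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from types import SimpleNamespace
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .contingency import ContingencyTable
from .ingest import ReportStore
from .meddra import MedDRAHierarchy

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for this table (zero cell or margin)."""


class ConvergenceError(RuntimeError):
    """Prior fit failed to converge; carries the best parameters found."""

    def __init__(self, message: str, best: "GPSPrior | None" = None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# Frequentist pair: ROR and PRR + chi-square
# ---------------------------------------------------------------------------

def ror(t: ContingencyTable, haldane: bool = True) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI.

    With ``haldane`` (default), a zero cell triggers the +0.5 correction on
    all four cells; without it a zero cell raises
    :class:`UndefinedStatisticError`.
    """
    a, b, c, d = (float(x) for x in t.as_tuple())
    if min(a, b, c, d) == 0:
        if not haldane:
            raise UndefinedStatisticError(f"zero cell in {t.as_tuple()}")
        logger.debug("Haldane-Anscombe +0.5 applied to %s", t.as_tuple())
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se)


def prr(t: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio and the Pearson chi-square statistic.

    The chi-square is the usual test of independence on the 2x2 table;
    ``yates`` applies the continuity correction (off by default).
    """
    a, b, c, d = t.as_tuple()
    if a + b == 0 or c + d == 0 or a + c == 0:
        raise UndefinedStatisticError(f"zero margin in {t.as_tuple()}")
    rate_bg = c / (c + d)
    est = math.inf if rate_bg == 0 else (a / (a + b)) / rate_bg
    n = t.n
    chi2 = 0.0
    for obs, row, col in ((a, a + b, a + c), (b, a + b, b + d),
                          (c, c + d, a + c), (d, c + d, b + d)):
        exp = row * col / n
        if exp > 0:
            dev = abs(obs - exp)
            if yates:
                dev = max(dev - 0.5, 0.0)
            chi2 += dev * dev / exp
    return est, chi2


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------

def bcpnn_ic(t: ContingencyTable, method: str = "closed") -> tuple[float, float]:
    """Information component and its lower 95% credibility bound.

    ``closed`` (default) is the shrinkage closed form; ``bate`` is the
    original two-layer Dirichlet/Beta-prior normal approximation with
    symmetric hyperparameters chosen so the prior IC expectation is zero.
    """
    a, b, c, d = t.as_tuple()
    n = t.n
    if n <= 0:
        raise UndefinedStatisticError("empty table")
    if method == "closed":
        e = (a + b) * (a + c) / n
        ic = math.log2((a + 0.5) / (e + 0.5))
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
        return ic, ic025
    if method == "bate":
        a1 = b1 = 1.0       # row/column Beta priors
        al = be = 2.0
        g11 = 1.0
        g = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
        ic = math.log2((a + g11) * (n + al) * (n + be)
                       / ((n + g) * (a + b + a1) * (a + c + b1)))
        var = (1 / math.log(2)) ** 2 * (
            (n - a + g - g11) / ((a + g11) * (1 + n + g))
            + (n - (a + b) + al - a1) / ((a + b + a1) * (1 + n + al))
            + (n - (a + c) + be - b1) / ((a + c + b1) * (1 + n + be)))
        return ic, ic - Z95 * math.sqrt(var)
    raise ValueError(f"unknown IC method {method!r}")


# ---------------------------------------------------------------------------
# MGPS: DuMouchel gamma-Poisson shrinker
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPSPrior:
    """Two-component gamma mixture prior on the relative reporting rate.

    Gamma components are shape/rate parameterized; ``w`` is the weight of
    the first component.  ``loglik`` records the marginal log-likelihood at
    the fitted optimum when produced by :func:`fit_gps_prior`.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float | None = None

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma parameters must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")


#: Canonical DuMouchel starting point plus dispersed alternatives; fixed list
#: keeps the quasi-Newton multistart deterministic.
_GPS_STARTS: tuple[tuple[float, float, float, float, float], ...] = (
    (0.2, 0.1, 2.0, 4.0, 1 / 3),
    (1.0, 1.0, 1.0, 1.0, 0.5),
    (0.5, 0.2, 4.0, 4.0, 0.2),
    (2.0, 4.0, 0.2, 0.1, 0.9),
)


def _nb_logpmf(a: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    # marginal of Poisson(lambda*E) with lambda ~ Gamma(alpha, rate beta)
    p = beta / (beta + e)
    return stats.nbinom.logpmf(a, alpha, p)


#: Box constraints on the working parameters (log shapes/rates, logit weight);
#: wide enough to be inactive at any statistically meaningful optimum while
#: keeping the line search away from overflow.
_GPS_BOUNDS = [(-20.0, 20.0)] * 4 + [(-30.0, 30.0)]


def _mixture_nll(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    la1, lb1, la2, lb2, lw = theta
    alpha1, beta1 = np.exp(la1), np.exp(lb1)
    alpha2, beta2 = np.exp(la2), np.exp(lb2)
    if not np.all(np.isfinite([alpha1, beta1, alpha2, beta2])):
        return 1e12
    w = special.expit(lw)
    comp = np.stack([
        np.log(w + 1e-300) + _nb_logpmf(a, alpha1, beta1, e),
        np.log(1 - w + 1e-300) + _nb_logpmf(a, alpha2, beta2, e),
    ])
    ll = special.logsumexp(comp, axis=0).sum()
    if not np.isfinite(ll):
        return 1e12
    return -ll


def fit_gps_prior_arrays(a: np.ndarray, e: np.ndarray,
                         max_iter: int = 500) -> GPSPrior:
    """Fit the mixture prior to (observed count, expected count) cells.

    Maximizes the negative-binomial marginal likelihood by bounded
    quasi-Newton from a fixed list of starting points; deterministic.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if a.shape != e.shape or a.size == 0:
        raise ValueError("need matching nonempty count/expected arrays")
    if np.any(e <= 0):
        raise ValueError("expected counts must be positive")
    if a.size < 100:
        logger.warning("fitting GPS prior on only %d cells; >=100 recommended", a.size)

    best = None
    for start in _GPS_STARTS:
        theta0 = np.array([math.log(start[0]), math.log(start[1]),
                           math.log(start[2]), math.log(start[3]),
                           special.logit(start[4])])
        res = optimize.minimize(_mixture_nll, theta0, args=(a, e),
                                method="L-BFGS-B", bounds=_GPS_BOUNDS,
                                options={"maxiter": max_iter})
        if best is None or res.fun < best.fun:
            best = res
    la1, lb1, la2, lb2, lw = best.x
    prior = GPSPrior(math.exp(la1), math.exp(lb1), math.exp(la2), math.exp(lb2),
                     float(special.expit(lw)), loglik=-float(best.fun))
    if not np.isfinite(best.fun):
        raise ConvergenceError("GPS prior fit did not converge", best=prior)
    return prior


def fit_gps_prior(tables: Sequence[ContingencyTable], max_iter: int = 500) -> GPSPrior:
    """Fit the mixture prior to a collection of contingency tables.

    Each table supplies one cell (a, E) with E = (a+b)(a+c)/N.
    """
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected_a for t in tables], dtype=float)
    return fit_gps_prior_arrays(a, e, max_iter=max_iter)


def _posterior_mixture(a: int, e: float, prior: GPSPrior):
    """Posterior over lambda given count a: gamma mixture (shapes, rates, weights)."""
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    logq = np.array([
        math.log(prior.w + 1e-300) + float(_nb_logpmf(np.array([a]), prior.alpha1, prior.beta1, np.array([e]))[0]),
        math.log(1 - prior.w + 1e-300) + float(_nb_logpmf(np.array([a]), prior.alpha2, prior.beta2, np.array([e]))[0]),
    ])
    logq -= special.logsumexp(logq)
    return shapes, rates, np.exp(logq)


def ebgm(t: ContingencyTable, prior: GPSPrior,
         cdf_tol: float = 1e-8) -> tuple[float, float]:
    """Empirical Bayes geometric mean of the relative reporting rate and its
    5th posterior percentile.

    EBGM is ``exp(E[ln lambda | a])`` under the posterior gamma mixture;
    EBGM05 is found by root-finding the mixture CDF at 0.05.
    """
    e = t.expected_a
    if e <= 0:
        raise UndefinedStatisticError("expected count must be positive")
    shapes, rates, q = _posterior_mixture(t.a, e, prior)
    mean_log = float(np.dot(q, special.digamma(shapes) - np.log(rates)))
    est = math.exp(mean_log)

    def mix_cdf(x: float) -> float:
        return float(np.dot(q, stats.gamma.cdf(x, shapes, scale=1.0 / rates)))

    # The mixture 5th percentile lies between the component 5th percentiles
    # (the mixture CDF is a convex combination of the component CDFs), which
    # gives a guaranteed bracket.  Root-find in log space so heavily
    # concentrated posteriors keep relative precision.
    comp_q = stats.gamma.ppf(0.05, shapes, scale=1.0 / rates)
    lo, hi = float(np.min(comp_q)), float(np.max(comp_q))
    if lo <= 0.0:
        # quantile at or below the smallest representable scale (degenerate
        # tiny-shape component); the 5th percentile is numerically zero
        return est, 0.0
    # evaluate the guards at exactly the points the root-finder would use,
    # so a one-ulp sign flip at an endpoint cannot break the bracket
    ylo, yhi = math.log(lo), math.log(hi)
    f_lo = mix_cdf(math.exp(ylo)) - 0.05
    f_hi = mix_cdf(math.exp(yhi)) - 0.05
    if f_lo >= 0.0:
        q05 = math.exp(ylo)
    elif f_hi <= 0.0:
        q05 = math.exp(yhi)
    else:
        y = optimize.brentq(lambda y: mix_cdf(math.exp(y)) - 0.05,
                            ylo, yhi, xtol=1e-14)
        q05 = math.exp(y)
    if abs(mix_cdf(q05) - 0.05) > cdf_tol:
        raise UndefinedStatisticError("posterior quantile did not converge")
    return est, float(q05)


# ---------------------------------------------------------------------------
# Combined gate and per-level driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Thresholds:
    """The four-method signal criteria; all configurable.

    Defaults are the standard published criteria: at least 3 reports, ROR
    lower 95% CI above 1, PRR >= 2 with chi-square >= 4, IC025 above 0 and
    EBGM05 above 2.
    """

    min_a: int = 3
    ror_lo_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0

    def __post_init__(self) -> None:
        if self.min_a < 0:
            raise ValueError("min_a must be >= 0")


@dataclass(frozen=True)
class DAResult:
    """All four statistics and the gate verdict for one event label."""

    label: str
    level: str
    a: int
    ror: float
    ror_lo95: float
    ror_hi95: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    signal: bool

    def __post_init__(self) -> None:
        if not (self.ror_lo95 <= self.ror <= self.ror_hi95):
            raise ValueError("ROR outside its own CI")
        if self.ic025 > self.ic:
            raise ValueError("IC025 exceeds IC")
        if self.ebgm05 > self.ebgm:
            # a bimodal posterior (degenerate prior fit) can place a minor
            # low-rate mode with weight just under 5%, pulling the geometric
            # mean below the 5th percentile; diagnostic, not an error
            logger.warning("EBGM05 %.4g exceeds EBGM %.4g for %r "
                           "(bimodal posterior from a degenerate prior fit)",
                           self.ebgm05, self.ebgm, self.label)
        if self.chi2 < 0:
            raise ValueError("chi-square must be nonnegative")


def evaluate_signal(r: DAResult, th: Thresholds) -> bool:
    """True iff the result passes every one of the four method thresholds."""
    return (r.a >= th.min_a
            and r.ror_lo95 > th.ror_lo_gt
            and r.prr >= th.prr_ge and r.chi2 >= th.chi2_ge
            and r.ic025 > th.ic025_gt
            and r.ebgm05 > th.ebgm05_gt)


def compute_all(all_reports: ReportStore, drug: str, level: str,
                h: MedDRAHierarchy, th: Thresholds | None = None,
                count_unit: str = "report", ic_method: str = "closed",
                yates: bool = False) -> list[DAResult]:
    """Run the full four-method screen at one aggregation level.

    The GPS prior is fitted once per level on every observed label cell
    before any per-cell EBGM; DAResults are emitted for labels with
    ``a >= th.min_a``.
    """
    from .contingency import build_all_tables

    th = th or Thresholds()
    cells = build_all_tables(all_reports, drug, level, h, min_count=0,
                             count_unit=count_unit)
    if not cells:
        return []
    prior = fit_gps_prior([t for _, t in cells])
    results = []
    for label, t in cells:
        if t.a < th.min_a:
            continue
        ror_est, lo, hi = ror(t)
        prr_est, chi2 = prr(t, yates=yates)
        ic, ic025 = bcpnn_ic(t, method=ic_method)
        eb, eb05 = ebgm(t, prior)
        gate = SimpleNamespace(a=t.a, ror_lo95=lo, prr=prr_est, chi2=chi2,
                               ic025=ic025, ebgm05=eb05)
        results.append(DAResult(label=label, level=level, a=t.a,
                                ror=ror_est, ror_lo95=lo, ror_hi95=hi,
                                prr=prr_est, chi2=chi2, ic=ic, ic025=ic025,
                                ebgm=eb, ebgm05=eb05,
                                signal=evaluate_signal(gate, th)))
    return results


def round2(x: float) -> str:
    """Round-half-up to 2 decimals for emitted tables."""
    if math.isinf(x):
        return "inf"
    return str(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
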