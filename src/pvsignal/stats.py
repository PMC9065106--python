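"""Disproportionality statistics: Information Component and reporting odds ratio.

The Information Component (IC) is the shrinkage log2 observed-to-expected
reporting ratio used by the Uppsala Monitoring Centre:

    IC = log2((N_obs + 0.5) / (N_exp + 0.5)),   N_exp = N_drug * N_effect / N_total

The +0.5 terms shrink the estimate toward 0 when counts are small.  A
drug-event pair is a signal when the lower bound of the 95% credibility
interval of the IC (IC025) is strictly positive.

Credibility interval
--------------------
Treating N_obs as Poisson with mean r * N_exp, the posterior of the
reporting rate ratio r under the shrinkage prior is

    r | data ~ Gamma(shape = N_obs + 0.5, rate = N_exp + 0.5)

whose mean reproduces the IC point estimate on the log2 scale.  IC025 and
IC975 are the log2 of the 2.5th and 97.5th posterior percentiles.  A legacy
normal approximation (IC +/- z * sd, with sd the exact standard deviation
of log2 r under the same gamma posterior) is available via
``method='normal_approx'`` for comparability with older implementations.

The reporting odds ratio (ROR) compares two exposures within the database
from a report-level 2x2 table: ROR = (a*d)/(b*c) with a Woolf (log-normal)
95% confidence interval; zero cells get the Haldane-Anscombe +0.5
correction, flagged in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats as sps

from .icsr import ContingencyTable, ICSRDataset
from .meddra import TermLevel

__all__ = [
    "SignalResult",
    "RorResult",
    "expected_count",
    "information_component",
    "ic_credibility_interval",
    "evaluate_signal",
    "reporting_odds_ratio",
    "ror_drug_vs_drug",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class SignalResult:
    """IC point estimate with credibility bounds and the counts behind them."""

    table: ContingencyTable
    expected: float
    ic: float
    ic025: float
    ic975: float

    @property
    def is_signal(self) -> bool:
        """Signal rule: strictly positive lower 95% credibility bound."""
        return self.ic025 > 0.0


@dataclass(frozen=True)
class RorResult:
    """Reporting odds ratio with Woolf 95% confidence interval."""

    a: int
    b: int
    c: int
    d: int
    ror: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool = False


def expected_count(t: ContingencyTable, background: str = "full") -> float:
    """Expected reports with drug and event under independence.

    ``background='full'`` (default, the IC formula's semantics):
    N_exp = N_drug * N_effect / N_total, with margins over the whole
    database including the exposed reports.  ``background='other_drugs'``
    applies the event rate among non-exposed reports to the exposed arm:
    N_exp = N_drug * (N_effect - N_obs) / (N_total - N_drug).
    """
    if t.n_total <= 0:
        raise ValueError("n_total must be positive")
    if background == "full":
        return t.n_drug * t.n_effect / t.n_total
    if background == "other_drugs":
        if t.n_total <= t.n_drug:
            raise ValueError("no unexposed reports to form the comparator")
        return t.n_drug * (t.n_effect - t.n_obs) / (t.n_total - t.n_drug)
    raise ValueError(f"background must be 'full' or 'other_drugs', got {background!r}")


def information_component(n_obs: float, n_expected: float) -> float:
    """IC = log2((n_obs + 0.5) / (n_expected + 0.5)); defined even at n_obs = 0."""
    n_obs = np.asarray(n_obs, dtype=float)
    n_expected = np.asarray(n_expected, dtype=float)
    if np.any(n_obs < 0) or np.any(n_expected < 0):
        raise ValueError("counts must be non-negative")
    out = np.log2((n_obs + 0.5) / (n_expected + 0.5))
    return float(out) if out.ndim == 0 else out


def ic_credibility_interval(
    n_obs: float,
    n_expected: float,
    mass: float = 0.95,
    method: str = "gamma",
) -> tuple[float, float]:
    """Central credibility interval of the IC posterior.

    Parameters
    ----------
    n_obs, n_expected
        Observed and expected report counts (scalars or arrays).
    mass
        Posterior mass of the central interval (default 0.95, giving the
        IC025/IC975 bounds of the signal rule).
    method
        ``'gamma'`` (default): exact quantiles of the
        Gamma(n_obs + 0.5, n_expected + 0.5) rate-ratio posterior.
        ``'normal_approx'``: legacy IC +/- z*sd approximation with the
        exact log-scale posterior standard deviation.
    """
    n_obs = np.asarray(n_obs, dtype=float)
    n_expected = np.asarray(n_expected, dtype=float)
    if np.any(n_obs < 0) or np.any(n_expected < 0):
        raise ValueError("counts must be non-negative")
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    alpha = (1.0 - mass) / 2.0
    shape = n_obs + 0.5
    rate = n_expected + 0.5
    if method == "gamma":
        lo = np.log2(sps.gamma.ppf(alpha, a=shape, scale=1.0 / rate))
        hi = np.log2(sps.gamma.ppf(1.0 - alpha, a=shape, scale=1.0 / rate))
    elif method == "normal_approx":
        # Var(ln r) = trigamma(shape) exactly under the gamma posterior
        sd = np.sqrt(special.polygamma(1, shape)) / _LN2
        z = sps.norm.ppf(1.0 - alpha)
        ic = np.log2(shape / rate)
        lo, hi = ic - z * sd, ic + z * sd
    else:
        raise ValueError(f"method must be 'gamma' or 'normal_approx', got {method!r}")
    if lo.ndim == 0:
        return float(lo), float(hi)
    return lo, hi


def evaluate_signal(
    t: ContingencyTable, mass: float = 0.95, method: str = "gamma",
    background: str = "full",
) -> SignalResult:
    """Compose expected count, IC and credibility interval into a decision."""
    n_exp = expected_count(t, background=background)
    ic = information_component(t.n_obs, n_exp)
    lo, hi = ic_credibility_interval(t.n_obs, n_exp, mass=mass, method=method)
    return SignalResult(table=t, expected=n_exp, ic=ic, ic025=lo, ic975=hi)


def reporting_odds_ratio(a: int, b: int, c: int, d: int, z: float = 1.959963984540054) -> RorResult:
    """ROR = (a*d)/(b*c) with Woolf log-normal 95% CI.

    ``a``/``b``: exposed reports with/without the event; ``c``/``d``: the
    comparator arm.  Any zero cell triggers the Haldane-Anscombe +0.5
    correction on all four cells (flagged in the result).
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"cells must be non-negative, got {cells}")
    if a + b == 0 or c + d == 0:
        raise ValueError(f"an arm has no reports: a+b={a + b}, c+d={c + d}")
    corrected = any(x == 0 for x in cells)
    fa, fb, fc, fd = (x + 0.5 for x in cells) if corrected else map(float, cells)
    ror = (fa * fd) / (fb * fc)
    se = math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
    log_ror = math.log(ror)
    return RorResult(
        a=a, b=b, c=c, d=d,
        ror=ror,
        ci_low=math.exp(log_ror - z * se),
        ci_high=math.exp(log_ror + z * se),
        continuity_corrected=corrected,
    )


def ror_drug_vs_drug(
    ds: ICSRDataset,
    drug_a: str,
    drug_b: str,
    term_code: str,
    level: TermLevel,
    roles=None,
) -> RorResult:
    """Head-to-head ROR of ``drug_a`` vs ``drug_b`` (reference) for one event.

    Restricted to reports suspected of exactly one of the two drugs;
    co-suspected reports are excluded.  Cells: a/b = drug_a reports
    with/without the event, c/d = drug_b reports with/without.
    """
    if drug_a == drug_b:
        raise ValueError("drugs must be distinct")
    ids_a = ds.reports_with_drug({drug_a}, roles=roles)
    ids_b = ds.reports_with_drug({drug_b}, roles=roles)
    both = ids_a & ids_b
    ids_a -= both
    ids_b -= both
    if not ids_a or not ids_b:
        raise ValueError(
            f"no exclusive reports for {'both drugs' if not (ids_a or ids_b) else (drug_a if not ids_a else drug_b)}"
        )
    event_ids = ds.reports_with_event(term_code, level)
    a = len(ids_a & event_ids)
    c = len(ids_b & event_ids)
    return reporting_odds_ratio(a, len(ids_a) - a, c, len(ids_b) - c)
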