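"""Disproportionality statistics on drug–event 2×2 contingency tables.

Every statistic here derives from the classical pharmacovigilance 2×2
table built over distinct case reports::

                     event of interest   all other events
    target drug             a                   b
    all other drugs         c                   d

Four families of estimators are provided: the reporting odds ratio (ROR)
with a Wald interval on the log scale, the proportional reporting ratio
(PRR) with an uncorrected Pearson chi-squared statistic, the BCPNN
information component (IC) with a closed-form posterior interval, and
the (closed-form) empirical Bayes geometric mean (EBGM).  The IC and
EBGM share the relative-reporting core a·N/((a+c)(a+b)), hence
IC = log2(EBGM) identically.

Zero cells never raise: an estimate that is unavailable for a table is
returned as NaN together with a reason tag, and its signal flag is
false.  No continuity or Haldane correction is applied anywhere — the
flags must reflect the raw formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ContingencyTable",
    "SignalStats",
    "CriteriaThresholds",
    "build_table",
    "ror_stat",
    "prr_stat",
    "ic_stat",
    "ebgm_stat",
    "evaluate_criteria",
    "compute_signal_stats",
    "rank_signals",
    "reconstruct_table",
    "signal_table",
]

#: z quantile used by the printed ROR / PRR / EBGM interval formulas.
Z95 = 1.96

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 drug–event table. Cells may be real-valued (reconstruction)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            if getattr(self, cell) < 0:
                raise ValueError(f"negative cell {cell!r} in contingency table")
        if self.n < 1:
            raise ValueError("contingency table total N must be >= 1")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class Estimate:
    """Point estimate with a 95% interval; NaN + reason when undefined."""

    value: float = math.nan
    lo: float = math.nan
    hi: float = math.nan
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)

    @property
    def interval_defined(self) -> bool:
        return not (math.isnan(self.lo) or math.isnan(self.hi))


def build_table(counts, term: str, level: str = "PT") -> ContingencyTable:
    """Build the 2×2 table for *term* from aggregated event counts.

    ``counts`` is a :class:`faersignal.cohort.EventCounts`.  Cells:
    a = target reports with the term, b = other target reports,
    c = non-target reports with the term, d = the remainder.
    """
    target, total = counts.term_counts(term, level)
    a = target
    b = counts.n_target_total - a
    c = total - a
    d = counts.n_all - a - b - c
    if b < 0 or c < 0 or d < 0:
        raise ValueError(
            f"inconsistent counts for {term!r}: a={a}, b={b}, c={c}, d={d}"
        )
    return ContingencyTable(a, b, c, d)


def ror_stat(t: ContingencyTable) -> Estimate:
    """Reporting odds ratio ad/(bc) with the log-scale Wald 95% interval.

    Any zero cell leaves the estimate undefined (no continuity
    correction is applied).
    """
    a, b, c, d = t.as_tuple()
    if min(a, b, c, d) <= 0:
        return Estimate(reason="zero-cell")
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return Estimate(ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))


@dataclass
class PrrResult:
    prr: Estimate
    chi2: float = math.nan

    @property
    def chi2_defined(self) -> bool:
        return not math.isnan(self.chi2)


def prr_stat(t: ContingencyTable) -> PrrResult:
    """PRR = a(c+d)/(c(a+b)) with log-scale Wald interval and Pearson χ².

    The χ² is the uncorrected (no Yates) Pearson statistic
    (ad−bc)²·N / ((a+b)(c+d)(a+c)(b+d)).  The PRR is defined whenever
    a > 0 and c > 0 (b or d may be zero); the interval additionally
    needs a finite standard error sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)).
    """
    a, b, c, d = t.as_tuple()
    n = t.n
    chi2 = math.nan
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins > 0:
        chi2 = (a * d - b * c) ** 2 * n / margins
    if a <= 0 or c <= 0:
        return PrrResult(Estimate(reason="zero-cell"), chi2)
    prr = a * (c + d) / (c * (a + b))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    if var < 0:  # numerically impossible in exact arithmetic
        var = 0.0
    se = math.sqrt(var)
    return PrrResult(
        Estimate(prr, prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se)), chi2
    )


def _bate_moments(t: ContingencyTable) -> tuple[float, float]:
    """Closed-form posterior mean and variance of the information
    component under the BCPNN beta-prior model of Bate et al. (1998),
    with the standard defaults alpha1 = beta1 = gamma11 = 1 and
    alpha = beta = 2 (the gamma prior parameter is tuned so that
    E(IC) = 0 under exact independence)."""
    a, b, c, _ = t.as_tuple()
    n = t.n
    alpha1 = beta1 = gamma11 = 1.0
    alpha = beta = 2.0
    row = a + b
    col = a + c
    gamma = gamma11 * (n + alpha) * (n + beta) / ((row + alpha1) * (col + beta1))
    e_ic = math.log(
        (a + gamma11) * (n + alpha) * (n + beta)
        / ((n + gamma) * (row + alpha1) * (col + beta1))
    ) / _LN2
    v_ic = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - row + alpha - alpha1) / ((row + alpha1) * (1 + n + alpha))
        + (n - col + beta - beta1) / ((col + beta1) * (1 + n + beta))
    ) / (_LN2 ** 2)
    return e_ic, v_ic


def ic_stat(
    t: ContingencyTable,
    *,
    estimator: str = "mle",
    interval: str = "closed",
    n_samples: int = 20000,
    rng: np.random.Generator | None = None,
) -> Estimate:
    """Information component IC = log2(a·N/((a+c)(a+b))).

    The point estimate is the observed/expected log-ratio shared with
    the EBGM (``estimator="mle"``, undefined for a = 0) or the BCPNN
    posterior expectation (``estimator="bate"``, defined everywhere).
    The 95% interval is IC ± 2·sqrt(V) with the Bate et al. (1998)
    closed-form posterior variance (``interval="closed"``), or a
    Monte-Carlo posterior interval from independent beta posteriors of
    the three reporting probabilities (``interval="mc"``).
    """
    a, b, c, _ = t.as_tuple()
    row, col, n = a + b, a + c, t.n
    e_ic, v_ic = _bate_moments(t)
    if estimator == "bate":
        ic = e_ic
    elif estimator == "mle":
        if a <= 0 or row <= 0 or col <= 0:
            return Estimate(reason="zero-cell")
        ic = math.log(a * n / (col * row)) / _LN2
    else:
        raise ValueError(f"unknown IC estimator {estimator!r}")
    if interval == "closed":
        half = 2.0 * math.sqrt(v_ic)
        return Estimate(ic, ic - half, ic + half)
    if interval == "mc":
        rng = np.random.default_rng(0) if rng is None else rng
        p11 = rng.beta(a + 1, n - a + 1, size=n_samples)
        p1x = rng.beta(row + 1, n - row + 1, size=n_samples)
        px1 = rng.beta(col + 1, n - col + 1, size=n_samples)
        draws = np.log2(p11 / (p1x * px1))
        lo, hi = np.quantile(draws, [0.025, 0.975])
        return Estimate(ic, float(lo), float(hi))
    raise ValueError(f"unknown IC interval method {interval!r}")


def ebgm_stat(t: ContingencyTable) -> Estimate:
    """Closed-form EBGM = a·N/((a+c)(a+b)) with a log-scale interval.

    The interval reuses the ROR-style standard error
    sqrt(1/a+1/b+1/c+1/d); for a = 0 the point estimate is 0 and the
    interval is undefined.
    """
    a, b, c, d = t.as_tuple()
    row, col = a + b, a + c
    if a <= 0:
        return Estimate(0.0, math.nan, math.nan, reason="zero-cell")
    if row <= 0 or col <= 0:
        return Estimate(reason="zero-cell")
    ebgm = a * t.n / (col * row)
    if min(b, c, d) <= 0:
        return Estimate(ebgm, math.nan, math.nan, reason="zero-cell")
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return Estimate(ebgm, ebgm * math.exp(-Z95 * se), ebgm * math.exp(Z95 * se))


@dataclass(frozen=True)
class CriteriaThresholds:
    """Signal-detection thresholds; defaults are the conventional ones:
    ROR lower 95% bound > 1 with n ≥ 3; PRR ≥ 2 with χ² ≥ 4 and n ≥ 3;
    IC025 > 0; EBGM05 > 2."""

    n_min: int = 3
    ror_lo: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


@dataclass
class SignalStats:
    """All four disproportionality estimates for one PT or SOC term."""

    term: str
    level: str
    n: float
    table: ContingencyTable
    ror: Estimate
    prr: PrrResult
    ic: Estimate
    ebgm: Estimate
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def undefined_reason(self) -> dict[str, str]:
        out = {}
        for name, est in (("ror", self.ror), ("prr", self.prr.prr),
                          ("ic", self.ic), ("ebgm", self.ebgm)):
            if est.reason is not None:
                out[name] = est.reason
        return out


def evaluate_criteria(
    s: SignalStats, thresholds: CriteriaThresholds = CriteriaThresholds()
) -> dict[str, bool]:
    """Per-algorithm signal flags plus 'any' and 'all' combinations.

    Boundary behaviour: the ROR/IC lower-bound rules are strict (>),
    the PRR and χ² rules are inclusive (≥).  An undefined statistic
    never flags.
    """
    th = thresholds
    n_ok = s.n >= th.n_min
    flags = {
        "ror": bool(
            s.ror.interval_defined and s.ror.lo > th.ror_lo and n_ok
        ),
        "prr": bool(
            s.prr.prr.defined
            and s.prr.chi2_defined
            and s.prr.prr.value >= th.prr_min
            and s.prr.chi2 >= th.chi2_min
            and n_ok
        ),
        "ic": bool(s.ic.interval_defined and s.ic.lo > th.ic025_min),
        "ebgm": bool(s.ebgm.interval_defined and s.ebgm.lo > th.ebgm05_min),
    }
    per_algo = [flags["ror"], flags["prr"], flags["ic"], flags["ebgm"]]
    flags["any"] = any(per_algo)
    flags["all"] = all(per_algo)
    return flags


def signal_stats_for_table(
    term: str,
    level: str,
    t: ContingencyTable,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    **ic_kwargs,
) -> SignalStats:
    s = SignalStats(
        term=term,
        level=level,
        n=t.a,
        table=t,
        ror=ror_stat(t),
        prr=prr_stat(t),
        ic=ic_stat(t, **ic_kwargs),
        ebgm=ebgm_stat(t),
    )
    s.flags = evaluate_criteria(s, thresholds)
    return s


def compute_signal_stats(
    counts,
    level: str = "PT",
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    **ic_kwargs,
) -> list[SignalStats]:
    """Run all four algorithms on every term of *level* in the counts."""
    return [
        signal_stats_for_table(term, level, build_table(counts, term, level),
                               thresholds, **ic_kwargs)
        for term in counts.terms(level)
    ]


_ORDER_KEYS = {
    "ebgm": lambda s: s.ebgm.value,
    "ror": lambda s: s.ror.value,
    "prr": lambda s: s.prr.prr.value,
    "ic": lambda s: s.ic.value,
    "n": lambda s: s.n,
    "chi2": lambda s: s.prr.chi2,
}


def rank_signals(
    all_stats: Iterable[SignalStats],
    top_n: int | None = None,
    order_key: str = "ebgm",
    min_n: float | None = None,
    flagged_only: bool = False,
    flag: str = "any",
) -> list[SignalStats]:
    """Rank terms descending by *order_key* (default EBGM).

    NaN keys sort last; ties break by larger n, then term name.  If
    ``min_n`` is given only terms with n strictly above it are kept
    (the conventional SOC-table cut is n > 100).  ``top_n <= 0`` gives
    an empty table.
    """
    if order_key not in _ORDER_KEYS:
        raise ValueError(f"unknown ranking key {order_key!r}")
    key = _ORDER_KEYS[order_key]
    pool = [
        s
        for s in all_stats
        if (min_n is None or s.n > min_n)
        and (not flagged_only or s.flags.get(flag, False))
    ]

    def sort_key(s: SignalStats):
        v = key(s)
        return (math.isnan(v), -v if not math.isnan(v) else 0.0, -s.n, s.term)

    ranked = sorted(pool, key=sort_key)
    if top_n is not None:
        ranked = ranked[: max(top_n, 0)]
    return ranked


def reconstruct_table(
    a: float,
    n_total: float,
    ror_target: float,
    prr_target: float,
    rtol: float = 1e-10,
) -> ContingencyTable:
    """Invert the ROR and PRR formulas: find real-valued b, c, d ≥ 0
    with a + b + c + d = N such that ror(t) = ror_target and
    prr(t) = prr_target.

    Given b, the PRR equation fixes c = a(N−a−b)/(PRR·(a+b)) exactly,
    so the problem reduces to a one-dimensional root find in b for the
    ROR residual, solved by bisection (Brent) on a bracketing grid.
    Useful for recovering the full table behind published (a, N, ROR,
    PRR) rows.  Raises with the residuals if no feasible solution
    exists.
    """
    if a < 1 or n_total <= a:
        raise ValueError("need a >= 1 and N > a")
    if not (ror_target > prr_target > 0):
        raise ValueError("need ROR > PRR > 0 for a feasible table")

    def c_of(b: float) -> float:
        return a * (n_total - a - b) / (prr_target * (a + b))

    def resid(b: float) -> float:
        c = c_of(b)
        d = n_total - a - b - c
        if c <= 0 or d <= 0:
            return -math.inf
        return a * d / (b * c) - ror_target

    b_max = n_total - a
    grid = np.geomspace(1e-9 * b_max, b_max * (1 - 1e-12), 400)
    vals = [resid(b) for b in grid]
    b_root = None
    for i in range(len(grid) - 1):
        if vals[i] > 0 >= vals[i + 1] and math.isfinite(vals[i + 1]):
            b_root = brentq(resid, grid[i], grid[i + 1], xtol=1e-13, rtol=8.9e-16)
            break
    if b_root is None:
        raise ValueError(
            "no feasible (b, c, d) for "
            f"a={a}, N={n_total}, ROR={ror_target}, PRR={prr_target}; "
            f"ROR residual range [{min(vals):.3g}, {max(vals):.3g}]"
        )
    b = b_root
    c = c_of(b)
    d = n_total - a - b - c
    t = ContingencyTable(a, b, c, d)
    ror_err = abs(ror_stat(t).value - ror_target) / ror_target
    prr_err = abs(prr_stat(t).prr.value - prr_target) / prr_target
    if ror_err > rtol or prr_err > rtol:
        raise ValueError(
            f"reconstruction did not converge: relative residuals "
            f"ror={ror_err:.2e}, prr={prr_err:.2e}"
        )
    return t


def signal_table(stats: Sequence[SignalStats], display: bool = False):
    """Tabulate signal statistics as a pandas DataFrame.

    With ``display=True`` numbers are rounded to 2 decimals in the
    style of published signal tables; otherwise full precision.
    """
    import pandas as pd

    rows = []
    for s in stats:
        rows.append(
            {
                "term": s.term,
                "level": s.level,
                "n": s.n,
                "ror": s.ror.value,
                "ror_lo95": s.ror.lo,
                "ror_hi95": s.ror.hi,
                "prr": s.prr.prr.value,
                "prr_lo95": s.prr.prr.lo,
                "prr_hi95": s.prr.prr.hi,
                "chi2": s.prr.chi2,
                "ic": s.ic.value,
                "ic025": s.ic.lo,
                "ic975": s.ic.hi,
                "ebgm": s.ebgm.value,
                "ebgm05": s.ebgm.lo,
                "ebgm95": s.ebgm.hi,
                "flag_ror": s.flags.get("ror"),
                "flag_prr": s.flags.get("prr"),
                "flag_ic": s.flags.get("ic"),
                "flag_ebgm": s.flags.get("ebgm"),
                "flag_any": s.flags.get("any"),
                "flag_all": s.flags.get("all"),
            }
        )
    df = pd.DataFrame(rows)
    if display and not df.empty:
        num = df.select_dtypes("number").columns
        df[num] = df[num].round(2)
    return df
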