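"""Quartile summaries, reporting conventions and nonparametric tests.

The conventions here reproduce SPSS output semantics, the de-facto standard
in nutrition epidemiology reporting:

* quantiles by linear interpolation of (n+1)p order statistics (SPSS
  HAVERAGE, "type 6"), with the numpy default ("type 7") selectable;
* percentages rounded half-up to 2 decimal places, and percentage-point
  changes formed from the already-rounded operands (the convention survey
  reports use when differencing printed percentages);
* Wilcoxon matched-pairs signed-rank: zero differences dropped, midranks
  for ties, tie-corrected normal z without continuity correction;
* McNemar: exact two-sided binomial when fewer than 25 discordant pairs,
  else the continuity-corrected chi-square;
* Kruskal-Wallis / Mann-Whitney / Pearson chi-square via scipy.

Each paired/rank test also exposes an exact enumeration mode used as its
own small-sample oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

from .intake import DomainError


# ---------------------------------------------------------------------------
# Rounding and percentage conventions
# ---------------------------------------------------------------------------


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, n: int, ndigits: int = 2) -> float:
    """``100*count/n`` rounded half-up, computed exactly before rounding."""
    count, n = int(count), int(n)
    if n <= 0:
        raise DomainError("percent undefined for n <= 0")
    if not 0 <= count <= n:
        raise DomainError(f"count {count} outside [0, {n}]")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(100 * count) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))


def pp_change(pct_before: float, pct_after: float, ndigits: int = 2) -> float:
    """Percentage-point reduction ``before - after`` from ROUNDED operands.

    Both operands must already be rounded (2 dp); the difference is rounded
    half-up again. Differencing rounded percentages is deliberate: it
    reproduces the arithmetic of printed tables, which can differ in the
    last digit from the unrounded-count difference.
    """
    return round_half_up(pct_before - pct_after, ndigits)


# ---------------------------------------------------------------------------
# Quartiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuartileSummary:
    p50: float
    p25: float
    p75: float

    def __post_init__(self) -> None:
        if not (self.p25 <= self.p50 <= self.p75):
            raise ValueError("quartiles out of order")

    def formatted(self, ndigits: int = 2) -> str:
        f = f"{{:.{ndigits}f}}"
        return f"{f.format(self.p50)} ({f.format(self.p25)}, {f.format(self.p75)})"


def quartiles(values, method: str = "type6") -> QuartileSummary:
    """Median and quartiles.

    ``type6``: linear interpolation at (n+1)p order statistics (SPSS
    HAVERAGE; the default). ``type7``: numpy/Excel default. ``hinges``:
    Tukey's hinges (SPSS EXAMINE's second quartile line).
    """
    arr = np.sort(np.asarray(list(values), dtype=float))
    if arr.size == 0:
        raise DomainError("quartiles of an empty list")
    if method == "hinges":
        n = arr.size
        half = arr[: (n + 1) // 2], arr[n // 2 :]
        p25 = float(np.median(half[0]))
        p75 = float(np.median(half[1]))
        return QuartileSummary(p50=float(np.median(arr)), p25=p25, p75=p75)
    np_method = {"type6": "weibull", "type7": "linear"}.get(method)
    if np_method is None:
        raise ValueError(f"unknown quantile method {method!r}")
    p25, p50, p75 = np.quantile(arr, [0.25, 0.5, 0.75], method=np_method)
    return QuartileSummary(p50=float(p50), p25=float(p25), p75=float(p75))


# ---------------------------------------------------------------------------
# Test result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedTestResult:
    test_name: str  # WILCOXON_SR | MCNEMAR
    statistic: float
    p_value: float
    n_effective: int
    degenerate: bool = False


@dataclass(frozen=True)
class GroupTestResult:
    test_name: str  # KRUSKAL_WALLIS | MANN_WHITNEY | CHI_SQUARE
    statistic: float
    p_value: float
    df: int | None = None


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed-rank
# ---------------------------------------------------------------------------


def _signed_rank_stats(d: np.ndarray) -> tuple[float, float, float, int]:
    """(W+, mean, sigma, n) of the positive-rank sum with midranks/ties."""
    ranks = sps.rankdata(np.abs(d))
    n = d.size
    w_pos = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    # tie correction over groups of tied |d|
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / 48.0)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    return w_pos, mean, math.sqrt(var), n


def wilcoxon_signed_rank(
    before, after, method: str = "spss"
) -> PairedTestResult:
    """Paired signed-rank test of ``after - before``.

    ``spss``: zeros dropped, tie-corrected normal z, no continuity
    correction, two-sided normal p. ``exact``: full enumeration of sign
    patterns over the non-zero differences (feasible up to ~20 pairs);
    two-sided p = 2*min(P(W+ <= w), P(W+ >= w)) capped at 1.
    """
    b = np.asarray(list(before), dtype=float)
    a = np.asarray(list(after), dtype=float)
    if b.shape != a.shape or b.size == 0:
        raise ValueError("before/after must be equal-length, non-empty")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise DomainError("no non-zero pairs")
    w_pos, mean, sigma, n = _signed_rank_stats(d)
    if method == "spss":
        z = 0.0 if sigma == 0 else (w_pos - mean) / sigma
        p = 2 * sps.norm.sf(abs(z))
        return PairedTestResult("WILCOXON_SR", float(z), float(min(p, 1.0)), n)
    if method == "exact":
        if n > 20:
            raise ValueError("exact enumeration limited to 20 non-zero pairs")
        ranks = sps.rankdata(np.abs(d))
        totals = []
        for signs in itertools.product((0, 1), repeat=n):
            totals.append(sum(r for r, s in zip(ranks, signs) if s))
        totals = np.asarray(totals)
        p_le = np.mean(totals <= w_pos + 1e-12)
        p_ge = np.mean(totals >= w_pos - 1e-12)
        p = min(1.0, 2 * min(p_le, p_ge))
        return PairedTestResult("WILCOXON_SR", w_pos, float(p), n)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# McNemar paired chi-square
# ---------------------------------------------------------------------------

#: Discordant-pair count below which the exact binomial p is used.
MCNEMAR_EXACT_LIMIT = 25


def mcnemar(flags_before, flags_after, method: str = "auto") -> PairedTestResult:
    """McNemar test on paired boolean flags.

    Discordant counts b (True->False) and c (False->True). ``auto`` follows
    the SPSS dual convention: exact two-sided binomial when
    ``b + c < 25``, else continuity-corrected chi-square
    ``(|b-c|-1)^2/(b+c)`` on 1 df. ``exact`` / ``chi2`` force a branch.
    No discordant pairs at all is degenerate (p = 1), not an error.
    """
    b_flags = [bool(x) for x in flags_before]
    a_flags = [bool(x) for x in flags_after]
    if len(b_flags) != len(a_flags):
        raise ValueError("before/after flag lists must have equal length")
    b = sum(1 for x, y in zip(b_flags, a_flags) if x and not y)
    c = sum(1 for x, y in zip(b_flags, a_flags) if not x and y)
    n_disc = b + c
    if n_disc == 0:
        return PairedTestResult("MCNEMAR", 0.0, 1.0, 0, degenerate=True)
    if method == "auto":
        method = "exact" if n_disc < MCNEMAR_EXACT_LIMIT else "chi2"
    if method == "exact":
        p = min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), n_disc, 0.5)))
        return PairedTestResult("MCNEMAR", float(min(b, c)), p, n_disc)
    if method == "chi2":
        stat = (abs(b - c) - 1) ** 2 / n_disc
        p = float(sps.chi2.sf(stat, df=1))
        return PairedTestResult("MCNEMAR", float(stat), p, n_disc)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Between-group tests (scipy-backed)
# ---------------------------------------------------------------------------


def kruskal_wallis(*groups) -> GroupTestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df)."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and groups[0] and isinstance(groups[0][0], (list, tuple, np.ndarray)):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise DomainError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise DomainError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # every observation identical: H = 0, p = 1 by convention
        return GroupTestResult("KRUSKAL_WALLIS", 0.0, 1.0, df=len(arrays) - 1)
    stat, p = sps.kruskal(*arrays)
    return GroupTestResult("KRUSKAL_WALLIS", float(stat), float(p), df=len(arrays) - 1)


def mann_whitney(a, b, method: str = "auto") -> GroupTestResult:
    """Mann-Whitney U, two-sided.

    ``asymptotic``: tie-corrected normal approximation without continuity
    correction (SPSS). ``exact``: enumeration over all arrangements of the
    pooled sample (used automatically for small tie-free samples, and
    available as the small-sample oracle even with ties when the number of
    arrangements is manageable).
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("empty sample")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if method == "auto":
        method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    if method == "asymptotic":
        if np.all(np.concatenate([x, y]) == x[0]):
            return GroupTestResult("MANN_WHITNEY", float(x.size * y.size / 2), 1.0)
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        return GroupTestResult("MANN_WHITNEY", float(res.statistic), float(res.pvalue))
    if method == "exact":
        n, m = x.size, y.size
        if math.comb(n + m, n) > 500_000:
            raise ValueError("exact enumeration infeasible for these sizes")
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)
        us = [
            sum(ranks[list(idx)]) - n * (n + 1) / 2
            for idx in itertools.combinations(range(n + m), n)
        ]
        us = np.asarray(us)
        mean = n * m / 2.0
        p = min(1.0, 2 * min(
            float(np.mean(us <= u_obs + 1e-12)),
            float(np.mean(us >= u_obs - 1e-12)),
        ))
        if abs(u_obs - mean) < 1e-12:
            p = 1.0
        return GroupTestResult("MANN_WHITNEY", u_obs, p)
    raise ValueError(f"unknown method {method!r}")


def chi_square_independence(table) -> GroupTestResult:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise DomainError("negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DomainError("zero margin in contingency table")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return GroupTestResult("CHI_SQUARE", float(stat), float(p), df=int(df))
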