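"""Categorical and two-group statistics for behavioural count data.

Implements the full decision scheme used to compare walking counts across
experimental groups: Pearson chi-squared without continuity correction, the
minimum-expected-count rule that routes a table either to the exact
significance of the Pearson statistic or to Fisher's exact test, exact r x c
tests by margin-constrained enumeration (Freeman-Halton), uncapped Bonferroni
family correction, Mann-Whitney U, and the normality / homoscedasticity
decision tree for two numeric samples.

Exact tests enumerate every table with the observed margins and weight each
by its multivariate hypergeometric probability

    P(T) = prod_i(R_i!) * prod_j(C_j!) / (N! * prod_ij(T_ij!)).

Two tail orderings are provided: ``prob`` (tables at least as improbable as
the observed one, the classical Fisher / Freeman-Halton convention) and
``chi2`` (tables whose Pearson statistic is at least as large).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ContingencyTable",
    "TestResult",
    "FamilySpec",
    "ZeroMarginError",
    "EnumerationGuardError",
    "pearson_chi2",
    "expected_counts",
    "expected_min",
    "fisher_exact_2x2",
    "exact_pearson_p",
    "freeman_halton",
    "bonferroni_adjust",
    "pairwise_group_comparison",
    "mann_whitney_u",
    "two_group_decision_test",
    "ratio_of_pairs",
]

#: total-count ceiling above which exact enumeration is refused
ENUMERATION_GUARD = 200
#: Monte-Carlo sample size used beyond the enumeration guard
MC_TABLES = 100_000
#: relative tolerance when comparing point probabilities / statistics in tails
_TAIL_RTOL = 1e-9


class ZeroMarginError(ValueError):
    """A row or column margin is zero; the requested statistic is undefined."""


class EnumerationGuardError(ValueError):
    """Table total exceeds the exact-enumeration guard."""


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("table total must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class TestResult:
    """Outcome of a statistical test: statistic, df, raw and adjusted p."""

    method: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float | None = None
    min_expected: float | None = None
    branch_taken: str | None = None
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "min_expected": self.min_expected,
            "branch": self.branch_taken,
            **self.notes,
        }


@dataclass(frozen=True)
class FamilySpec:
    """Bonferroni family: k pairwise tests, optionally capped at 1."""

    k: int = 6
    cap_at_one: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("family size k must be >= 1")


def _as_table(t) -> ContingencyTable:
    return t if isinstance(t, ContingencyTable) else ContingencyTable(np.asarray(t))


# ---------------------------------------------------------------------------
# Pearson chi-squared and expected counts
# ---------------------------------------------------------------------------

def expected_counts(t: ContingencyTable | np.ndarray) -> np.ndarray:
    """Expected counts E_ij = R_i * C_j / N under independence."""
    t = _as_table(t)
    return np.outer(t.row_margins, t.col_margins) / t.total


def expected_min(t: ContingencyTable | np.ndarray) -> float:
    """Smallest expected count; drives the exact-vs-Fisher branch rule."""
    return float(expected_counts(t).min())


def pearson_chi2(t: ContingencyTable | np.ndarray) -> TestResult:
    """Pearson chi-squared without continuity correction, asymptotic p.

    Raises :class:`ZeroMarginError` if any margin is zero (the statistic is
    then undefined because some expected counts are zero).
    """
    t = _as_table(t)
    if (t.row_margins == 0).any() or (t.col_margins == 0).any():
        raise ZeroMarginError("chi-squared undefined: a margin is zero")
    res = stats.chi2_contingency(t.counts, correction=False)
    return TestResult(
        method="pearson-chi2",
        statistic=float(res.statistic),
        df=float(res.dof),
        p_raw=float(res.pvalue),
        min_expected=float(res.expected_freq.min()),
    )


# ---------------------------------------------------------------------------
# Margin-constrained enumeration (exact tests)
# ---------------------------------------------------------------------------

def _log_factorials(n: int) -> np.ndarray:
    return np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, n + 1)))))


def _enumerate_tables(rows: list[int], cols: list[int]):
    """Yield every non-negative integer r x c table with the given margins."""
    r, c = len(rows), len(cols)

    def fill_row(j: int, left: int, avail: list[int], row: list[int]):
        if j == c - 1:
            if 0 <= left <= avail[j]:
                yield row + [left]
            return
        # upper bound keeps the remaining row feasible
        hi = min(left, avail[j])
        for v in range(hi + 1):
            yield from fill_row(j + 1, left - v, avail, row + [v])

    def fill(i: int, avail: list[int], acc: list[list[int]]):
        if i == r - 1:
            yield acc + [list(avail)]
            return
        for row in fill_row(0, rows[i], avail, []):
            rest = [avail[j] - row[j] for j in range(c)]
            yield from fill(i + 1, rest, acc + [row])

    yield from fill(0, list(cols), [])


def _log_table_prob(table: np.ndarray, lf: np.ndarray,
                    rows: np.ndarray, cols: np.ndarray, total: int) -> float:
    return (lf[rows].sum() + lf[cols].sum() - lf[total]
            - lf[table.ravel()].sum())


def _exact_tail(t: ContingencyTable, ordering: str,
                rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Exact tail probability under fixed margins.

    Returns ``(p, prob_sum)`` where ``prob_sum`` is the total probability
    mass over the reference set (1 for full enumeration; the Monte-Carlo
    fallback reports 1 by construction).
    """
    rows, cols = t.row_margins, t.col_margins
    if (rows == 0).any() or (cols == 0).any():
        # Only one table is compatible with a zero margin
        return 1.0, 1.0
    total = t.total
    lf = _log_factorials(total)
    expected = expected_counts(t)
    obs_chi2 = float(((t.counts - expected) ** 2 / expected).sum())
    obs_logp = _log_table_prob(t.counts, lf, rows, cols, total)

    def in_tail(table: np.ndarray) -> bool:
        if ordering == "prob":
            lp = _log_table_prob(table, lf, rows, cols, total)
            return lp <= obs_logp + _TAIL_RTOL
        chi2 = float(((table - expected) ** 2 / expected).sum())
        return chi2 >= obs_chi2 - _TAIL_RTOL

    if total <= ENUMERATION_GUARD:
        p = 0.0
        mass = 0.0
        for raw in _enumerate_tables(rows.tolist(), cols.tolist()):
            table = np.asarray(raw, dtype=np.int64)
            prob = math.exp(_log_table_prob(table, lf, rows, cols, total))
            mass += prob
            if in_tail(table):
                p += prob
        return min(p, 1.0), mass

    if rng is None:
        raise EnumerationGuardError(
            f"table total {total} exceeds enumeration guard "
            f"{ENUMERATION_GUARD}; pass rng= for Monte-Carlo mode")
    sampler = stats.random_table(rows, cols)
    hits = 0
    for chunk in np.array_split(sampler.rvs(MC_TABLES, random_state=rng),
                                max(1, MC_TABLES // 5000)):
        for table in chunk.astype(np.int64):
            if in_tail(table):
                hits += 1
    return hits / MC_TABLES, 1.0


def fisher_exact_2x2(t: ContingencyTable | np.ndarray) -> TestResult:
    """Two-sided Fisher exact test for a 2x2 table (point-probability rule).

    With margins fixed, sums the hypergeometric probabilities of all tables
    whose point probability does not exceed that of the observed table.
    A zero margin admits a single table; p = 1 by convention, flagged.
    """
    t = _as_table(t)
    if t.counts.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    zero_margin = bool((t.row_margins == 0).any() or (t.col_margins == 0).any())
    p, _ = _exact_tail(t, ordering="prob")
    return TestResult(
        method="fisher-exact",
        statistic=float(t.counts[0, 0]),
        df=0.0,
        p_raw=p,
        min_expected=expected_min(t),
        notes={"zero_margin": zero_margin},
    )


def exact_pearson_p(t: ContingencyTable | np.ndarray,
                    rng: np.random.Generator | None = None) -> TestResult:
    """Exact significance of the Pearson statistic under fixed margins.

    Enumerates all tables with the observed margins; p is the total
    multivariate-hypergeometric probability of tables whose chi-squared is at
    least the observed one. Refuses totals above ``ENUMERATION_GUARD`` unless
    an ``rng`` is supplied, in which case a seeded Monte-Carlo estimate over
    ``MC_TABLES`` Patefield-sampled tables is returned.
    """
    t = _as_table(t)
    if (t.row_margins == 0).any() or (t.col_margins == 0).any():
        # a zero margin admits exactly one table; the statistic is undefined
        return TestResult("exact-pearson", float("nan"), 0.0, 1.0,
                          min_expected=0.0, notes={"zero_margin": True})
    chi2 = pearson_chi2(t)
    p, _ = _exact_tail(t, ordering="chi2", rng=rng)
    return TestResult(
        method="exact-pearson",
        statistic=chi2.statistic,
        df=chi2.df,
        p_raw=p,
        min_expected=chi2.min_expected,
    )


def freeman_halton(t: ContingencyTable | np.ndarray, ordering: str = "prob",
                   rng: np.random.Generator | None = None) -> TestResult:
    """Freeman-Halton exact test for an r x c table.

    Default ``ordering="prob"`` sums tables whose point probability is at
    most the observed one (the Fisher convention, to which this reduces on
    2x2 tables); ``ordering="chi2"`` instead uses the Pearson statistic as
    the tail ordering. Both orderings are exposed because published exact
    p-values do not always say which was used.
    """
    t = _as_table(t)
    if ordering not in ("prob", "chi2"):
        raise ValueError("ordering must be 'prob' or 'chi2'")
    p, _ = _exact_tail(t, ordering=ordering, rng=rng)
    return TestResult(
        method=f"freeman-halton[{ordering}]",
        statistic=float("nan"),
        df=0.0,
        p_raw=p,
        min_expected=expected_min(t),
    )


def enumerated_probability_mass(t: ContingencyTable | np.ndarray) -> float:
    """Total probability over all margin-compatible tables (should be 1)."""
    t = _as_table(t)
    _, mass = _exact_tail(t, ordering="prob")
    return mass


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------

def bonferroni_adjust(p: float, fam: FamilySpec | int) -> float:
    """Multiply p by the family size k; uncapped unless the family caps at 1.

    Uncapped adjusted values can exceed 1 (e.g. p = 1 with k = 6 gives 6);
    they are reported as-is to keep the adjustment linear and invertible.
    """
    if isinstance(fam, int):
        fam = FamilySpec(k=fam)
    adjusted = p * fam.k
    return min(adjusted, 1.0) if fam.cap_at_one else adjusted


# ---------------------------------------------------------------------------
# Pairwise group comparison (the walking-count analysis)
# ---------------------------------------------------------------------------

def pairwise_group_comparison(groups: list[tuple[int, int]],
                              fam: FamilySpec | None = None,
                              labels: list[str] | None = None,
                              exact_pearson: bool = False
                              ) -> list[TestResult]:
    """All pairwise 2x2 comparisons of (walked, total) group counts.

    For each pair a 2x2 table [[w1, t1-w1], [w2, t2-w2]] is built and the
    Pearson chi-squared computed. When the minimum expected count exceeds 5
    the Pearson p is reported (asymptotic by default, which is what
    reproduces published adjusted values on these group sizes; set
    ``exact_pearson=True`` for the margin-constrained exact significance);
    below 5 Fisher's exact test is used. P-values are Bonferroni-multiplied
    by the number of pairs (uncapped) unless a family spec overrides it.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for walked, total in groups:
        if total <= 0:
            raise ValueError("every group needs total > 0")
        if not 0 <= walked <= total:
            raise ValueError("walked must lie in [0, total]")
    pairs = list(combinations(range(len(groups)), 2))
    if fam is None:
        fam = FamilySpec(k=len(pairs))
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]

    results = []
    for i, j in pairs:
        wi, ti = groups[i]
        wj, tj = groups[j]
        table = ContingencyTable(
            np.array([[wi, ti - wi], [wj, tj - wj]]),
            row_labels=(labels[i], labels[j]),
            col_labels=("walked", "not-walked"),
        )
        chi2 = pearson_chi2(table)
        if chi2.min_expected > 5:
            if exact_pearson:
                p_raw = exact_pearson_p(table).p_raw
                branch = "exact-pearson"
            else:
                p_raw = chi2.p_raw
                branch = "pearson-asymptotic"
        else:
            p_raw = fisher_exact_2x2(table).p_raw
            branch = "fisher-exact"
        results.append(TestResult(
            method="pairwise-chi2",
            statistic=chi2.statistic,
            df=chi2.df,
            p_raw=p_raw,
            p_adjusted=bonferroni_adjust(p_raw, fam),
            min_expected=chi2.min_expected,
            branch_taken=branch,
            notes={"pair": (labels[i], labels[j]), "k": fam.k},
        ))
    return results


# ---------------------------------------------------------------------------
# Mann-Whitney U and the two-group decision tree
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U, reported as min(U1, U2), with exact p when feasible.

    The exact null distribution is used for n1*n2 <= 400 when the pooled
    sample is tie-free; the normal approximation (tie-corrected) otherwise.
    Under complete separation of supports U = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact_ok = x.size * y.size <= 400 and not has_ties
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    return TestResult(
        method="mann-whitney",
        statistic=u,
        df=0.0,
        p_raw=float(res.pvalue),
        branch_taken=method,
    )


def two_group_decision_test(x, y, alpha: float = 0.05) -> TestResult:
    """Two-sample comparison routed by normality and variance screens.

    Each sample is screened with the Kolmogorov-Smirnov normality test in
    its Lilliefors form (parameters estimated from the data); homogeneity of
    variances uses Levene's test on means. Branches:

    * both normal and homoscedastic -> pooled-variance t-test,
    * both normal, heteroscedastic -> Welch's t-test,
    * normality fails -> Mann-Whitney.

    Samples smaller than 3 skip the screens and fall back to Mann-Whitney
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 3:
        warnings.warn("sample too small for normality screen; "
                      "falling back to Mann-Whitney", stacklevel=2)
        res = mann_whitney_u(x, y)
        res.branch_taken = "mann-whitney[small-n]"
        return res

    normal = all(lilliefors(s, dist="norm")[1] > alpha for s in (x, y))
    if not normal:
        res = mann_whitney_u(x, y)
        res.branch_taken = "mann-whitney"
        return res

    _, p_levene = stats.levene(x, y, center="mean")
    if p_levene > alpha:
        t, p = stats.ttest_ind(x, y, equal_var=True)
        return TestResult("t-test", float(t), float(x.size + y.size - 2),
                          float(p), branch_taken="t-test")
    t_res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult("welch", float(t_res.statistic), float(t_res.df),
                      float(t_res.pvalue), branch_taken="welch")


# ---------------------------------------------------------------------------
# Paired ratios (bundle diameters, segment cell-count ratios)
# ---------------------------------------------------------------------------

def ratio_of_pairs(numerators, denominators) -> dict:
    """Element-wise ratios of paired measurements with mean +/- sample SD."""
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    if num.shape != den.shape:
        raise ValueError("paired samples must have equal length")
    if (den <= 0).any():
        raise ValueError("denominators must be positive")
    ratios = num / den
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return {"ratios": ratios, "mean": float(ratios.mean()), "sd": sd,
            "n": int(ratios.size)}
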