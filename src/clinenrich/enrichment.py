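"""Clinical feature enrichment analysis (CFEA).

Given a population S of samples with clinical attributes C and a
subcohort s, every categorical attribute level is tested for
over-representation in s with the one-sided hypergeometric test — the
same machinery gene-set enrichment uses, applied to sample sets — and
every numerical attribute is compared between s and its complement
S \\ s with the two-sided Wilcoxon rank-sum test.  Raw p-values are
Bonferroni-adjusted across all tests performed.

The module follows the statsmodels idiom: :class:`CohortEnrichment` is
the model (data in the constructor), ``fit()`` runs the test battery and
returns :class:`EnrichmentResults` with a ``summary()`` table and TSV
export.  The :func:`cfea` function is the one-call wrapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clinotype_io import (
    CATEGORICAL,
    NUMERICAL,
    ClinotypeTable,
    report_frame,
    write_enrichment_report,
)
from .cohort_selection import Subcohort, select_manual
from .errors import ValidationError
from .preprocess import DiscretizationRule, discretize

#: both groups at most this large, and tie-free, for the exact rank-sum null
EXACT_RANKSUM_MAX = 25


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """One-sided over-representation tail P(X >= k).

    X ~ Hypergeometric(N, K, n): draw n samples from a population of N
    of which K carry the attribute level; k carriers were observed in
    the draw.  Returns a value in (0, 1].
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if N < 1 or not (0 <= n <= N) or not (0 <= K <= N):
        raise ValidationError(f"invalid counts n={n}, K={K}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValidationError(f"invalid count k={k} for n={n}, K={K}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 5e-324), 1.0)


@dataclass(frozen=True)
class RanksumOutcome:
    statistic: float  # Mann-Whitney U of the cohort side
    pvalue: float
    mode: str  # "exact" or "asymptotic"


def ranksum_pvalue(
    cohort_values: Sequence[float] | np.ndarray,
    rest_values: Sequence[float] | np.ndarray,
) -> RanksumOutcome:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) cohort vs complement.

    Missing values must already be dropped.  The exact null distribution
    is used when both groups have at most 25 observations and the pooled
    sample is tie-free; otherwise the normal approximation with tie and
    continuity correction.  The mode used is recorded on the result.
    """
    a = np.asarray(cohort_values, dtype=float)
    b = np.asarray(rest_values, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("rank-sum requires at least one value on each side")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    exact = tie_free and len(a) <= EXACT_RANKSUM_MAX and len(b) <= EXACT_RANKSUM_MAX
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return RanksumOutcome(float(res.statistic), float(res.pvalue), method)


def bonferroni(p: float, m: int) -> float:
    """Family-wise adjusted p-value min(1, m * p)."""
    if not (0 < p <= 1):
        raise ValidationError(f"p-value {p} outside (0, 1]")
    if m < 1:
        raise ValidationError("number of tests must be >= 1")
    return min(1.0, m * p)


@dataclass
class EnrichmentResult:
    """One attribute-level (or numerical attribute) test outcome.

    ``k``/``n``/``K``/``N`` are the non-missing counts the test actually
    used; for rank-sum rows k = n = cohort group size and K = N = pooled
    group size.  ``p_value`` is NaN for untestable rows (a group empty
    after dropping missing values).
    """

    attribute: str
    level: str | None
    test: str  # "hypergeometric" or "ranksum"
    k: int
    n: int
    K: int
    N: int
    statistic: float
    p_value: float
    p_adjusted: float
    enriched_flag: bool
    mode: str | None = None  # rank-sum null used, when applicable


class EnrichmentResults:
    """Fitted CFEA results: per-attribute tests with adjusted p-values.

    Attributes
    ----------
    results : list of EnrichmentResult
        Sorted by ascending adjusted p (untestable rows last).
    m_tests : int
        Number of tests actually performed — the Bonferroni factor.
    alpha : float
        Significance threshold applied to adjusted p-values.
    run_metadata : dict
        Subcohort provenance, parameters and adjustment method.
    """

    def __init__(
        self,
        results: list[EnrichmentResult],
        m_tests: int,
        alpha: float,
        run_metadata: dict | None = None,
    ) -> None:
        self.results = results
        self.m_tests = m_tests
        self.alpha = alpha
        self.run_metadata = dict(run_metadata or {})

    @property
    def frame(self) -> pd.DataFrame:
        """The report as a DataFrame (fixed column set, sorted)."""
        return report_frame(self.results)

    @property
    def enriched(self) -> pd.DataFrame:
        df = self.frame
        return df[df["enriched_flag"]].reset_index(drop=True)

    def top(self) -> EnrichmentResult | None:
        """The result with the smallest adjusted p, if any test ran."""
        tested = [r for r in self.results if not math.isnan(r.p_value)]
        if not tested:
            return None
        return min(tested, key=lambda r: (r.p_adjusted, r.attribute, r.level or ""))

    def to_tsv(self, path) -> None:
        write_enrichment_report(self, path)

    def summary(self, max_rows: int = 20) -> str:
        meta = self.run_metadata
        lines = [
            "Clinical Feature Enrichment Analysis",
            "=" * 68,
            f"cohort size: {meta.get('cohort_size', '?')}    "
            f"population size: {meta.get('population_size', '?')}",
            f"tests performed (Bonferroni m): {self.m_tests}    alpha: {self.alpha}",
            f"adjustment: {meta.get('adjustment', 'bonferroni')}    "
            f"selection: {meta.get('provenance', {}).get('mode', '?')}",
            f"enriched attributes (p_adjusted < alpha): {len(self.enriched)}",
            "-" * 68,
        ]
        df = self.frame.head(max_rows)
        with pd.option_context("display.width", 120, "display.max_columns", None):
            lines.append(df.to_string(index=False))
        if len(self.frame) > max_rows:
            lines.append(f"... {len(self.frame) - max_rows} more rows")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EnrichmentResults {len(self.results)} rows, m_tests={self.m_tests}, "
            f"{len(self.enriched)} enriched at alpha={self.alpha}>"
        )


class CohortEnrichment:
    """Model: which clinical attributes are enriched in a subcohort?

    Parameters
    ----------
    table : ClinotypeTable
        The population S with its attribute set C.
    cohort : Subcohort
        The selected sample set s (must be a subset of the table).
    rules : sequence of DiscretizationRule, optional
        Numerical attributes to additionally bin into categorical levels
        (e.g. survival at 300 days) before testing.
    alpha : float
        Significance level for the enriched flag, default 0.05.
    adjustment : {"bonferroni", "bh"}
        Multiple-testing correction; Benjamini-Hochberg is available but
        Bonferroni is the default.
    alternative : {"greater", "two-sided"}
        Hypergeometric tail.  "greater" flags over-representation only;
        "two-sided" (Fisher-style) also catches depletion.

    Notes
    -----
    Per attribute, the denominators shrink to the non-missing counts:
    N = population samples non-missing for the attribute, n = cohort
    samples non-missing, K/k = those at the tested level.  The rank-sum
    compares the cohort against its complement (independent groups); a
    side left empty after dropping missing values makes that attribute
    untestable and it is reported without a p-value.
    """

    def __init__(
        self,
        table: ClinotypeTable,
        cohort: Subcohort,
        rules: Sequence[DiscretizationRule] = (),
        alpha: float = 0.05,
        adjustment: str = "bonferroni",
        alternative: str = "greater",
    ) -> None:
        if not (0 < alpha < 1):
            raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
        if adjustment not in ("bonferroni", "bh"):
            raise ValidationError(f"unknown adjustment {adjustment!r}")
        if alternative not in ("greater", "two-sided"):
            raise ValidationError(f"unknown alternative {alternative!r}")
        unknown = set(cohort.member_ids) - set(table.sample_ids)
        if unknown:
            raise ValidationError(f"cohort IDs not in population: {sorted(unknown)}")
        self.table = table
        self.cohort = cohort
        self.rules = tuple(rules)
        self.alpha = alpha
        self.adjustment = adjustment
        self.alternative = alternative

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        cohort_ids: Sequence[str],
        id_column: str | None = None,
        type_overrides: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "CohortEnrichment":
        """Build model straight from a raw DataFrame and an ID list."""
        table = ClinotypeTable.from_dataframe(df, id_column=id_column, type_overrides=type_overrides)
        cohort = select_manual(list(cohort_ids), table)
        return cls(table, cohort, **kwargs)

    # -- fitting -----------------------------------------------------

    def _hyper_p(self, k: int, n: int, K: int, N: int) -> float:
        if self.alternative == "greater":
            return hypergeom_pvalue(k, n, K, N)
        table = np.array([[k, n - k], [K - k, (N - K) - (n - k)]])
        return float(stats.fisher_exact(table, alternative="two-sided")[1])

    def fit(self) -> EnrichmentResults:
        table = self.table
        for rule in self.rules:
            table = discretize(table, rule)

        in_cohort = table.data.index.isin(self.cohort.member_ids)
        rows: list[EnrichmentResult] = []

        for attr in table.attributes:
            col = table.column(attr.name)
            if attr.kind == CATEGORICAL:
                nonmiss = col.notna().to_numpy()
                N = int(nonmiss.sum())
                n = int((nonmiss & in_cohort).sum())
                vals = col.to_numpy(dtype=object)
                for level in attr.levels or ():
                    at_level = nonmiss & (vals == level)
                    K = int(at_level.sum())
                    k = int((at_level & in_cohort).sum())
                    if N == 0 or n == 0:
                        rows.append(
                            EnrichmentResult(attr.name, level, "hypergeometric",
                                             k, n, K, N, np.nan, np.nan, np.nan, False)
                        )
                        continue
                    p = self._hyper_p(k, n, K, N)
                    fold = (k / n) / (K / N) if K > 0 else np.nan
                    rows.append(
                        EnrichmentResult(attr.name, level, "hypergeometric",
                                         k, n, K, N, fold, p, np.nan, False)
                    )
            else:
                x = col.to_numpy(dtype=float)
                finite = np.isfinite(x)
                a = x[finite & in_cohort]
                b = x[finite & ~in_cohort]
                n = len(a)
                N = len(a) + len(b)
                if len(a) == 0 or len(b) == 0:
                    rows.append(
                        EnrichmentResult(attr.name, None, "ranksum",
                                         n, n, N, N, np.nan, np.nan, np.nan, False,
                                         mode="untestable")
                    )
                    continue
                out = ranksum_pvalue(a, b)
                rows.append(
                    EnrichmentResult(attr.name, None, "ranksum",
                                     n, n, N, N, out.statistic, out.pvalue, np.nan, False,
                                     mode=out.mode)
                )

        tested = [i for i, r in enumerate(rows) if not math.isnan(r.p_value)]
        m = len(tested)
        if m:
            if self.adjustment == "bonferroni":
                for i in tested:
                    rows[i].p_adjusted = bonferroni(rows[i].p_value, m)
            else:
                from statsmodels.stats.multitest import multipletests

                adj = multipletests([rows[i].p_value for i in tested], method="fdr_bh")[1]
                for i, q in zip(tested, adj):
                    rows[i].p_adjusted = float(q)
            for i in tested:
                rows[i].enriched_flag = bool(rows[i].p_adjusted < self.alpha)

        rows.sort(
            key=lambda r: (
                math.isnan(r.p_adjusted),
                r.p_adjusted if not math.isnan(r.p_adjusted) else 0.0,
                r.attribute,
                r.level or "",
            )
        )
        meta = {
            "cohort_size": len(self.cohort),
            "population_size": table.n_samples,
            "provenance": self.cohort.provenance,
            "adjustment": self.adjustment,
            "alternative": self.alternative,
            "alpha": self.alpha,
            "rules": [r.to_json() for r in self.rules],
            "ranksum_modes": {r.attribute: r.mode for r in rows if r.test == "ranksum"},
        }
        return EnrichmentResults(rows, m, self.alpha, meta)


def cfea(
    table: ClinotypeTable,
    cohort: Subcohort,
    rules: Sequence[DiscretizationRule] = (),
    alpha: float = 0.05,
    **kwargs,
) -> EnrichmentResults:
    """One-call clinical feature enrichment analysis.

    Applies the discretization rules, tests every categorical
    attribute-level (hypergeometric) and every numerical attribute
    (rank-sum vs complement), Bonferroni-adjusts across all tests, and
    returns the sorted results.
    """
    return CohortEnrichment(table, cohort, rules=rules, alpha=alpha, **kwargs).fit()
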