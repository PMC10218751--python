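"""Mutation-spectrum tables, variant-call filtering, and the statistical
tests used to compare spectra.

The spectrum table is a locus x mutation-class count matrix over a closed
class taxonomy (SNP classes, microhomology-mediated classes, Ty insertion
context classes, whole-gene deletion), with marginals — the shape in which
recurrently mutated loci are reported.  Variant calls are frequency-filtered
by ploidy (>= 85% alternate-allele frequency in haploids, >= 35% in diploids,
the latter admitting heterozygotes).  Family shares express each Ty family's
percentage of novel insertions.  Tests: chi-square (contingency or
goodness-of-fit, no continuity correction by default), exact/asymptotic
Wilcoxon rank-sum, and Kruskal-Wallis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MUTATION_CLASSES",
    "SpectrumTable",
    "filter_variant_calls",
    "build_spectrum_table",
    "family_share",
    "chisq_compare",
    "rank_tests",
]

MUTATION_CLASSES = (
    "missense",
    "nonsense",
    "indel",
    "other_SNP",
    "MHMI",
    "MHMD",
    "MHMGC",
    "Ty_in_ORF",
    "five_prime_Ty",
    "three_prime_Ty",
    "other_Ty_rearrangement",
    "whole_gene_deletion",
)

HAPLOID_MIN_FREQ = 0.85
DIPLOID_MIN_FREQ = 0.35


def filter_variant_calls(
    calls: pd.DataFrame,
    haploid_min: float = HAPLOID_MIN_FREQ,
    diploid_min: float = DIPLOID_MIN_FREQ,
) -> pd.DataFrame:
    """Retain calls passing the ploidy-dependent alternate-frequency floor."""
    if calls.empty:
        return calls.copy()
    if calls["ploidy"].isna().any():
        raise ValueError("every variant call needs a ploidy")
    bad = set(calls["ploidy"].unique()) - {"haploid", "diploid"}
    if bad:
        raise ValueError(f"unknown ploidy value(s): {sorted(bad)}")
    floor = calls["ploidy"].map({"haploid": haploid_min, "diploid": diploid_min})
    return calls[calls["alt_frequency"] >= floor].copy()


@dataclass
class SpectrumTable:
    """Locus x class count matrix with marginals."""

    counts: pd.DataFrame  # index: locus, columns: MUTATION_CLASSES

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["total"] = self.row_totals
        out.loc["total"] = list(self.column_totals) + [self.grand_total]
        return out


def build_spectrum_table(mutations: pd.DataFrame, loci: list[str] | None = None) -> SpectrumTable:
    """Count distinct mutation events per (locus, class).

    Events are de-duplicated by (clone_id, locus, class, position).  With an
    explicit ordered locus list, records at other loci are grouped under
    ``other``; otherwise loci appear sorted.
    """
    bad = set(mutations["class"].unique()) - set(MUTATION_CLASSES) if len(mutations) else set()
    if bad:
        raise ValueError(f"invalid mutation class label(s): {sorted(bad)}")
    dedup_cols = [c for c in ("clone_id", "locus", "class", "position") if c in mutations.columns]
    events = mutations.drop_duplicates(subset=dedup_cols) if len(mutations) else mutations
    if loci is not None:
        locus = events["locus"].where(events["locus"].isin(loci), "other") if len(events) else pd.Series(dtype=str)
        index = list(loci) + (["other"] if (len(events) and (locus == "other").any()) else [])
    else:
        locus = events["locus"] if len(events) else pd.Series(dtype=str)
        index = sorted(locus.unique()) if len(events) else []
    table = pd.crosstab(locus, events["class"]) if len(events) else pd.DataFrame()
    table = table.reindex(index=index, columns=list(MUTATION_CLASSES), fill_value=0).astype(int)
    table.index.name = "locus"
    return SpectrumTable(table)


def family_share(family_counts: dict[str, int], decimals: int = 0) -> dict[str, float]:
    """Percentage of novel insertions contributed by each Ty family."""
    if any(v < 0 for v in family_counts.values()):
        raise ValueError("family counts must be >= 0")
    total = sum(family_counts.values())
    if total == 0:
        raise ValueError("total family count is zero")
    return {
        fam: round(100.0 * n / total, decimals) if decimals > 0 else round(100.0 * n / total)
        for fam, n in family_counts.items()
    }


def chisq_compare(
    observed_a,
    observed_b=None,
    expected_proportions=None,
    yates: bool = False,
) -> tuple[float, int, float]:
    """Chi-square comparison of mutation spectra.

    Two modes: 2 x k contingency (``observed_a`` vs ``observed_b``, both count
    vectors) and goodness-of-fit (``observed_a`` vs ``expected_proportions``).
    Both use df = k - 1 and no continuity correction unless ``yates``.
    Categories with zero expectation under both samples are dropped with a
    warning.  Returns (statistic, df, p).
    """
    a = np.asarray(observed_a, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("observed vector must be 1-D with length >= 2")
    if (a < 0).any():
        raise ValueError("counts must be >= 0")
    if (observed_b is None) == (expected_proportions is None):
        raise ValueError("provide exactly one of observed_b / expected_proportions")

    if observed_b is not None:
        b = np.asarray(observed_b, dtype=float)
        if b.shape != a.shape:
            raise ValueError("observed vectors must have the same length")
        if a.sum() == 0 or b.sum() == 0:
            raise ValueError("all-zero observed vector")
        keep = (a + b) > 0
        if not keep.all():
            warnings.warn("dropping categories with zero counts in both samples")
            a, b = a[keep], b[keep]
        stat, p, df, _ = stats.chi2_contingency(np.vstack([a, b]), correction=yates)
        return float(stat), int(df), float(p)

    props = np.asarray(expected_proportions, dtype=float)
    if props.shape != a.shape:
        raise ValueError("proportions must match the observed vector length")
    if a.sum() == 0:
        raise ValueError("all-zero observed vector")
    keep = (props > 0) | (a > 0)
    if not keep.all():
        warnings.warn("dropping categories with zero expectation and zero observation")
        a, props = a[keep], props[keep]
    props = props / props.sum()
    stat, p = stats.chisquare(a, f_exp=props * a.sum())
    return float(stat), int(a.size - 1), float(p)


def _exact_rank_sum_p(x, y) -> tuple[float, float]:
    """Exact two-sided Wilcoxon rank-sum by full enumeration.

    Enumerates every assignment of the pooled (mid)ranks to the first group;
    two-sided p doubles the smaller tail (outcomes as or more extreme than
    the observed rank sum), capped at 1.  Handles ties via midranks.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    ws = np.array([sum(c) for c in combinations(ranks, n1)])
    eps = 1e-9
    lower = (ws <= w_obs + eps).mean()
    upper = (ws >= w_obs - eps).mean()
    p = min(1.0, 2.0 * min(lower, upper))
    return float(w_obs), p


def rank_tests(groups, method: str = "wilcoxon_rank_sum") -> tuple[float, float]:
    """Nonparametric group comparisons.

    ``wilcoxon_rank_sum`` (exactly two groups): exact enumeration of all rank
    assignments when the combined sample size is <= 20, otherwise the normal
    approximation with tie correction.  ``kruskal_wallis`` (two or more
    groups): chi-square approximation with tie correction.  Returns
    (statistic, p).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if method == "wilcoxon_rank_sum":
        if len(groups) != 2:
            raise ValueError("wilcoxon_rank_sum requires exactly two groups")
        x, y = groups
        if len(x) + len(y) <= 20:
            return _exact_rank_sum_p(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if method == "kruskal_wallis":
        res = stats.kruskal(*groups)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")
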