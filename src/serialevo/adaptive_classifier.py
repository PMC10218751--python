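"""Classification of condition-specific adaptive loci.

A locus is called *nitrogen adaptive* when it satisfies three criteria:
(1) it is recurrently mutated in independent lineages (lineage independence is
defined by distinct barcodes), (2) the carrying lineages' remeasured fitness
in nitrogen limitation exceeds the 0.01/generation detection threshold, and
(3) the fitness gain in nitrogen limitation is substantially greater than in
glucose limitation.  "Substantially greater" is operationalized as a
disjunction of an absolute gap (default 0.02/generation) and a ratio
(default 2x), both configurable.

Per-locus fitness is summarized by the *lower median* across carrying
lineages (the lower middle order statistic for even counts).  The robust
summary guards against hitchhiking: a passenger mutation shared between one
adaptive and one neutral background would otherwise average its way past the
threshold.

Loci recurrently mutated but without reproducible fitness gains are labelled
``inconclusive``; loci adaptive in both conditions with no condition gap are
``shared_adaptive``; everything else is ``neutral``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClassifierConfig",
    "summarize_by_locus",
    "classify_loci",
    "summarize_cohort",
    "lower_median",
]

#: Per-generation advantage conferred by spontaneous whole-genome doubling of
#: a haploid (autodiploidization) under these conditions.
AUTODIPLOID_S = 0.03


@dataclass(frozen=True)
class ClassifierConfig:
    min_recurrence: int = 2
    fitness_threshold: float = 0.01
    condition_gap: float = 0.02
    condition_ratio: float = 2.0

    def __post_init__(self) -> None:
        for name in ("min_recurrence", "fitness_threshold", "condition_gap", "condition_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def lower_median(values) -> float:
    """Lower median: the ceil(n/2)-th order statistic.

    Equal to the ordinary median for odd n; for even n it takes the lower of
    the two middle values instead of their mean, so one permissive outlier in
    a pair cannot carry the summary above a threshold.
    """
    arr = np.sort(np.asarray(list(values), dtype=float))
    if arr.size == 0:
        return float("nan")
    return float(arr[(arr.size - 1) // 2])


def _fitness_lookup(fitness: pd.DataFrame) -> pd.DataFrame:
    return fitness.set_index("barcode")


def summarize_by_locus(
    mutations: pd.DataFrame,
    fitness_by_condition: dict[str, pd.DataFrame],
    fitness_threshold: float = 0.01,
) -> pd.DataFrame:
    """Aggregate mutations by locus across independently barcoded lineages.

    ``mutations`` needs columns ``clone_id, barcode, locus, class, position``;
    ``fitness_by_condition`` maps condition name (``nitrogen``/``glucose``) to
    an aggregated fitness table (see ``fitness_inference.aggregate_replicates``).

    Returns one row per locus with recurrence (distinct barcodes), allele
    count (distinct mutation events), per-condition fitness summaries of the
    carrying lineages, and a ``reproducible_fitness`` flag: the lower-median
    nitrogen estimate exceeds the threshold and the carriers' replicate
    scatter is sign-consistent (at least half have s_sd < s_mean).
    """
    lookups = {c: _fitness_lookup(f) for c, f in fitness_by_condition.items()}
    known = set()
    for lk in lookups.values():
        known |= set(lk.index)
    unknown = set(mutations["barcode"]) - known
    if unknown:
        raise ValueError(f"mutation references unknown barcode(s): {sorted(unknown)[:5]}")

    events = mutations.drop_duplicates(subset=["clone_id", "locus", "class", "position"])
    rows = []
    for locus, sub in events.groupby("locus", sort=True):
        barcodes = sorted(sub["barcode"].unique())
        row = {
            "locus": locus,
            "n_unique_lineages": len(barcodes),
            "n_alleles": len(sub),
        }
        per_condition: dict[str, list[float]] = {}
        for cond, lk in lookups.items():
            present = [b for b in barcodes if b in lk.index]
            vals = lk.loc[present, "s_mean"].tolist()
            per_condition[cond] = vals
            row[f"s_{cond}"] = vals
            row[f"median_s_{cond}"] = lower_median(vals) if vals else float("nan")
        nit = lookups.get("nitrogen")
        if nit is not None:
            present = [b for b in barcodes if b in nit.index]
            means = nit.loc[present, "s_mean"].to_numpy(dtype=float)
            sds = nit.loc[present, "s_sd"].to_numpy(dtype=float) if "s_sd" in nit else np.zeros(len(present))
            consistent = (sds < means).mean() >= 0.5 if len(means) else False
            row["reproducible_fitness"] = bool(
                len(means) > 0 and lower_median(means) > fitness_threshold and consistent
            )
        else:
            row["reproducible_fitness"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def classify_loci(summaries: pd.DataFrame, config: ClassifierConfig | None = None) -> pd.DataFrame:
    """Attach one label per locus: nitrogen_adaptive, shared_adaptive,
    inconclusive or neutral."""
    if config is None:
        config = ClassifierConfig()
    out = summaries.copy()
    labels = []
    gaps = []
    for row in out.itertuples(index=False):
        med_n = getattr(row, "median_s_nitrogen", float("nan"))
        med_g = getattr(row, "median_s_glucose", float("nan"))
        if np.isnan(med_g):
            med_g = 0.0
        gap = med_n - med_g
        gaps.append(gap)
        recurrent = row.n_unique_lineages >= config.min_recurrence
        nitrogen_fit = (not np.isnan(med_n)) and med_n > config.fitness_threshold
        substantially_greater = (gap >= config.condition_gap) or (
            med_n >= config.condition_ratio * max(med_g, 0.0)
        )
        if recurrent and nitrogen_fit and row.reproducible_fitness and substantially_greater:
            labels.append("nitrogen_adaptive")
        elif recurrent and nitrogen_fit and med_g > config.fitness_threshold:
            labels.append("shared_adaptive")
        elif recurrent and not row.reproducible_fitness:
            labels.append("inconclusive")
        else:
            labels.append("neutral")
    out["label"] = labels
    out["condition_gap"] = gaps
    return out


def summarize_cohort(
    labelled: pd.DataFrame,
    mutations: pd.DataFrame,
    fitness: pd.DataFrame,
    ploidy: pd.Series | dict,
    threshold: float = 0.01,
    autodiploid_s: float = AUTODIPLOID_S,
    autodiploid_tol: float = 0.005,
) -> dict:
    """Cohort-level accounting of how many adaptive lineages the called loci
    explain.

    Per ploidy and combined: the number of adaptive lineages (detectable
    nitrogen fitness), the number carrying at least one mutation at a
    nitrogen-adaptive locus, and the percentage (nearest integer; ``None``
    when there are no adaptive lineages).  Diploids whose fitness is within
    ``autodiploid_tol`` of the autodiploidization effect and that carry no
    mutation at any summarized locus are counted separately as
    ``autodiploid_only`` and excluded from the adaptive denominator.
    """
    if isinstance(ploidy, dict):
        ploidy = pd.Series(ploidy)
    adaptive_loci = set(labelled.loc[labelled["label"] == "nitrogen_adaptive", "locus"])
    carriers = (
        mutations[mutations["locus"].isin(adaptive_loci)].groupby("barcode").size().index
    )
    mutated_anywhere = set(mutations["barcode"])

    fit = fitness.set_index("barcode")
    report: dict = {
        "nitrogen_adaptive_loci": sorted(adaptive_loci),
        "total_alleles_at_adaptive_loci": int(
            labelled.loc[labelled["label"] == "nitrogen_adaptive", "n_alleles"].sum()
        ),
        "by_ploidy": {},
    }
    total_adaptive = 0
    total_explained = 0
    n_autodiploid_only = 0
    for pl in sorted(set(ploidy.values)):
        barcodes = ploidy.index[ploidy == pl]
        barcodes = [b for b in barcodes if b in fit.index]
        s = fit.loc[barcodes, "s_mean"]
        adaptive = s[s > threshold]
        if pl == "diploid":
            auto_only = [
                b
                for b in adaptive.index
                if abs(fit.loc[b, "s_mean"] - autodiploid_s) <= autodiploid_tol
                and b not in mutated_anywhere
            ]
            n_autodiploid_only += len(auto_only)
            adaptive = adaptive.drop(auto_only)
        explained = [b for b in adaptive.index if b in carriers]
        pct = round(100 * len(explained) / len(adaptive)) if len(adaptive) else None
        report["by_ploidy"][pl] = {
            "n_adaptive": int(len(adaptive)),
            "n_explained": len(explained),
            "percent_explained": pct,
        }
        total_adaptive += len(adaptive)
        total_explained += len(explained)
    report["autodiploid_only"] = n_autodiploid_only
    report["combined"] = {
        "n_adaptive": total_adaptive,
        "n_explained": total_explained,
        "percent_explained": round(100 * total_explained / total_adaptive)
        if total_adaptive
        else None,
    }
    return report


def write_locus_table(labelled: pd.DataFrame, path: str | Path) -> None:
    cols = [
        "locus",
        "label",
        "n_unique_lineages",
        "n_alleles",
        "median_s_nitrogen",
        "median_s_glucose",
        "condition_gap",
        "reproducible_fitness",
    ]
    present = [c for c in cols if c in labelled.columns]
    labelled[present].to_csv(path, sep="\t", index=False)


def write_cohort_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
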