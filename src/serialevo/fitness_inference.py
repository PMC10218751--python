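"""Per-lineage selection-coefficient estimation from barcode count trajectories.

The estimator is the mean per-transfer log-ratio of a lineage's barcode
frequency against the summed frequency of a designated neutral reference set:

    s_i = (1 / (T * g)) * sum_t [ ln(f_i(t+1)/f_i(t)) - ln(F_N(t+1)/F_N(t)) ]

with f_i(t) the pseudocounted barcode frequency at timepoint t, F_N the total
neutral-set frequency, T the number of transfer intervals and g the number of
generations per transfer.  On noise-free exponential trajectories this
recovers s exactly; referencing against the neutral set (rather than the
population mean) matches the pooled remeasurement design, where the pool is
deliberately diluted 1:10 into unbarcoded ancestor precisely so that the
population mean fitness barely moves.

Fitness effects above 0.01 per generation are flagged ``detectable``,
the conventional detection floor for these pooled assays (about twice the
standard deviation between technical replicates).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "compute_frequencies",
    "estimate_lineage_fitness",
    "aggregate_replicates",
    "infer_fitness",
    "write_fitness_table",
    "read_fitness_table",
]

DETECTION_THRESHOLD = 0.01


def compute_frequencies(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Normalize counts to frequencies per (replicate, timepoint).

    f_i(t) = (c_i(t) + pseudocount) / sum_j (c_j(t) + pseudocount).
    Returns a tidy frame with ``frequency`` added alongside ``count``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    df = counts.copy()
    adj = df["count"].astype(float) + pseudocount
    totals = adj.groupby([df["replicate"], df["timepoint"]]).transform("sum")
    if (totals == 0).any():
        bad = df.loc[totals == 0, ["replicate", "timepoint"]].drop_duplicates()
        raise ValueError(
            "zero total count with zero pseudocount at "
            + ", ".join(f"(rep {r}, t {t})" for r, t in bad.itertuples(index=False))
        )
    df["frequency"] = adj / totals
    return df


def estimate_lineage_fitness(
    freqs: pd.DataFrame,
    neutral_barcodes,
    generations_per_transfer: float = 8.0,
) -> pd.DataFrame:
    """Per-replicate selection coefficients relative to the neutral set.

    Transfer intervals where a lineage's raw count is zero at both endpoints
    carry no information and get zero weight; a lineage with zero weight in a
    replicate is flagged not-estimable (``s`` = NaN) rather than guessed.

    Returns a frame with columns ``barcode, replicate, s, estimable``.
    """
    neutral = set(neutral_barcodes)
    if not neutral:
        raise ValueError("neutral set is empty")
    present = set(freqs["barcode"].unique())
    missing = neutral - present
    if missing:
        raise ValueError(f"neutral barcodes absent from table: {sorted(missing)[:5]}")
    g = float(generations_per_transfer)
    if g <= 0:
        raise ValueError("generations_per_transfer must be > 0")

    has_counts = "count" in freqs.columns
    rows = []
    for rep, sub in freqs.groupby("replicate", sort=True):
        f = sub.pivot(index="barcode", columns="timepoint", values="frequency").sort_index(axis=1)
        if f.shape[1] < 2:
            raise ValueError("need at least two timepoints")
        fn = f.loc[f.index.isin(neutral)].sum(axis=0).to_numpy()
        d_neutral = np.diff(np.log(fn))
        logf = np.log(f.to_numpy())
        d = np.diff(logf, axis=1) - d_neutral  # per-interval log-ratio slope
        if has_counts:
            c = (
                sub.pivot(index="barcode", columns="timepoint", values="count")
                .sort_index(axis=1)
                .to_numpy()
            )
            w = ~((c[:, :-1] == 0) & (c[:, 1:] == 0))
        else:
            w = np.ones_like(d, dtype=bool)
        wsum = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(wsum > 0, (d * w).sum(axis=1) / (g * wsum), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "barcode": f.index,
                    "replicate": rep,
                    "s": s,
                    "estimable": wsum > 0,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def aggregate_replicates(
    per_replicate: pd.DataFrame | list[float],
    threshold: float = DETECTION_THRESHOLD,
) -> pd.DataFrame:
    """Mean and sample standard deviation of s across replicates.

    Accepts either the frame from :func:`estimate_lineage_fitness` or a bare
    list of per-replicate values (treated as one anonymous lineage).  Single
    replicates get ``s_sd = 0`` with ``sd_defined = False``.  ``detectable``
    applies ``s_mean > threshold``; ``detection_floor`` reports 2 x sd, the
    empirical floor implied by replicate scatter.
    """
    if not isinstance(per_replicate, pd.DataFrame):
        values = list(per_replicate)
        if not values:
            raise ValueError("need at least one replicate value")
        per_replicate = pd.DataFrame(
            {"barcode": ["lineage"] * len(values), "replicate": range(len(values)), "s": values}
        )
    df = per_replicate.dropna(subset=["s"])
    grouped = df.groupby("barcode")["s"]
    out = grouped.agg(s_mean="mean", n_replicates="count").reset_index()
    sd = grouped.std(ddof=1).reset_index(name="s_sd")
    out = out.merge(sd, on="barcode")
    out["sd_defined"] = out["n_replicates"] > 1
    out["s_sd"] = out["s_sd"].fillna(0.0)
    out["detectable"] = out["s_mean"] > threshold
    out["detection_floor"] = 2.0 * out["s_sd"]
    return out[
        ["barcode", "s_mean", "s_sd", "n_replicates", "sd_defined", "detectable", "detection_floor"]
    ]


def infer_fitness(
    counts: pd.DataFrame,
    neutral_barcodes,
    generations_per_transfer: float = 8.0,
    pseudocount: float = 0.5,
    threshold: float = DETECTION_THRESHOLD,
) -> pd.DataFrame:
    """Counts -> frequencies -> per-replicate estimates -> aggregated table."""
    freqs = compute_frequencies(counts, pseudocount=pseudocount)
    per_rep = estimate_lineage_fitness(freqs, neutral_barcodes, generations_per_transfer)
    return aggregate_replicates(per_rep, threshold=threshold)


FITNESS_COLUMNS = ["barcode", "s_mean", "s_sd", "n_replicates", "detectable"]


def write_fitness_table(fitness: pd.DataFrame, path: str | Path) -> None:
    fitness[FITNESS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_fitness_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(FITNESS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fitness table {path} missing columns: {sorted(missing)}")
    return df
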