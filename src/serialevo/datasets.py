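"""Bundled worked-example data.

Small published summary tables from the fluctuating-nitrogen evolution
cohort: allele counts per mutation class at the recurrently mutated loci,
Ty family counts among novel insertions, and the adaptive-lineage accounting
fractions.  These are inputs for worked examples and cross-checks, not
outputs of this package.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .spectrum_stats import MUTATION_CLASSES

__all__ = [
    "recurrent_locus_spectrum",
    "spectrum_as_mutation_records",
    "cohort_counts",
]


def _data(name: str):
    return resources.files("serialevo.data").joinpath(name)


def recurrent_locus_spectrum() -> pd.DataFrame:
    """Allele counts per mutation class at recurrently mutated loci.

    One row per locus; ``nitrogen_adaptive`` marks the six loci meeting the
    nitrogen-adaptive criteria.
    """
    with resources.as_file(_data("nitrogen_recurrent_loci.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def spectrum_as_mutation_records(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Expand the per-locus class counts into one synthetic record per
    mutation event, suitable for ``build_spectrum_table``.

    Clone ids and positions are synthetic placeholders (each event is a
    distinct lineage/event in the source table).
    """
    if table is None:
        table = recurrent_locus_spectrum()
    rows = []
    k = 0
    for rec in table.itertuples(index=False):
        for cls in MUTATION_CLASSES:
            for _ in range(int(getattr(rec, cls))):
                rows.append(
                    {
                        "clone_id": f"event_{k:04d}",
                        "barcode": f"event_{k:04d}",
                        "locus": rec.locus,
                        "class": cls,
                        "position": k + 1,
                        "zygosity": "hemizygous",
                        "ploidy": "haploid",
                    }
                )
                k += 1
    return pd.DataFrame(rows)


def cohort_counts() -> dict:
    """Ty family counts and adaptive-lineage fractions (published summaries)."""
    with resources.as_file(_data("cohort_counts.json")) as path:
        with open(path) as fh:
            return json.load(fh)
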