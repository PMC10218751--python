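"""Curation of retrotransposon (Ty) insertion calls from breakpoint evidence.

New LTR-retrotransposon insertions leave LTR sequence in the unaligned part
of split reads at the junction.  This module matches that unaligned junction
sequence against a library of family LTR references (Ty1-Ty5) by local
alignment on both strands, applies the ploidy-dependent retention filter used
for breakpoint evidence (at most 15% of reads mapped perfectly for haploids,
at most 70% for diploids — a heterozygous insertion in a diploid leaves half
the reads mapping cleanly), annotates the genomic context of retained calls
(ORF / 5' / 3' window / intergenic, co-orientation with the target gene,
distance to the nearest downstream tRNA start), and tests for strand bias
among the insertions at a locus with an exact binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import reverse_complement
from scipy import stats

__all__ = [
    "LtrMatch",
    "GenomeAnnotation",
    "match_ltr",
    "filter_breakpoints",
    "call_insertions",
    "annotate_insertion",
    "annotate_calls",
    "orientation_bias_test",
]

FAMILY_ORDER = ("Ty1", "Ty2", "Ty3", "Ty4", "Ty5")
HAPLOID_MAX_MAPPED = 0.15
DIPLOID_MAX_MAPPED = 0.70


@dataclass(frozen=True)
class LtrMatch:
    family: str
    strand: str
    score: float
    identity: float
    aligned_length: int


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER = _aligner()


def _align_stats(query: str, target: str):
    """Best local alignment of query vs target: (score, identity, aligned_len)."""
    alignments = _ALIGNER.align(target, query)
    try:
        aln = alignments[0]
    except IndexError:
        return 0.0, 0.0, 0
    counts = aln.counts()  # gaps, identities, mismatches
    columns = counts.gaps + counts.identities + counts.mismatches
    if columns == 0:
        return 0.0, 0.0, 0
    return float(aln.score), counts.identities / columns, columns


def match_ltr(
    sequence: str,
    ltr_library: dict[str, str],
    min_identity: float = 0.80,
    min_length: int = 25,
) -> LtrMatch | None:
    """Assign a Ty family and strand to an unaligned junction sequence.

    Both strands of the sequence are locally aligned against every library
    LTR; the best hit is returned when its identity over the aligned columns
    is at least ``min_identity`` and at least ``min_length`` columns align.
    Ties break by score, then identity, then fixed family order Ty1 < ... < Ty5.
    Returns ``None`` for no acceptable match.
    """
    if not ltr_library:
        raise ValueError("LTR library is empty")
    sequence = str(sequence).upper().replace("N", "A")
    if not sequence:
        return None
    rc = reverse_complement(sequence)
    best: LtrMatch | None = None
    order = {f: i for i, f in enumerate(FAMILY_ORDER)}
    for family in sorted(ltr_library, key=lambda f: order.get(f, len(order))):
        target = ltr_library[family].upper()
        for strand, query in (("+", sequence), ("-", rc)):
            score, identity, length = _align_stats(query, target)
            if identity < min_identity or length < min_length:
                continue
            cand = LtrMatch(family, strand, score, identity, length)
            if best is None or (cand.score, cand.identity) > (best.score, best.identity):
                best = cand
    return best


def filter_breakpoints(evidence: pd.DataFrame) -> pd.DataFrame:
    """Ploidy-dependent retention of breakpoint evidence.

    Haploid records are kept when at most 15% of reads at the breakpoint
    mapped perfectly; diploid records when at most 70% did.  Order preserved;
    idempotent.
    """
    if evidence.empty:
        return evidence.copy()
    if evidence["ploidy"].isna().any():
        raise ValueError("every breakpoint record needs a ploidy")
    bad = set(evidence["ploidy"].unique()) - {"haploid", "diploid"}
    if bad:
        raise ValueError(f"unknown ploidy value(s): {sorted(bad)}")
    caps = evidence["ploidy"].map({"haploid": HAPLOID_MAX_MAPPED, "diploid": DIPLOID_MAX_MAPPED})
    return evidence[evidence["mapped_perfectly_fraction"] <= caps].copy()


def call_insertions(
    evidence: pd.DataFrame,
    ltr_library: dict[str, str],
    min_identity: float = 0.80,
    min_length: int = 25,
) -> pd.DataFrame:
    """Filter evidence, match each retained record to an LTR family, and emit
    curated Ty calls (records without an acceptable LTR match are dropped)."""
    retained = filter_breakpoints(evidence)
    rows = []
    for rec in retained.itertuples(index=False):
        m = match_ltr(rec.unaligned_sequence, ltr_library, min_identity, min_length)
        if m is None:
            continue
        rows.append(
            {
                "clone_id": rec.clone_id,
                "chromosome": rec.chromosome,
                "position": rec.position,
                "family": m.family,
                "strand": m.strand,
                "match_score": m.score,
                "match_identity": m.identity,
                "ploidy": rec.ploidy,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "clone_id",
            "chromosome",
            "position",
            "family",
            "strand",
            "match_score",
            "match_identity",
            "ploidy",
        ],
    )


class GenomeAnnotation:
    """Gene and tRNA models for insertion-context annotation.

    Coordinates are 1-based fully closed, the GFF3 convention.  Build either
    from a GFF3 file/string (features ``gene`` and ``tRNA_gene``) or directly
    from dataframes with columns ``seqid, start, end, strand, name``.
    """

    def __init__(self, genes: pd.DataFrame, trnas: pd.DataFrame):
        required = {"seqid", "start", "end", "strand", "name"}
        for df, what in ((genes, "genes"), (trnas, "tRNAs")):
            missing = required - set(df.columns)
            if missing:
                raise ValueError(f"{what} table missing columns: {sorted(missing)}")
        self.genes = genes.reset_index(drop=True)
        self.trnas = trnas.reset_index(drop=True)

    @classmethod
    def from_gff3(cls, source: str, from_string: bool = False) -> "GenomeAnnotation":
        import gffutils

        db = gffutils.create_db(
            source,
            dbfn=":memory:",
            from_string=from_string,
            merge_strategy="create_unique",
            keep_order=True,
        )

        def table(featuretype):
            rows = []
            for feat in db.features_of_type(featuretype):
                name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
                rows.append(
                    {
                        "seqid": feat.seqid,
                        "start": feat.start,
                        "end": feat.end,
                        "strand": feat.strand,
                        "name": name,
                    }
                )
            return pd.DataFrame(rows, columns=["seqid", "start", "end", "strand", "name"])

        return cls(table("gene"), table("tRNA_gene"))

    def chromosomes(self) -> set[str]:
        return set(self.genes["seqid"]) | set(self.trnas["seqid"])


def _trna_distance(annotation: GenomeAnnotation, chromosome: str, position: int):
    """Signed distance to the nearest downstream tRNA gene start.

    A tRNA is "downstream" of the insertion when the insertion lies upstream
    of the tRNA's transcription start on the tRNA's own strand; the distance
    is reported negative in that case (insertion upstream of the start).
    """
    trnas = annotation.trnas[annotation.trnas["seqid"] == chromosome]
    best = None
    for t in trnas.itertuples(index=False):
        tss = t.start if t.strand == "+" else t.end
        d = (position - tss) if t.strand == "+" else (tss - position)
        if d < 0 and (best is None or d > best):
            best = d
    return best


def annotate_insertion(
    call: dict | pd.Series,
    annotation: GenomeAnnotation,
    window_bp: int = 500,
) -> dict:
    """Fill the genomic-context fields of one Ty call.

    ``context`` is ``ORF`` when the position falls inside a gene span,
    ``five_prime``/``three_prime`` when within ``window_bp`` of a gene start/
    end (strand-aware), else ``intergenic``.  ``co_oriented`` compares the
    call strand to the target gene strand (None when intergenic).
    """
    call = dict(call)
    chrom, pos = call["chromosome"], int(call["position"])
    if chrom not in annotation.chromosomes():
        raise ValueError(f"annotation does not cover chromosome {chrom!r}")
    genes = annotation.genes[annotation.genes["seqid"] == chrom]

    context, target, distance = "intergenic", None, None
    for gene in genes.itertuples(index=False):
        if gene.start <= pos <= gene.end:
            context, target = "ORF", gene
            break
    if context == "intergenic":
        best = None
        for gene in genes.itertuples(index=False):
            if gene.strand == "+":
                five_lo, five_hi = gene.start - window_bp, gene.start - 1
                three_lo, three_hi = gene.end + 1, gene.end + window_bp
                d5, d3 = gene.start - pos, pos - gene.end
            else:
                five_lo, five_hi = gene.end + 1, gene.end + window_bp
                three_lo, three_hi = gene.start - window_bp, gene.start - 1
                d5, d3 = pos - gene.end, gene.start - pos
            if five_lo <= pos <= five_hi and (best is None or d5 < best[2]):
                best = ("five_prime", gene, d5)
            if three_lo <= pos <= three_hi and (best is None or d3 < best[2]):
                best = ("three_prime", gene, d3)
        if best is not None:
            context, target, distance = best

    call["context"] = context
    call["target_gene"] = target.name if target is not None else None
    call["co_oriented"] = (
        (call.get("strand") == target.strand) if target is not None else None
    )
    call["trna_distance"] = _trna_distance(annotation, chrom, pos)
    return call


def annotate_calls(
    calls: pd.DataFrame, annotation: GenomeAnnotation, window_bp: int = 500
) -> pd.DataFrame:
    rows = [annotate_insertion(row, annotation, window_bp) for _, row in calls.iterrows()]
    return pd.DataFrame(rows)


def orientation_bias_test(calls: pd.DataFrame | list[bool]) -> tuple[int, int, float]:
    """Exact two-sided binomial test of co-orientation against p = 0.5.

    Accepts either an annotated call table (uses its ``co_oriented`` column,
    dropping rows where it is undefined) or a bare list of booleans.  The
    two-sided p sums the probabilities of all outcomes no more likely than
    the observed one.  Returns (n_co, n_anti, p); raises on n = 0.
    """
    if isinstance(calls, pd.DataFrame):
        flags = calls["co_oriented"].dropna().astype(bool).tolist()
    else:
        flags = [bool(x) for x in calls]
    n = len(flags)
    if n == 0:
        raise ValueError("no calls with co_oriented set; orientation test undefined")
    n_co = sum(flags)
    p = stats.binomtest(n_co, n, 0.5, alternative="two-sided").pvalue
    return n_co, n - n_co, float(p)
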