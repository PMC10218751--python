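"""Detection of microhomology-mediated mutations.

Short sequences repeated in tandem ("microhomology") predispose the
intervening segment to deletion or duplication, and homologous donor loci to
ectopic gene conversion.  Given a reference allele and an observed allele at
a locus, this module

* finds the flanking microhomology at a pair of breakpoints
  (:func:`find_flank_homology` — the maximal shared prefix of the two
  suffixes starting at the breakpoints, exact match only);
* classifies a single contiguous difference as a microhomology-mediated
  deletion (MHMD) or tandem-duplication insertion (MHMI) when the junction
  homology reaches ``min_homology`` (:func:`classify_event`);
* scans a panel of donor genes for microhomology-mediated gene conversion
  (MHMGC): an internal segment of the observed allele absent from the
  reference but matching a donor paralog, as seen for FCY2 alleles converted
  from FCY21/FCY22 (:func:`scan_conversion_donor`).

Coordinates are 1-based.  When several breakpoint placements explain the same
allele (the usual ambiguity created by the homology itself), the leftmost
placement on the reference is reported and the ambiguity width recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

__all__ = [
    "JunctionAllele",
    "MHEvent",
    "find_flank_homology",
    "classify_event",
    "scan_conversion_donor",
    "apply_event",
]

_VALID = set("ACGT")


@dataclass(frozen=True)
class JunctionAllele:
    locus: str
    reference_sequence: str
    observed_sequence: str

    def __post_init__(self) -> None:
        for name in ("reference_sequence", "observed_sequence"):
            seq = getattr(self, name)
            if not seq or set(seq) - _VALID:
                raise ValueError(f"{name} must be non-empty over A/C/G/T")


@dataclass
class MHEvent:
    event_type: str  # MHMD | MHMI | MHMGC | none
    start: int = 0  # 1-based on the reference
    end: int = 0
    homology_length: int = 0
    homology_sequence: str = ""
    segment: str = ""
    ambiguity_width: int = 0
    frameshifting: bool | None = None
    donor: str | None = None
    donor_identity: float | None = None
    left_homology: int | None = None
    right_homology: int | None = None


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def find_flank_homology(reference: str, left_breakpoint: int, right_breakpoint: int) -> tuple[int, str]:
    """Microhomology shared by two breakpoints on the reference.

    Breakpoints are 1-based positions of the first base at/after each break;
    the homology is the maximal shared prefix of the two suffixes
    ``reference[left:]`` and ``reference[right:]`` (0 and "" when the first
    bases already differ).  Length is naturally capped by the sequence end.
    """
    n = len(reference)
    if not (1 <= left_breakpoint < right_breakpoint <= n):
        raise ValueError(
            f"breakpoints must satisfy 1 <= left < right <= {n}; "
            f"got ({left_breakpoint}, {right_breakpoint})"
        )
    k = _lcp(reference[left_breakpoint - 1 :], reference[right_breakpoint - 1 :])
    return k, reference[left_breakpoint - 1 : left_breakpoint - 1 + k]


def _single_difference(reference: str, observed: str):
    """Locate the single contiguous difference between the two sequences.

    Returns (kind, leftmost_pos0, length, ambiguity_width) where kind is
    'deletion'/'insertion'/'identity'; raises when the sequences cannot be
    explained by one contiguous indel (more than one difference block).
    """
    if reference == observed:
        return "identity", 0, 0, 0
    if len(reference) == len(observed):
        raise ValueError(
            "equal-length differing sequences: more than one difference block; "
            "use scan_conversion_donor for gene-conversion candidates"
        )
    long, short = (reference, observed) if len(reference) > len(observed) else (observed, reference)
    delta = len(long) - len(short)
    p = _lcp(long, short)
    s = _lcs(long, short)
    if p + s < len(short):
        raise ValueError(
            "more than one contiguous difference block; "
            "use scan_conversion_donor for gene-conversion candidates"
        )
    # valid placements of the indel start i: max(0, len(long)-delta-s) .. min(p, len(short))
    i_left = max(0, len(long) - delta - s)
    i_right = min(p, len(short))
    kind = "deletion" if len(reference) > len(observed) else "insertion"
    return kind, i_left, delta, i_right - i_left


def apply_event(reference: str, event: MHEvent) -> str:
    """Regenerate the observed allele by applying an MHMD/MHMI event to the
    reference (used by the reconstruction tests)."""
    if event.event_type == "MHMD":
        return reference[: event.start - 1] + reference[event.end :]
    if event.event_type == "MHMI":
        return reference[: event.start - 1] + event.segment + reference[event.start - 1 :]
    raise ValueError(f"cannot apply event of type {event.event_type!r}")


def classify_event(
    allele: JunctionAllele,
    min_homology: int = 3,
    coding: bool = True,
) -> MHEvent:
    """Classify a single contiguous difference as MHMD / MHMI / none.

    A deletion whose removed segment is flanked by an exact repeat of at
    least ``min_homology`` bp is MHMD; an insertion that tandem-duplicates
    the adjacent reference segment with the same flanking homology is MHMI.
    ``frameshifting`` is set (length change not a multiple of 3) when the
    locus is coding.  Sequences differing by more than one contiguous block
    raise, directing the caller to the gene-conversion scan.
    """
    ref, obs = allele.reference_sequence, allele.observed_sequence
    kind, i, delta, ambiguity = _single_difference(ref, obs)
    if kind == "identity":
        return MHEvent(event_type="none")
    frameshifting = (delta % 3 != 0) if coding else None

    if kind == "deletion":
        start, end = i + 1, i + delta  # 1-based inclusive deleted span
        hom_len, hom_seq = find_flank_homology(ref, start, end + 1)
        if hom_len >= min_homology:
            return MHEvent(
                "MHMD",
                start=start,
                end=end,
                homology_length=hom_len,
                homology_sequence=hom_seq,
                segment=ref[i : i + delta],
                ambiguity_width=ambiguity,
                frameshifting=frameshifting,
            )
        return MHEvent("none", start=start, end=end, ambiguity_width=ambiguity,
                       frameshifting=frameshifting)

    # insertion: inserted segment (leftmost placement) is obs[i:i+delta],
    # inserted before reference position i+1.  At the leftmost placement a
    # tandem duplication always duplicates the reference segment that follows
    # the insertion point.  The junction homology is measured on the observed
    # sequence, which carries both copies — exactly the computation the
    # role-swapped deletion performs on its reference, so MHMI/MHMD homology
    # lengths agree for corresponding events.
    inserted = obs[i : i + delta]
    tandem = inserted == ref[i : i + delta]
    if tandem:
        hom_len, hom_seq = find_flank_homology(obs, i + 1, i + delta + 1)
        if hom_len >= min_homology:
            return MHEvent(
                "MHMI",
                start=i + 1,
                end=i + delta,
                homology_length=hom_len,
                homology_sequence=hom_seq,
                segment=inserted,
                ambiguity_width=ambiguity,
                frameshifting=frameshifting,
            )
    return MHEvent("none", start=i + 1, end=i + delta, ambiguity_width=ambiguity,
                   frameshifting=frameshifting)


def _donor_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    return aligner


_DONOR_ALIGNER = _donor_aligner()


def scan_conversion_donor(
    allele: JunctionAllele,
    donors: dict[str, str],
    min_segment: int = 20,
    donor_min_identity: float = 0.90,
) -> MHEvent:
    """Identify a microhomology-mediated gene conversion and its donor.

    The replaced segment is delimited by the maximal shared prefix/suffix
    between observed and reference; the internal observed segment is then
    locally aligned (affine gaps) against each donor.  The best donor with
    identity >= ``donor_min_identity`` over >= ``min_segment`` aligned
    columns is reported, along with the exact junction homology between each
    retained reference flank and the donor sequence abutting the converted
    tract.  Returns an event of type ``none`` when no donor qualifies.
    """
    if not donors:
        raise ValueError("need at least one donor sequence")
    ref, obs = allele.reference_sequence, allele.observed_sequence
    if ref == obs:
        return MHEvent("none")
    p = _lcp(ref, obs)
    s = _lcs(ref, obs)
    s = min(s, min(len(ref), len(obs)) - p)
    segment = obs[p : len(obs) - s]
    if len(segment) < min_segment:
        return MHEvent("none")

    best = None
    for name in sorted(donors):
        alignments = _DONOR_ALIGNER.align(donors[name].upper(), segment)
        try:
            aln = alignments[0]
        except IndexError:
            continue
        counts = aln.counts()
        columns = counts.gaps + counts.identities + counts.mismatches
        if columns < min_segment:
            continue
        identity = counts.identities / columns
        if identity < donor_min_identity:
            continue
        d_start = int(aln.aligned[0][0][0])
        d_end = int(aln.aligned[0][-1][1])
        cand = (aln.score, identity, name, d_start, d_end)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    if best is None:
        return MHEvent("none")
    _, identity, name, d_start, d_end = best
    donor_seq = donors[name].upper()
    left_hom = _lcs(ref[:p], donor_seq[:d_start])
    right_hom = _lcp(ref[len(ref) - s :], donor_seq[d_end:])
    return MHEvent(
        "MHMGC",
        start=p + 1,
        end=len(ref) - s,
        homology_length=max(left_hom, right_hom),
        segment=segment,
        donor=name,
        donor_identity=float(identity),
        left_homology=left_hom,
        right_homology=right_hom,
    )
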