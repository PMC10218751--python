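"""Seeded synthetic-data generation for barcoded serial-transfer experiments.

This module emulates the pooled competitive fitness-remeasurement design used
in barcode lineage tracking studies: a pool of barcoded clones plus a set of
confirmed-neutral reference barcodes is diluted into an excess of unbarcoded
ancestor and propagated through repeated growth/bottleneck cycles, with the
barcode locus amplicon-sequenced at every transfer.  It also generates the
downstream evidence the rest of the package consumes — de novo mutation
tables with planted ground truth, split-read breakpoint evidence for
retrotransposon (Ty) insertions, and Luria-Delbruck fluctuation-assay colony
counts.

Growth within a cycle is deterministic exponential (a lineage with Malthusian
per-generation coefficient ``s`` grows by ``exp(s*g)`` per cycle relative to
neutral); stochasticity enters only at the bottleneck (multinomial sampling of
the transferred inoculum) and at read sampling.  This is the standard
serial-transfer approximation and keeps a closed-form oracle for testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "SimConfig",
    "TrueLineage",
    "TrajectorySet",
    "MutationClassSpec",
    "simulate_serial_transfer",
    "sample_barcode_reads",
    "build_remeasurement_pool",
    "simulate_evolved_cohort",
    "generate_breakpoint_evidence",
    "plant_ty_insertions",
    "simulate_fluctuation_assay",
    "synthetic_ltr_library",
    "write_ltr_library",
    "read_ltr_library",
    "write_count_table",
    "read_count_table",
]

UNBARCODED = "__unbarcoded__"

#: Default per-generation fitness grid for remeasurement pools: the effects
#: validated for the recurrently mutated loci span roughly 0.03-0.08 per
#: generation, with the detection floor at 0.01.
DEFAULT_S_GRID = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08)

TY_FAMILIES = ("Ty1", "Ty2", "Ty3", "Ty4", "Ty5")


@dataclass(frozen=True)
class MutationClassSpec:
    """One mutation class the evolution-mode generator can spawn.

    ``rate`` is a per-lineage, per-cycle probability; ``effect_range`` is the
    uniform range the per-generation fitness effect is drawn from; ``loci`` is
    the set of target locus names the event may hit.
    """

    name: str
    rate: float
    effect_range: tuple[float, float]
    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"mutation class {self.name!r}: rate must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Design constants of a simulated serial-transfer competition.

    Defaults mirror the pooled remeasurement design: 48 neutral reference
    barcodes, a test pool of ~345 clones, 90% unbarcoded ancestor, four
    transfers in triplicate.  ``generations_per_transfer`` defaults to 8
    (a 1:250 dilution, 400 uL into 100 mL, gives log2(250) ~ 7.97 doublings
    back to saturation).  ``bottleneck_size`` is the census of cells carried
    through a transfer; 8e6 corresponds to ~400 uL of saturated culture.
    """

    n_neutral_barcodes: int = 48
    n_test_barcodes: int = 345
    unbarcoded_fraction: float = 0.9
    n_transfers: int = 4
    generations_per_transfer: float = 8.0
    bottleneck_size: int = 8_000_000
    read_depth: int = 500_000
    n_replicates: int = 3
    mutation_classes: tuple[MutationClassSpec, ...] = ()
    ltr_library_path: str | None = None
    seed: int = 0
    mode: str = "remeasurement"
    deterministic: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.unbarcoded_fraction < 1:
            raise ValueError("unbarcoded_fraction must be in [0, 1)")
        if self.generations_per_transfer <= 0:
            raise ValueError("generations_per_transfer must be > 0")
        if self.n_transfers < 1:
            raise ValueError("n_transfers must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")
        n_lineages = self.n_neutral_barcodes + self.n_test_barcodes + 1
        if self.bottleneck_size < n_lineages:
            raise ValueError(
                f"bottleneck_size ({self.bottleneck_size}) smaller than the "
                f"number of lineages ({n_lineages})"
            )
        if self.mode not in ("remeasurement", "evolution"):
            raise ValueError("mode must be 'remeasurement' or 'evolution'")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TrueLineage:
    """Ground truth for one clone in the pool."""

    barcode: str
    clone_id: str
    true_s: float
    ploidy: str = "haploid"
    is_neutral_reference: bool = False
    mutations: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.true_s):
            raise ValueError(f"lineage {self.barcode}: true_s must be finite")


@dataclass
class TrajectorySet:
    """True frequencies and (optionally) sampled read counts of a competition.

    ``true_frequencies`` is a tidy frame with columns
    ``barcode, replicate, timepoint, frequency`` that includes the unbarcoded
    ancestor as the pseudo-lineage ``__unbarcoded__``; per (replicate,
    timepoint) the frequencies sum to 1.  ``counts`` has the same shape with a
    ``count`` column and excludes the unbarcoded ancestor (its barcode is not
    amplifiable).
    """

    true_frequencies: pd.DataFrame
    counts: pd.DataFrame | None = None

    def frequency_matrix(self, replicate: int) -> pd.DataFrame:
        """Wide barcode x timepoint matrix of true frequencies."""
        sub = self.true_frequencies[self.true_frequencies["replicate"] == replicate]
        return sub.pivot(index="barcode", columns="timepoint", values="frequency")


# ---------------------------------------------------------------------------
# pool construction


def build_remeasurement_pool(
    config: SimConfig,
    s_values=None,
    rng: np.random.Generator | None = None,
) -> list[TrueLineage]:
    """Assemble the fixed-genotype pool for a remeasurement competition.

    Neutral reference barcodes get ``s = 0``.  Test clones receive the
    coefficients in ``s_values`` (cycled if shorter than the pool); by default
    the grid 0.00-0.08 in 0.01 steps, matching the range of validated effects.
    """
    if s_values is None:
        s_values = DEFAULT_S_GRID
    s_values = list(s_values)
    lineages = [
        TrueLineage(
            barcode=f"neutral_{i:03d}",
            clone_id=f"neutral_{i:03d}",
            true_s=0.0,
            is_neutral_reference=True,
        )
        for i in range(config.n_neutral_barcodes)
    ]
    for i in range(config.n_test_barcodes):
        s = float(s_values[i % len(s_values)])
        lineages.append(
            TrueLineage(barcode=f"bc_{i:04d}", clone_id=f"clone_{i:04d}", true_s=s)
        )
    return lineages


def simulate_evolved_cohort(
    config: SimConfig,
    adaptive_loci: dict[str, int] | None = None,
    effect_range: tuple[float, float] = (0.03, 0.08),
    passenger_rate: float = 0.3,
    n_passenger_loci: int = 6000,
    diploid_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[TrueLineage], pd.DataFrame]:
    """Generate a sequenced-cohort ground truth with planted adaptive loci.

    ``adaptive_loci`` maps locus name -> number of independent lineages
    carrying an adaptive mutation there; effects are drawn uniformly from
    ``effect_range`` per generation (condition-specific: they apply in the
    nitrogen condition only).  Every clone additionally acquires
    Poisson(``passenger_rate``) fitness-neutral passenger point mutations
    scattered over a genome-wide pool of ``n_passenger_loci`` gene names;
    0.3 per clone reflects the low point-mutation load of clones isolated
    after ~200 generations.

    Returns the lineage list (``true_s`` is the nitrogen-condition
    coefficient) and a tidy mutation table with columns
    ``clone_id, barcode, locus, class, position, zygosity, ploidy, adaptive``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if adaptive_loci is None:
        adaptive_loci = {f"ADP{i}": 4 for i in range(1, 7)}
    lineages = build_remeasurement_pool(config, s_values=[0.0], rng=rng)
    test = [ln for ln in lineages if not ln.is_neutral_reference]
    n_needed = sum(adaptive_loci.values())
    if n_needed > len(test):
        raise ValueError("more adaptive lineages requested than test barcodes")

    if diploid_fraction > 0:
        for ln in test:
            if rng.random() < diploid_fraction:
                ln.ploidy = "diploid"

    adaptive_classes = ["missense", "nonsense", "indel", "Ty_in_ORF", "MHMD"]
    records: list[dict] = []
    carriers = rng.choice(len(test), size=n_needed, replace=False)
    idx = 0
    for locus, n_lineages in adaptive_loci.items():
        for _ in range(n_lineages):
            ln = test[carriers[idx]]
            idx += 1
            effect = float(rng.uniform(*effect_range))
            ln.true_s += effect
            rec = {
                "clone_id": ln.clone_id,
                "barcode": ln.barcode,
                "locus": locus,
                "class": str(rng.choice(adaptive_classes)),
                "position": int(rng.integers(1, 500_000)),
                "zygosity": "hemizygous" if ln.ploidy == "haploid" else "het",
                "ploidy": ln.ploidy,
                "adaptive": True,
            }
            ln.mutations.append(rec)
            records.append(rec)

    passenger_pool = [f"YGL{i:04d}" for i in range(n_passenger_loci)]
    for ln in test:
        for _ in range(rng.poisson(passenger_rate)):
            rec = {
                "clone_id": ln.clone_id,
                "barcode": ln.barcode,
                "locus": passenger_pool[int(rng.integers(n_passenger_loci))],
                "class": str(rng.choice(["missense", "other_SNP", "indel"])),
                "position": int(rng.integers(1, 500_000)),
                "zygosity": "hemizygous" if ln.ploidy == "haploid" else "het",
                "ploidy": ln.ploidy,
                "adaptive": False,
            }
            ln.mutations.append(rec)
            records.append(rec)

    columns = ["clone_id", "barcode", "locus", "class", "position", "zygosity", "ploidy", "adaptive"]
    mutations = pd.DataFrame(records, columns=columns)
    return lineages, mutations


# ---------------------------------------------------------------------------
# serial-transfer dynamics


def _spawn_evolution_mutations(
    config: SimConfig,
    lineages: list[TrueLineage],
    freqs: np.ndarray,
    cycle: int,
    rng: np.random.Generator,
) -> tuple[list[TrueLineage], np.ndarray]:
    """Evolution mode: spawn de novo mutant sub-lineages at class rates.

    A mutant keeps the parental barcode (barcodes pre-exist the mutation);
    ground truth distinguishes it by a new clone_id.  The sub-lineage starts
    at one cell's worth of frequency taken from its parent.
    """
    new_lineages = list(lineages)
    new_freqs = list(freqs[:-1])  # barcoded entries; last is unbarcoded
    one_cell = 1.0 / config.bottleneck_size
    for i, parent in enumerate(lineages):
        if parent.is_neutral_reference:
            continue
        for spec in config.mutation_classes:
            if rng.random() >= spec.rate or new_freqs[i] <= one_cell:
                continue
            locus = str(rng.choice(list(spec.loci)))
            effect = float(rng.uniform(*spec.effect_range))
            rec = {
                "clone_id": f"{parent.clone_id}.m{cycle}",
                "barcode": parent.barcode,
                "locus": locus,
                "class": spec.name,
                "position": int(rng.integers(1, 500_000)),
                "zygosity": "hemizygous" if parent.ploidy == "haploid" else "het",
                "ploidy": parent.ploidy,
                "adaptive": effect != 0.0,
            }
            child = TrueLineage(
                barcode=parent.barcode,
                clone_id=rec["clone_id"],
                true_s=parent.true_s + effect,
                ploidy=parent.ploidy,
                mutations=parent.mutations + [rec],
            )
            new_lineages.append(child)
            new_freqs.append(one_cell)
            new_freqs[i] -= one_cell
    out = np.array(new_freqs + [freqs[-1]])
    return new_lineages, out


def simulate_serial_transfer(
    config: SimConfig,
    lineages: list[TrueLineage] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[TrueLineage], TrajectorySet]:
    """Propagate the pool through growth/bottleneck cycles.

    Timepoint 0 is taken right after mixing with the unbarcoded ancestor.
    Per cycle, every lineage's abundance is multiplied by ``exp(s*g)``
    relative to neutral, renormalized, and (unless ``config.deterministic``)
    bottleneck-sampled multinomially to ``bottleneck_size`` cells.  In
    evolution mode, new mutant sub-lineages are spawned per lineage per cycle
    at the configured class rates.

    Returns the (possibly grown) lineage list and a :class:`TrajectorySet`
    with true frequencies over ``n_transfers + 1`` timepoints per replicate.
    Read counts are not drawn here; see :func:`sample_barcode_reads`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if lineages is None:
        # evolution starts from an isogenic (s = 0) pool; remeasurement pools
        # default to the validated-effect grid
        s_values = [0.0] if config.mode == "evolution" else None
        lineages = build_remeasurement_pool(config, s_values=s_values, rng=rng)
    g = config.generations_per_transfer

    rows = []
    all_lineages = list(lineages)
    for rep in range(config.n_replicates):
        rep_rng = np.random.default_rng(rng.integers(2**31))
        rep_lineages = [dataclasses.replace(ln, mutations=list(ln.mutations)) for ln in lineages]
        n0 = len(rep_lineages)
        barcoded_share = (1.0 - config.unbarcoded_fraction) / n0
        freqs = np.array([barcoded_share] * n0 + [config.unbarcoded_fraction])

        def record(t, lins, f):
            for ln, fi in zip(lins, f[:-1]):
                rows.append((ln.barcode, ln.clone_id, rep, t, fi))
            rows.append((UNBARCODED, UNBARCODED, rep, t, f[-1]))

        record(0, rep_lineages, freqs)
        for cycle in range(1, config.n_transfers + 1):
            s = np.array([ln.true_s for ln in rep_lineages] + [0.0])
            if config.bottleneck_size < len(s):
                raise ValueError("bottleneck_size smaller than lineage count")
            w = freqs * np.exp(s * g)
            freqs = w / w.sum()
            if config.mode == "evolution":
                rep_lineages, freqs = _spawn_evolution_mutations(
                    config, rep_lineages, freqs, cycle, rep_rng
                )
                freqs = freqs / freqs.sum()
            if not config.deterministic:
                cells = rep_rng.multinomial(config.bottleneck_size, freqs)
                freqs = cells / config.bottleneck_size
            record(cycle, rep_lineages, freqs)
        if rep == 0:
            all_lineages = rep_lineages
        else:
            known = {ln.clone_id for ln in all_lineages}
            all_lineages.extend(ln for ln in rep_lineages if ln.clone_id not in known)

    traj = pd.DataFrame(
        rows, columns=["barcode", "clone_id", "replicate", "timepoint", "frequency"]
    )
    # barcode-level frequencies (sub-lineages of one barcode summed)
    freq = (
        traj.groupby(["barcode", "replicate", "timepoint"], as_index=False)["frequency"]
        .sum()
        .sort_values(["replicate", "timepoint", "barcode"], ignore_index=True)
    )
    return all_lineages, TrajectorySet(true_frequencies=freq)


def sample_barcode_reads(
    trajectories: TrajectorySet,
    depth: int,
    seed: int,
) -> pd.DataFrame:
    """Draw barcode read counts by multinomial sampling at each timepoint.

    The unbarcoded ancestor is excluded before renormalization: its barcode
    locus is not amplifiable, so it is invisible to the sequencer.  The same
    seed yields identical counts.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    freq = trajectories.true_frequencies
    freq = freq[freq["barcode"] != UNBARCODED]
    rows = []
    for (rep, t), sub in freq.groupby(["replicate", "timepoint"], sort=True):
        p = sub["frequency"].to_numpy(dtype=float)
        total = p.sum()
        if depth == 0 or total == 0:
            counts = np.zeros(len(p), dtype=int)
        else:
            counts = rng.multinomial(int(depth), p / total)
        rows.extend(zip(sub["barcode"], [rep] * len(p), [t] * len(p), counts))
    out = pd.DataFrame(rows, columns=["barcode", "replicate", "timepoint", "count"])
    return out.sort_values(["replicate", "timepoint", "barcode"], ignore_index=True)


# ---------------------------------------------------------------------------
# LTR library and breakpoint evidence


def synthetic_ltr_library(seed: int = 7, length: int = 330) -> dict[str, str]:
    """One synthetic consensus LTR per Ty family (Ty1-Ty5).

    Sequences are independent uniform-random nucleotide strings of ~LTR
    length; random families share ~25% identity, which is ample separation
    for testing family assignment (real Ty1/Ty2 LTRs are more similar, so
    thresholds validated here are optimistic for those two families).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return {
        fam: "".join(rng.choice(bases, size=length)) for fam in TY_FAMILIES
    }


def write_ltr_library(library: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fam, seq in library.items():
            fh.write(f">{fam}_LTR synthetic consensus\n{seq}\n")


def read_ltr_library(path: str | Path) -> dict[str, str]:
    """Read a multi-FASTA of LTR references; family parsed from the header
    prefix (``>Ty1_...``)."""
    lib: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fam = rec.id.split("_")[0]
        lib[fam] = str(rec.seq).upper()
    if not lib:
        raise ValueError(f"empty LTR library: {path}")
    return lib


def plant_ty_insertions(
    n: int,
    rng: np.random.Generator,
    family_weights: dict[str, float] | None = None,
    chromosomes: tuple[str, ...] = ("chrI", "chrII", "chrIII", "chrIV"),
    diploid_fraction: float = 0.2,
) -> pd.DataFrame:
    """Draw ground-truth Ty insertions with family/orientation/position
    structure.  Default family weights mirror the strong Ty1 dominance among
    de novo insertions, with Ty2 a minority and Ty3 rare."""
    if family_weights is None:
        family_weights = {"Ty1": 0.92, "Ty2": 0.075, "Ty3": 0.005}
    fams = list(family_weights)
    p = np.array([family_weights[f] for f in fams], dtype=float)
    p = p / p.sum()
    rows = []
    for i in range(n):
        rows.append(
            {
                "clone_id": f"clone_{i:04d}",
                "chromosome": str(rng.choice(chromosomes)),
                "position": int(rng.integers(1_000, 1_000_000)),
                "family": str(rng.choice(fams, p=p)),
                "strand": "+" if rng.random() < 0.5 else "-",
                "ploidy": "diploid" if rng.random() < diploid_fraction else "haploid",
            }
        )
    return pd.DataFrame(rows)


def _mutate_sequence(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0:
        return seq
    out = list(seq)
    alphabet = "ACGT"
    for i, base in enumerate(out):
        if rng.random() < error_rate:
            choices = [b for b in alphabet if b != base]
            out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def generate_breakpoint_evidence(
    insertions: pd.DataFrame,
    ltr_library: dict[str, str],
    error_rate: float = 0.0,
    decoy_rate: float = 0.0,
    seed: int = 0,
    min_len: int = 30,
    max_len: int = 60,
) -> pd.DataFrame:
    """Emit split-read style breakpoint evidence for planted insertions.

    Each true insertion yields a record whose unaligned junction sequence is a
    >=25 bp substring of the correct family's LTR (reverse-complemented for
    minus-strand insertions) with per-base substitution errors at
    ``error_rate``, and a mapped-perfectly fraction below the retention
    threshold for the clone's ploidy (0.15 haploid / 0.70 diploid).  Decoys —
    a ``decoy_rate`` fraction added on top — carry either random junction
    sequence or an above-threshold mapped-perfectly fraction, and are labelled
    ``should_retain = False``.

    Truth columns (``true_family``, ``true_strand``, ``is_decoy``,
    ``should_retain``) ride along for validation.
    """
    if not ltr_library:
        raise ValueError("LTR library is empty")
    if not 0 <= error_rate <= 0.5:
        raise ValueError("error_rate must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    caps = {"haploid": 0.15, "diploid": 0.70}
    rows = []
    for rec in insertions.itertuples(index=False):
        ltr = ltr_library[rec.family]
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, len(ltr) - length + 1))
        seq = ltr[start : start + length]
        if rec.strand == "-":
            seq = reverse_complement(seq)
        seq = _mutate_sequence(seq, error_rate, rng)
        rows.append(
            {
                "clone_id": rec.clone_id,
                "chromosome": rec.chromosome,
                "position": rec.position,
                "unaligned_sequence": seq,
                "mapped_perfectly_fraction": float(rng.uniform(0, caps[rec.ploidy])),
                "ploidy": rec.ploidy,
                "true_family": rec.family,
                "true_strand": rec.strand,
                "is_decoy": False,
                "should_retain": True,
            }
        )
    n_decoys = int(round(decoy_rate * len(insertions)))
    bases = np.array(list("ACGT"))
    fams = list(ltr_library)
    for j in range(n_decoys):
        ploidy = "diploid" if rng.random() < 0.2 else "haploid"
        cap = caps[ploidy]
        if rng.random() < 0.5:
            # random-sequence decoy: passes the mapping filter, fails LTR match
            seq = "".join(rng.choice(bases, size=int(rng.integers(min_len, max_len + 1))))
            mapped = float(rng.uniform(0, cap))
        else:
            # above-threshold decoy: real LTR substring, fails the mapping filter
            fam = str(rng.choice(fams))
            ltr = ltr_library[fam]
            length = int(rng.integers(min_len, max_len + 1))
            start = int(rng.integers(0, len(ltr) - length + 1))
            seq = ltr[start : start + length]
            mapped = float(rng.uniform(cap + 0.01, 1.0))
        rows.append(
            {
                "clone_id": f"decoy_{j:04d}",
                "chromosome": "chrI",
                "position": int(rng.integers(1_000, 1_000_000)),
                "unaligned_sequence": seq,
                "mapped_perfectly_fraction": mapped,
                "ploidy": ploidy,
                "true_family": None,
                "true_strand": None,
                "is_decoy": True,
                "should_retain": False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fluctuation assay


def simulate_fluctuation_assay(
    per_division_rate: float,
    n_cultures: int = 16,
    final_population: int = 10_000_000,
    inoculum: int = 1_000,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a Luria-Delbruck fluctuation test.

    Each culture doubles from ``inoculum`` towards ``final_population``.  At
    generation k, mutation events arise Poisson(rate x newly divided cells);
    a mutant arising at generation k leaves ``2**(G-k)`` descendants,
    producing the heavy-tailed "jackpot" distribution of colony counts.
    When the final population is not an exact power of 2 times the inoculum,
    the last generation is partial (its new cells make up the remainder and
    leave single descendants); the total number of cell divisions is exactly
    ``final_population - inoculum`` either way, so the zero-mutant fraction
    follows exp(-rate * (final_population - inoculum)).  Returns one mutant
    count per culture.
    """
    if not 0 <= per_division_rate <= 1:
        raise ValueError("per_division_rate must be in [0, 1]")
    if final_population <= inoculum or inoculum < 1:
        raise ValueError("need final_population > inoculum >= 1")
    G = int(np.ceil(np.log2(final_population / inoculum)))
    rng = np.random.default_rng(seed)
    # new cells at generation k (1-based): inoculum * 2**(k-1), last partial
    new_cells = inoculum * (2.0 ** np.arange(G))
    new_cells[-1] = final_population - inoculum - new_cells[:-1].sum()
    descendants = 2.0 ** (G - np.arange(1, G + 1))
    events = rng.poisson(per_division_rate * new_cells, size=(n_cultures, G))
    return (events * descendants).sum(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# TSV / JSON plumbing

COUNT_COLUMNS = ["barcode", "replicate", "timepoint", "count"]


def write_count_table(counts: pd.DataFrame, path: str | Path) -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} missing columns: {sorted(missing)}")
    return df


def write_truth(lineages: list[TrueLineage], tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write ground-truth lineage labels as TSV, with a JSON sidecar carrying
    the per-lineage mutation records."""
    df = pd.DataFrame(
        {
            "barcode": [ln.barcode for ln in lineages],
            "clone_id": [ln.clone_id for ln in lineages],
            "true_s": [ln.true_s for ln in lineages],
            "ploidy": [ln.ploidy for ln in lineages],
            "is_neutral_reference": [ln.is_neutral_reference for ln in lineages],
        }
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {ln.clone_id: ln.mutations for ln in lineages if ln.mutations}
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
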