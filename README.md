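# serialevo

Analysis toolkit for barcoded serial-transfer evolution experiments in
budding yeast: simulation of pooled competitive fitness remeasurements,
selection-coefficient inference from barcode count trajectories,
classification of condition-specific adaptive loci, curation of LTR
retrotransposon (Ty) insertions from breakpoint evidence, detection of
microhomology-mediated mutations, and mutation-spectrum statistics.

## Who it is for

Experimental-evolution groups that track lineages with DNA barcodes
(BarSeq): a pool of barcoded clones plus a set of confirmed-neutral
reference barcodes is diluted into an excess of unbarcoded ancestor and
passaged through repeated growth/bottleneck cycles, with the barcode locus
amplicon-sequenced at each transfer.  The package turns those count tables
— and the mutation/breakpoint call tables produced by whole-genome
sequencing of isolated clones — into per-lineage fitness estimates,
adaptive-locus calls, curated Ty insertions and spectrum tables, with a
seeded synthetic-data generator that produces every input format with
ground-truth labels attached.

## The model

A lineage *i* with Malthusian selection coefficient *s<sub>i</sub>* (per
generation) changes log-frequency linearly relative to neutral lineages.
With *f<sub>i</sub>(t)* the barcode frequency at transfer *t*,
*F<sub>N</sub>(t)* the summed frequency of the neutral reference set,
*g* generations per transfer and *T* transfer intervals, the estimator is
the mean per-interval log-ratio slope:

    s_i = (1 / (T g)) * sum_t [ ln(f_i(t+1)/f_i(t)) - ln(F_N(t+1)/F_N(t)) ]

Effects above 0.01 per generation are flagged detectable (about twice the
standard deviation between technical replicates for this assay design).
A locus is called **nitrogen adaptive** when it is (1) recurrently mutated
in independent lineages (distinct barcodes), (2) validated to a fitness
effect > 0.01/generation in nitrogen limitation, and (3) substantially more
fit in nitrogen than in glucose limitation (absolute gap ≥ 0.02/generation
or ≥ 2× ratio).

Ty insertions are curated from split-read breakpoints: junction sequence is
matched to family LTR references (Ty1–Ty5) by local alignment on both
strands (identity ≥ 0.80 over ≥ 25 aligned bp), after a ploidy-dependent
retention filter (≤ 15 % of reads mapped perfectly for haploids, ≤ 70 % for
diploids).  Microhomology-mediated deletions/duplications are classified
from the exact repeat shared by the two junction suffixes, and gene
conversions by scanning donor paralogs for the replaced tract.

## Worked example

```bash
python examples/01_simulate_and_fit.py
```

```
lineages estimated : 348
median |s_hat - s| : 0.00069  (per generation)
detectable (>0.01) : 245
```

300 test lineages with true effects 0.00–0.08/generation, competed through
four transfers in triplicate at 5×10⁵ reads per timepoint, are recovered
with a median absolute error of ~7×10⁻⁴ — far below the 0.01 detection
threshold.  The other examples cover adaptive-locus classification
(`02`), Ty curation (`03`, 100 % family/strand accuracy at 2 % junction
error with all decoys rejected), microhomology events (`04`), the spectrum
tables and tests (`05` — the six recurrently mutated nitrogen-adaptive loci
carry 193 independent alleles, 73 of them at *GAT1*; Ty1 contributes 92 %
of de novo insertions under nitrogen limitation vs 87 % under glucose), and
the fluctuation assay (`06`).

A thin CLI mirrors the stages (`serialevo simulate | fit | classify |
tycall | mhscan | stats | run-all`); `run-all --config run.json --seed N`
executes the configured stages end to end with byte-identical outputs for
identical config + seed.

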