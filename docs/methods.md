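# Methods

## Serial-transfer competition model

The simulator (`serialevo.popsim`) models a pooled competitive fitness
remeasurement.  The pool holds `n_neutral_barcodes` confirmed-neutral
reference clones (default 48) and `n_test_barcodes` test clones (default
345), mixed into unbarcoded ancestor so that barcoded cells are a fraction
`1 - unbarcoded_fraction` of the culture (default 10 %); the dilution keeps
the population mean fitness nearly constant over the assay, which is why
fitness is referenced against the neutral set rather than the population
mean.  Timepoint 0 is taken right after mixing; the pool is then passaged
through `n_transfers` growth/bottleneck cycles (default 4) in
`n_replicates` (default 3).

Growth within a cycle is deterministic exponential: a lineage with
Malthusian per-generation coefficient *s* multiplies its abundance by
`exp(s*g)` relative to neutral, where `g = generations_per_transfer`.
Stochasticity enters only at the bottleneck (one multinomial draw of
`bottleneck_size` cells over lineage frequencies) and at read sampling (one
multinomial draw of `read_depth` reads over barcoded lineages only — the
ancestor's barcode locus is not amplifiable, so it is invisible to
sequencing).  This standard approximation keeps a closed-form oracle:
with sampling disabled, `ln(f_i(t)/f_N(t))` is exactly linear in *t* with
slope `s_i * g`.

Parameter defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| `generations_per_transfer` | 8.0 | a 400 µL → 100 mL transfer is a 1:250 dilution; log₂(250) ≈ 7.97 doublings back to saturation, rounded to 8; configurable because the true value is regime-dependent |
| `bottleneck_size` | 8×10⁶ cells | ~400 µL of saturated culture at ~2×10⁷ cells/mL |
| `read_depth` | 5×10⁵ reads/timepoint | typical BarSeq depth for a ~400-barcode pool (~10³ reads per barcode) |
| test-pool effect grid | 0.00–0.08 in 0.01 steps | the range of validated per-generation effects at the recurrently mutated loci; 0.01 is the assay detection floor |

Seeding: one master seed; per-replicate and per-operation generators are
derived by drawing 31-bit child seeds from the master stream, so identical
`SimConfig` + seed gives bit-identical outputs.

The evolution mode of `simulate_serial_transfer` spawns de novo mutant
sub-lineages per lineage per cycle at configured class rates; mutants keep
the parental barcode (barcodes pre-date the mutations) and are
distinguished in the ground truth by clone id, starting from one cell's
worth of frequency.  The planted-cohort generator
(`simulate_evolved_cohort`) is the front used for classifier validation:
it assigns adaptive mutations at named loci to disjoint lineages with
uniform effects (default 0.03–0.08/generation, nitrogen-specific) and adds
Poisson-distributed neutral passenger point mutations (mean 0.3 per clone)
over a genome-wide pool of 6 000 gene names.  The passenger load reflects
the low point-mutation count (0–5 SNPs/indels, including drivers) observed
in clones isolated after ~200 generations.

What the generator does **not** emulate: PCR chimeras and barcode hopping,
read-level errors (no FASTQ), clonal interference between barcoded lineages
and the ancestor (the ancestor is fixed at *s* = 0), chemostat dynamics,
and epistasis.  Passing tests therefore demonstrate correctness of the
estimators under multinomial sampling noise, not robustness to library
artefacts.

## Fitness estimation

`fitness_inference` uses the mean per-interval log-ratio against the summed
neutral frequency — not a regression or Bayesian fit — because it is exactly
unbiased on noise-free trajectories (recovery to 1e-9 is a test invariant)
and transparent to audit.  Frequencies are pseudocounted (default 0.5
reads) before logs; a transfer interval whose raw counts are zero at both
endpoints carries no information and is given zero weight; a lineage with
no informative interval is flagged not-estimable rather than guessed.
Replicates are aggregated by mean and sample standard deviation (ddof 1);
`detectable` applies `s_mean > 0.01` (configurable), and twice the
replicate sd is reported as the empirical detection floor.

## Adaptive-locus classification

`adaptive_classifier` implements the three-criterion rule.  Numeric
operationalizations the source design left open:

* **"Substantially greater" in nitrogen than glucose** — disjunction of an
  absolute gap (≥ 0.02/generation) and a ratio (≥ 2× the glucose median,
  floored at 0); both configurable.
* **Per-locus fitness summary** — the *lower median* (lower middle order
  statistic for even counts) of the carrying lineages' mean coefficients.
  For odd counts this is the ordinary median; for a pair it takes the lower
  value, so a neutral-background hitchhiker paired with one adaptive
  carrier cannot average past the threshold.  A genuinely adaptive pair
  (both carriers fit) still qualifies.
* **Reproducibility** — the lower-median nitrogen estimate exceeds the
  threshold and at least half of the carrying lineages have replicate sd
  smaller than their mean (sign-consistency).
* **Recurrence** — ≥ 2 distinct barcodes, the minimum at which loci with
  two independent hits qualify.
* Diploids whose fitness sits within ±0.005 of the autodiploidization
  effect (0.03/generation) and that carry no called mutation are reported
  as autodiploid-only and excluded from the adaptive denominator in the
  cohort accounting.

Label assignment is exclusive: nitrogen_adaptive, else shared_adaptive
(recurrent, fit above threshold in both conditions, no condition gap), else
inconclusive (recurrent without reproducible fitness), else neutral.

## Ty insertion curation

Junction sequences are matched to one consensus LTR per family by local
alignment (match +1, mismatch −2, gap open −5, extend −2) on both strands;
a hit requires identity ≥ 0.80 over ≥ 25 aligned columns, ties broken by
score, identity, then fixed family order Ty1 < … < Ty5.  The thresholds are
validated against a synthetic null: uniform-random 60-mers match in < 1 %
of draws.  The bundled synthetic LTR library uses independent random
consensus sequences (~25 % pairwise identity); real Ty1/Ty2 LTRs are more
similar, so family assignment between those two is easier here than on real
libraries — a documented optimism of the synthetic validation.

The breakpoint retention filter keeps haploid records with ≤ 15 % of reads
mapped perfectly and diploid records with ≤ 70 % (a heterozygous insertion
leaves about half the reads mapping cleanly).  Context annotation uses
1-based fully closed GFF3 coordinates: ORF when the junction falls in a
gene span, 5′/3′ when within a 500 bp strand-aware window (window size is a
convention of this package), else intergenic.  tRNA distance is signed:
negative when the insertion lies upstream of the nearest downstream tRNA's
transcription start on the tRNA's strand.  Orientation bias at a locus is
an exact two-sided binomial test against 0.5 (summing outcomes no more
probable than the observed one).  There is no algorithmic equivalent of
visual curation in a genome browser; retention is purely threshold-based.

## Microhomology-mediated events

Junction homology is the maximal exact shared prefix of the two suffixes at
the breakpoints (no mismatches inside the homology) — equivalent to an
exhaustive scan, which the tests run against 1 000 random instances.  When
several breakpoint placements explain the same allele, the leftmost is
reported with the ambiguity width.  Deletions (MHMD) require flanking
homology ≥ 3 bp (default); insertions (MHMI) must tandem-duplicate the
adjacent reference segment, with junction homology measured on the observed
sequence so that duplication/deletion role-swap symmetry holds exactly.
Every classified event regenerates the observed allele when applied to the
reference.  Frameshift status is the length change mod 3 at coding loci.

Gene conversions (MHMGC) are found by delimiting the replaced tract via the
maximal shared prefix/suffix between observed and reference, then locally
aligning it (match +1, mismatch −1, gap open −4, extend −1) against each
donor; the winner needs identity ≥ 0.90 over ≥ 20 aligned columns.  The
reported identity compares the observed tract to the donor (1.0 for a clean
conversion); donor-to-reference divergence is what makes the tract
detectable in the first place.  Exact junction homologies between the
retained reference flanks and the donor sequence flanking the matched tract
are reported per boundary.

## Spectrum statistics

Variant calls are frequency-filtered at ≥ 85 % (haploid) / ≥ 35 %
(diploid, admitting heterozygotes).  Spectrum tables count events
de-duplicated by (clone, locus, class, position) over the closed
twelve-class taxonomy.  Chi-square comparisons offer both 2×k contingency
and goodness-of-fit modes (df = k−1, no continuity correction by default;
Yates available); both are provided because published spectrum comparisons
rarely state which construction was used, and reference-genome family
counts are only partially printed — reproducing specific published
chi-square p-values is therefore not a validation target here.  The exact
Wilcoxon rank-sum enumerates all C(n, n₁) rank assignments (midranks for
ties) for combined n ≤ 20, doubling the smaller tail and capping at 1;
larger samples use the normal approximation with tie correction.
Kruskal-Wallis uses the chi-square approximation with tie correction.

## Fluctuation assay

The Luria-Delbrück simulator doubles cultures from the inoculum toward the
final population; mutation events per generation are Poisson in the number
of newly divided cells, and a mutant arising at generation *k* of *G*
leaves 2^(G−k) descendants.  When the final population is not an exact
power of 2 times the inoculum (the canonical ~10³ → 10⁷ design is not),
the last generation is partial so that total divisions equal
`final − inoculum` exactly, preserving the analytic zero-mutant fraction
`exp(−rate × (final − inoculum))` used as the test oracle.  Plating
efficiency is not modelled; counts are total mutants per culture.

## Problem sizes and determinism

The validation suite and the reproduction script use: 300-lineage
remeasurement pools at 5×10⁵ reads (estimator recovery), 20 seeded
planted-cohort runs (classifier recovery), 500 breakpoint records at 2 %
error with 20 % decoys (Ty curation), 1 000 random homology instances and
100 conversion fixtures (microhomology), 200 random 2×2 tables and 160
small rank-sum instances (statistics oracles), and 10 000 cultures
(fluctuation).  These sizes give tight Monte-Carlo bounds while keeping a
full run in seconds.  All randomness flows from explicit seeds; identical
configuration and seed reproduce every output byte-for-byte.

## Known limitations

* The fitness estimator is validated against its own generative model; on
  real data, PCR jackpots and chimeric reads add overdispersion the
  multinomial model understates.
* The classifier cannot distinguish a passenger locus whose every carrier
  also bears a true driver (driver-attribution is out of scope); such loci
  surface as recurrent and fit, exactly as they do in real cohorts, and
  need cohort-level inspection.
* Family assignment against per-element LTR libraries (rather than one
  consensus per family) is supported but untested against real LTR
  sequence divergence.
* The MHMGC scan assumes a single converted tract per allele.
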