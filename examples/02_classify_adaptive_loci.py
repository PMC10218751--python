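"""Classify condition-specific adaptive loci from a planted-truth cohort.

Simulates an evolved cohort in which six loci carry adaptive mutations in
3-6 independent lineages each (nitrogen-specific effects 0.03-0.08 per
generation) plus neutral passenger mutations, remeasures fitness in both the
nitrogen and glucose conditions, and applies the three-criterion rule
(recurrence, validated fitness > 0.01, condition specificity).
"""

import dataclasses

import numpy as np

from serialevo import adaptive_classifier as ac
from serialevo import fitness_inference as fi
from serialevo import popsim

rng = np.random.default_rng(5)
cfg = popsim.SimConfig(n_test_barcodes=300, seed=5)
planted = {"GAT9": 5, "PAR9": 4, "MEPA": 3, "MEPB": 3, "MEPC": 4, "FCY9": 6}
lineages, mutations = popsim.simulate_evolved_cohort(cfg, adaptive_loci=planted, rng=rng)

fitness = {}
for condition in ("nitrogen", "glucose"):
    pool = lineages
    if condition == "glucose":  # planted effects are nitrogen-specific
        pool = [dataclasses.replace(ln, true_s=0.0) for ln in lineages]
    _, traj = popsim.simulate_serial_transfer(cfg, pool, rng=np.random.default_rng(rng.integers(2**31)))
    counts = popsim.sample_barcode_reads(traj, cfg.read_depth, seed=int(rng.integers(2**31)))
    neutral = [ln.barcode for ln in lineages if ln.is_neutral_reference]
    fitness[condition] = fi.infer_fitness(counts, neutral)

summaries = ac.summarize_by_locus(mutations, fitness)
labelled = ac.classify_loci(summaries)
called = labelled[labelled["label"] == "nitrogen_adaptive"]

print(called[["locus", "n_unique_lineages", "median_s_nitrogen", "median_s_glucose"]].round(4))
print(f"\nplanted loci recovered: {set(called['locus']) == set(planted)}")
# Each called locus shows >=2 independent lineages whose nitrogen fitness
# median clears 0.01/generation while the glucose median stays near zero.
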