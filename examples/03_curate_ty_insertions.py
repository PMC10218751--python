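"""Curate Ty insertion calls from split-read breakpoint evidence.

Plants 150 Ty insertions (Ty1-dominated family mix), emits breakpoint
evidence with 2% junction-sequence errors plus 20% decoys, applies the
ploidy-dependent retention filter (<=15% mapped perfectly for haploids,
<=70% for diploids), assigns LTR family and strand by local alignment, and
tests the co-orientation of insertions at one locus.
"""

import numpy as np

from serialevo import popsim, ty_caller

rng = np.random.default_rng(7)
library = popsim.synthetic_ltr_library()
insertions = popsim.plant_ty_insertions(150, rng, diploid_fraction=0.2)
evidence = popsim.generate_breakpoint_evidence(
    insertions, library, error_rate=0.02, decoy_rate=0.2, seed=8
)

calls = ty_caller.call_insertions(evidence, library)
truth = evidence[["clone_id", "true_family", "true_strand", "is_decoy"]]
merged = calls.merge(truth, on="clone_id")

print(f"evidence records   : {len(evidence)} ({evidence['is_decoy'].sum()} decoys)")
print(f"retained calls     : {len(calls)} (decoys retained: {merged['is_decoy'].sum()})")
real = merged[~merged["is_decoy"]]
acc = ((real["family"] == real["true_family"]) & (real["strand"] == real["true_strand"])).mean()
print(f"family+strand acc  : {acc:.3f}")
print("family counts      :", calls["family"].value_counts().to_dict())

n_co, n_anti, p = ty_caller.orientation_bias_test(
    [bool(b) for b in rng.random(12) < 0.5]
)
print(f"orientation test   : {n_co} co / {n_anti} anti, exact binomial p = {p:.3f}")
# p near 1 means no strand bias, consistent with insertions acting by gene
# disruption rather than by enhancer-driven co-oriented activation.
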