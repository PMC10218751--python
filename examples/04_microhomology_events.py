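"""Detect microhomology-mediated deletion, duplication and gene conversion.

Constructs alleles with known junctions: a 37 bp deletion flanked by a 4 bp
repeat, a 9 bp in-frame tandem duplication, and a purine-cytosine-permease-
style gene conversion where an internal tract is replaced by the homologous
tract of a diverged donor paralog.
"""

import numpy as np

from serialevo import mh_detector as mh

# deletion flanked by the repeat TGCA (37 bp removed -> frameshift)
ref = "ATGAAA" + "TGCA" + "G" * 33 + "TGCA" + "CCCTAA"
obs = "ATGAAA" + "TGCA" + "CCCTAA"
ev = mh.classify_event(mh.JunctionAllele("GAT1", ref, obs), min_homology=3)
print(f"deletion   : {ev.event_type}, homology {ev.homology_length} bp "
      f"({ev.homology_sequence}), frameshift={ev.frameshifting}")

# in-frame tandem duplication with 3 bp junction homology
H, M = "CAT", "GGTCCA"
ref2 = "ATTAG" + H + M + H + "CCGTA"
obs2 = "ATTAG" + H + M + H + M + H + "CCGTA"
ev2 = mh.classify_event(mh.JunctionAllele("PAR32", ref2, obs2), min_homology=3)
print(f"duplication: {ev2.event_type}, homology {ev2.homology_length} bp, "
      f"frameshift={ev2.frameshifting}")

# gene conversion: internal 80 bp tract replaced from a diverged donor
rng = np.random.default_rng(3)
bases = list("ACGT")
fcy2 = "".join(rng.choice(bases, size=300))
tract = list(fcy2[100:180])
flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
for i in rng.choice(80, size=6, replace=False):
    tract[i] = flip[tract[i]]
tract = "".join(tract)
fcy22 = "".join(rng.choice(bases, size=30)) + tract + "".join(rng.choice(bases, size=30))
observed = fcy2[:100] + tract + fcy2[180:]
ev3 = mh.scan_conversion_donor(
    mh.JunctionAllele("FCY2", fcy2, observed),
    {"FCY21": "".join(rng.choice(bases, size=140)), "FCY22": fcy22},
)
print(f"conversion : {ev3.event_type}, donor={ev3.donor}, "
      f"identity={ev3.donor_identity:.2f}, tract {len(ev3.segment)} bp")
# The donor scan names which paralog templated the converted tract and the
# identity of the observed segment to that donor.
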