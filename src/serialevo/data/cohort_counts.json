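{
  "description": "Published summary counts from the fluctuating-nitrogen serial-transfer evolution cohort, used as worked-example inputs.",
  "ty_family_counts": {
    "nitrogen": {"Ty1": 828, "Ty2": 68, "Ty3": 2},
    "glucose": {"Ty1": 172, "Ty2": 19, "other": 6}
  },
  "adaptive_lineages": {
    "haploid": {"explained": 178, "adaptive": 224},
    "diploid": {"explained": 15, "adaptive": 29}
  }
}
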