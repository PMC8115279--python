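{
  "description": "Reference schema for hand-labeled morphology tables: expected per-class label counts of the curated training corpus (32 descriptor columns plus a 'class' column).",
  "classes": {
    "network": 236,
    "unbranched": 851,
    "swollen": 458,
    "punctate": 797
  },
  "n_descriptors": 32
}
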