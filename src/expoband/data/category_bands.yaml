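# Exposure-category bands for the log-transformed exposure score.
# Band 1 is the exact no-exposure score; bands 2-4 partition (1.00, 14.01]
# at roughly 34% and 67% of the maximum attainable score.
version: "1.0"
bands:
  - category: 1
    lower: 1.00
    upper: 1.00
    description: No exposure (e.g., office worker)
  - category: 2
    lower: 1.01
    upper: 4.76
    description: Low level of exposure (fully enclosed and highly controlled)
  - category: 3
    lower: 4.77
    upper: 9.38
    description: Medium level of exposure (partially enclosed and well controlled)
  - category: 4
    lower: 9.39
    upper: 14.01
    description: High level of exposure (little enclosed and poorly controlled)
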