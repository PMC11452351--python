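{
  "name": "out_of_africa_three_population",
  "description": "Three-population out-of-Africa model (African / European / East Asian) with an ancestral expansion, an out-of-Africa bottleneck, a Eurasian split and exponential growth in both non-African populations. Times in generations (25-year generations), sizes are diploid Ne, migration rates per generation.",
  "N_A": 7300,
  "N_AF": 12300,
  "N_B": 2100,
  "N_EU0": 1000,
  "r_EU": 0.004,
  "N_AS0": 510,
  "r_AS": 0.0055,
  "T_AF_gen": 8800,
  "T_B_gen": 5600,
  "T_EU_AS_gen": 848,
  "m_AF_B": 0.00025,
  "m_AF_EU": 3e-05,
  "m_AF_AS": 1.9e-05,
  "m_EU_AS": 9.6e-05,
  "sample_diploids": {"YRI": 108, "CEU": 99, "CHB": 103}
}
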