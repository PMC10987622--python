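# 4 x [7.5-min dark + 2-min light] regimen, synthetic experiment
schedule:
  acclimation_min: 30
  n_repeats: 4
  dark_min: 7.5
  light_min: 2
  final_dark_min: 25
synthetic:
  n_assays: 2
  fish_per_group: 12
  fish_sd: 0.0
  assay_sd: 0.05
  genotypes:
    - {label: WT}
    - {label: HT}
    - {label: HM, surge_scale: {120: 0.1, 450: 1.0}}
model:
  k: 40
  restarts: 2
posthoc:
  factor: genotype
  pairs: [[WT, HM]]
  phase: dark
  periods: [3, 4, 5]
alpha: 0.05
seed: 1
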