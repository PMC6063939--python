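# Demo study: 2000 samples x 2000 variants, three default EHR channels.
# Runs end-to-end in a couple of minutes on one CPU:
#   phenoscore run --config configs/demo.yaml --out runs/demo
n_samples: 2000
n_variants: 2000
n_causal: 50
h2_liability: 0.5
prevalence: 0.05
maf_low: 0.05
maf_high: 0.5
missing_rate: 0.02
seed: 1

channels:
  - {name: billing, sensitivity: 0.95, specificity: 0.90}
  - {name: problem_list, sensitivity: 0.60, specificity: 0.995}
  - {name: algorithm, sensitivity: 0.80, specificity: 0.995}

# extra billing occurrences: mean for billed true cases / billed false positives
billing_count_params: [2.0, 0.3]

# pipeline settings
pcs: 2
folds: 5
grid_min: 5.0e-5
grid_max: 0.1
grid_n: 12
maf_min: 0.01
callrate_min: 0.90
hwe_alpha: 1.0e-6
prune_window: 50
prune_step: 5
prune_vif_max: 10.0
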