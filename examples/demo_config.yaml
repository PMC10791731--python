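# Demo pipeline configuration: simulate the five-dose GY study, compute
# phase-wise specific rates, screen replicate outliers, run the batch-level
# PLS nutrient ranking, and compare ecFBA flux states of the 0.125x and 1.0x
# conditions against the 0.5x optimum.
output_dir: gyflux_demo_run
seed: 42
synth:
  doses: [0.125, 0.25, 0.5, 1.0, 2.0]
  n_replicates: 3
  noise_cv: 0.05
  plant_metabolite: glutamate
  plant_sign: -1
  plant_strength: 2.0
  outlier_batch: "GY0.5x#1"
  outlier_scale: 0.5
band_k: 1.0
frac_threshold: 0.5
vip_threshold: 1.00
relaxation: 0.20
flux_floor: 0.0001
fc_threshold: 1.2
dcw_per_cell: 250.0
phase: [6.0, 7.0]
reference_condition: GY0.5x
compare_conditions: [GY0.125x, GY1x]
p_total: 0.05
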