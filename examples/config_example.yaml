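# Full effect-plasmode benchmark from a simulated two-strain base.
# Run with:  plasmodeval run examples/config_example.yaml
mode: effects
out_dir: scratch/effects_run
seed: 3
base_sim:
  n_genes: 2000
  samples:
    - [s1, f1]
    - [s1, f1]
    - [s1, f1]
    - [s1, f1]
    - [s1, f2]
    - [s1, f2]
    - [s1, f2]
    - [s1, f3]
    - [s1, f3]
    - [s1, f3]
    - [s2, f1]
    - [s2, f1]
    - [s2, f1]
    - [s2, f1]
    - [s2, f2]
    - [s2, f2]
    - [s2, f2]
    - [s2, f2]
    - [s2, f3]
    - [s2, f3]
    - [s2, f3]
  mean_log_mu: 2.0
  sd_log_mu: 2.5
  dispersion_a0: 0.1
  dispersion_a1: 3.0
  frac_de: 0.35
  lfc_sd: 2.5
  block_lfc_sd: 0.6
  libsize_sd: 0.3
n_plasmodes: 6
de_fraction: 0.10
scenarios: [DE100, DE20_NONDE80]
measures: [raw, rnr, vsd, rld, pea, plg, spe, poi]
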