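# Bundled synthetic study: 2 stages x 2 replicates over a 2 Mb nuclear
# genome (two 1 Mb chromosomes) plus a 125 kb chloroplast, depth 20x.
seed: 1
outdir: seedmeth_out
group_a: S1
group_b: S2

simulate:
  n_chromosomes: 2
  chromosome_length: 1000000
  chloroplast_length: 125000
  depth_mean: 20
  conversion_error: 0.006
  n_genes: 300
  n_tes: 200
  fraction_intragenic_tes: 0.25
  stages: [S1, S2]
  n_replicates: 2
  n_planted_dmrs: 20
  planted_dmr_width: 300
  planted_dmr_levels: [0.2, 0.7]
  fraction_hyper_tes: 0.25
  te_chh_dmr_levels: [0.05, 0.55]
  expression_coupling: 0.5
  n_up_degs: 50
  n_down_degs: 50
  smallrna_lambda_bg: 0.001
  smallrna_density_ratio: 5.0
  smallrna_frac_24nt: 0.8

params:
  min_depth: 5
  alpha: 1.0e-4
  window: 100
  step: 50
  min_cytosines: 3
  min_diff: 25
  max_q: 0.01
  merge_gap: 50
  flank: 2000
  nbins: 10
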