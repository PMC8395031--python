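# Example run configuration for `dwirad run-all --config examples/phantom_run.yaml
# --seed 1 --out runs/demo`.
#
# Any omitted key keeps its library default; the full schema is the
# RunConfig / PhantomConfig / SelectionConfig / BankConfig dataclasses.
mode: phantom
n_icc: 20              # two-reader ICC subsample (0 disables the stage)
icc_perturb_px: 1.0
n_bootstrap: 500
make_plots: true

phantom:
  n_cases: 112
  positive_fraction: 0.43498       # 97/223
  train_fraction: 0.75
  texture_effect: 1.0              # 0 = null cohort, larger = stronger signal
  noise_sigma: 10.0
  b800_contrast: 150.0

selection:
  wilcoxon_alpha: 0.1
  mrmr_k: 20

bank:
  # drop "gabor" for a much faster run; the full bank is the default
  categories: [shape, firstorder, glcm, laws, gabor]
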