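# Bundled synthetic study: simulate cell maps with heterogeneous tumor-stroma
# mixing, extract image features, fit and validate the TKI-benefit model, and
# run the image-genomic enrichment stage, all from one seed.
seed: 20240915
out_dir: out/synthetic_study
stages:
  simulate: true
  features: true
  fit: true
  predict: true
  evaluate: true
  gsea: true
simulate:
  n_patients: 80
  theta: [0.0, 1.0]
  treat_fraction: 0.5
gsea:
  n_permutations: 1000
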