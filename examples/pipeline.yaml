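# Full synthetic study: simulate -> deconvolve -> aggregate -> cluster -> associate
# Run with: immunodecon run --config examples/pipeline.yaml --out-dir run --seed 0
seed: 0
n_permutations: 50
alpha: 0.05
harmonize: false
k: null          # null -> elbow selection over k_range
k_range: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
n_restarts: 10
tau: 0.02
association_tests: [grade, stage, tumor_status]
focal_family: CD8 T cells
generator:
  n_genes: 200
  n_samples: 500
  noise_sigma: 0.1
  seed: 0
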