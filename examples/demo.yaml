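# Demo pipeline configuration: synthetic 20-strain x 5-media study,
# 60 molecules in 15 families, 13% library coverage.
out_dir: scratch_demo_run
seed: 42
n_permutations: 100
simulate:
  n_strains: 20
  n_molecules: 60
  n_families: 15
  library_fraction: 0.13
  seed: 42
# Uncomment to analyse real files instead of simulating:
# input:
#   spectra_dir: path/to/mgf_dir
#   metadata: path/to/metadata.tsv
#   library: path/to/library.mgf
params:
  min_cosine: 0.7
  min_matched_peaks: 6
  top_k: 10
  max_family_size: 100
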