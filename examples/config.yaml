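# Full-pipeline configuration for `oneironet run --config examples/config.yaml`.
# Generate the inputs first, e.g.:
#   oneironet simulate --mode themes --seed 1 -o simdata
#   oneironet simulate --mode survey --seed 1 -o simdata
inputs:
  reports: simdata/reports.tsv
  rules: examples/rules.yaml
  survey: simdata/survey.csv
thresholds:
  min_doc_freq: 5
  min_phi: 0.2
spinglass:
  gamma: 1.0
  spins: 25
  restarts: 10
seed: 1
output_dir: results/run1
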