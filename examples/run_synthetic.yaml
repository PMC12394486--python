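# Full pipeline over a synthetic corpus with one injected association.
synthetic:
  n_reports: 10000
  quarters: ["2021Q1", "2021Q2", "2021Q3", "2021Q4"]
  seed: 1
  injected:
    - ["PEMBROLIZUMAB", "Endometrial cancer", "Immune-mediated hypothyroidism", 5.0]
cohort:
  drug_name_patterns: ["PEMBROLIZUMAB", "KEYTRUDA"]
  role_codes: ["PS"]
  date_window: ["2021Q1", "2021Q4"]
  sensitivity_window: ["2021Q3", "2021Q4"]
ic_dialect: log2-transform
rank_k: 30
quantile_method: linear
output_dir: results/example
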