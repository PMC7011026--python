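# Scenario manifest: each scenario is built by reading the listed parameter
# files in order; later files override earlier rows with the same name.
patient:
  weight_kg: 58.1
  bsa_m2: 1.59
scenarios:
  base_case:
    - parameters_base_case.csv
  no_wastage:
    - parameters_base_case.csv
    - parameters_no_wastage.csv
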