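# Drug catalog: dosing rules and vial/tablet prices (2018 USD).
# dosing_basis: per_kg (mg/kg), per_m2 (mg/m2), flat (mg per administration),
#   oral_daily_per_m2 (mg/m2/day), oral_daily_flat (mg/day).
drugs:
  docetaxel:
    dosing_basis: per_m2
    dose_amount: 75.0
    vials:
      - {strength: 20.0, price: 132.68}   # 40 mg/ml, 0.5 ml
      - {strength: 80.0, price: 500.50}   # 40 mg/ml, 2 ml
  trastuzumab:
    dosing_basis: per_kg
    dose_amount: 6.0
    loading_amount: 8.0
    vials:
      - {strength: 440.0, price: 1852.07}
  pertuzumab:
    dosing_basis: flat
    dose_amount: 420.0
    loading_amount: 840.0
    vials:
      - {strength: 420.0, price: 2282.21}
  pegfilgrastim:
    dosing_basis: flat
    dose_amount: 6.0
    vials:
      - {strength: 6.0, price: 662.68}
  tdm1:
    dosing_basis: per_kg
    dose_amount: 3.6
    vials:
      # catalog lists the small vial as 10 mg; corrected to 100 mg, the
      # strength required by both printed per-administration totals
      - {strength: 100.0, price: 1794.71}
      - {strength: 160.0, price: 2871.77}
  capecitabine:
    dosing_basis: oral_daily_per_m2
    dose_amount: 2000.0
    tablet: {strength: 500.0, price: 3.23}
  lapatinib:
    dosing_basis: oral_daily_flat
    dose_amount: 1500.0
    tablet: {strength: 1500.0, price: 97.74}
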