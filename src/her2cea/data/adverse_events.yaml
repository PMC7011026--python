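# Grade >=3 adverse-event management.  unit_costs are one-time per-event
# management costs (2018 USD).  Profile incidences are trial proportions
# back-derived as per_patient_cost / unit_cost (provenance: derived); the
# per-patient cost cells are the canonical values.
unit_costs:
  diarrhea: 3586.31
  neutropenia: 6904.98
  febrile_neutropenia: 22481.34
  thrombocytopenia: 18199.18
  hand_foot_syndrome: 2034.03
  rash: 321.16
  nausea_vomiting: 6958.51
  fatigue: 1017.01
  dyspnea: 4720.63
  cardiovascular_disorder: 2410.24
profiles:
  pth:
    total: 6628.78
    components:
      - {event: diarrhea, incidence: 0.09, per_patient_cost: 322.76}
      - {event: neutropenia, incidence: 0.49, per_patient_cost: 3383.44}
      - {event: febrile_neutropenia, incidence: 0.13, per_patient_cost: 2922.58}
  th:
    total: 4749.98
    components:
      - {event: neutropenia, incidence: 0.46, per_patient_cost: 3176.29}
      - {event: febrile_neutropenia, incidence: 0.07, per_patient_cost: 1573.69}
  tdm1:
    total: 2347.69
    components:
      - {event: thrombocytopenia, incidence: 0.129, per_patient_cost: 2347.69}
  lap_cap:
    total: 601.43
    components:
      - {event: diarrhea, incidence: 0.128, per_patient_cost: 459.05}
      - {event: hand_foot_syndrome, incidence: 0.07, per_patient_cost: 142.38}
  tras_lap:
    total: 321.70
    components:
      - {event: diarrhea, incidence: 0.07, per_patient_cost: 251.05}
      - {event: rash, incidence: 0.22, per_patient_cost: 70.65}
  tras_cap:
    total: 976.68
    components:
      - {event: diarrhea, incidence: 0.0533, per_patient_cost: 191.15}
      - {event: hand_foot_syndrome, incidence: 0.3247, per_patient_cost: 660.44}
      - {event: cardiovascular_disorder, incidence: 0.0519, per_patient_cost: 125.09}
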