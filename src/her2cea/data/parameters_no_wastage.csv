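name,baseline,low,high,sd,dist,schedule,units,assumption,provenance,note
trastuzumab_loading,1955.79,977.89,2933.68,488.9465,gamma,week 1 only,USD,rule50,published,8 mg/kg loading dose; fractional-vial charging
trastuzumab_maintenance,1466.84,733.42,2200.26,366.7099,gamma,every 3 weeks from week 4,USD,rule50,published,6 mg/kg maintenance dose; fractional-vial charging
docetaxel,760.88,380.44,1141.33,190.2211,gamma,every 3 weeks for 6 cycles,USD,rule50,published,75 mg/m2; fractional-vial charging
tdm1,3754.05,1877.02,5631.07,938.5124,gamma,every 3 weeks,USD,rule50,published,3.6 mg/kg; fractional-vial charging
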