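name,baseline,low,high,sd,dist,schedule,units,assumption,provenance,note
physician_fee,8.15,6.11,10.19,1.01875,gamma,every 3 weeks,USD,rule25,published,
pertuzumab_loading,4564.42,2282.21,6846.63,1141.105,gamma,week 1 only,USD,rule50,published,840 mg loading dose
pertuzumab_maintenance,2282.21,1141.11,3423.32,570.5525,gamma,every 3 weeks from week 4,USD,rule50,published,420 mg maintenance dose
trastuzumab_loading,3704.14,1852.07,5556.21,926.035,gamma,week 1 only,USD,rule50,published,8 mg/kg loading dose
trastuzumab_maintenance,1852.07,926.04,2778.11,463.0175,gamma,every 3 weeks from week 4,USD,rule50,published,6 mg/kg maintenance dose
docetaxel,765.86,382.93,1148.79,191.465,gamma,every 3 weeks for 6 cycles,USD,rule50,published,75 mg/m2 per administration
pegfilgrastim,662.68,331.34,994.02,165.67,gamma,every 3 weeks for 6 cycles,USD,rule50,published,6 mg per cycle
tdm1,4666.48,2333.24,6999.72,1166.62,gamma,every 3 weeks,USD,rule50,published,3.6 mg/kg per administration
capecitabine_weekly,158.27,79.14,237.41,39.5675,gamma,2 weeks on 1 week rest,USD,rule50,published,2000 mg/m2 daily; 7 tablets/day
lapatinib_weekly,684.18,342.09,1026.27,171.045,gamma,weekly,USD,rule50,published,1500 mg daily
ae_cost_pth,6628.784,3351.325,15468.774,3029.362,gamma,one time,USD,calculated,published,
ae_cost_th,4749.982,2411.924,11520.075,2277.038,gamma,one time,USD,calculated,published,
ae_cost_tdm1,2347.695,1166.942,4626.3412,864.8498,gamma,one time,USD,calculated,published,
ae_cost_lap_cap,601.4326,297.29,1160.6912,215.8503,gamma,one time,USD,calculated,published,per-patient total also printed with upper value 1206.61; sensitivity-bound value used
ae_cost_tras_lap,321.70,158.9764,619.8496,115.2183,gamma,one time,USD,calculated,published,
ae_cost_tras_cap,976.6843,519.1815,1954.2796,358.7745,gamma,one time,USD,calculated,published,
ct_scan,142.8571,107.1429,178.5714,17.85714,gamma,every 9 weeks,USD,rule25,derived,published SD 317.85714 corrected to 17.85714 by the (high-low)/4 rule
blood_work,6.27,4.7025,7.8375,0.78375,gamma,every 3 weeks,USD,rule25,published,complete blood count; the resource-use schedule also lists a 22.98 blood-test total
echocardiogram,119.05,89.2875,148.8125,14.88125,gamma,every 13 weeks,USD,rule25,published,resource-use schedule also lists a 99.52 unit cost; the value carrying SA bounds is used
palliative_care,7185.721,3592.86,10778.581,1796.43,gamma,one time,USD,rule50,published,one-time end-of-life cost at death
u_progression_free,0.785746,0.484478,0.9346889,0.112553,beta,state,utility,calculated,published,progression-free under treatment
u_response,0.061,0.025215,0.0742449,0.012257,beta,additive,utility,calculated,published,additive utility increment for treatment response
u_progressed,0.538,0.195937,0.8475389,0.162901,beta,state,utility,calculated,published,disease progression under treatment
du_progression,-0.248,-0.28854,-0.0871499,0.050348,uniform,one time,utility,calculated,published,SD printed with a minus sign; magnitude stored
du_ae_pth,-0.05553,-0.09841,-0.0156854,0.02068,uniform,one time,utility,calculated,published,SD printed with a minus sign; magnitude stored
du_ae_th,-0.03953,-0.05795,-0.0112224,0.011682,uniform,one time,utility,calculated,published,SD printed with a minus sign; magnitude stored
du_ae_tdm1,-0.00851,-0.01246,-0.0024128,0.002512,uniform,one time,utility,calculated,published,SD printed with a minus sign; magnitude stored
du_ae_lap_cap,-0.01826,-0.03193,-0.00395,0.006996,uniform,one time,utility,calculated,published,SD printed with a minus sign; magnitude stored
du_ae_tras_lap,-0.01716,-0.02629,-0.00425,0.005509,uniform,one time,utility,calculated,published,SD printed with a minus sign; magnitude stored
du_ae_tras_cap,-0.04017,-0.0747,-0.0092301,0.016367,uniform,one time,utility,calculated,published,listed negative beta/uniform; sampled uniform by default
os_shape_pth,0.543696,0.460437,0.6420112,0.09264,gamma,curve,dimensionless,regression,published,
os_shape_th,0.576501,0.501151,0.6631802,0.082668,gamma,curve,dimensionless,regression,published,
os_shape_tdm1,0.474333,0.414168,0.5432391,0.065853,gamma,curve,dimensionless,regression,published,
os_shape_lap_cap,0.464784,0.356733,0.605561,0.126953,gamma,curve,dimensionless,regression,published,
os_shape_tras_lap,0.588267,0.467906,0.7395881,0.138613,gamma,curve,dimensionless,regression,published,
os_shape_tras_cap,0.451302,0.33817,0.6022825,0.134751,gamma,curve,dimensionless,regression,published,
os_scale_pth,0.019241,0.016447,0.0225107,0.003094,gamma,curve,per week,regression,published,
os_scale_th,0.024996,0.021942,0.028476,0.003334,gamma,curve,per week,regression,published,
os_scale_tdm1,0.032557,0.029043,0.0364946,0.003802,gamma,curve,per week,regression,published,
os_scale_lap_cap,0.015981,0.0126,0.0202686,0.003912,gamma,curve,per week,regression,published,
os_scale_tras_lap,0.018985,0.015258,0.0236232,0.004268,gamma,curve,per week,regression,published,
os_scale_tras_cap,0.040966,0.032984,0.0508812,0.009131,gamma,curve,per week,regression,published,
pfs_shape_pth,0.621872,0.560543,0.6899112,0.066004,gamma,curve,dimensionless,regression,published,
pfs_shape_th,0.555381,0.504406,0.6115074,0.054643,gamma,curve,dimensionless,regression,published,
pfs_shape_tdm1,0.610611,0.55205,0.6753828,0.062925,gamma,curve,dimensionless,regression,published,
pfs_shape_lap_cap,0.516163,0.422877,0.6300273,0.105689,gamma,curve,dimensionless,regression,published,
pfs_shape_tras_lap,0.553842,0.480821,0.637952,0.080169,gamma,curve,dimensionless,regression,published,
pfs_shape_tras_cap,0.508397,0.410262,0.6300055,0.112114,gamma,curve,dimensionless,regression,published,
pfs_scale_pth,0.052051,0.046527,0.0582304,0.005971,gamma,curve,per week,regression,published,
pfs_scale_th,0.074128,0.067234,0.081729,0.007396,gamma,curve,per week,regression,published,
pfs_scale_tdm1,0.104256,0.093296,0.116504,0.011841,gamma,curve,per week,regression,published,
pfs_scale_lap_cap,0.03389,0.027966,0.0410695,0.006685,gamma,curve,per week,regression,published,
pfs_scale_tras_lap,0.082315,0.069929,0.0968932,0.013757,gamma,curve,per week,regression,published,
pfs_scale_tras_cap,0.115186,0.093703,0.1415951,0.024435,gamma,curve,per week,regression,published,
ae_weekly_prob_pth,0.002564,0.001282,0.0038466,0.000641,beta,weekly,probability,calculated,published,
ae_weekly_prob_th,0.001969,0.000984,0.0029528,0.000492,beta,weekly,probability,calculated,published,
ae_weekly_prob_tdm1,0.004039,0.00202,0.0060591,0.00101,beta,weekly,probability,calculated,published,
ae_weekly_prob_lap_cap,0.0105,0.00525,0.0157506,0.002625,beta,weekly,probability,calculated,published,
ae_weekly_prob_tras_lap,0.001941,0.000971,0.0029122,0.000485,beta,weekly,probability,calculated,published,
ae_weekly_prob_tras_cap,0.005766,0.002883,0.0086493,0.001442,beta,weekly,probability,calculated,published,
discount_weekly,0.000662,0.0,0.000939,,uniform,weekly,rate per week,calculated,published,
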