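import textwrap

import pytest

from her2cea import load_drugs, load_parameters, load_regimens


@pytest.fixture(scope="session")
def base_ps():
    return load_parameters(scenario="base_case")


@pytest.fixture(scope="session")
def nw_ps():
    return load_parameters(scenario="no_wastage")


@pytest.fixture(scope="session")
def drugs():
    return load_drugs()


@pytest.fixture(scope="session")
def regimens():
    return load_regimens()


TOY_PARAMS = """\
name,baseline,low,high,sd,dist,schedule,units,assumption,provenance,note
physician_fee,0,,,,none,every 3 weeks,USD,,config,
blood_work,0,,,,none,every 3 weeks,USD,,config,
ct_scan,0,,,,none,every 9 weeks,USD,,config,
echocardiogram,0,,,,none,every 13 weeks,USD,,config,
trastuzumab_loading,0,,,,none,week 1 only,USD,,config,
trastuzumab_maintenance,0,,,,none,every 3 weeks,USD,,config,
docetaxel,0,,,,none,every 3 weeks,USD,,config,
tdm1,0,,,,none,every 3 weeks,USD,,config,
flat_drug,100.0,50.0,150.0,25.0,gamma,weekly,USD,rule50,config,
palliative_care,0,,,,none,one time,USD,,config,
u_progression_free,1.0,,,,none,state,utility,,config,
u_response,0.0,,,,none,additive,utility,,config,
u_progressed,1.0,,,,none,state,utility,,config,
du_progression,0.0,,,,none,one time,utility,,config,
du_ae_flat,-0.05,,,,none,one time,utility,,config,
ae_cost_flat,100.0,,,,none,one time,USD,,config,
ae_weekly_prob_flat,0.0,,,,none,weekly,probability,,config,
pfs_shape_flat,1.0,,,,none,curve,dimensionless,,config,
pfs_scale_flat,1e-18,,,,none,curve,per week,,config,
os_shape_flat,1.0,,,,none,curve,dimensionless,,config,
os_scale_flat,1e-18,,,,none,curve,per week,,config,
discount_weekly,0.0,0.0,0.001,,none,weekly,rate per week,,config,
"""

TOY_MANIFEST = """\
patient: {weight_kg: 58.1, bsa_m2: 1.59}
scenarios:
  base_case: [toy_params.csv]
"""

TOY_REGIMENS = """\
regimens:
  flat:
    label: toy flat-cost regimen
    her2_targeted: false
    components:
      - param: flat_drug
        weeks: [{start: 1, period: 1}]
"""

TOY_AE = """\
unit_costs: {}
profiles:
  flat:
    total: 0.0
    components: []
"""


@pytest.fixture(scope="session")
def toy_source(tmp_path_factory):
    """A one-regimen data source: constant $100/week drug, negligible
    progression/death hazards, unit utilities, no background costs.
    Closed-form expectations (geometric discount sums, QALY = time alive)
    hold exactly for it."""
    root = tmp_path_factory.mktemp("toy_source")
    (root / "toy_params.csv").write_text(textwrap.dedent(TOY_PARAMS))
    (root / "manifest.yaml").write_text(textwrap.dedent(TOY_MANIFEST))
    (root / "regimens.yaml").write_text(textwrap.dedent(TOY_REGIMENS))
    (root / "adverse_events.yaml").write_text(textwrap.dedent(TOY_AE))
    return root


@pytest.fixture(scope="session")
def toy_ps(toy_source):
    return load_parameters(toy_source, "base_case")
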