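"""Vial costing, weekly streams, adverse-event and background costs."""

import itertools
import math

import numpy as np
import pytest

from her2cea import (
    ae_event_cost,
    background_cost_stream,
    compute_dose,
    vial_cost_fractional,
    vial_cost_wastage,
    weekly_cost_stream,
)
from her2cea.costing import (
    DrugSpec,
    VialOption,
    load_ae_profiles,
    oral_daily_cost,
)
from her2cea.params import PatientProfile, load_yaml


def brute_force_min_cost(dose, vials):
    """Independent oracle: exhaustively enumerate whole-vial multisets."""
    best = math.inf
    uppers = [math.ceil(dose / v.strength) if dose > 0 else 0 for v in vials]
    for counts in itertools.product(*(range(u + 1) for u in uppers)):
        strength = sum(c * v.strength for c, v in zip(counts, vials))
        if strength >= dose:
            best = min(best, sum(c * v.price for c, v in zip(counts, vials)))
    return best


DOC_VIALS = (VialOption(20, 132.68), VialOption(80, 500.50))
TDM1_VIALS = (VialOption(100, 1794.71), VialOption(160, 2871.77))
TRAS_VIALS = (VialOption(440, 1852.07),)


class TestComputeDose:
    def test_per_kg(self, drugs, base_ps):
        assert compute_dose(drugs["tdm1"], base_ps.patient) == pytest.approx(209.16)

    def test_per_m2(self, drugs, base_ps):
        assert compute_dose(drugs["docetaxel"], base_ps.patient) == pytest.approx(119.25)

    def test_flat_with_loading(self, drugs, base_ps):
        pert = drugs["pertuzumab"]
        assert compute_dose(pert, base_ps.patient, "loading") == 840.0
        assert compute_dose(pert, base_ps.patient) == 420.0

    def test_trastuzumab_loading(self, drugs, base_ps):
        assert compute_dose(
            drugs["trastuzumab"], base_ps.patient, "loading"
        ) == pytest.approx(464.8)


class TestVialWastage:
    @pytest.mark.parametrize(
        "dose, vials, combo, cost",
        [
            (119.25, DOC_VIALS, ((20.0, 2), (80.0, 1)), 765.86),
            (209.16, TDM1_VIALS, ((100.0, 1), (160.0, 1)), 4666.48),
            (464.8, TRAS_VIALS, ((440.0, 2),), 3704.14),
            (0.0, DOC_VIALS, (), 0.0),
        ],
    )
    def test_published_combinations(self, dose, vials, combo, cost):
        result = vial_cost_wastage(dose, vials)
        assert result.counts == combo
        assert result.cost == pytest.approx(cost, abs=1e-9)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            vial_cost_wastage(-1.0, DOC_VIALS)

    def test_matches_brute_force_on_random_catalogs(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            k = rng.integers(1, 4)
            vials = [
                VialOption(
                    strength=float(rng.integers(1, 30) * 10),
                    price=float(np.round(rng.uniform(10, 2000), 2)),
                )
                for _ in range(k)
            ]
            dose = float(np.round(rng.uniform(0, 600), 2))
            got = vial_cost_wastage(dose, vials).cost
            want = brute_force_min_cost(dose, vials)
            assert got == pytest.approx(want, abs=1e-9)

    def test_tie_broken_by_fewer_vials(self):
        vials = [VialOption(10, 50.0), VialOption(20, 100.0)]
        result = vial_cost_wastage(20, vials)
        assert result.counts == ((20.0, 1),)


class TestVialFractional:
    def test_tdm1_exact_fraction(self):
        # 1 whole 160 mg + (209.16-160)/100 of a 100 mg vial
        cost = vial_cost_fractional(209.16, TDM1_VIALS)
        assert cost == pytest.approx(2871.77 + 0.4916 * 1794.71, abs=1e-6)
        assert round(cost, 2) == 3754.05

    def test_docetaxel_exact_fraction_reproduces_published_cost(self):
        # wastage combo 80+20+20 with the last 20 mg vial charged pro rata
        cost = vial_cost_fractional(119.25, DOC_VIALS)
        assert round(cost, 2) == 760.88

    def test_trastuzumab_printed_fractions(self):
        assert vial_cost_fractional(
            464.8, TRAS_VIALS, fractions={440: 1.056}
        ) == pytest.approx(1955.79, abs=0.005)
        assert vial_cost_fractional(
            348.6, TRAS_VIALS, fractions={440: 0.792}
        ) == pytest.approx(1466.84, abs=0.005)

    def test_trastuzumab_exact_close_to_printed(self):
        cost = vial_cost_fractional(348.6, TRAS_VIALS)
        assert cost == pytest.approx(348.6 / 440 * 1852.07, abs=1e-9)
        assert abs(cost - 1466.84) < 0.51

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            vial_cost_fractional(100, TRAS_VIALS, fractions={440: -0.5})

    def test_wastage_dominates_fractional(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            vials = [
                VialOption(float(rng.integers(1, 30) * 10),
                           float(rng.uniform(10, 2000)))
                for _ in range(rng.integers(1, 4))
            ]
            dose = float(rng.uniform(0, 500))
            assert (
                vial_cost_wastage(dose, vials).cost
                >= vial_cost_fractional(dose, vials) - 1e-9
            )


class TestOralDosing:
    def test_capecitabine_rounds_up_to_whole_tablets(self, drugs, base_ps):
        # 2000 mg/m2 × 1.59 = 3180 mg -> 7 × 500 mg tablets
        assert oral_daily_cost(drugs["capecitabine"], base_ps.patient) == (
            pytest.approx(7 * 3.23)
        )

    def test_lapatinib_daily(self, drugs, base_ps):
        assert oral_daily_cost(drugs["lapatinib"], base_ps.patient) == 97.74
        assert 7 * 97.74 == pytest.approx(684.18)


# Every published total weekly cost, both scenarios.
PUBLISHED_WEEKLY = [
    ("pth", "base_case", 1, 9697.10),
    ("pth", "base_case", 2, 0.0),
    ("pth", "base_case", 4, 5562.82),
    ("pth", "base_case", 16, 5562.82),
    ("pth", "base_case", 17, 4134.28),
    ("pth", "base_case", 18, 0.0),
    ("pth", "base_case", 29, 4134.28),
    ("th", "base_case", 1, 4470.00),
    ("th", "base_case", 4, 2617.93),
    ("th", "base_case", 16, 2617.93),
    ("th", "base_case", 17, 1852.07),
    ("th", "base_case", 26, 1852.07),
    ("tdm1", "base_case", 1, 4666.48),
    ("tdm1", "base_case", 2, 0.0),
    ("tdm1", "base_case", 4, 4666.48),
    ("lap_cap", "base_case", 1, 842.45),
    ("lap_cap", "base_case", 2, 842.45),
    ("lap_cap", "base_case", 3, 684.18),
    ("lap_cap", "base_case", 4, 842.45),
    ("tras_lap", "base_case", 1, 4388.32),
    ("tras_lap", "base_case", 2, 684.18),
    ("tras_lap", "base_case", 3, 684.18),
    ("tras_lap", "base_case", 4, 2536.25),
    ("tras_lap", "base_case", 5, 684.18),
    ("tras_lap", "base_case", 7, 2536.25),
    ("tras_lap", "base_case", 8, 684.18),
    ("tras_cap", "base_case", 1, 3862.41),
    ("tras_cap", "base_case", 2, 158.27),
    ("tras_cap", "base_case", 3, 3704.14),
    ("tras_cap", "base_case", 4, 2010.34),
    ("tras_cap", "base_case", 5, 158.27),
    ("tras_cap", "base_case", 6, 3704.14),
    ("tras_cap", "base_case", 7, 2010.34),
    ("tras_cap", "base_case", 10, 2010.34),
    ("tras_cap", "base_case", 11, 158.27),
    ("tras_cap", "base_case", 12, 3704.14),
    ("pth", "no_wastage", 1, 7943.77),
    ("pth", "no_wastage", 4, 5172.61),
    ("pth", "no_wastage", 17, 3749.05),
    ("th", "no_wastage", 1, 2716.67),
    ("th", "no_wastage", 4, 2227.72),
    ("th", "no_wastage", 17, 1466.84),
    ("tdm1", "no_wastage", 1, 3754.05),
    ("lap_cap", "no_wastage", 1, 842.45),
    ("tras_lap", "no_wastage", 1, 2639.97),
    ("tras_lap", "no_wastage", 4, 2151.02),
    ("tras_lap", "no_wastage", 7, 2151.02),
    ("tras_cap", "no_wastage", 1, 2114.06),
    ("tras_cap", "no_wastage", 3, 1955.79),
    ("tras_cap", "no_wastage", 4, 1625.11),
    ("tras_cap", "no_wastage", 10, 1625.11),
]


@pytest.mark.parametrize("regimen, scenario, week, expected", PUBLISHED_WEEKLY)
def test_weekly_stream_reproduces_published_totals(
    regimen, scenario, week, expected, base_ps, nw_ps
):
    ps = base_ps if scenario == "base_case" else nw_ps
    stream = weekly_cost_stream(regimen, ps, 30)
    assert stream[week] == pytest.approx(expected, abs=0.005)


def test_stream_is_periodic_after_loading_phase(base_ps):
    stream = weekly_cost_stream("tras_lap", base_ps, 60)
    for w in range(20, 58):
        assert stream[w] == stream[w + 3]


def test_unknown_regimen_errors(base_ps):
    from her2cea.params import ConfigurationError

    with pytest.raises(ConfigurationError, match="nonsense"):
        weekly_cost_stream("nonsense", base_ps, 10)


class TestAdverseEventCosts:
    def test_totals_match_published(self, base_ps):
        profiles = load_ae_profiles(base_ps)
        published = load_yaml("adverse_events.yaml")["profiles"]
        for name, profile in profiles.items():
            total = ae_event_cost(
                (inc, unit) for _, inc, unit in profile.components
            )
            assert total == pytest.approx(published[name]["total"], abs=0.05), name

    def test_components_match_published_cells(self, base_ps):
        profiles = load_ae_profiles(base_ps)
        published = load_yaml("adverse_events.yaml")["profiles"]
        for name, profile in profiles.items():
            cells = {
                c["event"]: c["per_patient_cost"]
                for c in published[name]["components"]
            }
            for event, inc, unit in profile.components:
                assert inc * unit == pytest.approx(cells[event], abs=0.05)

    def test_tdm1_thrombocytopenia(self):
        assert ae_event_cost([(0.129, 18199.18)]) == pytest.approx(2347.69, abs=0.005)

    def test_empty_profile(self):
        assert ae_event_cost([]) == 0.0

    def test_negative_incidence_rejected(self):
        with pytest.raises(ValueError):
            ae_event_cost([(-0.1, 100.0)])

    def test_profile_binds_scenario_parameters(self, base_ps):
        profiles = load_ae_profiles(base_ps)
        assert profiles["pth"].event_cost == base_ps.value("ae_cost_pth")
        assert profiles["pth"].weekly_prob == base_ps.value("ae_weekly_prob_pth")
        assert profiles["pth"].event_disutility < 0


class TestBackgroundStream:
    def test_first_week_charges_every_schedule(self, base_ps):
        stream = background_cost_stream(True, 30, base_ps)
        expected = 8.15 + 6.27 + 142.8571 + 119.05
        assert stream[1] == pytest.approx(expected, abs=1e-6)

    def test_off_weeks_are_zero(self, base_ps):
        stream = background_cost_stream(True, 30, base_ps)
        assert stream[2] == 0.0
        assert stream[3] == 0.0

    def test_no_echo_off_her2(self, base_ps):
        on = background_cost_stream(True, 53, base_ps)
        off = background_cost_stream(False, 53, base_ps)
        echo = base_ps.value("echocardiogram")
        diff = np.asarray(on.costs) - np.asarray(off.costs)
        assert set(np.round(diff[diff > 0], 6)) == {round(echo, 6)}
        # echo recurs on weeks 1, 14, 27, 40, 53 (every 13 weeks)
        assert set(np.nonzero(diff)[0]) == {0, 13, 26, 39, 52}


def test_drug_spec_validation():
    with pytest.raises(ValueError):
        DrugSpec(name="x", dosing_basis="per_pound", dose_amount=1.0,
                 vials=(VialOption(10, 1.0),))
    with pytest.raises(ValueError):
        DrugSpec(name="x", dosing_basis="flat", dose_amount=1.0)
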