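"""EDI, AI percentages, hazard quotients, consumption limits, servings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sehg import calibration
from sehg.config import StudyConfig
from sehg.intake import (
    ai_percent,
    consumption_limits,
    cr_lim,
    cr_mm,
    edi,
    hazard_quotient,
    hq_flagged,
    net_se,
    nutrient_profile_at_ai,
    per_child_exposure,
    population_exposure,
    servings_to_meet_ai,
)

positive = st.floats(min_value=1e-6, max_value=1e4, allow_nan=False)
nonnegative = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


class TestEdi:
    def test_hand_computed_fish_example(self):
        per_bw, total = edi(0.078, 24.2, 13.87)
        assert total == pytest.approx(1.8876)
        assert per_bw == pytest.approx(1.8876 / 13.87)

    def test_zero_intake(self):
        assert edi(0.4, 0.0, 13.87) == (0.0, 0.0)

    def test_units_identity(self):
        per_bw, _ = edi(1.0, 13.87, 13.87)
        assert per_bw == pytest.approx(1.0)

    def test_rejects_nonpositive_bw(self):
        with pytest.raises(ValueError):
            edi(0.4, 10.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(conc=nonnegative, ir=nonnegative, bw=positive)
    def test_dimensional_consistency(self, conc, ir, bw):
        per_bw, total = edi(conc, ir, bw)
        assert per_bw * bw == pytest.approx(total, rel=1e-12, abs=1e-12)


class TestAiPercent:
    @pytest.mark.parametrize(
        "edi_se, expected",
        [(3.24, 16.20), (0.71, 3.55), (20.0, 100.0)],
    )
    def test_published_values(self, edi_se, expected):
        assert ai_percent(edi_se, 20.0) == pytest.approx(expected)

    def test_rejects_nonpositive_ai(self):
        with pytest.raises(ValueError):
            ai_percent(5.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(a=nonnegative, b=nonnegative)
    def test_linearity_with_net(self, a, b):
        """AI% of the net equals the difference of the AI percentages."""
        assert ai_percent(net_se(a, b), 20.0) == pytest.approx(
            ai_percent(a, 20.0) - ai_percent(b, 20.0), rel=1e-9, abs=1e-9
        )


class TestNetSe:
    @pytest.mark.parametrize(
        "se, hg, expected",
        [(17.37, 0.56, 16.81), (4.2, 0.0, 4.2), (0.24, 0.75, -0.51)],
    )
    def test_mass_based_examples(self, se, hg, expected):
        assert net_se(se, hg) == pytest.approx(expected)

    def test_molar_equivalent_mode_rescales_hg(self):
        assert net_se(10.0, 1.0, molar_equivalent=True) == pytest.approx(
            10.0 - 78.971 / 200.59
        )


class TestHazardQuotient:
    def test_boundary_not_flagged(self):
        hq = hazard_quotient(0.23, 0.23)
        assert hq == 1.0 and not hq_flagged(hq)

    def test_fish_example(self):
        assert hazard_quotient(0.1363, 0.23) == pytest.approx(0.593, abs=1e-3)

    def test_zero_exposure(self):
        assert hazard_quotient(0.0, 0.23) == 0.0

    def test_hq_equals_one_at_cr_lim_consumption(self):
        """Eating exactly CR_lim of a food gives HQ = 1 against the EPA RfD."""
        cfg = StudyConfig()
        conc = 0.093
        limit = cr_lim(cfg.rfd_hg_epa, cfg.default_bw, conc)
        per_bw, _ = edi(conc, limit, cfg.default_bw)
        epa_rfd_ug = cfg.rfd_hg_epa * 1000.0  # mg/kg/day → µg/kg-BW/day
        assert hazard_quotient(per_bw, epa_rfd_ug) == pytest.approx(1.0, rel=1e-12)


class TestConsumptionLimits:
    def test_marine_and_freshwater_hg_limits(self):
        assert cr_lim(0.0001, 13.87, 0.093) == pytest.approx(14.91, abs=5e-3)
        assert cr_lim(0.0001, 13.87, 0.044) == pytest.approx(31.52, abs=5e-3)

    def test_zero_rfd_gives_zero_limit(self):
        assert cr_lim(0.0, 13.87, 0.093) == 0.0

    def test_unbounded_when_concentration_zero(self):
        with pytest.raises(ValueError, match="unbounded"):
            cr_lim(0.0001, 13.87, 0.0)

    def test_monthly_fish_meals_match_published_values(self):
        """US EPA 65-g meals: ~7/month marine, 14.8/month freshwater."""
        marine = cr_mm(cr_lim(0.0001, 13.87, 0.093), 30.44, 65.0)
        fresh = cr_mm(cr_lim(0.0001, 13.87, 0.044), 30.44, 65.0)
        assert round(marine) == 7
        assert fresh == pytest.approx(14.8, abs=0.05)

    def test_unit_portion(self):
        assert cr_mm(3.0, 30.0, 90.0) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=200)
    @given(limit=nonnegative, days=st.floats(28.5, 31.5), k=st.floats(0.5, 4.0), portion=positive)
    def test_inverse_linearity_in_portion(self, limit, days, k, portion):
        assert cr_mm(limit, days, k * portion) * k == pytest.approx(
            cr_mm(limit, days, portion), rel=1e-9, abs=1e-12
        )

    @settings(derandomize=True, max_examples=200)
    @given(rfd=positive, bw=positive, k=st.floats(0.5, 4.0), conc=positive)
    def test_cr_lim_inverse_linearity_in_concentration(self, rfd, bw, k, conc):
        assert cr_lim(rfd, bw, k * conc) * k == pytest.approx(cr_lim(rfd, bw, conc), rel=1e-9)

    def test_limits_table_conventions(self, config):
        frame = consumption_limits(
            calibration.reference_exposure_inputs().rename(columns={"hg_conc_equiv": "hg_conc"}),
            config,
        )
        fish_hg = frame[(frame["category"] == "Fish") & (frame["element"] == "Hg")].iloc[0]
        assert not np.isnan(fish_hg["cr_mm_meals"])  # EPA meal convention for fish
        eggs_se = frame[(frame["category"] == "Eggs") & (frame["element"] == "Se")].iloc[0]
        assert np.isnan(eggs_se["cr_mm_meals"])
        assert eggs_se["cr_mm_servings"] == pytest.approx(67.5, abs=0.1)


class TestServings:
    def test_published_fish_servings(self):
        assert servings_to_meet_ai(20, 0.309, 35) == pytest.approx(1.85, abs=5e-3)
        assert servings_to_meet_ai(20, 0.452, 35) == pytest.approx(1.26, abs=5e-3)

    def test_one_egg_after_ceiling(self):
        exact = servings_to_meet_ai(20, 0.521, 60)
        assert exact == pytest.approx(0.64, abs=5e-3)
        assert servings_to_meet_ai(20, 0.521, 60, whole_units=True) == 1.0

    def test_nutrient_scaling(self):
        assert nutrient_profile_at_ai(2.0, {"protein": 7.0}) == {"protein": 14.0}
        assert nutrient_profile_at_ai(0.0, {"DHA": 100.0}) == {"DHA": 0.0}
        assert nutrient_profile_at_ai(1.85, {"DHA": 100.0})["DHA"] == pytest.approx(185.0)
        with pytest.raises(ValueError):
            nutrient_profile_at_ai(1.0, {"DHA": -1.0})


class TestPopulationPipeline:
    def test_reproduces_published_adequacy_table(self, config):
        """Back-solved calibration reproduces every published column to ±0.02 pp."""
        inputs = calibration.reference_exposure_inputs()
        table = population_exposure(
            inputs.rename(columns={"hg_conc_equiv": "hg_conc"}),
            inputs["intake_g_day"].to_dict(),
            config,
        ).set_index("category")
        published_edi = {  # µg/day, gross and net
            "Eggs": (17.37, 16.81),
            "Fish": (9.41, 7.52),
            "Fruits": (0.24, -0.51),
            "Grains and related products": (15.79, 14.27),
            "Leafy vegetables": (0.71, 0.11),
            "Legumes and related products": (3.26, 2.88),
            "Meat and meat products": (12.63, 12.04),
            "Milk and dairy products": (17.99, 15.99),
            "Non-leafy vegetables": (1.86, 1.59),
            "Rice": (1.37, 1.28),
            "Shellfish": (3.24, 3.01),
        }
        for category, (ai_pct, net_pct) in calibration.AI_PERCENT_TARGETS.items():
            row = table.loc[category]
            assert row["ai_pct"] == pytest.approx(ai_pct, abs=0.02)
            assert row["net_ai_pct"] == pytest.approx(net_pct, abs=0.02)
            gross, net = published_edi[category]
            assert row["edi_se_total"] == pytest.approx(gross, abs=0.02)
            assert row["net_se"] == pytest.approx(net, abs=0.02)

    def test_per_child_mode_matches_population_on_degenerate_cohort(self, config):
        """If every child has the mean intake and default BW, per-child EDIs
        aggregate to the population values exactly."""
        import pandas as pd

        inputs = calibration.reference_exposure_inputs()
        conc = inputs.rename(columns={"hg_conc_equiv": "hg_conc"})
        intakes = pd.DataFrame(
            [
                {"child_id": f"c{i}", "category": cat, "intake_rate": inputs.at[cat, "intake_g_day"]}
                for i in range(3)
                for cat in inputs.index
            ]
        )
        per_child = per_child_exposure(conc, intakes, config=config)
        pop = population_exposure(conc, inputs["intake_g_day"].to_dict(), config).set_index("category")
        means = per_child.groupby("category")["ai_pct"].mean()
        for category in inputs.index:
            assert means[category] == pytest.approx(pop.at[category, "ai_pct"], rel=1e-12)
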