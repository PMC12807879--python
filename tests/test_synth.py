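"""Generators: moment matching, determinism, calibration round-trips."""

import numpy as np
import pandas as pd
import pytest

from sehg import calibration
from sehg.growth import fit_growth_model, interpolate_lms, screen_covariates
from sehg.intake import net_ai_wide, per_child_exposure
from sehg.io import children_to_frame, intakes_to_frame
from sehg.risk_benefit import summarize_category, summarize_panel
from sehg.records import CATEGORIES
from sehg.synth import (
    CategoryDistSpec,
    CohortSpec,
    default_food_specs,
    gen_cohort,
    gen_food_panel,
    gen_outcomes,
    lognormal_params_from_moments,
    simulate_study,
)


class TestMomentMatching:
    def test_hair_hg_closed_form(self):
        mu, sigma = lognormal_params_from_moments(1.11, 1.15)
        assert mu == pytest.approx(-0.260, abs=5e-4)
        assert sigma == pytest.approx(0.854, abs=5e-4)

    def test_degenerate_point_mass(self):
        assert lognormal_params_from_moments(3.0, 0.0) == (np.log(3.0), 0.0)

    def test_monte_carlo_round_trip(self):
        """10⁶ draws from the matched params reproduce mean/sd within 1%."""
        mu, sigma = lognormal_params_from_moments(0.408, 0.192)
        draws = np.exp(np.random.default_rng(0).normal(mu, sigma, size=1_000_000))
        assert draws.mean() == pytest.approx(0.408, rel=0.01)
        assert draws.std(ddof=1) == pytest.approx(0.192, rel=0.01)

    def test_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            lognormal_params_from_moments(0.0, 1.0)


class TestFoodPanel:
    def test_default_panel_matches_survey_layout(self):
        panel = gen_food_panel(seed=0)
        assert len(panel) == 108
        by_cat = pd.Series([s.category for s in panel]).value_counts()
        assert by_cat["Fish"] == 13 and by_cat["Meat and meat products"] == 18
        subs = [s.subcategory for s in panel if s.category == "Fish"]
        assert subs.count("Marine fish") == 9 and subs.count("Freshwater fish") == 4

    def test_moment_recovery_at_large_n(self, config):
        """Fish-spec draws at n = 2000 recover the target means within 3%
        and the target SDs within 3 standard errors of the SD estimator."""
        spec = CategoryDistSpec("Fish", 2000, 0.408, 0.192, 0.078, 0.072)
        panel = gen_food_panel([spec], seed=1)
        s = summarize_category(panel, config)
        assert s.se_mass_mean == pytest.approx(0.408, rel=0.03)
        assert s.hg_mass_mean == pytest.approx(0.078, rel=0.03)
        # the SD estimator of a heavy-tailed lognormal is itself noisy:
        # rel. SE(s) ≈ sqrt((kurtosis − 1)/(4n)) from the matched lognormal
        for target_mean, target_sd, got in (
            (0.408, 0.192, s.se_mass_sd),
            (0.078, 0.072, s.hg_mass_sd),
        ):
            _, sigma = lognormal_params_from_moments(target_mean, target_sd)
            e = np.exp(sigma**2)
            kurt = e**4 + 2 * e**3 + 3 * e**2 - 3
            rel_se = np.sqrt((kurt - 1) / (4 * 2000))
            assert got == pytest.approx(target_sd, rel=3 * rel_se)

    def test_single_sample_per_category(self):
        panel = gen_food_panel([CategoryDistSpec("Eggs", 1, 0.5, 0.04, 0.01, 0.004)], seed=2)
        assert len(panel) == 1

    def test_seed_determinism(self):
        a = gen_food_panel(seed=42)
        b = gen_food_panel(seed=42)
        assert a == b
        assert gen_food_panel(seed=43) != a

    def test_log_correlation_hook(self):
        spec = CategoryDistSpec("Fish", 4000, 0.4, 0.2, 0.08, 0.07, log_correlation=0.8)
        panel = gen_food_panel([spec], seed=3)
        se = np.log([s.se_conc for s in panel])
        hg = np.log([s.hg_conc for s in panel])
        assert np.corrcoef(se, hg)[0, 1] == pytest.approx(0.8, abs=0.05)


class TestCohort:
    def test_hair_exceedance_matches_lognormal_tail(self, lms_table):
        """P(hair Hg > 1) under the matched lognormal is ≈ 0.38."""
        spec = CohortSpec(n_children=100_000, intake_means={})
        children, _, _ = gen_cohort(spec, lms_table, seed=5)
        frac = np.mean([c.hair_hg > 1.0 for c in children])
        assert frac == pytest.approx(0.38, abs=0.02)

    def test_zero_latent_z_puts_children_on_the_median(self, lms_table):
        spec = CohortSpec(n_children=20, growth_z_sd=0.0, intake_means={"Fish": 20.0})
        children, _, _ = gen_cohort(spec, lms_table, seed=6)
        for child in children:
            _, M, _ = interpolate_lms(lms_table, child.sex, "weight-for-age", child.age * 12)
            assert child.weight == pytest.approx(M, rel=1e-9)

    def test_age_and_sex_marginals(self, lms_table):
        children, _, _ = gen_cohort(CohortSpec(n_children=20_000, intake_means={}), lms_table, seed=7)
        ages = np.array([c.age for c in children])
        assert ages.mean() == pytest.approx(2.9, abs=0.05)
        assert np.mean([c.sex == "male" for c in children]) == pytest.approx(0.54, abs=0.02)

    def test_byte_identical_outputs_under_fixed_seed(self, tmp_path, lms_table):
        spec = CohortSpec(n_children=30)
        for run in ("a", "b"):
            children, intakes, _ = gen_cohort(spec, lms_table, seed=9)
            children_to_frame(children).to_csv(tmp_path / f"children_{run}.csv", index=False)
            intakes_to_frame(intakes).to_csv(tmp_path / f"intakes_{run}.csv", index=False)
        assert (tmp_path / "children_a.csv").read_bytes() == (tmp_path / "children_b.csv").read_bytes()
        assert (tmp_path / "intakes_a.csv").read_bytes() == (tmp_path / "intakes_b.csv").read_bytes()

    def test_lms_range_guard(self, lms_table):
        spec = CohortSpec(n_children=5, age_max=6.9)
        with pytest.raises(ValueError, match="LMS table"):
            gen_cohort(spec, lms_table.head(10), seed=0)


class TestOutcomes:
    @staticmethod
    def _exposures(children, config, seed=0, categories=("Eggs",)):
        """Net AI% per child for a category subset, from one default panel."""
        means = calibration.reference_intake_means()
        panel = gen_food_panel(seed=0)
        summaries = [
            s for s in summarize_panel(panel, config, include_total=False)
            if s.category in categories
        ]
        rng = np.random.default_rng(seed)
        intakes = pd.DataFrame(
            [
                {
                    "child_id": c.child_id,
                    "category": category,
                    "intake_rate": float(rng.gamma(4.0, means[category] / 4.0)),
                }
                for category in categories
                for c in children
            ]
        )
        exposure = per_child_exposure(summaries, intakes, children, config)
        return net_ai_wide(exposure)

    def test_noiseless_beta_recovered_exactly(self, lms_table, config):
        children, _, _ = gen_cohort(CohortSpec(n_children=60, intake_means={}), lms_table, seed=21)
        wide = self._exposures(children, config, seed=21)
        outcome, truth = gen_outcomes(children, wide, {"Eggs": 0.01}, noise_sd=0.0, seed=1)
        data = pd.DataFrame({"y": outcome, "x": wide["Eggs"].loc[outcome.index]})
        r = fit_growth_model(data, "y", "x")
        assert r.beta == pytest.approx(truth["betas"]["Eggs"], rel=1e-9)

    def test_null_betas_give_nominal_screen_rate(self, lms_table, config):
        """With beta = 0 the exposure passes the p < 0.2 screen ~20% of runs."""
        children, _, _ = gen_cohort(CohortSpec(n_children=150, intake_means={}), lms_table, seed=22)
        hits, reps = 0, 300
        for i in range(reps):
            wide = self._exposures(children, config, seed=100 + i)
            outcome, _ = gen_outcomes(children, wide, {"Eggs": 0.0}, noise_sd=1.0, seed=i)
            data = pd.DataFrame({"y": outcome, "x": wide["Eggs"].loc[outcome.index]})
            hits += bool(screen_covariates(data, "y", ["x"]))
        assert hits / reps == pytest.approx(0.2, abs=0.06)

    def test_mismatched_ids_rejected(self, lms_table, config):
        children, _, _ = gen_cohort(CohortSpec(n_children=10, intake_means={}), lms_table, seed=23)
        wide = pd.DataFrame({"Eggs": np.ones(3)}, index=["zz1", "zz2", "zz3"])
        with pytest.raises(ValueError, match="child ids"):
            gen_outcomes(children, wide, {"Eggs": 0.01}, noise_sd=0.1)


class TestEndToEnd:
    def test_hbv_ordering_of_large_calibrated_panel(self, config):
        """A large panel at the survey calibration ranks foods as published:
        eggs > fish > shellfish > meat, with fruits negative and last."""
        specs = [
            CategoryDistSpec(s.category, 2000, s.se_mean, s.se_sd, s.hg_mean, s.hg_sd, s.subcategory)
            for s in default_food_specs()
        ]
        panel = gen_food_panel(specs, seed=4)
        summaries = {
            s.category: s.hbv_se
            for s in summarize_panel(panel, config, include_total=False)
            if s.category in CATEGORIES
        }
        assert summaries["Eggs"] > summaries["Fish"] > summaries["Shellfish"]
        assert summaries["Shellfish"] > summaries["Meat and meat products"]
        assert summaries["Fruits"] < 0
        assert summaries["Fruits"] == min(summaries.values())

    def test_simulate_study_determinism_and_artifacts(self, tmp_path):
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        simulate_study(n_children=40, seed=17, out_dir=out_a)
        simulate_study(n_children=40, seed=17, out_dir=out_b)
        for name in ("foods.csv", "children.csv", "intakes.csv", "lms.csv", "truth.json"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()
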