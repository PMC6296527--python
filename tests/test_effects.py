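"""Tests for contrasts, geometric-mean summaries and the mixed model."""

import numpy as np
import pandas as pd
import pytest

from cryptscore.effects import (
    ContrastSpec,
    TreatmentEffectModel,
    absolute_effect_from_means,
    build_contrasts,
    confounder_screen,
    effects_table,
    fit_treatment_model,
    geometric_mean_ci,
    load_reference_group_means,
    relative_effect_from_means,
    summary_effects_from_group_means,
)
from cryptscore.simulate import STUDY_ARM_SIZES, TrialSimParams, simulate_trial


class TestContrasts:
    def test_three_specs_returned_without_data(self):
        specs = build_contrasts()
        assert set(specs) == {"vitD_vs_noD", "ca_vs_noCa", "caD_vs_ca"}
        for s in specs.values():
            assert not (s.treated_arms & s.reference_arms)

    def test_calcium_contrast_excludes_two_arm_participants(self):
        s = build_contrasts()["ca_vs_noCa"]
        assert s.excluded_arms == {"Ca2arm", "CaD2arm"}
        treated = sum(STUDY_ARM_SIZES[a] for a in s.treated_arms)
        reference = sum(STUDY_ARM_SIZES[a] for a in s.reference_arms)
        assert (treated, reference) == (33, 29)

    def test_vitamin_d_contrast_counts_match_study(self):
        s = build_contrasts()["vitD_vs_noD"]
        assert sum(STUDY_ARM_SIZES[a] for a in s.treated_arms) == 53
        assert sum(STUDY_ARM_SIZES[a] for a in s.reference_arms) == 51

    def test_overlapping_arm_sets_rejected(self):
        with pytest.raises(ValueError):
            ContrastSpec("bad", frozenset({"Ca"}), frozenset({"Ca", "P"}))


class TestGeometricMean:
    def test_single_value_identity(self):
        n, gm, lo, hi = geometric_mean_ci([7.0])
        assert n == 1 and gm == pytest.approx(7.0)
        assert np.isnan(lo) and np.isnan(hi)

    def test_closed_form_pair(self):
        _, gm, lo, hi = geometric_mean_ci([1.0, 100.0])
        assert gm == pytest.approx(10.0)
        assert lo < gm < hi

    def test_lognormal_convergence(self, rng):
        mu = 2.5
        vals = np.exp(rng.normal(mu, 0.8, 10_000))
        _, gm, lo, hi = geometric_mean_ci(vals)
        assert abs(np.log(gm) - mu) < 3 * 0.8 / np.sqrt(10_000)
        assert lo <= np.exp(mu) <= hi

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_ci([1.0, 0.0])


class TestClosedForms:
    @pytest.mark.parametrize(
        "quad,expected",
        [
            ((1196.0, 1273.0, 1153.0, 1269.0), 0.97),  # proliferation, whole crypt
            ((303.8, 309.3, 302.5, 238.4), 1.29),      # differentiation, upper zone
            ((2.0, 3.0, 4.0, 6.0), 1.0),               # equal proportional change
        ],
    )
    def test_relative_effect(self, quad, expected):
        assert round(relative_effect_from_means(*quad), 2) == expected

    @pytest.mark.parametrize(
        "quad,expected",
        [
            ((603.2, 540.4, 599.4, 495.1), 41.5),
            ((724.8, 701.7, 631.8, 693.6), -84.9),
            ((5.0, 5.0, 9.0, 9.0), 0.0),
        ],
    )
    def test_absolute_effect(self, quad, expected):
        assert round(absolute_effect_from_means(*quad), 1) == expected

    def test_relative_effect_requires_positive_means(self):
        with pytest.raises(ValueError):
            relative_effect_from_means(0.0, 1.0, 1.0, 1.0)


class TestMixedModel:
    def test_interaction_equals_closed_form_on_complete_data(self, effect_trial_df):
        contrast = build_contrasts()["vitD_vs_noD"]
        model = TreatmentEffectModel(effect_trial_df, contrast, "mib1", "whole")
        res = model.fit()
        gm = {(s.group, s.visit): s.geometric_mean for s in model.group_visit_summaries()}
        closed = relative_effect_from_means(
            gm[("treated", "baseline")], gm[("treated", "year1")],
            gm[("reference", "baseline")], gm[("reference", "year1")],
        )
        assert res.relative_effect == pytest.approx(closed, abs=1e-6)

    def test_estimate_near_planted_effect(self, effect_trial_df):
        contrast = build_contrasts()["vitD_vs_noD"]
        est = fit_treatment_model(effect_trial_df, contrast, "mib1", "whole")
        assert est.ci_low < 1.3 * 1.15 and est.ci_high > 1.3 * 0.85
        assert est.ci_low <= est.relative_effect <= est.ci_high

    def test_matches_independent_mixed_model_fit(self, effect_trial_df, tmp_path):
        """Cross-check the interaction estimate against lme4 via Rscript."""
        import shutil, subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        contrast = build_contrasts()["vitD_vs_noD"]
        model = TreatmentEffectModel(effect_trial_df, contrast, "mib1", "whole")
        res = model.fit()
        csv = tmp_path / "d.csv"
        model.data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- lmer(log_value ~ is_follow * is_treated + (1 | participant_id), data = d, REML = TRUE)\n"
            "cat(fixef(m)['is_follow:is_treated'])\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        beta_r = float(out.stdout.strip().split()[-1])
        assert np.log(res.relative_effect) == pytest.approx(beta_r, abs=1e-4)

    def test_empty_stratum_raises_diagnostic(self, null_trial_df):
        spec = ContrastSpec("odd", frozenset({"D"}), frozenset())
        with pytest.raises(ValueError, match="odd"):
            TreatmentEffectModel(null_trial_df, spec, "mib1", "whole")

    def test_analysis_is_by_assigned_arm(self, null_trial_df):
        # relabelling values does not move participants between strata:
        # group sizes come from arm assignment only
        contrast = build_contrasts()["ca_vs_noCa"]
        model = TreatmentEffectModel(null_trial_df, contrast, "mib1", "whole")
        ns = {(s.group, s.visit): s.n for s in model.group_visit_summaries()}
        assert ns[("treated", "baseline")] == 33
        assert ns[("reference", "baseline")] == 29
        assert "Ca2arm" not in set(model.data["arm"])


class TestConfounderScreen:
    def test_null_covariate_not_retained(self, null_trial_df):
        contrast = build_contrasts()["vitD_vs_noD"]
        df = null_trial_df.copy()
        rng = np.random.default_rng(5)
        noise = pd.Series(
            rng.normal(0, 1, df["participant_id"].nunique()),
            index=sorted(df["participant_id"].unique()),
        )
        df["noise_cov"] = df["participant_id"].map(noise)
        retained, log = confounder_screen(
            df, contrast, "mib1", "whole", candidates=["noise_cov"]
        )
        assert retained == []
        assert log.loc[log["covariate"] == "noise_cov", "proportional_change"].iloc[0] < 0.05

    def test_planted_time_varying_confounder_retained(self):
        # a participant-constant covariate cannot move a within-participant
        # difference-in-differences on complete data, so the planted
        # confounder must vary over visits: energy intake rises ~400 kcal
        # in the vitamin-D arms at follow-up while the outcome responds to
        # current energy.  The unadjusted effect soaks up the diet change
        # (~ +20%); adjustment removes it, so the screen must retain energy.
        params = TrialSimParams(
            baseline_log_mean={("p21", "whole"): 6.4},
            between_participant_sd=0.3,
            within_participant_sd=0.4,
            seed=12,
        )
        df = simulate_trial(params)
        rng = np.random.default_rng(99)
        treated = df["arm"].isin(["D", "CaD", "CaD2arm"])
        y1 = df["visit"] == "year1"
        slope = 5e-4  # log-OD per kcal
        delta = np.where(treated & y1, 400.0, 0.0) + rng.normal(0, 150, len(df))
        energy = df["total_energy_kcal"] + delta
        df["total_energy_kcal"] = energy
        df["value"] = df["value"] * np.exp(slope * (energy - 1500.0))
        contrast = build_contrasts()["vitD_vs_noD"]
        retained, log = confounder_screen(
            df, contrast, "p21", "whole", candidates=["total_energy_kcal"]
        )
        assert retained == ["total_energy_kcal"]
        row = log[log["covariate"] == "total_energy_kcal"].iloc[0]
        assert row["proportional_change"] >= 0.10

    def test_constant_covariate_skipped_with_warning(self, null_trial_df):
        df = null_trial_df.assign(const_cov=1.0)
        contrast = build_contrasts()["vitD_vs_noD"]
        with pytest.warns(UserWarning, match="no variance"):
            retained, _ = confounder_screen(
                df, contrast, "mib1", "whole", candidates=["const_cov"]
            )
        assert retained == []


class TestSummaryMode:
    def test_reference_table_reproduces_reported_effects_on_whole_crypt_p21(self):
        ref = load_reference_group_means()
        eff = summary_effects_from_group_means(ref)
        row = eff[(eff["variable"] == "p21") & (eff["zone"] == "whole")
                  & (eff["contrast"] == "caD_vs_ca")].iloc[0]
        assert round(row["relative_effect"], 2) == 1.26
        assert round(row["absolute_effect"], 1) == 120.7

    def test_missing_role_raises(self):
        bad = pd.DataFrame(
            {
                "variable": ["x"], "zone": ["whole"], "contrast": ["c"],
                "role": ["treated"], "gm_baseline": [1.0], "gm_followup": [2.0],
            }
        )
        with pytest.raises(ValueError, match="reference"):
            summary_effects_from_group_means(bad)


def test_effects_table_covers_all_contrasts(effect_trial_df):
    table = effects_table(effect_trial_df)
    assert set(table["contrast"]) == {"vitD_vs_noD", "ca_vs_noCa", "caD_vs_ca"}
    assert set(table["variable"]) == {"mib1"}
    # each contrast block carries four group-visit summary rows
    assert len(table) == 3 * 4
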