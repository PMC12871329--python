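"""Behavioral battery: regression contracts, symmetries, and model signatures."""

import numpy as np
import pandas as pd
import pytest

from gazeflux.analyses import (
    dwell_consistency_regression,
    first_dwell_regression,
    gaze_cascade,
    melfb_interaction,
    melfb_quintiles,
    post_report_gaze_test,
    residual_rt_vs_sum,
    summary_curves,
)
from gazeflux.data_model import FixationEpoch, TrialRecord, TrialSet, derive_features
from gazeflux.simulators import AddmParams, ModelSpec, PdgParams
from gazeflux.synthetic import DwellModel, StudyDesign, generate_dataset


class TestMelfb:
    def test_addm_bias_grows_with_overall_value(self, addm_features):
        """Multiplicative attention predicts a last-fixation bias that
        increases across sum_r quintiles (positive rank correlation) and a
        positive, significant interaction slope."""
        q = melfb_quintiles(addm_features)
        betas = q.extra["beta_lastfix_by_quintile"].to_numpy()
        rho = np.corrcoef(np.arange(5), betas)[0, 1]
        assert rho > 0
        inter = melfb_interaction(addm_features)
        assert inter.extra["interaction_slope"] > 0
        assert inter.extra["interaction_p"] < 0.01

    def test_pdg_bias_flat_in_overall_value(self, pdg_features):
        """Post-decisional gaze predicts no magnitude modulation of the
        last-fixation bias."""
        inter = melfb_interaction(pdg_features)
        assert inter.extra["interaction_p"] > 0.05

    def test_separation_is_flagged(self):
        """A choice perfectly determined by the last fixation with no value
        signal separates the logit; the fit is flagged, not silent."""
        rng = np.random.default_rng(3)
        n = 200
        last = rng.choice(["left", "right"], n)
        df = pd.DataFrame({
            "participant_id": ["s"] * n,
            "r_left": 5, "r_right": 5,
            "choice": last,
            "rt": 1.0,
            "sum_r": rng.integers(0, 21, n),
            "last_fixated": last,
        })
        res = melfb_quintiles(df)
        assert res.flags["separation"] or res.flags["penalized"]

    def test_duplicating_trials_shrinks_se(self, pdg_features):
        half = pdg_features.iloc[:1000]
        doubled = pd.concat([half, half], ignore_index=True)
        a = melfb_interaction(half)
        b = melfb_interaction(doubled)
        assert b.extra["interaction_slope"] == pytest.approx(
            a.extra["interaction_slope"], abs=1e-6)
        assert b.bse["lastfix_x_sumr"] < a.bse["lastfix_x_sumr"]

    def test_shuffled_sumr_calibrated_null(self, pdg_features):
        """Permuting sum_r across trials breaks any magnitude modulation:
        interaction p-values are approximately uniform (KS test)."""
        rng = np.random.default_rng(4)
        feats = pdg_features.iloc[:1200].copy()
        pvals = []
        for _ in range(60):
            feats["sum_r"] = rng.permutation(feats["sum_r"].to_numpy())
            pvals.append(melfb_interaction(feats).extra["interaction_p"])
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_order_invariance(self, pdg_features):
        shuffled = pdg_features.sample(frac=1.0, random_state=0)
        a = melfb_interaction(pdg_features).extra["interaction_slope"]
        b = melfb_interaction(shuffled).extra["interaction_slope"]
        assert a == pytest.approx(b, rel=1e-6)


class TestDwellConsistency:
    def test_addm_predicts_larger_gaze_bias_when_inconsistent(self, addm_features):
        r = dwell_consistency_regression(addm_features)
        assert r.extra["beta_c"] < 0
        assert r.extra["p_one_tailed"] < 0.01

    def test_pdg_predicts_no_consistency_effect(self, pdg_features):
        r = dwell_consistency_regression(pdg_features)
        assert r.extra["p_one_tailed"] > 0.05

    def test_sign_flip_is_exact(self, pdg_features):
        flipped = pdg_features.copy()
        flipped["delta_dwell"] = -flipped["delta_dwell"]
        a = dwell_consistency_regression(pdg_features)
        b = dwell_consistency_regression(flipped)
        assert b.extra["beta_c"] == pytest.approx(-a.extra["beta_c"])

    def test_all_consistent_raises(self):
        df = pd.DataFrame({
            "participant_id": ["s"] * 10,
            "rt": np.linspace(1, 2, 10),
            "delta_dwell": np.linspace(-0.2, 0.4, 10),
            "consistent": [1.0] * 10,
        })
        with pytest.raises(ValueError, match="consistent"):
            dwell_consistency_regression(df)

    def test_ties_excluded(self, pdg_features):
        r = dwell_consistency_regression(pdg_features)
        n_defined = int(pdg_features["consistent"].isin([0.0, 1.0]).sum())
        assert r.n == n_defined


class TestFirstDwell:
    def test_pdg_multi_dwell_trials_show_no_duration_effect(self, pdg_features):
        """On PDG data the first-dwell duration carries no information about
        choice once the bound was not crossed during it."""
        r = first_dwell_regression(pdg_features, 3)
        assert r.extra["lr_p"] > 0.05

    def test_value_coefficients_have_expected_signs(self, addm_features):
        r = first_dwell_regression(addm_features, 2)
        assert r.params["r_first"] > 0
        assert r.params["r_other"] < 0

    def test_constant_duration_raises(self):
        df = pd.DataFrame({
            "participant_id": ["s"] * 30,
            "n_dwells": 2,
            "first_fixated": ["left"] * 30,
            "first_dwell_duration": 0.3,
            "r_left": np.arange(30) % 10,
            "r_right": (np.arange(30) + 3) % 10,
            "choice": ["left", "right"] * 15,
        })
        with pytest.raises(ValueError, match="constant"):
            first_dwell_regression(df, 2)

    def test_dwell_count_out_of_range(self, pdg_features):
        with pytest.raises(ValueError):
            first_dwell_regression(pdg_features, 7)


def _always_on_chosen_trials(n=20):
    trials = []
    for i in range(n):
        choice = "left" if i % 2 == 0 else "right"
        trials.append(TrialRecord(
            "s", 4, 3, choice, 1.0,
            [FixationEpoch(choice, 0.0, 1.5)],
        ))
    return TrialSet(trials)


class TestGazeCascade:
    def test_always_on_chosen_gives_unit_curve(self):
        c = gaze_cascade(_always_on_chosen_trials(), alignment="response",
                         window=(-0.5, 0.2))
        assert np.nanmin(c.mean) == pytest.approx(1.0)

    def test_curve_bounded(self, pdg_study):
        c = gaze_cascade(pdg_study, alignment="response")
        ok = ~np.isnan(c.mean)
        assert (c.mean[ok] >= 0).all() and (c.mean[ok] <= 1).all()

    def test_pdg_response_aligned_rises_to_report(self, pdg_study):
        """The cascade: P(on chosen) sits at chance far from the report and
        increases monotonically over the final 500 ms (the span of the
        post-commitment latencies), Spearman rho > 0.9 on a binned curve."""
        from scipy import stats
        c = gaze_cascade(pdg_study, alignment="response")
        far = (c.t >= -1.2) & (c.t <= -0.7)
        assert np.nanmean(c.mean[far]) == pytest.approx(0.5, abs=0.03)
        sel = (c.t >= -0.5) & (c.t <= 0)
        # average to 20 ms bins to damp per-millisecond sampling noise
        m = c.mean[sel][: (sel.sum() // 20) * 20].reshape(-1, 20).mean(axis=1)
        rho = stats.spearmanr(np.arange(m.size), m).statistic
        assert rho > 0.9

    def test_pdg_continues_rising_after_report(self, pdg_study):
        """Mean P(on chosen) in the 200 ms after the report exceeds the mean
        in the 200 ms before it."""
        c = gaze_cascade(pdg_study, alignment="response", window=(-0.3, 0.3))
        pre = np.nanmean(c.mean[(c.t >= -0.2) & (c.t < 0)])
        post = np.nanmean(c.mean[(c.t > 0) & (c.t <= 0.2)])
        assert post > pre

    def test_stimulus_alignment_blanks_final_500ms(self):
        ts = _always_on_chosen_trials()
        c = gaze_cascade(ts, alignment="stimulus", window=(0.0, 1.2))
        # rt = 1.0 for all trials: times >= 0.5 carry no gaze data
        assert np.isnan(c.mean[c.t > 0.55]).all()
        assert c.display_start is not None

    def test_fixation_time_alignment_has_no_off_item_gaps(self, addm_study):
        c = gaze_cascade(addm_study, alignment="fixation_time",
                         window=(-1.0, 0.0))
        assert np.isfinite(c.mean[(c.t > -0.5) & (c.t < -0.01)]).all()


class TestPostReportGaze:
    def test_pdg_post_exceeds_pre(self, pdg_study):
        df, test = post_report_gaze_test(pdg_study)
        assert (df["p_post"] > df["p_pre"]).mean() > 0.5
        assert test["pvalue"] < 0.05

    def test_identical_windows_yield_null(self):
        trials = []
        for i in range(12):
            trials.append(TrialRecord(
                f"p{i}", 4, 3, "left", 1.0,
                [FixationEpoch("left", 0.0, 0.9),
                 FixationEpoch("right", 0.9, 1.1),
                 FixationEpoch("left", 1.1, 1.4)],
            ))
        df, test = post_report_gaze_test(TrialSet(trials))
        assert test["pvalue"] == 1.0

    def test_empty_window_participant_dropped(self):
        good = TrialRecord("a", 4, 3, "left", 1.0,
                           [FixationEpoch("left", 0.0, 1.4)])
        bad = TrialRecord("b", 4, 3, "left", 1.0,
                          [FixationEpoch("left", 0.0, 0.5)])  # nothing near rt
        df, test = post_report_gaze_test(TrialSet([good, bad]))
        assert test["n_excluded"] == 1
        assert list(df["participant_id"]) == ["a"]


class TestResidualRt:
    def test_pdg_magnitude_effect_negative_slope(self, pdg_features):
        """gamma > 0 scales evidence variance with sum_r, producing faster
        responses at higher overall value."""
        r = residual_rt_vs_sum(pdg_features)
        assert r.extra["slope"] < 0
        assert r.extra["p"] < 0.05

    def test_zero_gamma_no_magnitude_effect(self, dwell_model):
        ts = generate_dataset(
            ModelSpec("pdg", PdgParams(gamma=0.0)),
            StudyDesign(n_participants=6, n_trials_per_participant=150),
            dwell_model, np.random.default_rng(77))
        r = residual_rt_vs_sum(derive_features(ts))
        assert abs(r.extra["slope"]) < 2.5 * r.extra["slope_se"]

    def test_additive_attention_lacks_magnitude_effect(self, dwell_model):
        ts = generate_dataset(
            ModelSpec("addm_add", AddmParams(theta=1.0, omega=0.7)),
            StudyDesign(n_participants=6, n_trials_per_participant=150),
            dwell_model, np.random.default_rng(78))
        r = residual_rt_vs_sum(derive_features(ts))
        assert abs(r.extra["slope"]) < 2.5 * r.extra["slope_se"]

    def test_too_few_levels_raises(self):
        df = pd.DataFrame({
            "participant_id": ["s"] * 10,
            "delta_r": [0, 1] * 5,
            "sum_r": np.arange(10),
            "rt": np.linspace(1, 2, 10),
        })
        with pytest.raises(ValueError, match="levels"):
            residual_rt_vs_sum(df)


class TestSummaryCurves:
    def test_deterministic_chooser_steps_at_zero(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(400):
            dr = int(rng.integers(-5, 6))
            choice = "right" if dr > 0 else ("left" if dr < 0 else
                                             rng.choice(["left", "right"]))
            rows.append({
                "participant_id": "s", "delta_r": dr, "sum_r": 10,
                "choice": choice, "rt": 1.0,
                "dwell_left": 0.5, "dwell_right": 0.5,
                "last_fixated": choice, "first_fixated": "left",
                "first_dwell_duration": 0.3, "n_dwells": 2,
            })
        curves = summary_curves(pd.DataFrame(rows))
        psy = curves["psychometric"].set_index("delta_r")["chose_right"]
        assert (psy[psy.index < 0] == 0).all()
        assert (psy[psy.index > 0] == 1).all()

    def test_mirrored_dataset_mirrors_psychometric(self, pdg_features):
        f = pdg_features
        mirrored = f.copy()
        mirrored["delta_r"] = -f["delta_r"]
        mirrored[["r_left", "r_right"]] = f[["r_right", "r_left"]].to_numpy()
        mirrored["choice"] = np.where(f["choice"] == "left", "right", "left")
        mirrored["last_fixated"] = f["last_fixated"].map(
            {"left": "right", "right": "left", "unresolved": "unresolved"})
        mirrored["first_fixated"] = f["first_fixated"].map(
            {"left": "right", "right": "left", "unresolved": "unresolved"})
        d = mirrored[["dwell_left", "dwell_right"]].to_numpy()
        mirrored[["dwell_left", "dwell_right"]] = d[:, ::-1]
        a = summary_curves(pdg_features)["psychometric"]
        b = summary_curves(mirrored)["psychometric"]
        merged = a.merge(b, left_on="delta_r", right_on=b["delta_r"] * -1,
                         suffixes=("_a", "_b"))
        assert np.allclose(merged["chose_right_a"],
                           1 - merged["chose_right_b"], atol=1e-12)

    def test_edge_pooling_flag_changes_deciles(self, pdg_features):
        a = summary_curves(pdg_features, per_participant_edges=True)
        b = summary_curves(pdg_features, per_participant_edges=False)
        assert not np.allclose(a["p_left_vs_delta_dwell"]["x"],
                               b["p_left_vs_delta_dwell"]["x"])
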