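"""Map-level statistics: summaries, circular correlations, selection control,
size-eccentricity fits, gaze stability, localisation scoring."""

import numpy as np
import pandas as pd
import pytest

from motionprf.errors import InsufficientDataError, ValidationError
from motionprf.map_metrics import (circ_corr, gaze_mad, group_circ_corr,
                                   localisation_design, r2_sigma_association,
                                   score_localisation, selection_control,
                                   sigma_vs_ecc, summarize_by_area)


def fit_table(r2, sigma, area="V1", x0=None, y0=None):
    n = len(r2)
    return pd.DataFrame({
        "vertex_id": np.arange(n), "area": area,
        "x0": x0 if x0 is not None else np.ones(n),
        "y0": y0 if y0 is not None else np.zeros(n),
        "sigma": sigma, "r2": r2,
    })


class TestSummarizeByArea:
    def test_hand_computed_five_vertex_area(self):
        t = fit_table(r2=[0.01, 0.04, 0.06, 0.2, 0.9], sigma=[1, 2, 3, 4, 5])
        s = summarize_by_area(t, threshold=0.05)
        row = s.iloc[0]
        assert row["prop_responsive"] == pytest.approx(0.6)
        assert row["median_sigma"] == 4
        assert row["median_r2"] == pytest.approx(0.2)
        assert row["n_vertices"] == 5

    def test_all_above_threshold(self):
        t = fit_table(r2=[0.5, 0.6], sigma=[1.0, 2.0])
        assert summarize_by_area(t).iloc[0]["prop_responsive"] == 1.0

    def test_empty_area_flagged_with_nan_medians(self):
        t = fit_table(r2=[0.01, 0.02], sigma=[1.0, 2.0])
        row = summarize_by_area(t).iloc[0]
        assert row["n_responsive"] == 0
        assert np.isnan(row["median_sigma"])

    def test_prop_equals_bruteforce_count(self):
        rng = np.random.default_rng(0)
        t = fit_table(r2=rng.uniform(0, 0.3, 200), sigma=rng.uniform(0.5, 3, 200))
        t["area"] = np.where(np.arange(200) % 2 == 0, "V1", "MT+")
        s = summarize_by_area(t, threshold=0.05).set_index("area")
        for area in ("V1", "MT+"):
            sub = t[t["area"] == area]
            assert s.loc[area, "prop_responsive"] == \
                (sub["r2"] > 0.05).sum() / len(sub)

    def test_labels_mapping(self):
        t = fit_table(r2=[0.1, 0.2], sigma=[1, 2]).drop(columns="area")
        s = summarize_by_area(t, labels={0: "V1", 1: "V2"})
        assert set(s["area"]) == {"V1", "V2"}
        with pytest.raises(ValidationError):
            summarize_by_area(t, labels={0: "V1"})


class TestCircCorr:
    def test_identical_nondegenerate_vectors_give_one(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(-np.pi, np.pi, 50)
        assert circ_corr(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_formula_on_hand_pairs(self):
        a = np.array([0.1, 1.2, -2.0, 3.0, -0.7, 2.2])
        b = np.array([0.3, 1.0, -1.5, -3.0, -0.2, 1.9])
        abar = np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))
        bbar = np.arctan2(np.mean(np.sin(b)), np.mean(np.cos(b)))
        num = np.sum(np.sin(a - abar) * np.sin(b - bbar))
        den = np.sqrt(np.sum(np.sin(a - abar) ** 2) * np.sum(np.sin(b - bbar) ** 2))
        assert circ_corr(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_matches_independent_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        a = rng.uniform(-np.pi, np.pi, 80)
        b = np.angle(np.exp(1j * (a + rng.normal(0, 0.8, 80))))
        r_ref = pingouin.circ_corrcc(a, b)[0]
        assert circ_corr(a, b) == pytest.approx(r_ref, abs=1e-10)

    def test_null_distribution_is_tight(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(200):
            a = rng.uniform(-np.pi, np.pi, 1000)
            b = rng.uniform(-np.pi, np.pi, 1000)
            if abs(circ_corr(a, b)) < 0.1:
                hits += 1
        assert hits >= 0.95 * 200

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-np.pi, np.pi, 60)
        b = np.angle(np.exp(1j * (a + rng.normal(0, 0.5, 60))))
        base = circ_corr(a, b)
        for shift in (0.7, -2.0, np.pi):
            rotated = circ_corr(np.angle(np.exp(1j * (a + shift))),
                                np.angle(np.exp(1j * (b + shift))))
            assert rotated == pytest.approx(base, abs=1e-10)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            circ_corr(np.array([0.0, 1.0]), np.array([0.5, 1.5]))


class TestGroupCircCorr:
    def test_all_zero_correlations(self):
        out = group_circ_corr(np.array([0.0, 0.0, 0.0]))
        assert out["mean_z"] == 0.0
        assert out["degenerate"]  # identical values: t undefined

    def test_identical_nonzero_correlations_flagged(self):
        out = group_circ_corr(np.array([0.5, 0.5, 0.5]))
        assert out["mean_z"] == pytest.approx(np.arctanh(0.5))
        assert out["degenerate"] and np.isnan(out["p"])

    def test_unit_correlation_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            out = group_circ_corr(np.array([1.0, 0.5, 0.4]))
        assert np.isfinite(out["mean_z"])

    def test_power_against_true_positive_association(self):
        # 5 subjects, n=500 vertex pairs with genuinely coupled angles
        # (concentrated marginals, true rho ~ 0.4): the group test should
        # reject H0 at alpha=.05 in >80% of replicates
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(100):
            rs = []
            for _ in range(5):
                a = rng.normal(0, 1.0, 500)
                b = np.angle(np.exp(1j * (a + rng.normal(0, 1.3, 500))))
                rs.append(circ_corr(np.angle(np.exp(1j * a)), b))
            if group_circ_corr(np.array(rs))["p"] < 0.05:
                rejections += 1
        assert rejections > 80


class TestSelectionControl:
    def test_full_survivor_set_reproduces_reference(self):
        rng = np.random.default_rng(6)
        t = fit_table(r2=rng.uniform(0, 0.4, 100), sigma=rng.uniform(0.5, 4, 100))
        ref = summarize_by_area(t)
        out = selection_control(t, {"other": set(t["vertex_id"])})
        assert out.iloc[0]["median_sigma"] == ref.iloc[0]["median_sigma"]
        assert out.iloc[0]["prop_responsive"] == ref.iloc[0]["prop_responsive"]

    def test_excluding_top_sigma_quartile_lowers_median(self):
        rng = np.random.default_rng(7)
        sigma = rng.uniform(0.5, 4, 200)
        t = fit_table(r2=np.full(200, 0.2), sigma=sigma)
        keep = set(t.loc[t["sigma"] < np.quantile(sigma, 0.75), "vertex_id"])
        out = selection_control(t, {"lowpass": keep})
        full_median = np.median(sigma)
        assert out.iloc[0]["median_sigma"] < full_median

    def test_own_survivors_reproduce_reference_medians_exactly(self):
        rng = np.random.default_rng(8)
        t = fit_table(r2=rng.uniform(0, 0.3, 150), sigma=rng.uniform(0.5, 4, 150))
        own = set(t.loc[t["r2"] > 0.05, "vertex_id"])
        out = selection_control(t, {"self": own})
        ref = summarize_by_area(t)
        assert out.iloc[0]["median_sigma"] == ref.iloc[0]["median_sigma"]
        assert out.iloc[0]["median_r2"] == ref.iloc[0]["median_r2"]

    def test_unknown_vertex_ids_rejected(self):
        t = fit_table(r2=[0.1], sigma=[1.0])
        with pytest.raises(ValidationError):
            selection_control(t, {"bad": {999}})


class TestSigmaVsEcc:
    def test_recovers_generated_slope(self):
        rng = np.random.default_rng(9)
        ecc = rng.uniform(0, 8, 300)
        ang = rng.uniform(-np.pi, np.pi, 300)
        sigma = 0.5 + 0.1 * ecc + rng.normal(0, 0.05, 300)
        t = fit_table(r2=np.full(300, 0.3), sigma=sigma,
                      x0=ecc * np.cos(ang), y0=ecc * np.sin(ang))
        out = sigma_vs_ecc(t)
        assert out.iloc[0]["slope"] == pytest.approx(0.1, abs=0.02)
        assert out.iloc[0]["intercept"] == pytest.approx(0.5, abs=0.05)

    def test_constant_sigma_gives_zero_slope(self):
        rng = np.random.default_rng(10)
        ecc = rng.uniform(0, 8, 100)
        t = fit_table(r2=np.full(100, 0.3), sigma=np.full(100, 1.7),
                      x0=ecc, y0=np.zeros(100))
        assert sigma_vs_ecc(t).iloc[0]["slope"] == pytest.approx(0.0, abs=1e-10)

    def test_slope_ordering_preserved_across_areas(self):
        rng = np.random.default_rng(11)
        frames = []
        for area, slope in [("V1", 0.05), ("V3A", 0.2), ("MT+", 0.4)]:
            ecc = rng.uniform(0, 8, 200)
            f = fit_table(r2=np.full(200, 0.3),
                          sigma=0.5 + slope * ecc + rng.normal(0, 0.05, 200),
                          x0=ecc, y0=np.zeros(200))
            f["area"] = area
            frames.append(f)
        t = pd.concat(frames).reset_index(drop=True)
        t["vertex_id"] = np.arange(len(t))
        out = sigma_vs_ecc(t).set_index("area")
        assert out.loc["V1", "slope"] < out.loc["V3A", "slope"] < out.loc["MT+", "slope"]

    def test_insufficient_vertices_flagged(self):
        t = fit_table(r2=np.full(5, 0.3), sigma=np.ones(5))
        assert sigma_vs_ecc(t).iloc[0]["flagged"]


class TestR2SigmaAssociation:
    def test_perfect_monotone_gives_rho_one(self):
        t = fit_table(r2=np.linspace(0.1, 0.9, 20), sigma=np.linspace(1, 3, 20))
        rho, _ = r2_sigma_association(t)
        assert rho == pytest.approx(1.0)

    def test_matches_rank_formula_oracle(self):
        r2 = np.array([0.10, 0.22, 0.31, 0.08, 0.50, 0.45, 0.12, 0.27])
        sigma = np.array([2.0, 1.1, 0.9, 2.4, 0.7, 1.0, 1.8, 1.5])
        t = fit_table(r2=r2, sigma=sigma)
        rho, _ = r2_sigma_association(t, min_n=8)
        # Spearman via the classic no-ties formula
        d = pd.Series(r2).rank() - pd.Series(sigma).rank()
        rho_hand = 1 - 6 * (d**2).sum() / (8 * (8**2 - 1))
        assert rho == pytest.approx(rho_hand, abs=1e-12)

    def test_degenerate_input_rejected(self):
        t = fit_table(r2=np.full(20, 0.3), sigma=np.linspace(1, 3, 20))
        with pytest.raises(ValidationError):
            r2_sigma_association(t)


class TestGazeMad:
    def test_constant_gaze_zero_mad(self):
        out = gaze_mad(np.full(50, 1.3), np.full(50, -0.2))
        assert (out.mad_x, out.mad_y) == (0.0, 0.0)

    def test_hand_computed_mad(self):
        out = gaze_mad(np.array([0., 1., 2., 100.] * 5), np.zeros(20))
        assert out.mad_x == 1.0

    def test_run_with_too_few_valid_samples_excluded(self):
        out = gaze_mad(np.arange(9.0), np.arange(9.0))
        assert out.excluded and out.mad_x is None and "9" in out.reason
        ok = gaze_mad(np.arange(10.0), np.arange(10.0))
        assert not ok.excluded


class TestLocalisation:
    def test_design_enumeration(self):
        d = localisation_design()
        per_block = d[d["condition"] == "bar_only"]
        assert len(per_block) == 220  # 22 positions x 2 orientations x 5 repeats
        assert per_block["eccentricity"].nunique() == 11
        assert per_block["offset"].nunique() == 22
        assert (per_block["eccentricity"] >= 1.4 - 1e-9).all()

    def test_all_correct_gives_unit_proportion_and_flat_line(self):
        d = localisation_design(conditions=("bar_only",))
        d["response"] = d["truth"]
        out = score_localisation(d)
        assert (out["by_eccentricity"]["prop_correct"] == 1.0).all()
        assert out["linear_fits"]["bar_only"]["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_guesser_scores_quarter_everywhere(self):
        rng = np.random.default_rng(12)
        d = localisation_design(conditions=("global",), repeats=60)
        d["response"] = rng.choice(["above", "below", "left", "right"], len(d))
        out = score_localisation(d, reference="global")
        props = out["by_eccentricity"]["prop_correct"]
        assert props.mean() == pytest.approx(0.25, abs=0.03)
        assert ((props - 0.25).abs() < 0.15).all()

    def test_bin_totals_match_design_counts(self):
        d = localisation_design(conditions=("kinetic",))
        d["response"] = "above"
        out = score_localisation(d, reference="kinetic")
        assert (out["by_eccentricity"]["n"] == 20).all()  # 2 offsets x 2 orient x 5

    def test_malformed_responses_rejected_per_trial(self):
        d = localisation_design(conditions=("bar_only",))
        d["response"] = d["truth"]
        d.loc[:4, "response"] = "dunno"
        out = score_localisation(d)
        assert out["n_rejected"] == 5

    def test_declining_condition_yields_negative_slope_contrast(self):
        rng = np.random.default_rng(13)
        d = localisation_design(conditions=("bar_only", "transparent"))
        correct = []
        for _, row in d.iterrows():
            if row["condition"] == "bar_only":
                p = 0.98
            else:
                p = max(0.3, 0.95 - 0.07 * row["eccentricity"])
            correct.append(rng.uniform() < p)
        d["response"] = np.where(correct, d["truth"], "above")
        out = score_localisation(d)
        c = out["slope_contrasts"]["transparent"]
        assert c["slope_diff"] < 0
        assert c["p"] < 0.01
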