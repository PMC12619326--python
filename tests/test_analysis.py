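import numpy as np
import pandas as pd
import pytest

import serialdep as sd
from serialdep.analysis import (
    fit_orientation_bias,
    peak_location,
    per_degree_condition_tests,
    rm_anova_oneway,
)
from serialdep.circular import ori_diff, wrap_ori


class TestPreprocess:
    def test_removes_injected_cardinal_bias(self):
        t = sd.generate_experiment(
            sd.DesignSpec.exp1(n_participants=3, n_trials=600),
            profiles=sd.SDProfile(0.0),
            noise=sd.NoiseSpec(response_sd=6.0, cardinal_amplitude=3.0),
            seed=11,
        )
        pre = sd.preprocess(t)
        for _, sub in pre.groupby("participant_id"):
            refit = fit_orientation_bias(
                sub["stimulus_ori"].to_numpy(), sub["corrected_error"].to_numpy()
            )
            resid_amp = (refit.max() - refit.min()) / 2
            assert resid_amp < 0.3

    def test_bias_free_noiseless_input_untouched(self):
        t = sd.generate_experiment(
            sd.DesignSpec.exp1(n_participants=2, n_trials=200),
            profiles=sd.SDProfile(0.0),
            noise=sd.NoiseSpec(response_sd=1e-3),
            seed=12,
            participant_amp_sd=0.0,
        )
        pre = sd.preprocess(t)
        assert np.allclose(pre["corrected_error"], pre["error"], atol=1e-3)
        # the 3-SD rule is scale-free, so only the expected tail is flagged
        assert pre["excluded"].mean() < 0.02

    def test_bias_free_noisy_input_few_exclusions(self, null_exp1_table):
        pre = sd.preprocess(null_exp1_table)
        # exclusions limited to the expected 3-sigma tail
        assert pre["excluded"].mean() < 0.01

    def test_planted_gross_error_flagged(self, null_exp1_table):
        t = null_exp1_table.copy()
        i = t.index[100]
        t.loc[i, "response_ori"] = wrap_ori(t.loc[i, "stimulus_ori"] + 85.0)
        pre = sd.preprocess(t)
        assert bool(pre.loc[i, "excluded"])

    def test_noisy_participant_fully_excluded(self, rng):
        n = 300
        good = pd.DataFrame(
            {
                "participant_id": 0,
                "trial_index": np.arange(n),
                "role": "response1",
                "condition": "non-cued",
                "stimulus_ori": rng.uniform(0, 180, n),
                "prev_inducer_ori": rng.uniform(0, 180, n),
                "excluded": False,
            }
        )
        good["response_ori"] = wrap_ori(good["stimulus_ori"] + rng.normal(0, 8, n))
        bad = good.copy()
        bad["participant_id"] = 1
        bad["response_ori"] = rng.uniform(0, 180, n)  # guessing: circular SD >> 30
        pre = sd.preprocess(pd.concat([good, bad], ignore_index=True))
        assert pre[pre.participant_id == 1]["excluded"].all()
        assert not pre[pre.participant_id == 0]["excluded"].all()

    def test_small_participant_skipped(self, rng):
        t = pd.DataFrame(
            {
                "participant_id": 9,
                "trial_index": np.arange(10),
                "role": "response1",
                "condition": "non-cued",
                "stimulus_ori": rng.uniform(0, 180, 10),
                "response_ori": rng.uniform(0, 180, 10),
                "prev_inducer_ori": rng.uniform(0, 180, 10),
                "excluded": False,
            }
        )
        pre = sd.preprocess(t)
        assert pre.attrs["skipped_participants"] == [9]


class TestSignedBias:
    def _table(self, stim, resp, ref):
        return pd.DataFrame(
            {
                "participant_id": 0,
                "stimulus_ori": stim,
                "response_ori": resp,
                "prev_inducer_ori": ref,
                "corrected_error": ori_diff(np.asarray(resp), np.asarray(stim)),
                "excluded": False,
            }
        )

    def test_error_toward_reference_positive(self):
        t = self._table([50.0], [55.0], [80.0])  # error +5, reference at +30
        assert sd.signed_bias(t)["bias"].iloc[0] == pytest.approx(5.0)

    def test_error_away_from_reference_negative(self):
        t = self._table([50.0], [55.0], [20.0])  # error +5, reference at -30
        assert sd.signed_bias(t)["bias"].iloc[0] == pytest.approx(-5.0)

    def test_undefined_direction_dropped(self):
        t = self._table([50.0, 50.0, 50.0], [55.0] * 3, [50.0, 140.0, 80.0])
        out = sd.signed_bias(t)
        assert len(out) == 1
        assert out.attrs["n_undefined_direction"] == 2

    def test_mirror_reflection_negates_bias(self, small_exp1_table):
        pre = sd.preprocess(small_exp1_table)
        b1 = sd.signed_bias(pre)
        mirrored = pre.copy()
        for col in ("stimulus_ori", "response_ori", "prev_inducer_ori"):
            mirrored[col] = wrap_ori(-mirrored[col])
        # re-derive corrected errors under reflection
        mirrored["corrected_error"] = -pre["corrected_error"]
        b2 = sd.signed_bias(mirrored)
        assert np.allclose(b2["bias"].to_numpy(), b1["bias"].to_numpy(), atol=1e-9)


class TestDensityAsymmetryCurve:
    def test_null_curve_within_bootstrap_bands(self, null_exp1_table):
        pre = sd.preprocess(null_exp1_table)
        b = sd.signed_bias(pre)
        curve = sd.density_asymmetry_curve(b, n_boot=300, seed=1)
        se = (curve.ci_high - curve.ci_low) / (2 * 1.96)
        assert np.all(np.abs(curve.asymmetry) < 3.5 * se)

    def test_negating_biases_negates_curve(self, small_exp1_table):
        pre = sd.preprocess(small_exp1_table)
        b = sd.signed_bias(pre)
        c1 = sd.density_asymmetry_curve(b)
        neg = b.copy()
        neg["bias"] = -neg["bias"]
        c2 = sd.density_asymmetry_curve(neg)
        assert np.allclose(c2.asymmetry, -c1.asymmetry)
        assert np.allclose(c2.mean_deg, -c1.mean_deg)

    def test_asymmetry_bounded(self, small_exp1_table):
        pre = sd.preprocess(small_exp1_table)
        curve = sd.density_asymmetry_curve(sd.signed_bias(pre))
        assert np.all(curve.asymmetry >= -1.0) and np.all(curve.asymmetry <= 1.0)

    def test_rejects_bad_bandwidth(self, small_exp1_table):
        pre = sd.preprocess(small_exp1_table)
        with pytest.raises(ValueError):
            sd.density_asymmetry_curve(sd.signed_bias(pre), bandwidth=0.0)


class TestMeanBiasTest:
    def test_planted_attraction_detected(self):
        t = sd.generate_experiment(
            sd.DesignSpec.exp1(n_participants=18),
            profiles=sd.SDProfile(2.0, 35.0),
            seed=21,
        )
        res = sd.mean_bias_test(sd.signed_bias(sd.preprocess(t)))
        row = res.iloc[0]
        assert row["mean_asym"] > 0
        assert row["p"] < 0.05

    def test_constant_zero_errors_degenerate(self):
        t = pd.DataFrame(
            {
                "participant_id": np.repeat([0, 1, 2], 60),
                "bias": 0.0,
            }
        )
        res = sd.mean_bias_test(t)
        assert bool(res["degenerate"].iloc[0])

    def test_single_participant_descriptive_only(self):
        t = pd.DataFrame({"participant_id": 0, "bias": np.r_[1.0, -2.0, 3.0]})
        res = sd.mean_bias_test(t)
        assert np.isnan(res["p"].iloc[0])

    def test_participant_permutation_equivariance(self, small_exp1_table):
        pre = sd.preprocess(small_exp1_table)
        b = sd.signed_bias(pre)
        res1 = sd.mean_bias_test(b)
        relabeled = b.copy()
        ids = sorted(b["participant_id"].unique())
        mapping = dict(zip(ids, np.roll(ids, 1)))
        relabeled["participant_id"] = relabeled["participant_id"].map(mapping)
        res2 = sd.mean_bias_test(relabeled)
        assert res1["mean_asym"].iloc[0] == pytest.approx(res2["mean_asym"].iloc[0])
        assert res1["t"].iloc[0] == pytest.approx(res2["t"].iloc[0])


class TestPerDegreeTests:
    @pytest.fixture(scope="class")
    def curves_two_conditions(self):
        t = sd.generate_experiment(
            sd.DesignSpec.exp1(n_participants=10, n_trials=400),
            profiles={
                "cued": sd.SDProfile(2.5, 35.0),
                "non-cued": sd.SDProfile(0.0, 35.0),
            },
            seed=31,
            participant_amp_sd=0.0,
        )
        b = sd.signed_bias(sd.preprocess(t))
        # within-streak analysis: immediate report of the second stimulus
        b = b[b["role"] == "response2"]
        return sd.participant_curves(b, by="condition")

    def test_f_equals_t_squared_for_two_conditions(self, rng):
        data = rng.normal(size=(12, 2, 5))
        F, p, df1, df2 = rm_anova_oneway(data)
        from scipy import stats

        t, pt = stats.ttest_rel(data[:, 0, :], data[:, 1, :], axis=0)
        assert np.allclose(F, t**2, rtol=1e-9)
        assert np.allclose(p, pt, rtol=1e-9)

    def test_rm_anova_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        data = rng.normal(size=(9, 3))
        F, p, df1, df2 = rm_anova_oneway(data[:, :, None])
        long = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(9), 3),
                "cond": np.tile(np.arange(3), 9),
                "y": data.ravel(),
            }
        )
        res = pg.rm_anova(data=long, dv="y", within="cond", subject="subj")
        assert df1 == res["ddof1"].iloc[0] and df2 == res["ddof2"].iloc[0]
        assert float(np.asarray(F).ravel()[0]) == pytest.approx(res["F"].iloc[0], rel=1e-6)
        assert float(np.asarray(p).ravel()[0]) == pytest.approx(res["p_unc"].iloc[0], rel=1e-6)

    def test_identical_conditions_no_structure(self, rng):
        # duplicate the same curves under two labels: F is ~0 everywhere
        vals = rng.normal(size=(8, 91))
        rows = []
        for pid in range(8):
            for cond in ("a", "b"):
                for d in range(91):
                    rows.append((pid, cond, float(d), vals[pid, d]))
        curves = pd.DataFrame(rows, columns=["participant_id", "condition", "delta", "value"])
        rep = per_degree_condition_tests(curves, alpha=0.05)
        assert np.nanmax(rep.anova_F) < 1e-9

    def test_condition_difference_cluster_near_peak(self, curves_two_conditions):
        rep = per_degree_condition_tests(curves_two_conditions, alpha=0.05)
        anova_clusters = [c for c in rep.clusters if c["kind"] == "anova"]
        assert any(c["lo"] <= 35 <= c["hi"] for c in anova_clusters)

    def test_missing_condition_raises(self, curves_two_conditions):
        broken = curves_two_conditions[
            ~(
                (curves_two_conditions.participant_id == 0)
                & (curves_two_conditions.condition == "cued")
            )
        ]
        with pytest.raises(ValueError):
            per_degree_condition_tests(broken)


class TestPeakLocation:
    def test_monotone_curve_boundary_flag(self):
        res = peak_location((np.arange(91.0), np.linspace(0, 1, 91)))
        assert res["peak"] == 90.0 and res["boundary"]

    def test_flat_curve_undefined(self):
        res = peak_location((np.arange(91.0), np.zeros(91)))
        assert res["flat"] and res["peak"] is None

    def test_empty_curve_raises(self):
        with pytest.raises(ValueError):
            peak_location((np.arange(3.0), np.full(3, np.nan)))
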