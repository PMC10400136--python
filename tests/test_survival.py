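"""Left-truncated KM/Cox: hand-derived cases, oracle parity, imputation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from _oracles import cox_oracle, km_oracle

from hrdscar.survival import (
    KmCurve,
    OutcomeAnalysis,
    SurvivalInputError,
    build_design,
    cox_fit,
    impute_missing,
    km_left_truncated,
    landmark_survival,
)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_left_truncated([0, 0, 0], [1, 2, 3], [1, 1, 1])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert curve.median == 2.0

    def test_no_events_flat_curve(self):
        curve = km_left_truncated([0, 0], [5, 7], [0, 0])
        assert curve.median is None
        assert curve.survival_at(6.0) == 1.0

    def test_entry_after_time_rejected(self):
        with pytest.raises(SurvivalInputError, match="entry"):
            km_left_truncated([2.0], [1.0], [1])

    def test_delayed_entry_shrinks_early_risk_set(self):
        # entries (0, 0, 2.5): the late entrant is not at risk at t=1
        curve = km_left_truncated([0, 0, 2.5], [1, 3, 4], [1, 1, 1])
        assert curve.at_risk[0] == 2
        assert curve.survival[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_classical_km_without_truncation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        times = np.round(rng.exponential(10, n), 1) + 0.1
        events = rng.random(n) < 0.7
        curve = km_left_truncated(np.zeros(n), times, events)
        ev_times, surv = km_oracle(np.zeros(n), times, events)
        assert np.allclose(curve.times, ev_times)
        assert np.allclose(curve.survival, surv, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_risk_set_oracle_with_truncation(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 80
        entries = np.round(rng.exponential(1.0, n), 2)
        times = entries + np.round(rng.exponential(8, n), 2) + 0.01
        events = rng.random(n) < 0.8
        curve = km_left_truncated(entries, times, events)
        ev_times, surv = km_oracle(entries, times, events)
        assert np.allclose(curve.survival, surv, atol=1e-12)


class TestLandmark:
    def test_time_zero_is_one(self):
        curve = km_left_truncated([0, 0], [1, 2], [1, 0])
        assert landmark_survival(curve, 0.0) == 1.0

    def test_step_convention_right_continuous(self):
        curve = KmCurve(
            times=np.array([6.0, 12.0]),
            survival=np.array([0.5, 0.25]),
            at_risk=np.array([10, 5]),
            n_subjects=10,
            n_events=7,
            median=6.0,
        )
        assert landmark_survival(curve, 12.0) == 0.25
        assert landmark_survival(curve, 11.9) == 0.5

    def test_beyond_last_time_all_events(self):
        curve = km_left_truncated([0, 0, 0], [1, 2, 3], [1, 1, 1])
        assert landmark_survival(curve, 10.0) == 0.0

    def test_negative_time_rejected(self):
        curve = km_left_truncated([0], [1], [1])
        with pytest.raises(SurvivalInputError):
            landmark_survival(curve, -1.0)


class TestImputation:
    def _records(self, ecog):
        return pd.DataFrame({"ecog": ecog, "ca19_9_bin": ["normal"] * len(ecog)})

    def test_no_missing_is_identity(self):
        rec = self._records(["0", "1", "0"])
        out = impute_missing(rec, seed=0)
        assert list(out["ecog"]) == ["0", "1", "0"]
        assert out["ecog_imputed"].sum() == 0

    def test_deterministic_given_seed(self):
        rec = self._records(["0", "1", "missing", "missing"])
        out1 = impute_missing(rec, seed=42)
        out2 = impute_missing(rec, seed=42)
        pd.testing.assert_frame_equal(out1, out2)

    def test_never_alters_observed_cells(self):
        rec = self._records(["0", "1", "missing"])
        out = impute_missing(rec, seed=3)
        assert list(out["ecog"][:2]) == ["0", "1"]
        assert out["ecog"].iloc[2] in {"0", "1"}
        assert out["ecog_imputed"].iloc[2] == 1

    def test_draws_follow_observed_distribution(self):
        # 1000 observed values split 50/50, 10000 missing to fill in
        rec = self._records(["0"] * 500 + ["1"] * 500 + ["missing"] * 10000)
        out = impute_missing(rec, seed=7)
        frac0 = (out["ecog"][1000:] == "0").mean()
        assert abs(frac0 - 0.5) < 3 * np.sqrt(0.25 / 10000)

    def test_entirely_missing_covariate_rejected(self):
        rec = self._records(["missing", "missing"])
        with pytest.raises(SurvivalInputError, match="entirely missing"):
            impute_missing(rec, seed=0)


def _basic_records(rng, n, beta=0.0, entries=None):
    """Exponential survival with one binary covariate at log-HR ``beta``."""
    group = rng.integers(0, 2, n)
    t = rng.exponential(1.0, n) / (0.1 * np.exp(beta * group))
    cens = rng.exponential(30.0, n)
    rec = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "group": group,
            "entry_months": np.zeros(n) if entries is None else entries,
            "os_months": np.minimum(t, cens),
            "os_event": (t <= cens).astype(int),
            "ttnt_months": np.minimum(t, cens),
            "ttnt_event": (t <= cens).astype(int),
        }
    )
    return rec


class TestCox:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(0)
        rec = _basic_records(rng, 600, beta=0.0)
        fit = cox_fit(rec, covariates=(), extra_columns=("group",))
        lo, hi = fit.ci("group")
        assert lo < 1.0 < hi
        assert fit.hr("group") == pytest.approx(1.0, abs=0.25)

    def test_no_events_rejected(self):
        rng = np.random.default_rng(1)
        rec = _basic_records(rng, 20)
        rec["os_event"] = 0
        with pytest.raises(SurvivalInputError, match="no events"):
            cox_fit(rec, covariates=(), extra_columns=("group",))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_partial_likelihood_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = 60
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(0, 1, n)
        t = rng.exponential(1.0, n) / (0.1 * np.exp(0.5 * x1 - 0.3 * x2))
        events = rng.random(n) < 0.8
        rec = pd.DataFrame(
            {
                "x1": x1,
                "x2": x2,
                "entry_months": np.zeros(n),
                "os_months": t,
                "os_event": events.astype(int),
            }
        )
        fit = cox_fit(rec, covariates=(), extra_columns=("x1", "x2"))
        beta_hat = cox_oracle(np.column_stack([x1, x2]), t, events)
        assert fit.summary.loc["x1", "coef"] == pytest.approx(beta_hat[0], abs=1e-6)
        assert fit.summary.loc["x2", "coef"] == pytest.approx(beta_hat[1], abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_delayed_entry_matches_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = 80
        x = rng.normal(0, 1, n)
        entries = rng.exponential(1.0, n)
        t = entries + rng.exponential(8.0, n)
        events = rng.random(n) < 0.85
        rec = pd.DataFrame(
            {"x": x, "entry_months": entries, "os_months": t,
             "os_event": events.astype(int)}
        )
        fit = cox_fit(rec, covariates=(), extra_columns=("x",))
        beta_hat = cox_oracle(x[:, None], t, events, entries=entries)
        assert fit.summary.loc["x", "coef"] == pytest.approx(beta_hat[0], abs=1e-6)


class TestDesign:
    def test_reference_levels_dropped(self):
        rec = pd.DataFrame(
            {
                "age": [60.0, 70.0],
                "surgery": [0, 1],
                "ecog": ["0", "1"],
                "ca19_9_bin": ["normal", ">59xULN"],
                "tissue": ["pancreas", "liver"],
            }
        )
        design = build_design(rec)
        assert "ecog_1" in design.columns and "ecog_0" not in design.columns
        assert "tissue_liver" in design.columns
        assert design.loc[0].sum() == 60.0  # reference patient: only age

    def test_unimputed_missing_rejected(self):
        rec = pd.DataFrame(
            {"age": [60.0], "surgery": [0], "ecog": ["missing"],
             "ca19_9_bin": ["normal"], "tissue": ["liver"]}
        )
        with pytest.raises(SurvivalInputError, match="impute"):
            build_design(rec)


class TestStratifiedComparison:
    def _cohort(self, rng, n=300):
        rec = _basic_records(rng, n)
        rec["age"] = rng.normal(66, 8, n)
        rec["surgery"] = rng.integers(0, 2, n)
        rec["ecog"] = rng.choice(["0", "1"], n)
        rec["ca19_9_bin"] = rng.choice(["normal", "<59xULN"], n)
        rec["tissue"] = rng.choice(["pancreas", "liver"], n)
        rec["treatment"] = np.where(rec["group"] == 1, "FOLFIRINOX", "GP")
        return rec.drop(columns="group")

    def test_single_stratum_cohort_no_crash(self):
        rng = np.random.default_rng(5)
        rec = self._cohort(rng)
        calls = pd.DataFrame({"sample": rec.patient_id, "call": "negative"})
        res = OutcomeAnalysis(rec, calls).fit(endpoint="rwOS", seed=0)
        assert list(res.table["stratum"]) == ["HRDsig(-)"]
        assert "HRDsig(+)" not in set(res.table["stratum"])

    def test_missing_biomarker_call_rejected(self):
        rng = np.random.default_rng(6)
        rec = self._cohort(rng, 50)
        calls = pd.DataFrame(
            {"sample": rec.patient_id[:-1], "call": "negative"}
        )
        with pytest.raises(SurvivalInputError, match="without a biomarker"):
            OutcomeAnalysis(rec, calls)

    def test_endpoints_use_distinct_event_columns(self):
        rng = np.random.default_rng(7)
        rec = self._cohort(rng)
        # make TTNT strictly earlier than OS so the tables must differ
        rec["ttnt_months"] = rec["os_months"] / 2
        calls = pd.DataFrame({"sample": rec.patient_id, "call": "negative"})
        model = OutcomeAnalysis(rec, calls)
        os_tab = model.fit(endpoint="rwOS", seed=0).table
        tt_tab = model.fit(endpoint="TTNT", seed=0).table
        assert os_tab["median_gp"].iloc[0] > tt_tab["median_gp"].iloc[0]

    def test_summary_mentions_exclusions(self):
        rng = np.random.default_rng(8)
        rec = self._cohort(rng)
        rec.loc[0, "entry_months"] = rec.loc[0, "os_months"] + 1.0
        calls = pd.DataFrame({"sample": rec.patient_id, "call": "negative"})
        res = OutcomeAnalysis(rec, calls).fit(endpoint="rwOS", seed=0)
        assert res.n_excluded_pre_entry == 1
        assert "1 pre-entry exclusions" in res.summary()
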