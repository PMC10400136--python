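"""Left-truncated survival analysis: Kaplan-Meier, Cox, stratified outcomes.

Patients enter the risk set only at their genomic-report date (delayed
entry relative to the start of first-line therapy), so all estimators use
left-truncation-adjusted risk sets: at time t the risk set is
``{i : entry_i < t <= time_i}``.  Estimation is delegated to lifelines
(``KaplanMeierFitter`` with ``entry``, ``CoxPHFitter`` with ``entry_col``,
Efron tie handling); this module owns the endpoint definitions, covariate
coding, random-sample imputation and the biomarker x treatment
stratification.

Covariate coding: age continuous; ECOG and CA19-9 categorical with "0" /
"normal" reference; biopsy tissue reference "pancreas"; treatment indicator
1 = FOLFIRINOX, 0 = GP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, StatError

from .genome import BRCA_PALB2

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "surgery", "ecog", "ca19_9_bin", "tissue")
IMPUTABLE = ("ecog", "ca19_9_bin")
MISSING_TOKEN = "missing"

_CATEGORICAL_REFERENCE = {
    "ecog": "0",
    "ca19_9_bin": "normal",
    "tissue": "pancreas",
}


class SurvivalInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KmCurve:
    """Product-limit survival curve with delayed-entry risk sets."""

    times: np.ndarray  # event times (steps)
    survival: np.ndarray  # S(t) immediately after each event time
    at_risk: np.ndarray  # risk-set size at each event time
    n_subjects: int
    n_events: int
    median: float | None  # first time S(t) <= 0.5, None if never reached

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value S(t)."""
        if t < 0:
            raise SurvivalInputError(f"landmark time {t} < 0")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_left_truncated(
    entries: np.ndarray, times: np.ndarray, events: np.ndarray
) -> KmCurve:
    """Kaplan-Meier estimate accounting for left truncation.

    Requires ``entries <= times`` element-wise (patients whose follow-up
    ends before entry must be excluded upstream; they would never be
    observed in a delayed-entry design).
    """
    entries = np.asarray(entries, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if entries.shape != times.shape or times.shape != events.shape:
        raise SurvivalInputError("entries, times, events must have equal length")
    bad = entries > times
    if bad.any():
        i = int(np.argmax(bad))
        raise SurvivalInputError(
            f"entry {entries[i]} exceeds time {times[i]} at index {i}"
        )
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events, entry=entries)
    sf = kmf.survival_function_
    event_times = kmf.event_table.index.values[kmf.event_table["observed"].values > 0]
    surv = np.array([float(sf.loc[t].iloc[0]) for t in event_times])
    at_risk = kmf.event_table.loc[event_times, "at_risk"].values.astype(int)
    med = kmf.median_survival_time_
    return KmCurve(
        times=np.asarray(event_times, dtype=float),
        survival=surv,
        at_risk=at_risk,
        n_subjects=len(times),
        n_events=int(events.sum()),
        median=None if np.isinf(med) else float(med),
    )


def landmark_survival(curve: KmCurve, t_months: float) -> float:
    """S(t) at a landmark time (e.g. 12 or 24 months)."""
    return curve.survival_at(t_months)


# ---------------------------------------------------------------------------
# imputation


def impute_missing(
    records: pd.DataFrame,
    seed: int,
    columns: tuple[str, ...] = IMPUTABLE,
    missing_token: str = MISSING_TOKEN,
) -> pd.DataFrame:
    """Random-sample imputation: each missing value is replaced by a uniform
    draw from the observed values of that covariate.

    Deterministic given ``seed``; original missingness is flagged in
    ``<col>_imputed`` columns; non-missing cells are never altered.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    for col in columns:
        if col not in out.columns:
            continue
        vals = out[col].astype(object)
        mask = vals.isna() | (vals == missing_token)
        observed = vals[~mask].to_numpy()
        out[f"{col}_imputed"] = mask.astype(int).to_numpy()
        if not mask.any():
            continue
        if len(observed) == 0:
            raise SurvivalInputError(f"covariate {col!r} is entirely missing")
        draws = observed[rng.integers(0, len(observed), int(mask.sum()))]
        vals.loc[mask] = draws
        out[col] = vals
    return out


# ---------------------------------------------------------------------------
# Cox model


@dataclass
class CoxFit:
    """Adjusted Cox proportional-hazards fit (delayed entry, Efron ties)."""

    endpoint: str
    summary: pd.DataFrame  # index = covariate; coef, se, hr, ci, p
    n: int
    n_events: int
    seed: int | None = None

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["hr_lower_95"]), float(row["hr_upper_95"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def _endpoint_cols(endpoint: str) -> tuple[str, str]:
    if endpoint == "rwOS":
        return "os_months", "os_event"
    if endpoint == "TTNT":
        return "ttnt_months", "ttnt_event"
    raise SurvivalInputError(f"unknown endpoint {endpoint!r} (use rwOS or TTNT)")


def build_design(records: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Dummy-code categorical covariates against their reference levels."""
    design = pd.DataFrame(index=records.index)
    for cov in covariates:
        if cov not in records.columns:
            raise SurvivalInputError(f"covariate {cov!r} missing from records")
        if cov in _CATEGORICAL_REFERENCE:
            ref = _CATEGORICAL_REFERENCE[cov]
            values = records[cov].astype(str)
            if (values == MISSING_TOKEN).any():
                raise SurvivalInputError(
                    f"covariate {cov!r} still contains missing values; impute first"
                )
            for level in sorted(set(values) - {ref}):
                safe = (
                    level.replace(">=", "ge").replace("<", "lt").replace(">", "gt")
                    .replace("xULN", "uln")
                )
                design[f"{cov}_{safe}"] = (values == level).astype(float)
        else:
            design[cov] = records[cov].astype(float)
    return design


def cox_fit(
    records: pd.DataFrame,
    endpoint: str = "rwOS",
    covariates=DEFAULT_COVARIATES,
    extra_columns: tuple[str, ...] = (),
    entry_col: str | None = "entry_months",
    seed: int | None = None,
) -> CoxFit:
    """Adjusted Cox PH fit on completed (imputed) records.

    ``extra_columns`` are numeric columns (e.g. a treatment indicator or an
    interaction term) entered as-is.  The partial likelihood uses
    delayed-entry risk sets when ``entry_col`` is given, and Efron tie
    handling.
    """
    duration_col, event_col = _endpoint_cols(endpoint)
    if records[event_col].sum() < 1:
        raise SurvivalInputError("no events in records")
    design = build_design(records, covariates)
    for col in extra_columns:
        design[col] = records[col].astype(float)
    df = design.copy()
    df["__T"] = records[duration_col].astype(float).to_numpy()
    df["__E"] = records[event_col].astype(int).to_numpy()
    kwargs = {}
    if entry_col is not None:
        df["__entry"] = records[entry_col].astype(float).to_numpy()
        kwargs["entry_col"] = "__entry"
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="__T", event_col="__E",
                fit_options={"precision": 1e-12}, **kwargs)
    except ConvergenceError as err:
        raise SurvivalInputError(f"Cox model failed to converge: {err}") from err
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "hr_lower_95": s["exp(coef) lower 95%"],
            "hr_upper_95": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxFit(
        endpoint=endpoint,
        summary=summary,
        n=len(df),
        n_events=int(df["__E"].sum()),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# stratified biomarker x treatment comparison


def _drop_pre_entry(records: pd.DataFrame) -> pd.DataFrame:
    """Remove patients unobservable under left truncation, with a logged count."""
    for col in ("os_months", "ttnt_months"):
        if col not in records.columns:
            return records
    mask = (records["os_months"] <= records["entry_months"]) | (
        records["ttnt_months"] <= records["entry_months"]
    )
    n_drop = int(mask.sum())
    if n_drop:
        logger.info("left truncation: excluding %d patients whose follow-up "
                    "ended before study entry", n_drop)
    return records.loc[~mask].copy()


def _arm_km(grp: pd.DataFrame, endpoint: str) -> dict:
    duration_col, event_col = _endpoint_cols(endpoint)
    out = {"n": len(grp), "n_events": int(grp[event_col].sum())}
    if len(grp) == 0:
        out.update({"median": None, "surv_1y": None, "surv_2y": None})
        return out
    try:
        curve = km_left_truncated(
            grp["entry_months"].to_numpy(),
            grp[duration_col].to_numpy(),
            grp[event_col].to_numpy(),
        )
    except StatError:
        # delayed-entry risk set emptied before the first event; the
        # product-limit curve is undefined for this (tiny) arm
        out.update({"median": None, "surv_1y": None, "surv_2y": None})
        return out
    out.update(
        {
            "median": curve.median,
            "surv_1y": curve.survival_at(12.0),
            "surv_2y": curve.survival_at(24.0),
        }
    )
    return out


@dataclass
class OutcomeResults:
    """Per-stratum outcome table from :class:`OutcomeAnalysis`."""

    endpoint: str
    table: pd.DataFrame
    n_excluded_pre_entry: int
    seed: int

    def summary(self) -> str:
        lines = [
            f"Stratified {self.endpoint} analysis "
            f"(FOLFIRINOX vs GP, left-truncated; "
            f"{self.n_excluded_pre_entry} pre-entry exclusions)",
            "",
        ]
        with pd.option_context("display.width", 140, "display.max_columns", 20):
            lines.append(self.table.to_string(index=False,
                                              float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


class OutcomeAnalysis:
    """Stratified outcome model: biomarker x treatment survival comparison.

    Strata are HRDsig(+) / HRDsig(−), optionally crossed with
    BRCA1/2/PALB2 mutation status, plus the combined either-positive
    biomarker.  ``fit`` computes per-stratum, per-arm KM medians and 1-/2-
    year landmark survival plus the covariate-adjusted FOLFIRINOX-vs-GP
    hazard ratio from a stratum-restricted Cox model.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        hrdsig_calls: pd.DataFrame,
        brca_palb2_mutant: pd.Series | None = None,
        covariates=DEFAULT_COVARIATES,
    ):
        calls = hrdsig_calls.set_index("sample")["call"] if "sample" in hrdsig_calls else hrdsig_calls
        merged = records.copy()
        merged["hrdsig_pos"] = (
            merged["patient_id"].map(calls).map({"positive": True, "negative": False})
        )
        if merged["hrdsig_pos"].isna().any():
            missing = merged.loc[merged["hrdsig_pos"].isna(), "patient_id"].tolist()[:5]
            raise SurvivalInputError(
                f"patients without a biomarker call, e.g. {missing}"
            )
        if brca_palb2_mutant is not None:
            merged["brca_palb2_mut"] = (
                merged["patient_id"].map(brca_palb2_mutant).astype(bool)
            )
        self.records = merged
        self.covariates = covariates

    def fit(self, endpoint: str = "rwOS", seed: int = 0) -> OutcomeResults:
        records = _drop_pre_entry(self.records)
        n_excluded = len(self.records) - len(records)
        records = impute_missing(records, seed)
        records["treatment_folfirinox"] = (
            records["treatment"] == "FOLFIRINOX"
        ).astype(int)

        strata: list[tuple[str, pd.Series]] = [
            ("HRDsig(+)", records["hrdsig_pos"]),
            ("HRDsig(-)", ~records["hrdsig_pos"]),
        ]
        if "brca_palb2_mut" in records.columns:
            mut = records["brca_palb2_mut"]
            strata += [
                ("HRDsig(+) BRCA/PALB2 mut", records["hrdsig_pos"] & mut),
                ("HRDsig(+) BRCA/PALB2 wt", records["hrdsig_pos"] & ~mut),
                ("HRDsig(-) BRCA/PALB2 mut", ~records["hrdsig_pos"] & mut),
                ("HRDsig(-) BRCA/PALB2 wt", ~records["hrdsig_pos"] & ~mut),
                ("HRDsig(+) or BRCA/PALB2 mut", records["hrdsig_pos"] | mut),
                ("dual negative", ~records["hrdsig_pos"] & ~mut),
            ]

        duration_col, event_col = _endpoint_cols(endpoint)
        rows = []
        for name, mask in strata:
            grp = records.loc[mask]
            if len(grp) == 0:
                continue
            folf = grp.loc[grp["treatment_folfirinox"] == 1]
            gp = grp.loc[grp["treatment_folfirinox"] == 0]
            row = {"stratum": name, "n": len(grp)}
            for arm_name, arm in (("folfirinox", folf), ("gp", gp)):
                stats = _arm_km(arm, endpoint)
                row[f"n_{arm_name}"] = stats["n"]
                row[f"median_{arm_name}"] = stats["median"]
                row[f"surv1y_{arm_name}"] = stats["surv_1y"]
                row[f"surv2y_{arm_name}"] = stats["surv_2y"]
            enough = (
                grp[event_col].sum() >= 10
                and folf[event_col].sum() >= 3
                and gp[event_col].sum() >= 3
            )
            if enough:
                try:
                    fit = cox_fit(
                        grp,
                        endpoint=endpoint,
                        covariates=self.covariates,
                        extra_columns=("treatment_folfirinox",),
                        seed=seed,
                    )
                    row["ahr"] = fit.hr("treatment_folfirinox")
                    lo, hi = fit.ci("treatment_folfirinox")
                    row["ahr_lower_95"], row["ahr_upper_95"] = lo, hi
                    row["ahr_p"] = fit.p("treatment_folfirinox")
                    row["flag"] = ""
                except SurvivalInputError as err:
                    row.update(
                        {"ahr": None, "ahr_lower_95": None, "ahr_upper_95": None,
                         "ahr_p": None, "flag": f"no aHR: {err}"}
                    )
            else:
                row.update(
                    {"ahr": None, "ahr_lower_95": None, "ahr_upper_95": None,
                     "ahr_p": None, "flag": "no aHR: insufficient events"}
                )
            rows.append(row)
        table = pd.DataFrame(rows)
        return OutcomeResults(endpoint, table, n_excluded, seed)


def stratified_comparison(
    records: pd.DataFrame,
    hrdsig_calls: pd.DataFrame,
    endpoint: str = "rwOS",
    brca_palb2_mutant: pd.Series | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Functional wrapper around :class:`OutcomeAnalysis`."""
    model = OutcomeAnalysis(records, hrdsig_calls, brca_palb2_mutant)
    return model.fit(endpoint=endpoint, seed=seed).table


def brca_palb2_mutant_series(statuses: pd.DataFrame) -> pd.Series:
    """Per-sample flag: any pathogenic alteration in BRCA1, BRCA2 or PALB2."""
    sub = statuses[statuses["gene"].isin(BRCA_PALB2)]
    return (
        sub.assign(mut=sub["status"] != "wildtype")
        .groupby("sample")["mut"]
        .any()
    )
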