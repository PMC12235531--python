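"""Secondary matched cohort analysis: enrollment, CEM weights, margins.

Arms are defined at enrollment after the formulary window opens: patients
with any fluticasone-salmeterol DPI fill on/after the window start are
``switched`` (enrolled at the first such fill); patients with controller
fills after the window start but never a DPI fill are ``not_switched``
(enrolled at their first post-window controller fill). Baseline covariates
are measured over the 365 days before enrollment.

Coarsened exact matching (CEM): patients are grouped by a coarsened
covariate signature; strata lacking either arm are discarded; switched
patients keep weight 1 and controls in stratum s get
(m_Ts / m_Cs) * (m_C / m_T), so the weighted control sample reproduces the
switched arm's stratum distribution and the weighted control total equals
the matched control count.

Outcomes at 90/180-day horizons are estimated by weighted logistic (binary)
or Poisson (fill counts) regression on arm plus the ten baseline
covariates; predictive margins average model predictions with the arm set
uniformly to each value over all weighted patients, the absolute difference
is the margin difference, the ratio measure is the exponentiated arm
coefficient, and CIs come from the delta method on the coefficient
covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from . import timegrid as tg
from .config import DEFAULT_FORMULARY_WINDOW, DEFAULT_STUDY_END, \
    DEFAULT_STUDY_START
from .errors import EstimationError, InputError
from .exposure import CONTROLLER_PRODUCTS
from .io import parse_region_timeline
from .outcomes import CauseClassifier, DEFAULT_CLASSIFIER, classify_codes, \
    round_half_up

logger = logging.getLogger(__name__)

Z95 = 1.96

BASELINE_COVARIATES = ("age", "sex", "copd", "asthma", "ed_prior_year",
                       "hosp_prior_year", "albuterol_fills_prior_year",
                       "prednisone_prior_year", "smoking", "region")

COUNT_OUTCOMES = ("albuterol", "prednisone")
BINARY_OUTCOMES = ("ed_all", "ed_respiratory", "ed_pneumonia",
                   "hosp_all", "hosp_respiratory", "hosp_pneumonia",
                   "mortality")
COHORT_OUTCOMES = COUNT_OUTCOMES + BINARY_OUTCOMES


# --------------------------------------------------------------------------
# enrollment

def enroll(patients: pd.DataFrame, fills: pd.DataFrame, events: pd.DataFrame,
           formulary_window=DEFAULT_FORMULARY_WINDOW, *,
           lookback_days: int = 365) -> pd.DataFrame:
    """One enrollment record per eligible patient (arm, date, baseline)."""
    ws = pd.Timestamp(formulary_window[0])
    f = fills.copy()
    f["fill_date"] = pd.to_datetime(f["fill_date"])
    post = f[(f["fill_date"] >= ws) & f["product"].isin(CONTROLLER_PRODUCTS)]
    first_fs = post[post["product"] == "fs_dpi"].groupby("patient_id")[
        "fill_date"].min()
    non_fs = post[post["product"] != "fs_dpi"]
    first_non_fs = non_fs.groupby("patient_id")["fill_date"].min()
    switched = first_fs.rename("enrollment_date").to_frame()
    switched["arm"] = "switched"
    controls = first_non_fs[~first_non_fs.index.isin(first_fs.index)] \
        .rename("enrollment_date").to_frame()
    controls["arm"] = "not_switched"
    enr = pd.concat([switched, controls]).reset_index()
    n_excluded = patients["patient_id"].nunique() - len(enr)
    if n_excluded > 0:
        logger.info("enrollment excluded %d patients without post-window "
                    "controller fills", n_excluded)

    p = patients.set_index("patient_id")
    enr = enr.merge(
        p[["birth_date", "sex", "copd", "asthma", "smoking", "death_date",
           "region_timeline"]],
        left_on="patient_id", right_index=True, how="left")
    enr["age"] = ((enr["enrollment_date"] - pd.to_datetime(enr["birth_date"]))
                  .dt.days / tg.DAYS_PER_YEAR).astype(int)
    enr["region"] = [
        _region_at(tl, d) for tl, d in
        zip(enr["region_timeline"], enr["enrollment_date"])]

    # prior-year utilization
    lb = pd.Timedelta(days=lookback_days)
    fm = f.merge(enr[["patient_id", "enrollment_date"]], on="patient_id")
    in_win = (fm["fill_date"] < fm["enrollment_date"]) & \
        (fm["fill_date"] >= fm["enrollment_date"] - lb)
    alb = fm[in_win & fm["product"].isin(("albuterol_mdi", "albuterol_neb"))] \
        .groupby("patient_id").size()
    pred = fm.loc[in_win & (fm["product"] == "prednisone"), "patient_id"].unique()
    e = events.copy()
    if len(e):
        e["event_date"] = pd.to_datetime(e["event_date"])
        em = e.merge(enr[["patient_id", "enrollment_date"]], on="patient_id")
        in_win = (em["event_date"] < em["enrollment_date"]) & \
            (em["event_date"] >= em["enrollment_date"] - lb)
        ed = em.loc[in_win & (em["encounter"] == "ed_visit"),
                    "patient_id"].unique()
        hosp = em.loc[in_win & (em["encounter"] == "hospitalization"),
                      "patient_id"].unique()
    else:
        ed = hosp = np.array([], dtype=object)
    enr["albuterol_fills_prior_year"] = enr["patient_id"].map(alb).fillna(0) \
        .astype(int)
    enr["prednisone_prior_year"] = enr["patient_id"].isin(pred)
    enr["ed_prior_year"] = enr["patient_id"].isin(ed)
    enr["hosp_prior_year"] = enr["patient_id"].isin(hosp)
    return enr.drop(columns=["region_timeline"])


def _region_at(timeline_str, date):
    tl = parse_region_timeline(timeline_str)
    region = tl[0][1]
    for s, r in tl:
        if s <= date:
            region = r
        else:
            break
    return region


# --------------------------------------------------------------------------
# coarsened exact matching

@dataclass(frozen=True)
class CoarseningRules:
    """Bin edges for continuous/count covariates; categoricals pass as-is."""

    age_bin_years: int = 10
    albuterol_bin_edges: tuple = (0, 1, 4, 7)  # 0, 1-3, 4-6, >=7

    def signature(self, enr: pd.DataFrame) -> pd.Series:
        age_bin = (enr["age"] // self.age_bin_years).astype(int)
        alb = np.searchsorted(np.asarray(self.albuterol_bin_edges),
                              enr["albuterol_fills_prior_year"].to_numpy(),
                              side="right") - 1
        parts = [age_bin.astype(str), enr["sex"].astype(str),
                 enr["copd"].astype(str), enr["asthma"].astype(str),
                 enr["ed_prior_year"].astype(str),
                 enr["hosp_prior_year"].astype(str),
                 pd.Series(alb, index=enr.index).astype(str),
                 enr["prednisone_prior_year"].astype(str),
                 enr["smoking"].astype(str), enr["region"].astype(str)]
        sig = parts[0]
        for part in parts[1:]:
            sig = sig + "|" + part
        return sig


def cem_weights(enrollments: pd.DataFrame,
                rules: CoarseningRules = None) -> pd.DataFrame:
    """CEM weights: switched weight 1; controls reweighted within strata."""
    rules = rules or CoarseningRules()
    cov_cols = [c for c in BASELINE_COVARIATES if c in enrollments.columns]
    if enrollments[cov_cols].isna().any().any():
        raise InputError("baseline covariates contain missing values")
    sig = rules.signature(enrollments)
    df = pd.DataFrame({"patient_id": enrollments["patient_id"].to_numpy(),
                       "arm": enrollments["arm"].to_numpy(),
                       "stratum": sig.to_numpy()})
    counts = df.pivot_table(index="stratum", columns="arm", values="patient_id",
                            aggfunc="count", fill_value=0)
    for arm in ("switched", "not_switched"):
        if arm not in counts.columns:
            counts[arm] = 0
    matched_strata = counts.index[(counts["switched"] > 0)
                                  & (counts["not_switched"] > 0)]
    m_t = int(counts.loc[matched_strata, "switched"].sum())
    m_c = int(counts.loc[matched_strata, "not_switched"].sum())
    if m_t == 0 or m_c == 0:
        raise EstimationError("an arm is empty after matching")
    n_unmatched = len(df) - int(
        df["stratum"].isin(matched_strata).sum())
    if n_unmatched:
        logger.info("CEM discarded %d patients in unmatched strata",
                    n_unmatched)
    df["matched"] = df["stratum"].isin(matched_strata)
    ts = df["stratum"].map(counts["switched"])
    cs = df["stratum"].map(counts["not_switched"])
    w = np.where(~df["matched"], 0.0,
                 np.where(df["arm"] == "switched", 1.0,
                          (ts / cs) * (m_c / m_t)))
    df["weight"] = w
    return df[["patient_id", "stratum", "matched", "weight"]]


def smd(enrollments: pd.DataFrame, weights: pd.Series, covariate: str) -> float:
    """Weighted standardized mean difference for one covariate.

    Weighted arm means are compared on the scale of the unweighted pooled
    standard deviation sqrt((s_T^2 + s_C^2)/2). Categorical covariates are
    expanded to level indicators and the maximum |SMD| over levels is
    returned. A zero pooled SD yields 0 when the means agree and NaN
    otherwise.
    """
    col = enrollments[covariate]
    if col.dtype == bool or not pd.api.types.is_numeric_dtype(col):
        levels = col.unique()
        if len(levels) <= 2 and col.dtype == bool:
            values = {None: col.astype(float)}
        else:
            values = {lv: (col == lv).astype(float) for lv in sorted(map(str, levels))}
            col = col.astype(str)
            values = {lv: (col == lv).astype(float) for lv in sorted(col.unique())}
        return max(abs(_smd_numeric(enrollments["arm"], v, weights))
                   for v in values.values())
    return _smd_numeric(enrollments["arm"], col.astype(float), weights)


def _smd_numeric(arm: pd.Series, x: pd.Series, w: pd.Series) -> float:
    t = (arm == "switched").to_numpy()
    x = x.to_numpy(dtype=float)
    w = np.asarray(w, dtype=float)
    wt, wc = w[t], w[~t]
    if wt.sum() == 0 or wc.sum() == 0:
        raise EstimationError("an arm has zero total weight")
    mean_t = np.average(x[t], weights=wt)
    mean_c = np.average(x[~t], weights=wc)
    sd_t = np.std(x[t], ddof=1) if t.sum() > 1 else 0.0
    sd_c = np.std(x[~t], ddof=1) if (~t).sum() > 1 else 0.0
    pooled = np.sqrt((sd_t ** 2 + sd_c ** 2) / 2)
    if pooled == 0:
        return 0.0 if np.isclose(mean_t, mean_c) else float("nan")
    return float((mean_t - mean_c) / pooled)


def balance_table(enrollments: pd.DataFrame, weights: pd.DataFrame,
                  covariates=BASELINE_COVARIATES) -> pd.DataFrame:
    """SMD before (unit weights) and after CEM weighting, per covariate."""
    merged = enrollments.merge(weights[["patient_id", "weight"]],
                               on="patient_id")
    pre_w = pd.Series(1.0, index=merged.index)
    post = merged[merged["weight"] > 0]
    rows = []
    for cov in covariates:
        rows.append({
            "covariate": cov,
            "smd_before": smd(merged, pre_w, cov),
            "smd_after": smd(post, post["weight"], cov),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# outcome measurement over a horizon

def measure_outcomes(enrollments: pd.DataFrame, fills: pd.DataFrame,
                     events: pd.DataFrame, horizon_days: int, *,
                     study_end=DEFAULT_STUDY_END,
                     classifier: CauseClassifier = DEFAULT_CLASSIFIER,
                     doses_per_equivalent: float = 100.0) -> pd.DataFrame:
    """Per-patient outcome values over [enrollment, enrollment + horizon).

    Patients whose horizon extends past the study end are excluded (their
    outcomes are not fully observable); death does not censor event
    outcomes, and mortality is its own binary outcome.
    """
    limit = pd.Timestamp(study_end) + pd.Timedelta(days=1)
    enr = enrollments.copy()
    enr["enrollment_date"] = pd.to_datetime(enr["enrollment_date"])
    h = pd.Timedelta(days=horizon_days)
    enr = enr[enr["enrollment_date"] + h <= limit]
    out = enr[["patient_id"]].copy().set_index("patient_id")
    for oc in COHORT_OUTCOMES:
        out[oc] = 0
    windows = enr.set_index("patient_id")["enrollment_date"]

    f = fills.merge(windows.rename("enr"), left_on="patient_id",
                    right_index=True)
    fd = pd.to_datetime(f["fill_date"])
    in_win = (fd >= f["enr"]) & (fd < f["enr"] + h)
    alb_mdi = f[in_win & (f["product"] == "albuterol_mdi")] \
        .groupby("patient_id").size()
    neb = f[in_win & (f["product"] == "albuterol_neb")]
    if len(neb):
        if neb["neb_doses"].isna().any():
            raise InputError("nebulized albuterol fill lacks neb_doses")
        neb_eq = neb.groupby("patient_id")["neb_doses"] \
            .sum().astype(float) / doses_per_equivalent
    else:
        neb_eq = pd.Series(dtype=float)
    alb = alb_mdi.reindex(out.index, fill_value=0) \
        + pd.Series(round_half_up(neb_eq.reindex(out.index, fill_value=0.0)),
                    index=out.index)
    out["albuterol"] = alb.astype(int)
    out["prednisone"] = f[in_win & (f["product"] == "prednisone")] \
        .groupby("patient_id").size().reindex(out.index, fill_value=0)

    if len(events):
        e = events.merge(windows.rename("enr"), left_on="patient_id",
                         right_index=True)
        edt = pd.to_datetime(e["event_date"])
        in_win = (edt >= e["enr"]) & (edt < e["enr"] + h)
        e = e[in_win]
        cause = classify_codes(e["principal_icd10"], classifier)
        is_ed = (e["encounter"] == "ed_visit").to_numpy()
        is_hosp = (e["encounter"] == "hospitalization").to_numpy()
        for name, mask in (
                ("ed_all", is_ed),
                ("ed_respiratory", is_ed & np.isin(cause, ("copd", "asthma"))),
                ("ed_pneumonia", is_ed & (cause == "pneumonia")),
                ("hosp_all", is_hosp),
                ("hosp_respiratory",
                 is_hosp & np.isin(cause, ("copd", "asthma"))),
                ("hosp_pneumonia", is_hosp & (cause == "pneumonia"))):
            pids = e.loc[mask, "patient_id"].unique()
            out[name] = out.index.isin(pids).astype(int)
    death = pd.to_datetime(enr.set_index("patient_id")["death_date"])
    died = (death.notna() & (death >= windows) & (death < windows + h))
    out["mortality"] = died.reindex(out.index, fill_value=False).astype(int)
    return out.reset_index()


# --------------------------------------------------------------------------
# weighted regression with predictive margins

@dataclass
class CohortMargins:
    """Adjusted arm levels, ratio measure and absolute difference."""

    outcome: str
    horizon: int
    family: str  # 'binomial' or 'poisson'
    level_switched: float
    level_not_switched: float
    level_switched_ci: tuple
    level_not_switched_ci: tuple
    ratio: float
    ratio_ci: tuple
    absolute_difference: float
    absolute_difference_ci: tuple
    n_switched: int
    n_not_switched: int
    scale: str  # 'percent' for binary outcomes, 'count' for fills

    def summary(self) -> str:
        unit = "%" if self.scale == "percent" else " fills"
        measure = "OR" if self.family == "binomial" else "IRR"
        return (
            f"{self.outcome} at {self.horizon} days: "
            f"switched {self.level_switched:.2f}{unit} vs "
            f"not switched {self.level_not_switched:.2f}{unit}; "
            f"{measure} {self.ratio:.2f} "
            f"({self.ratio_ci[0]:.2f} to {self.ratio_ci[1]:.2f}); "
            f"absolute difference {self.absolute_difference:.2f} "
            f"({self.absolute_difference_ci[0]:.2f} to "
            f"{self.absolute_difference_ci[1]:.2f})")


class CohortOutcomeModel:
    """Weighted GLM for one cohort outcome at one horizon.

    ``fit`` runs logistic (binary) or Poisson (count) regression on arm plus
    the baseline covariates in the CEM-weighted population and computes
    predictive margins.
    """

    def __init__(self, enrollments: pd.DataFrame, weights: pd.DataFrame,
                 outcome_values: pd.DataFrame, outcome: str, horizon: int,
                 adjust: bool = True):
        self.outcome = outcome
        self.horizon = horizon
        self.family = "poisson" if outcome in COUNT_OUTCOMES else "binomial"
        df = enrollments.merge(weights[["patient_id", "weight"]],
                               on="patient_id")
        df = df.merge(outcome_values[["patient_id", outcome]], on="patient_id")
        df = df[df["weight"] > 0].reset_index(drop=True)
        if df.empty or df["arm"].nunique() < 2:
            raise EstimationError(
                f"outcome {outcome!r}: an arm is empty in the weighted sample")
        self._df = df
        cols = {"const": np.ones(len(df)),
                "arm": (df["arm"] == "switched").astype(float)}
        if adjust:
            cols["age"] = df["age"].astype(float)
            cols["sex[female]"] = (df["sex"] == "female").astype(float)
            for b in ("copd", "asthma", "ed_prior_year", "hosp_prior_year",
                      "prednisone_prior_year"):
                cols[b] = df[b].astype(float)
            cols["albuterol_fills_prior_year"] = \
                df["albuterol_fills_prior_year"].astype(float)
            for lv in ("former", "never"):  # current = reference
                cols[f"smoking[{lv}]"] = (df["smoking"] == lv).astype(float)
            regions = sorted(df["region"].unique())
            for lv in regions[1:]:
                cols[f"region[{lv}]"] = (df["region"] == lv).astype(float)
        self._X = pd.DataFrame(cols)
        self._y = df[outcome].to_numpy(dtype=float)
        self._w = df["weight"].to_numpy(dtype=float)

    def fit(self) -> CohortMargins:
        if self._y.sum() == 0 or \
                (self.family == "binomial" and (self._y == 1).all()):
            raise EstimationError(
                f"outcome {self.outcome!r}: degenerate outcome in the "
                f"weighted sample (non-estimable)")
        fam = sm.families.Poisson() if self.family == "poisson" \
            else sm.families.Binomial()
        glm = sm.GLM(self._y, self._X, family=fam, freq_weights=self._w)
        try:
            res = glm.fit(maxiter=200, tol=1e-10)
        except Exception as exc:  # perfect separation, singular matrix, ...
            raise EstimationError(
                f"outcome {self.outcome!r}: GLM failed: {exc}") from exc
        beta = res.params.to_numpy()
        cov = res.cov_params().to_numpy()
        arm_idx = self._X.columns.get_loc("arm")
        X = self._X.to_numpy(dtype=float)
        wsum = self._w.sum()
        margins, grads = {}, {}
        for a in (0.0, 1.0):
            Xa = X.copy()
            Xa[:, arm_idx] = a
            eta = Xa @ beta
            if self.family == "binomial":
                mu = expit(eta)
                dmu = mu * (1 - mu)
            else:
                mu = np.exp(eta)
                dmu = mu
            margins[a] = float(np.sum(self._w * mu) / wsum)
            grads[a] = (self._w[:, None] * dmu[:, None] * Xa).sum(axis=0) / wsum
        scale_factor = 100.0 if self.family == "binomial" else 1.0
        level = {a: margins[a] * scale_factor for a in margins}
        level_ci = {}
        for a in margins:
            se = float(np.sqrt(grads[a] @ cov @ grads[a]))
            level_ci[a] = ((margins[a] - Z95 * se) * scale_factor,
                           (margins[a] + Z95 * se) * scale_factor)
        gdiff = grads[1.0] - grads[0.0]
        se_diff = float(np.sqrt(gdiff @ cov @ gdiff))
        diff = level[1.0] - level[0.0]
        diff_ci = (diff - Z95 * se_diff * scale_factor,
                   diff + Z95 * se_diff * scale_factor)
        b_arm = float(beta[arm_idx])
        se_arm = float(np.sqrt(cov[arm_idx, arm_idx]))
        with np.errstate(over="ignore"):  # quasi-separation -> inf CI bound
            ratio_ci = (float(np.exp(b_arm - Z95 * se_arm)),
                        float(np.exp(b_arm + Z95 * se_arm)))
        arm_counts = self._df["arm"].value_counts()
        return CohortMargins(
            outcome=self.outcome, horizon=self.horizon, family=self.family,
            level_switched=level[1.0], level_not_switched=level[0.0],
            level_switched_ci=level_ci[1.0],
            level_not_switched_ci=level_ci[0.0],
            ratio=float(np.exp(b_arm)),
            ratio_ci=ratio_ci,
            absolute_difference=diff, absolute_difference_ci=diff_ci,
            n_switched=int(arm_counts.get("switched", 0)),
            n_not_switched=int(arm_counts.get("not_switched", 0)),
            scale="percent" if self.family == "binomial" else "count")


def fit_and_margins(enrollments, weights, outcome_values, outcome, horizon,
                    adjust: bool = True) -> CohortMargins:
    """Convenience wrapper: build and fit one CohortOutcomeModel."""
    return CohortOutcomeModel(enrollments, weights, outcome_values, outcome,
                              horizon, adjust=adjust).fit()


@dataclass
class CohortStudyResult:
    """Outcome-by-horizon margins table plus the balance diagnostics."""

    table: pd.DataFrame
    balance: pd.DataFrame
    enrollments: pd.DataFrame
    weights: pd.DataFrame
    margins: dict

    def summary(self) -> str:
        lines = ["Matched cohort study (adjusted predictive margins)"]
        for (oc, h), m in self.margins.items():
            lines.append(m.summary())
        return "\n".join(lines)


def run_cohort_analysis(patients, fills, events, *,
                        rules: CoarseningRules = None, horizons=(90, 180),
                        adjust: bool = True,
                        formulary_window=DEFAULT_FORMULARY_WINDOW,
                        study_end=DEFAULT_STUDY_END,
                        classifier: CauseClassifier = DEFAULT_CLASSIFIER,
                        outcomes=COHORT_OUTCOMES) -> CohortStudyResult:
    """Run the full secondary analysis on claims-shaped tables."""
    enr = enroll(patients, fills, events, formulary_window)
    weights = cem_weights(enr, rules)
    bal = balance_table(enr, weights)
    rows, margins = [], {}
    for h in horizons:
        values = measure_outcomes(enr, fills, events, h, study_end=study_end,
                                  classifier=classifier)
        for oc in outcomes:
            try:
                m = fit_and_margins(enr, weights, values, oc, h,
                                    adjust=adjust)
            except EstimationError as exc:
                logger.warning("cohort outcome %s at %d days not estimable: "
                               "%s", oc, h, exc)
                rows.append({"outcome": oc, "horizon": h,
                             "level_switched": np.nan,
                             "level_not_switched": np.nan,
                             "ratio": np.nan, "ratio_low": np.nan,
                             "ratio_high": np.nan, "abs_diff": np.nan,
                             "abs_diff_low": np.nan, "abs_diff_high": np.nan,
                             "n_switched": 0, "n_not_switched": 0,
                             "scale": "percent" if oc in BINARY_OUTCOMES
                             else "count"})
                continue
            margins[(oc, h)] = m
            rows.append({
                "outcome": oc, "horizon": h,
                "level_switched": m.level_switched,
                "level_not_switched": m.level_not_switched,
                "ratio": m.ratio, "ratio_low": m.ratio_ci[0],
                "ratio_high": m.ratio_ci[1],
                "abs_diff": m.absolute_difference,
                "abs_diff_low": m.absolute_difference_ci[0],
                "abs_diff_high": m.absolute_difference_ci[1],
                "n_switched": m.n_switched,
                "n_not_switched": m.n_not_switched,
                "scale": m.scale,
            })
    return CohortStudyResult(table=pd.DataFrame(rows), balance=bal,
                             enrollments=enr, weights=weights, margins=margins)
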