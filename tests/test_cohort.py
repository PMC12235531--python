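"""Secondary cohort analysis: enrollment, CEM weights, SMD, margins."""

import numpy as np
import pandas as pd
import pytest

from inhalerswitch import CoarseningRules, CohortOutcomeModel, \
    EstimationError, InputError, balance_table, cem_weights, enroll, \
    fit_and_margins, measure_outcomes, run_cohort_analysis, smd

from conftest import make_events, make_fills, make_patient

WINDOW = (pd.Timestamp("2021-07-01").date(), pd.Timestamp("2021-09-30").date())


def _enrollments(n_t, n_c, rng=None, **overrides):
    """Hand-built enrollment table with constant defaults."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n_t + n_c):
        rows.append({
            "patient_id": f"P{i:03d}",
            "arm": "switched" if i < n_t else "not_switched",
            "enrollment_date": pd.Timestamp("2021-10-01"),
            "age": 68, "sex": "male", "copd": True, "asthma": False,
            "ed_prior_year": False, "hosp_prior_year": False,
            "albuterol_fills_prior_year": 2, "prednisone_prior_year": False,
            "smoking": "former", "region": "South",
            "death_date": pd.NaT,
        })
    df = pd.DataFrame(rows)
    for col, values in overrides.items():
        df[col] = values
    return df


def test_enrollment_arm_and_date_rules():
    patients = pd.concat([
        make_patient("X"), make_patient("Y"), make_patient("Z")],
        ignore_index=True)
    fills = pd.concat([
        make_fills("X", [("2021-05-01", "bf_mdi"), ("2021-08-02", "bf_mdi"),
                         ("2021-10-15", "fs_dpi")]),
        make_fills("Y", [("2021-11-01", "other_controller")]),
        make_fills("Z", [("2021-05-01", "bf_mdi")]),  # nothing post-window
    ], ignore_index=True)
    enr = enroll(patients, fills, make_events("X", []), WINDOW)
    enr = enr.set_index("patient_id")
    # X has a post-window DPI fill -> switched, enrolled at that fill
    assert enr.loc["X", "arm"] == "switched"
    assert enr.loc["X", "enrollment_date"] == pd.Timestamp("2021-10-15")
    assert enr.loc["Y", "arm"] == "not_switched"
    assert enr.loc["Y", "enrollment_date"] == pd.Timestamp("2021-11-01")
    assert "Z" not in enr.index


def test_enrollment_baseline_covariates():
    patients = make_patient("X", birth="1951-10-01", timeline="2018-01-01:West")
    fills = pd.concat([
        make_fills("X", [("2021-05-01", "bf_mdi"), ("2021-10-15", "fs_dpi"),
                         ("2021-02-01", "albuterol_mdi"),
                         ("2020-10-20", "albuterol_neb", 30, 100),
                         ("2020-10-01", "albuterol_mdi"),  # outside 365 d
                         ("2021-06-01", "prednisone", 1)]),
    ], ignore_index=True)
    events = make_events("X", [("2021-03-01", "ed_visit", "J449"),
                               ("2019-01-01", "hospitalization", "J189")])
    enr = enroll(patients, fills, events, WINDOW).set_index("patient_id")
    assert enr.loc["X", "age"] == 70
    assert enr.loc["X", "albuterol_fills_prior_year"] == 2
    assert bool(enr.loc["X", "prednisone_prior_year"])
    assert bool(enr.loc["X", "ed_prior_year"])
    assert not bool(enr.loc["X", "hosp_prior_year"])  # too old
    assert enr.loc["X", "region"] == "West"


def test_enrollment_matches_generator_bookkeeping(small_cohort):
    cfg = small_cohort.config
    enr = enroll(small_cohort.patients, small_cohort.fills,
                 small_cohort.events, cfg.formulary_window)
    ws = pd.Timestamp(cfg.formulary_window[0])
    f = small_cohort.fills
    dpi_post = set(f.loc[(f["product"] == "fs_dpi")
                         & (f["fill_date"] >= ws), "patient_id"])
    got_switched = set(enr.loc[enr["arm"] == "switched", "patient_id"])
    assert got_switched == dpi_post
    # every switched patient is a generator-flagged switcher
    truth = small_cohort.truth.set_index("patient_id")
    assert truth.loc[sorted(got_switched), "is_switcher"].all()


def test_cem_weights_worked_example():
    # stratum A: 2 switched / 4 controls; stratum B: 1 / 1
    enr = _enrollments(3, 5)
    enr.loc[:, "region"] = ["South", "South", "West",
                            "South", "South", "South", "South", "West"]
    w = cem_weights(enr).set_index("patient_id")
    merged = enr.set_index("patient_id").join(w[["weight"]])
    controls = merged[merged["arm"] == "not_switched"]
    assert np.allclose(
        controls.loc[controls["region"] == "South", "weight"], 5 / 6)
    assert np.allclose(
        controls.loc[controls["region"] == "West", "weight"], 5 / 3)
    assert np.allclose(merged.loc[merged["arm"] == "switched", "weight"], 1.0)
    # weight conservation: weighted controls = matched control count
    assert controls["weight"].sum() == pytest.approx(5.0)


def test_cem_identical_covariates_all_weights_one():
    w = cem_weights(_enrollments(4, 6))
    assert np.allclose(w["weight"], 1.0)


def test_cem_unmatched_stratum_gets_zero_weight():
    enr = _enrollments(2, 3)
    enr.loc[enr["patient_id"] == "P004", "region"] = "Northeast"  # control only
    w = cem_weights(enr).set_index("patient_id")
    assert w.loc["P004", "weight"] == 0.0
    assert not w.loc["P004", "matched"]


def test_cem_missing_baseline_rejected_and_empty_arm_raises():
    enr = _enrollments(2, 2)
    enr.loc[0, "smoking"] = np.nan
    with pytest.raises(InputError):
        cem_weights(enr)
    enr2 = _enrollments(2, 2)
    enr2.loc[enr2["arm"] == "switched", "region"] = "West"  # disjoint strata
    with pytest.raises(EstimationError):
        cem_weights(enr2)


def test_cem_weight_conservation_random(small_cohort):
    enr = enroll(small_cohort.patients, small_cohort.fills,
                 small_cohort.events, small_cohort.config.formulary_window)
    w = cem_weights(enr)
    merged = enr.merge(w, on="patient_id")
    matched_controls = merged[(merged["arm"] == "not_switched")
                              & merged["matched"]]
    assert matched_controls["weight"].sum() == pytest.approx(
        len(matched_controls), rel=1e-12)
    # local balance: weighted stratum totals agree between arms
    g = merged[merged["weight"] > 0].groupby(["stratum", "arm"])[
        "weight"].sum().unstack(fill_value=0.0)
    ratio = g["not_switched"] * (g["switched"].sum()
                                 / g["not_switched"].sum())
    assert np.allclose(ratio, g["switched"])


def test_smd_identical_distributions_zero():
    enr = _enrollments(5, 5)
    w = pd.Series(1.0, index=enr.index)
    assert smd(enr, w, "age") == 0.0
    assert smd(enr, w, "smoking") == 0.0


def test_smd_hand_computed_example():
    enr = _enrollments(2, 2, age=[60, 70, 50, 80])
    w = pd.Series(1.0, index=enr.index)
    # means 65 vs 65? no: switched (60,70)=65, controls (50,80)=65 -> 0
    assert smd(enr, w, "age") == pytest.approx(0.0)
    enr2 = _enrollments(2, 2, age=[60, 70, 75, 85])
    sd_t = np.std([60, 70], ddof=1)
    sd_c = np.std([75, 85], ddof=1)
    expected = (65 - 80) / np.sqrt((sd_t ** 2 + sd_c ** 2) / 2)
    assert smd(enr2, w, "age") == pytest.approx(expected)


def test_smd_on_coarsened_covariates_is_zero_after_cem(small_cohort):
    rules = CoarseningRules()
    enr = enroll(small_cohort.patients, small_cohort.fills,
                 small_cohort.events, small_cohort.config.formulary_window)
    w = cem_weights(enr, rules)
    merged = enr.merge(w, on="patient_id")
    post = merged[merged["weight"] > 0].copy()
    post["age_bin"] = post["age"] // rules.age_bin_years
    assert abs(smd(post, post["weight"], "age_bin")) < 1e-12
    assert abs(smd(post, post["weight"], "smoking")) < 1e-12
    assert abs(smd(post, post["weight"], "region")) < 1e-12


def test_balance_table_improves_after_weighting(small_cohort):
    enr = enroll(small_cohort.patients, small_cohort.fills,
                 small_cohort.events, small_cohort.config.formulary_window)
    w = cem_weights(enr)
    bal = balance_table(enr, w)
    assert set(bal["covariate"]) >= {"age", "sex", "smoking", "region"}
    assert (bal["smd_after"].abs() <= bal["smd_before"].abs() + 0.05).all()


def test_margins_equal_raw_proportions_without_covariates():
    rng = np.random.default_rng(5)
    enr = _enrollments(40, 60)
    w = pd.DataFrame({"patient_id": enr["patient_id"], "weight": 1.0})
    y = (rng.random(100) < np.where(enr["arm"] == "switched", 0.4, 0.25)
         ).astype(int)
    values = pd.DataFrame({"patient_id": enr["patient_id"], "hosp_all": y})
    m = CohortOutcomeModel(enr, w, values, "hosp_all", 180,
                           adjust=False).fit()
    p_t = y[:40].mean()
    p_c = y[40:].mean()
    assert m.level_switched == pytest.approx(100 * p_t, abs=1e-8)
    assert m.level_not_switched == pytest.approx(100 * p_c, abs=1e-8)
    # odds ratio equals the contingency-table cross-product ratio
    or_hand = (p_t / (1 - p_t)) / (p_c / (1 - p_c))
    assert m.ratio == pytest.approx(or_hand, rel=1e-6)
    # the absolute difference is exactly the difference of the margins
    assert m.absolute_difference == m.level_switched - m.level_not_switched


def test_margin_difference_identity_on_fitted_model(small_cohort):
    cfg = small_cohort.config
    res = run_cohort_analysis(small_cohort.patients, small_cohort.fills,
                              small_cohort.events, horizons=(180,),
                              formulary_window=cfg.formulary_window,
                              study_end=cfg.study_end)
    for m in res.margins.values():
        assert m.absolute_difference == pytest.approx(
            m.level_switched - m.level_not_switched, abs=1e-12)


def test_measure_outcomes_windows_and_mortality():
    enr = _enrollments(1, 1)
    enr.loc[0, "death_date"] = pd.Timestamp("2021-12-01")  # within 90 d
    enr.loc[1, "death_date"] = pd.Timestamp("2022-08-01")  # beyond 180 d
    fills = make_fills("P000", [("2021-10-05", "albuterol_mdi"),
                                ("2022-05-01", "albuterol_mdi")])
    events = make_events("P001", [("2021-11-01", "hospitalization", "J189")])
    out = measure_outcomes(enr, fills, events, 90,
                           study_end=pd.Timestamp("2022-12-31").date())
    out = out.set_index("patient_id")
    assert out.loc["P000", "albuterol"] == 1  # second fill beyond horizon
    assert out.loc["P000", "mortality"] == 1
    assert out.loc["P001", "mortality"] == 0
    assert out.loc["P001", "hosp_pneumonia"] == 1
    assert out.loc["P001", "hosp_all"] == 1


def test_measure_outcomes_drops_incomplete_followup():
    enr = _enrollments(1, 1)
    enr.loc[1, "enrollment_date"] = pd.Timestamp("2022-11-01")
    out = measure_outcomes(enr, make_fills("P000", [("2021-10-05",
                                                     "albuterol_mdi")]),
                           make_events("P000", []), 180,
                           study_end=pd.Timestamp("2022-12-31").date())
    assert set(out["patient_id"]) == {"P000"}


def test_null_cohort_difference_cis_mostly_cover_zero(null_cohort):
    cfg = null_cohort.config
    res = run_cohort_analysis(null_cohort.patients, null_cohort.fills,
                              null_cohort.events, horizons=(180,),
                              formulary_window=cfg.formulary_window,
                              study_end=cfg.study_end)
    t = res.table.dropna(subset=["abs_diff"])
    misses = ((t["abs_diff_low"] > 0) | (t["abs_diff_high"] < 0)).sum()
    assert misses <= 2


def test_weights_only_variant_agrees_with_adjusted_on_null(null_cohort):
    cfg = null_cohort.config
    kw = dict(horizons=(180,), formulary_window=cfg.formulary_window,
              study_end=cfg.study_end, outcomes=("hosp_all", "mortality"))
    adj = run_cohort_analysis(null_cohort.patients, null_cohort.fills,
                              null_cohort.events, adjust=True, **kw)
    unadj = run_cohort_analysis(null_cohort.patients, null_cohort.fills,
                                null_cohort.events, adjust=False, **kw)
    both = adj.table.merge(unadj.table, on=["outcome", "horizon"],
                           suffixes=("_adj", "_w"))
    both = both.dropna(subset=["abs_diff_adj", "abs_diff_w"])
    # on CEM-balanced null data the two estimators target the same quantity
    for _, r in both.iterrows():
        joint = np.hypot(r["abs_diff_adj"] - r["abs_diff_low_adj"],
                         r["abs_diff_w"] - r["abs_diff_low_w"]) / 1.96
        assert abs(r["abs_diff_adj"] - r["abs_diff_w"]) < 2.5 * joint * 1.96


def test_consistency_interval_width_shrinks_with_n():
    from inhalerswitch import CohortConfig, generate_cohort
    widths = {}
    for n in (800, 3200):
        c = generate_cohort(CohortConfig(n_patients=n, seed=29))
        res = run_cohort_analysis(c.patients, c.fills, c.events,
                                  horizons=(180,),
                                  outcomes=("hosp_all",))
        row = res.table.iloc[0]
        widths[n] = row["abs_diff_high"] - row["abs_diff_low"]
        assert row["abs_diff_low"] <= row["abs_diff"] <= row["abs_diff_high"]
    assert widths[3200] < widths[800]
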