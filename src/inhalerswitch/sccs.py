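"""Within-person (self-controlled case series) conditional Poisson analysis.

The estimand is the incidence rate ratio (IRR) of each outcome during
fluticasone-salmeterol DPI exposure versus budesonide-formoterol MDI
exposure, estimated by conditioning a per-patient fixed-effects Poisson
model on each patient's total event count. For patient i with intervals j
of length t_ij, covariates x_ij and event counts y_ij, conditioning yields
the multinomial log-likelihood

    l(beta) = sum_i sum_j y_ij * log p_ij,
    p_ij = t_ij exp(x_ij' beta) / sum_k t_ik exp(x_ik' beta),

which eliminates all time-invariant patient characteristics. Only patients
with at least one event and at least two intervals contribute. Covariates
are exposure dummies (MDI reference; uncovered "neither" time is retained
as a third level with its own coefficient) plus 5-year age-band,
calendar-quarter, region, and quarter-by-region dummies. Columns with no
within-patient variation, and columns collinear within-patient with earlier
ones, are dropped deterministically in input order. Newton-Raphson with
step-halving maximizes the likelihood; standard errors come from the
observed information, and Wald 95% intervals use the normal 1.96 critical
value. An exposure level with zero events among informative patients has an
infinite MLE and is flagged non-estimable instead of being reported as a
huge finite number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import DEFAULT_FORMULARY_WINDOW, DEFAULT_STUDY_END, \
    DEFAULT_STUDY_START, SCCS_OUTCOMES
from .errors import ConvergenceError, EstimationError, InputError
from .exposure import DPI, GracePolicy, MDI, NEITHER, build_exposure_table, \
    gap_exclusion, sccs_inclusion
from .outcomes import CauseClassifier, DEFAULT_CLASSIFIER, classify_codes
from .person_time import SCCSDesign, build_person_time

logger = logging.getLogger(__name__)

REGION_ORDER = ("South", "Midwest", "West", "Northeast")
QUARTER_ORDER = (1, 2, 3, 4)
Z95 = 1.96


# --------------------------------------------------------------------------
# likelihood machinery

def _group_ptr(groups: np.ndarray) -> np.ndarray:
    """Boundaries of consecutive runs in a sorted integer group array."""
    n = groups[-1] + 1 if len(groups) else 0
    return np.searchsorted(groups, np.arange(n + 1))


def _run_ptr(groups: np.ndarray) -> np.ndarray:
    """Run boundaries of a grouped (not necessarily dense) id array."""
    n = len(groups)
    if n == 0:
        return np.zeros(1, dtype=np.int64)
    return np.concatenate([[0], np.flatnonzero(np.diff(groups) != 0) + 1,
                           [n]]).astype(np.int64)


def _softmax_by_group(eta, ptr, sizes):
    gmax = np.maximum.reduceat(eta, ptr[:-1])
    z = np.exp(eta - np.repeat(gmax, sizes))
    denom = np.add.reduceat(z, ptr[:-1])
    return z / np.repeat(denom, sizes)


def conditional_loglik(beta, X, y, logt, ptr, sizes):
    """The written conditional (multinomial) log-likelihood.

    Returns -inf when an event interval has zero probability (an
    overshooting Newton candidate); step-halving then rejects the step.
    """
    p = _softmax_by_group(logt + X @ beta, ptr, sizes)
    mask = y > 0
    with np.errstate(divide="ignore"):
        return float(np.sum(y[mask] * np.log(p[mask])))


def _fit_newton(X, y, logt, ptr, sizes, max_iter=50, tol=1e-8):
    if X.shape[1] == 0:  # nothing estimable: intercept-free null model
        ll = conditional_loglik(np.zeros(0), X, y, logt, ptr, sizes)
        return np.zeros(0), np.zeros((0, 0)), ll, 0, True
    n_events = float(y.sum())
    gtol = tol * max(1.0, n_events)
    n_g = np.add.reduceat(y, ptr[:-1])
    beta = np.zeros(X.shape[1])
    ll = conditional_loglik(beta, X, y, logt, ptr, sizes)
    converged, it = False, 0
    for it in range(1, max_iter + 1):
        p = _softmax_by_group(logt + X @ beta, ptr, sizes)
        mu = np.repeat(n_g, sizes) * p
        grad = X.T @ (y - mu)
        if np.abs(grad).max() < gtol:
            converged = True
            break
        gbar = np.empty((len(sizes), X.shape[1]))
        pX = p[:, None] * X
        for j in range(X.shape[1]):
            gbar[:, j] = np.add.reduceat(pX[:, j], ptr[:-1])
        H = X.T @ (mu[:, None] * X) - (gbar * n_g[:, None]).T @ gbar
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            H = H + np.eye(X.shape[1]) * (1e-8 * np.trace(H) / X.shape[1] + 1e-12)
            step = np.linalg.solve(H, grad)
        # step-halving safeguards the ascent
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new = conditional_loglik(cand, X, y, logt, ptr, sizes)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll = beta + scale * step, ll_new
    else:
        raise ConvergenceError(
            f"Newton did not converge in {max_iter} iterations "
            f"(|grad|_max={np.abs(grad).max():.3e}, tol={gtol:.3e})")
    # observed information at the optimum
    p = _softmax_by_group(logt + X @ beta, ptr, sizes)
    mu = np.repeat(n_g, sizes) * p
    gbar = np.empty((len(sizes), X.shape[1]))
    pX = p[:, None] * X
    for j in range(X.shape[1]):
        gbar[:, j] = np.add.reduceat(pX[:, j], ptr[:-1])
    H = X.T @ (mu[:, None] * X) - (gbar * n_g[:, None]).T @ gbar
    cov = np.linalg.inv(H)
    return beta, cov, ll, it, converged


def _drop_collinear(X: np.ndarray, names, ptr, sizes):
    """Sequential first-kept column selection on within-patient variation.

    A column whose within-patient-demeaned version lies (numerically) in the
    span of earlier kept demeaned columns is unidentified in the conditional
    likelihood and is dropped; this removes patient-constant covariates and
    the over-parameterized part of quarter+region+interaction in one pass.
    """
    means = np.add.reduceat(X, ptr[:-1], axis=0) / sizes[:, None]
    Xd = X - np.repeat(means, sizes, axis=0)
    kept, dropped, basis = [], [], []
    for j in range(X.shape[1]):
        v = Xd[:, j].copy()
        for q in basis:
            v -= (q @ v) * q
        nv = np.linalg.norm(v)
        if nv > 1e-9 * max(1.0, np.linalg.norm(Xd[:, j])):
            basis.append(v / nv)
            kept.append(j)
        else:
            dropped.append(names[j])
    return kept, dropped


# --------------------------------------------------------------------------
# model / results objects

class SCCSModel:
    """Conditional Poisson SCCS model for one outcome.

    Built from a person-time interval table (see
    :func:`inhalerswitch.person_time.build_person_time`); ``fit`` returns an
    :class:`SCCSResults`.
    """

    def __init__(self, person_time: pd.DataFrame, outcome: str,
                 covariates=("age_band", "quarter", "region", "quarter:region"),
                 extra_columns=(), event_stratum=None):
        if outcome not in person_time.columns:
            raise InputError(f"person-time table has no outcome column {outcome!r}")
        self.outcome = outcome
        pt = person_time
        totals = pt.groupby("patient_id")[outcome].transform("sum")
        n_int = pt.groupby("patient_id")[outcome].transform("size")
        keep = (totals > 0) & (n_int >= 2)
        if event_stratum is not None:
            keep &= (totals == 1) if str(event_stratum) == "1" else (totals >= 2)
        pt = pt.loc[keep]
        if pt.empty:
            raise EstimationError(
                f"no informative patients for outcome {outcome!r}")
        pt = pt.sort_values(["patient_id", "start_day"], kind="stable") \
            if "start_day" in pt.columns else pt.sort_values("patient_id",
                                                             kind="stable")
        self.n_informative = pt["patient_id"].nunique()
        self.n_events = int(pt[outcome].sum())

        cols, names = [], []

        def add(col, name):
            cols.append(np.asarray(col, dtype=float))
            names.append(name)

        exposure = pt["exposure"].to_numpy()
        add(exposure == DPI, "dpi_fs")
        add(exposure == NEITHER, "neither")
        if "age_band" in covariates and "age_band" in pt.columns:
            # reference = band with the most events, so sparse outcomes do
            # not end up contrasted against an event-free reference band
            ev_by_band = pt.groupby("age_band")[outcome].sum()
            ref_band = ev_by_band.sort_index().idxmax()
            for b in np.sort(pt["age_band"].unique()):
                if b != ref_band:
                    add(pt["age_band"].to_numpy() == b, f"age_band[{b}]")
        qd = rd = None
        if "quarter" in covariates and "quarter" in pt.columns:
            q = pt["quarter"].to_numpy()
            qlevels = [x for x in QUARTER_ORDER if (q == x).any()]
            qd = {x: (q == x).astype(float) for x in qlevels[1:]}
            for x in qlevels[1:]:
                add(qd[x], f"quarter[Q{x}]")
        if "region" in covariates and "region" in pt.columns:
            r = pt["region"].to_numpy()
            observed = set(r)
            rlevels = [x for x in REGION_ORDER if x in observed]
            rlevels += [x for x in sorted(observed) if x not in REGION_ORDER]
            rd = {x: (r == x).astype(float) for x in rlevels[1:]}
            for x in rlevels[1:]:
                add(rd[x], f"region[{x}]")
        if "quarter:region" in covariates and qd and rd:
            for xq, vq in qd.items():
                for xr, vr in rd.items():
                    add(vq * vr, f"quarter[Q{xq}]:region[{xr}]")
        for name in extra_columns:
            add(pt[name].to_numpy(), name)

        X = np.column_stack(cols) if cols else np.empty((len(pt), 0))
        codes, _ = pd.factorize(pt["patient_id"], sort=False)
        groups_all = codes.astype(np.int64)
        y_all = pt[outcome].to_numpy(dtype=float)
        logt_all = np.log(pt["length_days"].to_numpy(dtype=float))

        # A dummy level has an infinite MLE when, among the patients for
        # whom the level varies within-patient (the only ones informing its
        # coefficient), either the on-level or the off-level event count is
        # zero. The exact limiting MLE assigns zero probability to the
        # event-free side of such a level, i.e. it excludes that (always
        # event-free) person-time from the affected patients' denominators —
        # so the level's column is removed and the losing rows are excluded
        # rather than pooled with the reference level (pooling would
        # misattribute the level's rate to the reference). Exposure levels
        # are instead flagged non-estimable, per the reporting contract.
        # Exclusions can unmask further degenerate levels, so the screen
        # iterates to a fixed point.
        self.non_estimable = []
        self.zero_event_columns = []
        self.excluded_interval_count = 0
        alive = np.ones(len(pt), dtype=bool)
        active = np.ones(X.shape[1], dtype=bool)
        for _ in range(64):
            idx = np.flatnonzero(alive)
            g = groups_all[idx]
            ptr = _run_ptr(g)
            sizes = np.diff(ptr)
            yv = y_all[idx]
            changed = False
            for j in np.flatnonzero(active):
                col = X[idx, j]
                if col.size == 0 or not np.isin(col, (0.0, 1.0)).all() \
                        or col.min() == col.max():
                    continue  # non-dummy/constant: collinearity handles it
                gmin = np.minimum.reduceat(col, ptr[:-1])
                gmax = np.maximum.reduceat(col, ptr[:-1])
                in_varying = np.repeat(gmin != gmax, sizes)
                on = yv[in_varying & (col > 0)].sum()
                off = yv[in_varying & (col <= 0)].sum()
                if on == 0 or off == 0:
                    active[j] = False
                    changed = True
                    if names[j] in ("dpi_fs", "neither"):
                        self.non_estimable.append(names[j])
                    else:
                        self.zero_event_columns.append(names[j])
                        lose = in_varying & ((col > 0) if on == 0
                                             else (col <= 0))
                        alive[idx[lose]] = False
                        self.excluded_interval_count += int(lose.sum())
                    break  # re-derive groups before screening further
            if not changed:
                break
        if self.zero_event_columns:
            logger.info(
                "outcome %s: resolved zero-information levels %s by "
                "excluding %d event-free intervals", outcome,
                self.zero_event_columns, self.excluded_interval_count)

        idx = np.flatnonzero(alive)
        self._groups = groups_all[idx]
        self._ptr = _run_ptr(self._groups)
        self._sizes = np.diff(self._ptr)
        self._y = y_all[idx]
        self._logt = logt_all[idx]
        Xa = X[np.ix_(idx, np.flatnonzero(active))]
        names_a = [nm for nm, a in zip(names, active) if a]
        kept, self.dropped_columns = _drop_collinear(
            Xa, names_a, self._ptr, self._sizes)
        self._X = np.ascontiguousarray(Xa[:, kept])
        self.param_names = [names_a[j] for j in kept]
        if self.dropped_columns:
            logger.info("outcome %s: dropped collinear columns %s",
                        outcome, self.dropped_columns)

    def loglik(self, beta) -> float:
        return conditional_loglik(np.asarray(beta, float), self._X, self._y,
                                  self._logt, self._ptr, self._sizes)

    # sanity bounds: a nuisance level whose estimate escapes these lies on a
    # jointly flat (separated) direction, not a real covariate effect
    _PRUNE_ABS_BETA = 10.0
    _PRUNE_BSE = 50.0

    def fit(self, max_iter=50, tol=1e-8) -> "SCCSResults":
        self.pruned_columns = []
        X, names = self._X, list(self.param_names)
        y, logt, groups = self._y, self._logt, self._groups
        for _ in range(6):
            ptr = _run_ptr(groups)
            sizes = np.diff(ptr)
            beta, cov, ll, n_iter, converged = _fit_newton(
                X, y, logt, ptr, sizes, max_iter=max_iter, tol=tol)
            bse = np.sqrt(np.diag(cov))
            bad = [j for j, nm in enumerate(names)
                   if nm not in ("dpi_fs", "neither")
                   and (abs(beta[j]) > self._PRUNE_ABS_BETA
                        or bse[j] > self._PRUNE_BSE)]
            if not bad:
                break
            # A member of a jointly diverging dummy direction: the losing
            # side's rows among within-patient-varying patients are
            # event-free (otherwise the likelihood could not diverge), so
            # the exact limiting MLE excludes that person-time. If the rows
            # are not event-free (the bound caught something else), fall
            # back to dropping the column alone.
            drop_rows = np.zeros(len(y), dtype=bool)
            for j in bad:
                self.pruned_columns.append(names[j])
                col = X[:, j]
                if np.isin(col, (0.0, 1.0)).all() and col.min() != col.max():
                    gmin = np.minimum.reduceat(col, ptr[:-1])
                    gmax = np.maximum.reduceat(col, ptr[:-1])
                    in_varying = np.repeat(gmin != gmax, sizes)
                    side = (col > 0) if beta[j] < 0 else (col <= 0)
                    rows = in_varying & side
                    if y[rows].sum() == 0:
                        drop_rows |= rows
            keep_cols = [j for j in range(X.shape[1]) if j not in bad]
            keep_rows = np.flatnonzero(~drop_rows)
            X = X[np.ix_(keep_rows, keep_cols)]
            names = [names[j] for j in keep_cols]
            y, logt, groups = y[~drop_rows], logt[~drop_rows], \
                groups[~drop_rows]
            self.excluded_interval_count += int(drop_rows.sum())
            # row surgery can degenerate further columns; re-check rank
            ptr2 = _run_ptr(groups)
            kept, newly_dropped = _drop_collinear(X, names, ptr2,
                                                  np.diff(ptr2))
            if newly_dropped:
                self.dropped_columns = self.dropped_columns + newly_dropped
                X = np.ascontiguousarray(X[:, kept])
                names = [names[j] for j in kept]
        if self.pruned_columns:
            logger.info("outcome %s: resolved unidentified directions %s",
                        self.outcome, self.pruned_columns)
        self._X, self.param_names = X, names
        self._y, self._logt, self._groups = y, logt, groups
        self._ptr = _run_ptr(groups)
        self._sizes = np.diff(self._ptr)
        return SCCSResults(self, pd.Series(beta, index=self.param_names),
                           pd.DataFrame(cov, index=self.param_names,
                                        columns=self.param_names),
                           ll, n_iter, converged)


class SCCSResults:
    """Estimates, uncertainties and diagnostics of a fitted SCCS model."""

    def __init__(self, model, params, cov, loglik, n_iter, converged):
        self.model = model
        self.outcome = model.outcome
        self.params = params
        self.cov = cov
        self.bse = pd.Series(np.sqrt(np.diag(cov.values)), index=params.index)
        self.loglik = loglik
        self.n_iter = n_iter
        self.converged = converged
        self.n_informative = model.n_informative
        self.n_events = model.n_events
        self.dropped_columns = model.dropped_columns
        self.pruned_columns = getattr(model, "pruned_columns", [])
        self.non_estimable = model.non_estimable

    @property
    def irr(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2) if alpha != 0.05 else Z95
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"low": lo, "high": hi})

    def irr_conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return np.exp(self.conf_int(alpha))

    def exposure_summary(self) -> dict:
        """Headline DPI-vs-MDI estimate row."""
        out = {"outcome": self.outcome, "irr": np.nan, "ci_low": np.nan,
               "ci_high": np.nan, "p": np.nan,
               "n_informative": self.n_informative, "n_events": self.n_events,
               "non_estimable": "dpi_fs" in self.non_estimable}
        if "dpi_fs" in self.params.index:
            ci = self.irr_conf_int().loc["dpi_fs"]
            out.update(irr=float(self.irr["dpi_fs"]),
                       ci_low=float(ci["low"]), ci_high=float(ci["high"]),
                       p=float(self.pvalues["dpi_fs"]))
        return out

    def summary(self) -> str:
        ci = self.irr_conf_int()
        lines = [
            f"SCCS conditional Poisson fit: outcome = {self.outcome}",
            f"informative patients: {self.n_informative}   "
            f"events: {self.n_events}   log-likelihood: {self.loglik:.3f}",
            f"converged: {self.converged} in {self.n_iter} Newton iterations",
            "-" * 72,
            f"{'parameter':<28}{'IRR':>9}{'95% low':>10}{'95% high':>10}"
            f"{'p':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<28}{np.exp(self.params[name]):>9.3f}"
                f"{np.exp(self.params[name] - Z95 * self.bse[name]):>10.3f}"
                f"{np.exp(self.params[name] + Z95 * self.bse[name]):>10.3f}"
                f"{self.pvalues[name]:>10.2g}")
        if self.dropped_columns:
            lines.append(f"dropped (collinear): {', '.join(self.dropped_columns)}")
        if self.non_estimable:
            lines.append(f"non-estimable levels: {', '.join(self.non_estimable)}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# multiplicity

def hochberg_adjust(p_values) -> np.ndarray:
    """Hochberg step-up adjusted p-values (family-wise error control).

    With ascending p_(1..m): adjusted_(m) = p_(m) and adjusted_(i) =
    min(adjusted_(i+1), (m-i+1) * p_(i)), capped at 1, mapped back to the
    input order. NaNs are passed through and excluded from the family.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ps = pv[order]
    adj = np.empty(m)
    running = ps[-1]
    for i in range(m - 1, -1, -1):
        running = min(running, (m - i) * ps[i])
        adj[i] = min(running, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[valid] = res
    return out


# --------------------------------------------------------------------------
# study pipeline

@dataclass
class SCCSStudyResult:
    """One analysis variant: per-outcome IRR table plus the fitted models."""

    table: pd.DataFrame
    fits: dict
    variant: str = "primary"

    def summary(self) -> str:
        lines = [f"Self-controlled case series — variant: {self.variant}",
                 f"{'outcome':<20}{'IRR (95% CI)':>24}{'p':>10}"
                 f"{'p (Hochberg)':>14}{'patients':>10}{'events':>9}"]
        for _, r in self.table.iterrows():
            if np.isnan(r["irr"]):
                est = "non-estimable"
            else:
                est = f"{r['irr']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})"
            lines.append(f"{r['outcome']:<20}{est:>24}{r['p']:>10.2g}"
                         f"{r['p_hochberg']:>14.2g}{r['n_informative']:>10}"
                         f"{r['n_events']:>9}")
        return "\n".join(lines)


def exclude_pneumonia_ed_near_hospitalization(
        events: pd.DataFrame, window_days: int = 3,
        classifier: CauseClassifier = DEFAULT_CLASSIFIER) -> pd.DataFrame:
    """Drop pneumonia ED visits 0..window_days days before a pneumonia
    hospitalization of the same patient (the visit that led to admission)."""
    if events.empty:
        return events
    cause = classify_codes(events["principal_icd10"], classifier)
    dates = pd.to_datetime(events["event_date"])
    is_pneu_ed = (events["encounter"] == "ed_visit") & (cause == "pneumonia")
    is_pneu_hosp = (events["encounter"] == "hospitalization") \
        & (cause == "pneumonia")
    hosp = events.loc[is_pneu_hosp, ["patient_id"]].assign(
        hosp_date=dates[is_pneu_hosp])
    ed = events.loc[is_pneu_ed, ["patient_id"]].assign(
        ed_date=dates[is_pneu_ed], _row=np.flatnonzero(is_pneu_ed.to_numpy()))
    merged = ed.merge(hosp, on="patient_id")
    delta = (merged["hosp_date"] - merged["ed_date"]).dt.days
    drop_rows = merged.loc[(delta >= 0) & (delta <= window_days), "_row"].unique()
    return events.drop(events.index[drop_rows])


def run_primary_analysis(patients, fills, events, *,
                         policy: GracePolicy = None,
                         design: SCCSDesign = None,
                         study_start=DEFAULT_STUDY_START,
                         study_end=DEFAULT_STUDY_END,
                         formulary_window=DEFAULT_FORMULARY_WINDOW,
                         gap_exclude: bool = False,
                         outcomes=None, event_stratum=None,
                         classifier: CauseClassifier = DEFAULT_CLASSIFIER,
                         variant: str = "primary") -> SCCSStudyResult:
    """Run the within-person analysis end-to-end on claims-shaped tables."""
    policy = policy or GracePolicy(1 / 3)
    design = design or SCCSDesign()
    included = sccs_inclusion(fills, formulary_window[0])
    if len(included) == 0:
        raise EstimationError("no patients meet the switch inclusion criterion")
    patients = patients[patients["patient_id"].isin(included)]
    fills = fills[fills["patient_id"].isin(included)]
    events = events[events["patient_id"].isin(included)]
    periods = build_exposure_table(patients, fills, policy,
                                   study_start=study_start, study_end=study_end)
    if gap_exclude:
        excluded = gap_exclusion(periods)
        bad = set(excluded.index[excluded])
        if bad:
            logger.info("gap exclusion removed %d patients", len(bad))
            periods = periods[~periods["patient_id"].isin(bad)]
            events = events[~events["patient_id"].isin(bad)]
            fills = fills[~fills["patient_id"].isin(bad)]
    pt = build_person_time(patients, periods, fills, events,
                           study_start=study_start, study_end=study_end,
                           design=design, classifier=classifier)
    rows, fits = [], {}
    for oc in (outcomes or design.outcomes):
        model = SCCSModel(pt, oc, event_stratum=event_stratum)
        res = model.fit()
        fits[oc] = res
        rows.append(res.exposure_summary())
    table = pd.DataFrame(rows)
    table["p_hochberg"] = hochberg_adjust(table["p"].to_numpy())
    return SCCSStudyResult(table=table, fits=fits, variant=variant)


def sensitivity_suite(patients, fills, events, **kwargs) -> dict:
    """The sensitivity analyses: grace variants, gap exclusion, pneumonia-ED
    exclusion, and stratification by per-patient event count."""
    window_days = kwargs.pop("pneumonia_ed_window_days", 3)
    out = {}
    for name, grace in (("grace_0", 0.0), ("grace_33", 1 / 3), ("grace_100", 1.0)):
        out[name] = run_primary_analysis(
            patients, fills, events, policy=GracePolicy(grace),
            variant=name, **kwargs)
    out["gap_excluded"] = run_primary_analysis(
        patients, fills, events, gap_exclude=True, variant="gap_excluded",
        **kwargs)
    ev2 = exclude_pneumonia_ed_near_hospitalization(
        events, window_days=window_days,
        classifier=kwargs.get("classifier", DEFAULT_CLASSIFIER))
    out["pneumonia_ed_excluded"] = run_primary_analysis(
        patients, fills, ev2, variant="pneumonia_ed_excluded", **kwargs)
    for name, stratum in (("one_event", "1"), ("multiple_events", "2+")):
        try:
            out[name] = run_primary_analysis(
                patients, fills, events, event_stratum=stratum, variant=name,
                **kwargs)
        except EstimationError as exc:
            logger.info("stratum %s skipped: %s", name, exc)
    return out


def _preswitch_flags(patients, fills, events, lookback_days=365):
    """Per-patient booleans over the year before the first DPI fill."""
    dpi = fills[fills["product"] == "fs_dpi"]
    first = pd.to_datetime(dpi.groupby("patient_id")["fill_date"].min())
    out = pd.DataFrame(index=patients["patient_id"])
    out["preswitch_rescue"] = False
    out["preswitch_ed"] = False
    out["preswitch_hosp"] = False
    f = fills.merge(first.rename("anchor"), left_on="patient_id",
                    right_index=True)
    fd = pd.to_datetime(f["fill_date"])
    in_window = (fd < f["anchor"]) & \
        (fd >= f["anchor"] - pd.Timedelta(days=lookback_days))
    rescue = f.loc[in_window & f["product"].isin(
        ("albuterol_mdi", "albuterol_neb")), "patient_id"].unique()
    out.loc[out.index.isin(rescue), "preswitch_rescue"] = True
    e = events.merge(first.rename("anchor"), left_on="patient_id",
                     right_index=True)
    edt = pd.to_datetime(e["event_date"])
    in_window = (edt < e["anchor"]) & \
        (edt >= e["anchor"] - pd.Timedelta(days=lookback_days))
    ed = e.loc[in_window & (e["encounter"] == "ed_visit"), "patient_id"].unique()
    hosp = e.loc[in_window & (e["encounter"] == "hospitalization"),
                 "patient_id"].unique()
    out.loc[out.index.isin(ed), "preswitch_ed"] = True
    out.loc[out.index.isin(hosp), "preswitch_hosp"] = True
    return out


def subgroup_suite(patients, fills, events, **kwargs) -> dict:
    """Refit every outcome within each subgroup of the subgroup scheme.

    Returns {(variable, level): SCCSStudyResult}; empty subgroups are
    skipped with a log entry.
    """
    flags = _preswitch_flags(patients, fills, events)
    p = patients.set_index("patient_id").join(flags)
    groups = {
        ("sex", "female"): p["sex"] == "female",
        ("sex", "male"): p["sex"] == "male",
        ("diagnosis", "copd"): p["copd"].astype(bool),
        ("diagnosis", "asthma"): p["asthma"].astype(bool),
        ("smoking", "current"): p["smoking"] == "current",
        ("smoking", "former"): p["smoking"] == "former",
        ("smoking", "never"): p["smoking"] == "never",
        ("combat_veteran", "yes"): p["combat_veteran"].astype(bool),
        ("combat_veteran", "no"): ~p["combat_veteran"].astype(bool),
        ("preswitch_rescue", "yes"): p["preswitch_rescue"],
        ("preswitch_rescue", "no"): ~p["preswitch_rescue"],
        ("preswitch_ed", "yes"): p["preswitch_ed"],
        ("preswitch_ed", "no"): ~p["preswitch_ed"],
        ("preswitch_hosp", "yes"): p["preswitch_hosp"],
        ("preswitch_hosp", "no"): ~p["preswitch_hosp"],
    }
    out = {}
    for key, mask in groups.items():
        pids = set(p.index[mask])
        if not pids:
            logger.info("subgroup %s skipped: empty", key)
            continue
        try:
            out[key] = run_primary_analysis(
                patients[patients["patient_id"].isin(pids)],
                fills[fills["patient_id"].isin(pids)],
                events[events["patient_id"].isin(pids)],
                variant=f"{key[0]}={key[1]}", **kwargs)
        except EstimationError as exc:
            logger.info("subgroup %s skipped: %s", key, exc)
    return out
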