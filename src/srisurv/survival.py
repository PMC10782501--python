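"""Quintile-based mortality models.

Exposures (SRI, mean sleep duration) enter as quintile factors with Q1
(least regular / shortest sleep) as the reference.  All-cause mortality
is modelled with Cox proportional hazards on the time-since-recording
scale (Efron tie handling); cause-specific mortality with Fine–Gray
proportional sub-distribution hazards, where participants failing from
competing causes remain in the risk set carrying inverse-probability-of-
censoring weights estimated by Kaplan–Meier of the censoring
distribution.

Adjustment sets mirror the epidemiological convention of a "minimal"
model (age, sex, ethnicity) and a "full" model adding sociodemographic,
lifestyle and medication covariates.  Rows with missing values in a
model's adjustment set are dropped (complete-case) and counted.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from sklearn.base import BaseEstimator

from .quintiles import QUINTILE_LABELS, QuintileAssignment, assign_quintiles

MINIMAL_ADJUSTMENT: tuple[str, ...] = ("age", "sex", "ethnicity")
FULL_ADJUSTMENT: tuple[str, ...] = MINIMAL_ADJUSTMENT + (
    "physical_activity",
    "employment",
    "income",
    "deprivation",
    "social_activities",
    "social_visits",
    "smoking",
    "urbanicity",
    "shift_work",
    "meds_chol_htn",
)

# fixed level order => deterministic dummy coding (first level is reference)
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "sex": ["female", "male"],
    "ethnicity": ["white", "other"],
    "employment": ["employed", "not_employed"],
    "social_activities": ["yes", "no"],
    "smoking": ["never", "previous", "current"],
    "urbanicity": ["urban", "rural"],
    "shift_work": ["no", "yes"],
    "meds_chol_htn": ["no", "yes"],
}

CAUSES = ("cardiometabolic", "cancer", "other")

MODEL_IDS = {
    ("sri",): 1,
    ("sleep_duration",): 2,
    ("sri", "sleep_duration"): 3,
}


@dataclass
class ModelFit:
    """Fitted mortality model: coefficients, HR table and fit statistics."""

    model_id: int
    family: str  # "cox" | "fine_gray"
    outcome: str  # "all_cause" | cause label
    adjustment: str  # "minimal" | "full"
    predictors: tuple[str, ...]
    coefficients: pd.DataFrame  # index=term; columns coef, se, p
    hazard_ratios: pd.DataFrame  # tidy: term, quintile, hr, ci_low, ci_high, p
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    n_dropped: int
    n_params: int
    row_hash: str
    quintile_cut_points: dict[str, np.ndarray] = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        """Rows mirroring the published table layout."""
        out = self.hazard_ratios.copy()
        out.insert(0, "model", self.model_id)
        out.insert(1, "adjustment", self.adjustment)
        out.insert(2, "outcome", self.outcome)
        out.insert(3, "family", self.family)
        out["n"] = self.n
        out["n_events"] = self.n_events
        return out


def adjustment_covariates(
    adjustment: str, extra: tuple[str, ...] = ()
) -> tuple[str, ...]:
    if adjustment == "minimal":
        base = MINIMAL_ADJUSTMENT
    elif adjustment == "full":
        base = FULL_ADJUSTMENT
    elif adjustment == "none":  # unadjusted: quintile terms only
        base = ()
    else:
        raise ValueError(
            f"adjustment must be 'minimal', 'full' or 'none', got {adjustment!r}"
        )
    return base + tuple(c for c in extra if c not in base)


def _dummy_code(col: pd.Series, name: str) -> pd.DataFrame:
    """Deterministic treatment coding for a categorical covariate."""
    levels = CATEGORICAL_LEVELS.get(name)
    if levels is None:
        levels = sorted(col.dropna().astype(str).unique())
    cat = pd.Categorical(col.astype(str).where(col.notna()), categories=levels)
    out = pd.DataFrame(index=col.index)
    for lev in levels[1:]:
        out[f"{name}_{lev}"] = (cat == lev).astype(float)
    out[pd.isna(cat)] = np.nan
    return out


def quintile_dummies(
    labels: pd.Series, name: str
) -> pd.DataFrame:
    out = pd.DataFrame(index=labels.index)
    for q in QUINTILE_LABELS[1:]:
        out[f"{name}_{q}"] = (labels == q).astype(float)
    out[labels.isna()] = np.nan
    return out


def build_design(
    cohort: pd.DataFrame,
    predictors: tuple[str, ...],
    adjustment: str,
    extra_covariates: tuple[str, ...] = (),
    time_col: str = "follow_up_time",
    event_col: str = "event",
    precomputed_quintiles: dict[str, QuintileAssignment] | None = None,
) -> tuple[pd.DataFrame, dict[str, QuintileAssignment], int]:
    """Build the model matrix for the quintile survival models.

    Quintile cut points for each exposure are computed on *all* rows with
    that exposure observed, before the complete-case drop on covariates —
    matching the convention of splitting the analysed population once and
    then fitting models on the adjustment-complete subset.

    Returns (design, quintile assignments, number of rows dropped).
    The design holds time, event and float covariate columns only.
    """
    covs = adjustment_covariates(adjustment, extra_covariates)
    missing_cols = [c for c in (*predictors, *covs, time_col, event_col)
                    if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks required columns: {missing_cols}")

    assignments: dict[str, QuintileAssignment] = {}
    parts = [cohort[[time_col, event_col]].astype(float)]
    for p in predictors:
        if precomputed_quintiles and p in precomputed_quintiles:
            qa = precomputed_quintiles[p]
        else:
            qa = assign_quintiles(cohort[p], variable=p)
        assignments[p] = qa
        parts.append(quintile_dummies(qa.labels, p))
    for c in covs:
        if c in CATEGORICAL_LEVELS or cohort[c].dtype == object:
            parts.append(_dummy_code(cohort[c], c))
        else:
            parts.append(cohort[[c]].astype(float))
    design = pd.concat(parts, axis=1)
    n0 = len(design)
    design = design.dropna()
    return design, assignments, n0 - len(design)


def _row_hash(index: pd.Index) -> str:
    payload = ",".join(map(str, sorted(map(str, index)))).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _hr_table(
    summary: pd.DataFrame, predictors: tuple[str, ...]
) -> pd.DataFrame:
    """Tidy per-quintile hazard-ratio table with the Q1 reference rows."""
    rows = []
    for p in predictors:
        rows.append({"term": p, "quintile": "Q1", "hr": 1.0,
                     "ci_low": np.nan, "ci_high": np.nan, "p": np.nan})
        for q in QUINTILE_LABELS[1:]:
            name = f"{p}_{q}"
            if name not in summary.index:
                continue
            s = summary.loc[name]
            rows.append({
                "term": p,
                "quintile": q,
                "hr": float(np.exp(s["coef"])),
                "ci_low": float(np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"])),
                "ci_high": float(np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"])),
                "p": float(s["p"]),
            })
    return pd.DataFrame(rows, columns=["term", "quintile", "hr", "ci_low", "ci_high", "p"])


def _event_indicator(
    cohort: pd.DataFrame, outcome: str, event_col: str, cause_col: str
) -> pd.Series:
    ev = cohort[event_col].astype(float)
    if outcome == "all_cause":
        return ev
    if cause_col not in cohort.columns:
        raise ValueError(f"cause-specific outcome {outcome!r} needs a {cause_col!r} column")
    return ((ev > 0) & (cohort[cause_col] == outcome)).astype(float)


class QuintileCoxPH(BaseEstimator):
    """Cox proportional-hazards model over exposure quintiles.

    Parameters
    ----------
    predictors : tuple of str
        Exposure columns entered as quintile factors ("sri",
        "sleep_duration", or both).
    adjustment : {"minimal", "full"}
        Covariate set; "minimal" is age + sex + ethnicity.
    outcome : str
        "all_cause", or a cause label for a cause-specific Cox model
        (competing deaths censored at their event time).
    extra_covariates : tuple of str
        Additional adjustment columns (sensitivity analyses).

    After ``fit``, ``model_fit_`` holds the full :class:`ModelFit`;
    ``hazard_ratios_``, ``log_likelihood_``, ``aic_``, ``n_``,
    ``n_events_`` are convenience views.  ``predict`` returns the partial
    hazard for new cohort rows using the training quintile cut points.
    """

    def __init__(
        self,
        predictors: tuple[str, ...] = ("sri",),
        adjustment: str = "minimal",
        outcome: str = "all_cause",
        extra_covariates: tuple[str, ...] = (),
        time_col: str = "follow_up_time",
        event_col: str = "event",
        cause_col: str = "cause",
    ):
        self.predictors = predictors
        self.adjustment = adjustment
        self.outcome = outcome
        self.extra_covariates = extra_covariates
        self.time_col = time_col
        self.event_col = event_col
        self.cause_col = cause_col

    def fit(self, X: pd.DataFrame, y=None) -> "QuintileCoxPH":
        cohort = X.copy()
        cohort["_event"] = _event_indicator(
            cohort, self.outcome, self.event_col, self.cause_col
        )
        design, assignments, n_dropped = build_design(
            cohort,
            tuple(self.predictors),
            self.adjustment,
            tuple(self.extra_covariates),
            time_col=self.time_col,
            event_col="_event",
        )
        n_events = int(design["_event"].sum())
        if n_events == 0:
            raise ValueError(f"no events for outcome {self.outcome!r}; cannot fit")
        if (design[self.time_col] <= 0).any():
            raise ValueError("follow_up_time must be positive for all analysed rows")

        cph = CoxPHFitter()
        try:
            # tight Newton tolerance: cause-specific Cox and the degenerate
            # Fine-Gray path must agree to ~1e-6 relative on the HRs
            cph.fit(design, duration_col=self.time_col, event_col="_event",
                    fit_options={"precision": 1e-10, "max_steps": 500})
        except ConvergenceError as err:
            raise ConvergenceError(
                f"Cox model failed to converge (outcome={self.outcome!r}, "
                f"adjustment={self.adjustment!r}); check separation or collinearity "
                f"in the adjustment covariates: {err}"
            ) from err

        self.estimator_ = cph
        self._design_ = design
        self.quintile_assignments_ = assignments
        k = len(cph.params_)
        self.model_fit_ = ModelFit(
            model_id=MODEL_IDS.get(tuple(self.predictors), 0),
            family="cox",
            outcome=self.outcome,
            adjustment=self.adjustment,
            predictors=tuple(self.predictors),
            coefficients=cph.summary[["coef", "se(coef)", "p"]].rename(
                columns={"se(coef)": "se"}
            ),
            hazard_ratios=_hr_table(cph.summary, tuple(self.predictors)),
            log_likelihood=float(cph.log_likelihood_),
            aic=float(2 * k - 2 * cph.log_likelihood_),
            n=len(design),
            n_events=n_events,
            n_dropped=n_dropped,
            n_params=k,
            row_hash=_row_hash(design.index),
            quintile_cut_points={p: a.cut_points for p, a in assignments.items()},
        )
        self.hazard_ratios_ = self.model_fit_.hazard_ratios
        self.log_likelihood_ = self.model_fit_.log_likelihood
        self.aic_ = self.model_fit_.aic
        self.n_ = self.model_fit_.n
        self.n_events_ = self.model_fit_.n_events
        return self

    def _design_for_predict(self, X: pd.DataFrame) -> pd.DataFrame:
        parts = []
        for p in self.predictors:
            cuts = self.model_fit_.quintile_cut_points[p]
            idx = np.searchsorted(cuts, X[p].to_numpy(dtype=float), side="left")
            labels = pd.Series(
                pd.Categorical.from_codes(
                    np.where(X[p].notna(), idx, -1), categories=QUINTILE_LABELS
                ),
                index=X.index,
            )
            parts.append(quintile_dummies(labels, p))
        covs = adjustment_covariates(self.adjustment, tuple(self.extra_covariates))
        for c in covs:
            if c in CATEGORICAL_LEVELS or X[c].dtype == object:
                parts.append(_dummy_code(X[c], c))
            else:
                parts.append(X[[c]].astype(float))
        return pd.concat(parts, axis=1)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Partial hazard exp(x'beta) relative to the baseline."""
        design = self._design_for_predict(X)
        return self.estimator_.predict_partial_hazard(design).to_numpy()


def _censoring_survival(times: np.ndarray, censored: np.ndarray):
    """Kaplan–Meier of the censoring distribution; returns G(t-) lookup."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=censored)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    vals = sf.iloc[:, 0].to_numpy(dtype=float)

    def g_minus(t: np.ndarray) -> np.ndarray:
        # value of the right-continuous step function just before t
        idx = np.searchsorted(grid, np.asarray(t, dtype=float), side="left") - 1
        out = np.where(idx >= 0, vals[np.clip(idx, 0, None)], 1.0)
        return out

    return g_minus


def build_fine_gray_dataset(
    times: np.ndarray,
    target_event: np.ndarray,
    competing_event: np.ndarray,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Counting-process dataset implementing the Fine–Gray risk set.

    Subjects failing from a competing cause remain at risk after their
    failure time, carrying the weight G(t-)/G(T_i-) at each subsequent
    target-cause event time t, where G is the Kaplan–Meier estimate of
    the censoring survival function.  Everyone else contributes one
    interval (0, T_i] with weight 1.
    """
    times = np.asarray(times, dtype=float)
    target = np.asarray(target_event, dtype=bool)
    competing = np.asarray(competing_event, dtype=bool)
    censored = ~target & ~competing
    g_minus = _censoring_survival(times, censored.astype(int))

    event_times = np.unique(times[target])
    cov = covariates.reset_index(drop=True)
    n = len(times)

    ids, starts, stops, events, weights, cov_rows = [], [], [], [], [], []
    for i in range(n):
        ids.append(i)
        starts.append(0.0)
        stops.append(times[i])
        events.append(1 if target[i] else 0)
        weights.append(1.0)
        cov_rows.append(i)
        if competing[i]:
            later = event_times[event_times > times[i]]
            if later.size:
                g_ti = g_minus(np.array([times[i]]))[0]
                w_later = g_minus(later) / g_ti if g_ti > 0 else np.zeros(later.size)
                prev = times[i]
                for t_k, w in zip(later, w_later):
                    if w <= 0:
                        break
                    ids.append(i)
                    starts.append(prev)
                    stops.append(t_k)
                    events.append(0)
                    weights.append(float(w))
                    cov_rows.append(i)
                    prev = t_k

    long_df = pd.DataFrame(
        {"id": ids, "start": starts, "stop": stops, "event": events, "w": weights}
    )
    return pd.concat(
        [long_df, cov.iloc[cov_rows].reset_index(drop=True)], axis=1
    )


def fine_gray_from_arrays(
    times: np.ndarray,
    target_event: np.ndarray,
    competing_event: np.ndarray,
    covariates: pd.DataFrame,
) -> CoxTimeVaryingFitter:
    """Fit the Fine–Gray weighted partial likelihood from raw arrays.

    Builds the IPCW counting-process dataset and maximises the weighted
    partial likelihood; returns the fitted start–stop Cox model.  Used by
    :class:`FineGraySubdistribution` and directly testable against
    independent implementations.
    """
    long_df = build_fine_gray_dataset(times, target_event, competing_event, covariates)
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer IPCW weights are intended
        ctv.fit(
            long_df,
            id_col="id",
            event_col="event",
            start_col="start",
            stop_col="stop",
            weights_col="w",
            fit_options={"precision": 1e-10, "r_precision": 1e-12, "max_steps": 500},
        )
    return ctv


class FineGraySubdistribution(BaseEstimator):
    """Fine–Gray proportional sub-distribution hazards model.

    Estimates sub-hazard ratios for mortality from ``cause`` while
    treating deaths from all other causes as competing events that remain
    in the risk set with inverse-probability-of-censoring weights.  The
    weighted partial (pseudo-)likelihood is maximised by a start–stop Cox
    fitter over the IPCW counting-process dataset built by
    :func:`build_fine_gray_dataset`.

    With no competing events the dataset collapses to the plain Cox
    layout, and estimates agree numerically with the cause-specific
    :class:`QuintileCoxPH`.
    """

    def __init__(
        self,
        cause: str = "cardiometabolic",
        predictors: tuple[str, ...] = ("sri",),
        adjustment: str = "minimal",
        extra_covariates: tuple[str, ...] = (),
        time_col: str = "follow_up_time",
        event_col: str = "event",
        cause_col: str = "cause",
    ):
        self.cause = cause
        self.predictors = predictors
        self.adjustment = adjustment
        self.extra_covariates = extra_covariates
        self.time_col = time_col
        self.event_col = event_col
        self.cause_col = cause_col

    def fit(self, X: pd.DataFrame, y=None) -> "FineGraySubdistribution":
        cohort = X.copy()
        target = _event_indicator(cohort, self.cause, self.event_col, self.cause_col)
        cohort["_event"] = target
        design, assignments, n_dropped = build_design(
            cohort,
            tuple(self.predictors),
            self.adjustment,
            tuple(self.extra_covariates),
            time_col=self.time_col,
            event_col="_event",
        )
        if design["_event"].sum() == 0:
            raise ValueError(f"no events of cause {self.cause!r}; cannot fit")

        any_event = cohort.loc[design.index, self.event_col].astype(float) > 0
        target_b = design["_event"].to_numpy() > 0
        competing_b = any_event.to_numpy() & ~target_b
        self.n_competing_ = int(competing_b.sum())

        cov_cols = [c for c in design.columns if c not in (self.time_col, "_event")]
        try:
            ctv = fine_gray_from_arrays(
                design[self.time_col].to_numpy(),
                target_b,
                competing_b,
                design[cov_cols],
            )
        except ConvergenceError as err:
            raise ConvergenceError(
                f"Fine–Gray model failed to converge (cause={self.cause!r}, "
                f"adjustment={self.adjustment!r}): {err}"
            ) from err

        self.estimator_ = ctv
        self.quintile_assignments_ = assignments
        k = len(ctv.params_)
        self.model_fit_ = ModelFit(
            model_id=MODEL_IDS.get(tuple(self.predictors), 0),
            family="fine_gray",
            outcome=self.cause,
            adjustment=self.adjustment,
            predictors=tuple(self.predictors),
            coefficients=ctv.summary[["coef", "se(coef)", "p"]].rename(
                columns={"se(coef)": "se"}
            ),
            hazard_ratios=_hr_table(ctv.summary, tuple(self.predictors)),
            log_likelihood=float(ctv.log_likelihood_),
            aic=float(2 * k - 2 * ctv.log_likelihood_),
            n=len(design),
            n_events=int(design["_event"].sum()),
            n_dropped=n_dropped,
            n_params=k,
            row_hash=_row_hash(design.index),
            quintile_cut_points={p: a.cut_points for p, a in assignments.items()},
        )
        self.hazard_ratios_ = self.model_fit_.hazard_ratios
        self.log_likelihood_ = self.model_fit_.log_likelihood
        self.aic_ = self.model_fit_.aic
        self.n_ = self.model_fit_.n
        self.n_events_ = self.model_fit_.n_events
        return self


def fit_cox(
    cohort: pd.DataFrame,
    predictors: tuple[str, ...] = ("sri",),
    adjustment: str = "minimal",
    outcome: str = "all_cause",
    **kwargs,
) -> ModelFit:
    """Fit a quintile Cox PH model and return its :class:`ModelFit`."""
    est = QuintileCoxPH(
        predictors=predictors, adjustment=adjustment, outcome=outcome, **kwargs
    )
    return est.fit(cohort).model_fit_


def fit_fine_gray(
    cohort: pd.DataFrame,
    cause: str,
    predictors: tuple[str, ...] = ("sri",),
    adjustment: str = "minimal",
    **kwargs,
) -> ModelFit:
    """Fit a Fine–Gray sub-distribution hazards model for one cause."""
    est = FineGraySubdistribution(
        cause=cause, predictors=predictors, adjustment=adjustment, **kwargs
    )
    return est.fit(cohort).model_fit_


def schoenfeld_residuals(fit: QuintileCoxPH) -> pd.DataFrame:
    """Scaled Schoenfeld residuals for proportional-hazards diagnostics.

    Optional output: the models do not gate on these, they are for
    inspection (one row per event, one column per coefficient).
    """
    if not hasattr(fit, "_design_"):
        raise ValueError("estimator must be fitted before computing residuals")
    return fit.estimator_.compute_residuals(fit._design_, kind="scaled_schoenfeld")
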