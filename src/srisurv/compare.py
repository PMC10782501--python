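"""Model comparison: AIC relative likelihood, likelihood-ratio tests, and
the polynomial regression of SRI on sleep duration.

Two comparisons are used for the "is regularity a stronger predictor
than duration" question:

* non-nested, equally sized models (SRI-only vs duration-only) are
  compared by Akaike information criterion; the worse model's *relative
  likelihood* exp((AIC_min - AIC_other)/2) is the probability-like weight
  that it minimises information loss relative to the better one;
* nested models (SRI-only vs SRI + duration) are compared by the
  likelihood-ratio test, 2(l_full - l_reduced) ~ chi-square with df equal
  to the number of added coefficients (4 when adding one quintile factor).

The SRI ~ duration association itself is summarised by ordinary least
squares with duration entered as a linear, quadratic and cubic
polynomial, compared by nested F-tests, with the fitted cubic's local
maximum ("turning point") reported when it lies inside the observed
duration range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .survival import ModelFit

_NEG_TOL = 1e-8


@dataclass(frozen=True)
class ComparisonResult:
    kind: str  # "aic_relative_likelihood" | "likelihood_ratio_test"
    statistic: float  # |delta AIC| or the LRT chi-square
    df: int | None  # LRT only
    p_or_relative_likelihood: float
    better: str | None = None  # label of the preferred model (AIC comparison)
    worse: str | None = None


def _label(fit: ModelFit) -> str:
    return f"model{fit.model_id}/{fit.adjustment}/{fit.outcome}"


def _check_same_rows(a: ModelFit, b: ModelFit) -> None:
    if a.row_hash != b.row_hash or a.n != b.n:
        raise ValueError(
            "model fits use different row sets "
            f"(n={a.n} vs {b.n}); comparison is invalid"
        )


def compare_aic(fit_a: ModelFit, fit_b: ModelFit) -> ComparisonResult:
    """AIC comparison of two (possibly non-nested) fits on the same rows.

    Reports the relative likelihood of the worse model,
    exp((AIC_min - AIC_other)/2) in (0, 1]; symmetric in argument order.
    """
    if fit_a.outcome != fit_b.outcome:
        raise ValueError("AIC comparison requires the same outcome")
    _check_same_rows(fit_a, fit_b)
    delta = fit_a.aic - fit_b.aic
    better, worse = (fit_a, fit_b) if delta <= 0 else (fit_b, fit_a)
    return ComparisonResult(
        kind="aic_relative_likelihood",
        statistic=abs(delta),
        df=None,
        p_or_relative_likelihood=float(np.exp(-abs(delta) / 2.0)),
        better=_label(better),
        worse=_label(worse),
    )


def lrt_nested(reduced: ModelFit, full: ModelFit) -> ComparisonResult:
    """Likelihood-ratio test of nested fits on the same rows."""
    if not set(reduced.predictors).issubset(full.predictors):
        raise ValueError("reduced model's predictors must be a subset of the full model's")
    _check_same_rows(reduced, full)
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("full model has fewer coefficients than the reduced model")
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if stat < -max(_NEG_TOL * max(1.0, abs(full.log_likelihood)), 1e-6):
        raise ArithmeticError(
            f"negative LRT statistic {stat:.3g}: the full model's likelihood fell "
            "below the reduced model's beyond numerical tolerance (optimisation failure)"
        )
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return ComparisonResult(
        kind="likelihood_ratio_test",
        statistic=float(stat),
        df=df,
        p_or_relative_likelihood=p,
    )


def chi2_sf(statistic: float, df: int) -> float:
    """Upper-tail chi-square probability (the LRT p-value arithmetic)."""
    return float(stats.chi2.sf(statistic, df))


@dataclass
class PolynomialFitResult:
    """OLS fits of SRI on sleep duration for degrees 1-3 with F-tests."""

    coefficients: dict[int, np.ndarray]  # degree -> [b0..b_degree]
    adj_r_squared: dict[int, float]
    f_tests: dict[tuple[int, int], tuple[float, int, int, float]]
    # (reduced deg, full deg) -> (F, df_num, df_den, p)
    turning_point: float | None  # duration (h) at the cubic's local maximum
    sri_at_turning_point: float | None
    n: int
    models: dict[int, object] = field(default_factory=dict, repr=False)


def fit_sri_duration_polynomials(
    cohort: pd.DataFrame,
    sri_col: str = "sri",
    duration_col: str = "sleep_duration",
) -> PolynomialFitResult:
    """Regress SRI on duration, duration^2, duration^3 and compare fits.

    Nested F-tests follow the ANOVA convention in which each comparison's
    denominator is the residual mean square of the largest (cubic) model,
    so the two reported tests against the cubic share the same
    denominator degrees of freedom.
    """
    df = cohort[[sri_col, duration_col]].dropna()
    y = df[sri_col].to_numpy(dtype=float)
    x = df[duration_col].to_numpy(dtype=float)
    n = len(df)
    if n < 5:
        raise ValueError("need at least 5 complete rows for the polynomial fits")
    if np.std(x) < 1e-8 * max(1.0, abs(np.mean(x))):
        raise ValueError("sleep duration is (near-)constant; polynomial design degenerate")

    fits = {}
    for deg in (1, 2, 3):
        X = np.column_stack([x**k for k in range(deg + 1)])
        fits[deg] = sm.OLS(y, X).fit()

    df_den = int(fits[3].df_resid)
    mse_full = fits[3].ssr / df_den
    f_tests = {}
    for red, full in ((1, 2), (1, 3), (2, 3)):
        df_num = full - red
        f = (fits[red].ssr - fits[full].ssr) / df_num / mse_full
        f_tests[(red, full)] = (
            float(f), df_num, df_den, float(stats.f.sf(f, df_num, df_den))
        )

    b = fits[3].params  # b0 + b1 x + b2 x^2 + b3 x^3
    turning = None
    sri_at = None
    disc = (2 * b[2]) ** 2 - 4 * (3 * b[3]) * b[1]
    if abs(b[3]) > 0 and disc > 0:
        roots = np.roots([3 * b[3], 2 * b[2], b[1]])
        for r in sorted(roots):
            if not np.isreal(r):
                continue
            r = float(np.real(r))
            second = 6 * b[3] * r + 2 * b[2]
            if second < 0 and x.min() <= r <= x.max():
                turning = r
                sri_at = float(b[0] + b[1] * r + b[2] * r**2 + b[3] * r**3)
                break

    return PolynomialFitResult(
        coefficients={d: np.asarray(f.params) for d, f in fits.items()},
        adj_r_squared={d: float(f.rsquared_adj) for d, f in fits.items()},
        f_tests=f_tests,
        turning_point=turning,
        sri_at_turning_point=sri_at,
        n=n,
        models=fits,
    )


class SleepDurationSRIRegression:
    """Thin estimator wrapper over :func:`fit_sri_duration_polynomials`.

    ``fit(X)`` expects a cohort frame with the SRI and duration columns;
    the :class:`PolynomialFitResult` lands in ``result_`` and
    ``predict(durations)`` evaluates the fitted cubic.
    """

    def __init__(self, sri_col: str = "sri", duration_col: str = "sleep_duration"):
        self.sri_col = sri_col
        self.duration_col = duration_col

    def get_params(self, deep: bool = True) -> dict:
        return {"sri_col": self.sri_col, "duration_col": self.duration_col}

    def set_params(self, **params) -> "SleepDurationSRIRegression":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "SleepDurationSRIRegression":
        self.result_ = fit_sri_duration_polynomials(X, self.sri_col, self.duration_col)
        return self

    def predict(self, durations: np.ndarray) -> np.ndarray:
        b = self.result_.coefficients[3]
        d = np.asarray(durations, dtype=float)
        return b[0] + b[1] * d + b[2] * d**2 + b[3] * d**3
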