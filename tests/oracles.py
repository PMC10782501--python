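"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths (and lifelines):
the SRI oracle is a literal loop over every 24-h epoch pair, the Cox
oracle evaluates the explicit Efron partial likelihood and maximises it
with a generic optimiser, and the weighted start-stop oracle evaluates
the Fine-Gray pseudo-likelihood and score by direct summation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

SLEEP, WAKE, MISSING = 1, 0, 2  # mirrors the package's codes


def brute_force_sri(states, epochs_per_day: int):
    """SRI by looping over every pair (i, i + epochs_per_day).

    Returns (sri or None, concordant, valid).
    """
    states = list(states)
    conc = valid = 0
    for i in range(len(states) - epochs_per_day):
        a, b = states[i], states[i + epochs_per_day]
        if a == MISSING or b == MISSING:
            continue
        valid += 1
        if a == b:
            conc += 1
    if valid == 0:
        return None, 0, 0
    return 200.0 * conc / valid - 100.0, conc, valid


def cox_efron_loglik(beta, times, events, X):
    """Explicit Cox partial log-likelihood with Efron tie correction."""
    beta = np.atleast_1d(beta)
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(times[events.astype(bool)]):
        dead = (times == t) & events.astype(bool)
        at_risk = times >= t
        d = int(dead.sum())
        s_r = w[at_risk].sum()
        s_d = w[dead].sum()
        ll += eta[dead].sum()
        for l in range(d):
            ll -= np.log(s_r - (l / d) * s_d)
    return ll


def fit_cox_oracle(times, events, X, x0=None):
    """Maximise the Efron partial likelihood with a generic optimiser."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    p = X.shape[1]
    x0 = np.zeros(p) if x0 is None else x0
    res = minimize(
        lambda b: -cox_efron_loglik(b, times, events, X),
        x0,
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    return res.x, -res.fun


def weighted_startstop_loglik_and_score(beta, df, cov_cols):
    """Weighted partial log-likelihood and score for start-stop data.

    Breslow form (exact for untied event times): each event row e at time
    t_e contributes w_e*(eta_e - log sum_{j in R(t_e)} w_j exp(eta_j))
    with R(t) = rows with start < t <= stop.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = df[list(cov_cols)].to_numpy(dtype=float)
    eta = X @ beta
    w = df["w"].to_numpy(dtype=float)
    start = df["start"].to_numpy(dtype=float)
    stop = df["stop"].to_numpy(dtype=float)
    ev = df["event"].to_numpy(dtype=bool)

    ll = 0.0
    score = np.zeros_like(beta)
    for e in np.where(ev)[0]:
        t = stop[e]
        risk = (start < t) & (t <= stop)
        rw = w[risk] * np.exp(eta[risk])
        denom = rw.sum()
        xbar = (rw[:, None] * X[risk]).sum(axis=0) / denom
        ll += w[e] * (eta[e] - np.log(denom))
        score += w[e] * (X[e] - xbar)
    return ll, score


def km_censoring_survival(times, censored):
    """Hand-rolled Kaplan-Meier of the censoring distribution.

    Returns a function G(t-) (left limit of the right-continuous KM step).
    """
    times = np.asarray(times, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    uniq = np.unique(times[censored])
    surv = []
    g = 1.0
    for t in uniq:
        n_at_risk = (times >= t).sum()
        d = ((times == t) & censored).sum()
        g *= 1.0 - d / n_at_risk
        surv.append(g)
    uniq = np.asarray(uniq)
    surv = np.asarray(surv)

    def g_minus(t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(uniq, t, side="left") - 1
        return np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)

    return g_minus
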