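"""Foundational survival estimators.

Kaplan-Meier product-limit curves, restricted mean survival time (RMST) with
the large-sample Greenwood-type variance, RMST differences with normal-theory
confidence intervals, Cox proportional-hazards fitting (lifelines backend)
with AIC, Harrell's concordance, and bootstrap calibration by risk quartile.

All estimators accept plain numpy arrays of times (months) and event
indicators (1 = event, 0 = right-censored).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "RMSTEstimate",
    "RMSTDifference",
    "CoxFit",
    "kaplan_meier",
    "rmst",
    "rmst_difference",
    "fit_cox",
    "null_partial_loglik",
    "harrell_c",
    "calibration_by_quartile",
    "design_matrix",
]

OUTCOME_COLUMNS = {"os": ("os_time", "os_event"), "pfs": ("pfs_time", "pfs_event")}


def _check_sample(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if time.size == 0:
        raise ValueError("empty survival sample")
    if not np.all(np.isfinite(time)) or np.any(time < 0):
        raise ValueError("times must be finite and nonnegative")
    if not np.all((event == 0) | (event == 1)):
        raise ValueError("event indicators must be 0/1")
    return time, event


@dataclass
class SurvivalCurve:
    """Kaplan-Meier estimate: S(t) after each distinct event time.

    ``var_terms`` holds the cumulative Greenwood sum
    sum_{t_j <= t} d_j / (n_j (n_j - d_j)) used for pointwise and RMST
    variances.
    """

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t_j+)
    at_risk: np.ndarray        # n_j
    events: np.ndarray         # d_j
    var_terms: np.ndarray      # cumulative Greenwood terms
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_dict(self) -> dict:
        return {"times": self.times.tolist(), "survival": self.survival.tolist(),
                "at_risk": self.at_risk.tolist(), "events": self.events.tolist(), "n": self.n}


@dataclass
class RMSTEstimate:
    estimate: float
    se: float
    tau: float
    n: int
    n_events: int

    def ci(self, alpha: float = 0.05) -> tuple[float, float]:
        z = norm.ppf(1 - alpha / 2)
        return self.estimate - z * self.se, self.estimate + z * self.se


@dataclass
class RMSTDifference:
    difference: float
    se: float
    ci_low: float
    ci_high: float
    tau: float
    alpha: float
    n_treated: int
    n_control: int


def kaplan_meier(time, event) -> SurvivalCurve:
    """Product-limit estimate; censored subjects at an event time remain at
    risk for events at that time (standard convention)."""
    time, event = _check_sample(time, event)
    n = time.size
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]
    # distinct times with any event
    utimes, first_idx = np.unique(t_sorted, return_index=True)
    # counts at each distinct observed time
    d = np.zeros(utimes.size, dtype=int)
    c = np.zeros(utimes.size, dtype=int)
    idx = np.searchsorted(utimes, t_sorted)
    np.add.at(d, idx, e_sorted)
    np.add.at(c, idx, 1 - e_sorted)
    total = d + c
    at_risk_all = n - np.concatenate(([0], np.cumsum(total)[:-1]))
    keep = d > 0
    tj, dj, nj = utimes[keep], d[keep], at_risk_all[keep]
    frac = 1.0 - dj / nj
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gterm = np.where(nj > dj, dj / (nj * (nj - dj)), 0.0)
    return SurvivalCurve(times=tj, survival=surv, at_risk=nj, events=dj,
                         var_terms=np.cumsum(gterm), n=n)


def rmst(time, event, tau: float) -> RMSTEstimate:
    """Area under the Kaplan-Meier curve on [0, tau].

    The variance is the standard large-sample form of the integrated
    product-limit estimator: sum over event times t_j <= tau of
    A_j^2 d_j / (n_j (n_j - d_j)) with A_j the area under the curve from
    t_j to tau. If follow-up ends (by censoring) before tau the curve is
    extended flat and a warning is logged.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    time, event = _check_sample(time, event)
    curve = kaplan_meier(time, event)

    last_obs = time.max()
    if last_obs < tau and (curve.times.size == 0 or curve.survival[-1] > 0):
        logger.warning("largest observed time %.3g < tau=%.3g; curve extended flat", last_obs, tau)

    tj = curve.times
    sj = curve.survival
    k = int(np.searchsorted(tj, tau, side="left"))  # events strictly before tau count fully
    # integration knots: 0, t_1..t_k, tau
    knots = np.concatenate(([0.0], tj[:k], [tau]))
    heights = np.concatenate(([1.0], sj[:k]))
    widths = np.diff(knots)
    est = float(np.sum(heights * widths))

    # A_j = area from t_j to tau, for each event time t_j <= tau
    suffix = np.cumsum((heights * widths)[::-1])[::-1]
    areas_after = suffix[1:]  # suffix[j] = area from knot j to tau; knot j = t_j
    dj, nj = curve.events[:k], curve.at_risk[:k]
    with np.errstate(divide="ignore", invalid="ignore"):
        gterms = np.where(nj > dj, dj / (nj * (nj - dj)), 0.0)
    var = float(np.sum(areas_after**2 * gterms))
    return RMSTEstimate(estimate=est, se=float(np.sqrt(max(var, 0.0))), tau=float(tau),
                        n=time.size, n_events=int(event.sum()))


def rmst_difference(time_treated, event_treated, time_control, event_control,
                    tau: float, alpha: float = 0.05) -> RMSTDifference:
    """Treated minus control RMST at tau with a normal-theory CI.

    A positive difference means longer restricted mean survival in the
    treated arm.
    """
    r1 = rmst(time_treated, event_treated, tau)
    r0 = rmst(time_control, event_control, tau)
    diff = r1.estimate - r0.estimate
    se = float(np.sqrt(r1.se**2 + r0.se**2))
    z = norm.ppf(1 - alpha / 2)
    return RMSTDifference(difference=diff, se=se, ci_low=diff - z * se,
                          ci_high=diff + z * se, tau=float(tau), alpha=alpha,
                          n_treated=r1.n, n_control=r0.n)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Fitted proportional-hazards model (partial likelihood, Efron ties)."""

    variables: list[str]            # design-matrix column names
    coefs: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    n: int
    n_events: int
    converged: bool
    ties: str = "efron"
    baseline_cumhaz: pd.Series | None = field(default=None, repr=False)
    means: np.ndarray | None = field(default=None, repr=False)

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefs)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        """X beta on the raw (uncentered) design scale."""
        Xm = X[self.variables].to_numpy(dtype=float)
        return Xm @ self.coefs

    def survival_at(self, X: pd.DataFrame, tau: float) -> np.ndarray:
        """Absolute survival S(tau | x) from the Breslow baseline."""
        if self.baseline_cumhaz is None:
            raise ValueError("fit has no baseline cumulative hazard")
        ch = self.baseline_cumhaz
        idx = np.searchsorted(ch.index.to_numpy(), tau, side="right") - 1
        h0 = 0.0 if idx < 0 else float(ch.iloc[idx])
        # lifelines baseline is relative to covariate means
        lp = self.linear_predictor(X) - float(self.means @ self.coefs)
        return np.exp(-h0 * np.exp(lp))

    def to_dict(self) -> dict:
        return {"variables": self.variables, "coefs": self.coefs.tolist(),
                "loglik": self.loglik, "aic": self.aic, "n": self.n,
                "n_events": self.n_events, "ties": self.ties,
                "hazard_ratios": self.hazard_ratios.tolist()}


def null_partial_loglik(time, event, ties: str = "efron") -> float:
    """Partial log-likelihood of the model with no covariates (beta = 0)."""
    time, event = _check_sample(time, event)
    curve_times = np.unique(time[event == 1])
    ll = 0.0
    for t in curve_times:
        nrisk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        if ties == "breslow":
            ll -= d * np.log(nrisk)
        else:  # efron: tied deaths each see the risk set shrunk by l/d * d = l
            ll -= float(np.sum(np.log(nrisk - np.arange(d))))
    return ll


def design_matrix(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Numeric design matrix: categorical (object) columns are expanded to
    0/1 dummies against their lexicographically first level."""
    if not variables:
        return pd.DataFrame(index=table.index)
    parts = []
    for v in variables:
        col = table[v]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(x for x in col.dropna().unique())
            for lev in levels[1:]:
                d = (col == lev).astype(float)
                d[col.isna()] = np.nan
                parts.append(d.rename(f"{v}[{lev}]"))
        else:
            parts.append(col.astype(float))
    return pd.concat(parts, axis=1)


def fit_cox(table: pd.DataFrame, outcome: str, variables: list[str],
            ties: str = "efron") -> CoxFit:
    """Maximize the Cox partial likelihood for `outcome` in {"os","pfs"}.

    Rows incomplete on the requested variables are dropped (complete-case)
    with the dropped count logged. An empty variable list yields the null
    model (loglik of beta=0, AIC = -2 loglik).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    tcol, ecol = OUTCOME_COLUMNS[outcome]
    X = design_matrix(table, list(variables))
    df = pd.concat([table[[tcol, ecol]], X], axis=1)
    complete = df.dropna()
    dropped = len(df) - len(complete)
    if dropped:
        logger.info("fit_cox(%s): %d incomplete rows dropped (%d used)",
                    outcome, dropped, len(complete))
    time = complete[tcol].to_numpy(dtype=float)
    event = complete[ecol].to_numpy(dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")

    if X.shape[1] == 0:
        ll = null_partial_loglik(time, event, ties)
        return CoxFit(variables=[], coefs=np.zeros(0), cov=np.zeros((0, 0)),
                      loglik=ll, aic=-2 * ll, n=len(complete),
                      n_events=int(event.sum()), converged=True, ties=ties,
                      baseline_cumhaz=None, means=np.zeros(0))

    for c in X.columns:
        if complete[c].nunique() <= 1:
            raise ValueError(f"degenerate design: column {c!r} is constant on the analysis set")

    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(complete, duration_col=tcol, event_col=ecol)
        except ConvergenceError:
            raise RuntimeError("Cox fit failed to converge")

    names = list(cph.params_.index)
    coefs = cph.params_.to_numpy()
    k = len(names)
    ll = float(cph.log_likelihood_)
    return CoxFit(variables=names, coefs=coefs,
                  cov=cph.variance_matrix_.to_numpy(),
                  loglik=ll, aic=-2 * ll + 2 * k, n=len(complete),
                  n_events=int(event.sum()), converged=converged, ties="efron",
                  baseline_cumhaz=cph.baseline_cumulative_hazard_.iloc[:, 0],
                  means=complete[names].mean().to_numpy())


# ---------------------------------------------------------------------------
# discrimination & calibration
# ---------------------------------------------------------------------------


def harrell_c(score, time, event) -> float:
    """Harrell's concordance: P(higher risk score fails earlier) over usable
    pairs; tied scores count 1/2. Vectorized O(n^2) enumeration."""
    score = np.asarray(score, dtype=float)
    time, event = _check_sample(time, event)
    if score.shape != time.shape:
        raise ValueError("score and sample lengths differ")
    # usable pair (i, j): t_i < t_j and event_i, or t_i == t_j and exactly one event
    ti = time[:, None]
    tj = time[None, :]
    ei = event[:, None].astype(bool)
    ej = event[None, :].astype(bool)
    usable = (ti < tj) & ei
    usable |= (ti == tj) & ei & ~ej
    si = score[:, None]
    sj = score[None, :]
    conc = np.sum(usable & (si > sj)) + 0.5 * np.sum(usable & (si == sj))
    npairs = int(np.sum(usable))
    if npairs == 0:
        raise ValueError("no usable pairs for concordance")
    return float(conc / npairs)


def calibration_by_quartile(model: CoxFit, table: pd.DataFrame, outcome: str,
                            tau: float, n_boot: int = 500, seed: int = 0,
                            score=None) -> pd.DataFrame:
    """Predicted vs observed survival at tau within risk-score quartiles.

    Patients are grouped by quartile of `score` (default: the model's linear
    predictor); per quartile the mean model-predicted S(tau|x) is compared to
    the Kaplan-Meier estimate at tau, with percentile bootstrap CIs over
    ``n_boot`` resamples of the quartile's patients.
    """
    from .risk import assign_quartiles  # local import to avoid a cycle

    tcol, ecol = OUTCOME_COLUMNS[outcome]
    X = design_matrix(table, _base_variables(model.variables))
    use = pd.concat([table[[tcol, ecol]], X], axis=1).dropna()
    if use.empty:
        raise ValueError("no complete rows for calibration")
    Xc = use[model.variables]
    pred = model.survival_at(Xc, tau)
    s = model.linear_predictor(Xc) if score is None else np.asarray(score)[use.index]
    labels = assign_quartiles(s)
    time = use[tcol].to_numpy(dtype=float)
    event = use[ecol].to_numpy(dtype=int)

    rng = np.random.default_rng(seed)
    rows = []
    for q in (1, 2, 3, 4):
        m = labels == q
        if not m.any():
            raise ValueError(f"empty quartile Q{q}")
        tq, eq, pq = time[m], event[m], pred[m]
        obs = kaplan_meier(tq, eq).survival_at(tau)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, tq.size, tq.size)
            boots[b] = kaplan_meier(tq[idx], eq[idx]).survival_at(tau)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append({"quartile": q, "n": int(m.sum()), "predicted": float(pq.mean()),
                     "observed": float(obs), "observed_ci_low": float(lo),
                     "observed_ci_high": float(hi)})
    return pd.DataFrame(rows)


def _base_variables(design_names: list[str]) -> list[str]:
    """Recover raw column names from dummy-expanded design names."""
    out = []
    for name in design_names:
        base = name.split("[", 1)[0]
        if base not in out:
            out.append(base)
    return out
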