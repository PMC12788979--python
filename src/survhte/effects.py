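"""Effect-modeling inference: Monte-Carlo cross-validated GATES.

Single-split ITE estimates from a causal survival forest are noisy and
their in-sample quartiles are adaptively chosen, so naive per-quartile CIs
are invalid. The generic machine-learning inference framework repairs this
by repeated sample splitting: in each of S repetitions the trial is split
into an auxiliary fold (fits the forest) and a main fold (receives ITE
predictions, is cut into ITE quartiles, and yields per-quartile RMST
differences). Per-repetition intervals are computed at level 1 - alpha/2 and
the medians of point estimates and interval endpoints across repetitions are
reported as the nominal 1 - alpha inference (median aggregation absorbs the
extra alpha/2 of splitting uncertainty).

Also provided: median-aggregated split-frequency variable importance and
covariate profiles by ITE quartile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import ForestConfig, fit_forest, predict_ite, variable_importance
from .risk import assign_quartiles
from .survival import OUTCOME_COLUMNS, rmst_difference

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "GatesResult",
    "monte_carlo_gates",
    "aggregate_importance",
    "ite_quartile_profiles",
]


@dataclass
class SplitPlan:
    repetitions: int = 100
    aux_fraction: float = 0.5
    seed: int = 0

    def validate(self):
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not 0 < self.aux_fraction < 1:
            raise ValueError("aux_fraction must be in (0, 1)")


@dataclass
class GatesResult:
    """Aggregated group-average treatment effects over ITE quartiles."""

    summary: pd.DataFrame            # Q1..Q4 + ATE: estimate, ci_low, ci_high, n_reps
    per_rep: pd.DataFrame            # repetition x quartile point estimates
    importance: pd.Series            # median split-frequency importance, sums to 1
    patient_ite: pd.Series           # per-patient median main-fold ITE (NaN if never in main)
    n_dropped: int
    tau: float
    alpha: float
    outcome: str

    @property
    def estimates(self) -> np.ndarray:
        return self.summary.loc[self.summary["group"] != "ATE", "estimate"].to_numpy()


def monte_carlo_gates(table: pd.DataFrame, outcome: str, tau: float,
                      covariates: list[str], forest_config: ForestConfig,
                      plan: SplitPlan, alpha: float = 0.05,
                      treatment_col: str = "arm") -> GatesResult:
    """Monte-Carlo cross-validated quartile cATEs with median aggregation.

    ``table`` rows incomplete on the covariates or outcome are dropped up
    front (logged). Repetitions in which an ITE quartile of the main fold
    contains a single arm are dropped; more than 20% dropped is an error.
    Deterministic given ``plan.seed`` and ``forest_config.seed``.
    """
    plan.validate()
    tcol, ecol = OUTCOME_COLUMNS[outcome]
    cols = [tcol, ecol, treatment_col] + list(covariates)
    data = table[cols].dropna().reset_index(drop=True)
    n = len(data)
    dropped_rows = len(table) - n
    if dropped_rows:
        logger.info("monte_carlo_gates: %d incomplete rows dropped (%d used)", dropped_rows, n)
    if n < 80:
        raise ValueError("need at least 80 complete patients")

    n_aux = int(round(n * plan.aux_fraction))
    S = plan.repetitions
    est = np.full((S, 4), np.nan)
    lo = np.full((S, 4), np.nan)
    hi = np.full((S, 4), np.nan)
    importances: list[pd.Series] = []
    ite_acc: list[list[float]] = [[] for _ in range(n)]
    n_dropped = 0

    time = data[tcol].to_numpy(dtype=float)
    event = data[ecol].to_numpy(dtype=int)
    arm = data[treatment_col].to_numpy(dtype=int)
    Xall = data[list(covariates)]

    for s in range(S):
        rng = np.random.default_rng(plan.seed + s)
        perm = rng.permutation(n)
        aux, main = perm[:n_aux], perm[n_aux:]
        cfg = ForestConfig(**{**forest_config.__dict__,
                              "tau": tau, "seed": (forest_config.seed + 7919 * s) % (2**31)})
        forest = fit_forest(Xall.iloc[aux], arm[aux], time[aux], event[aux], cfg)
        ite = predict_ite(forest, Xall.iloc[main])
        for i, v in zip(main, ite):
            ite_acc[i].append(float(v))
        labels = assign_quartiles(ite)

        ok = True
        rep_est = np.empty(4)
        rep_lo = np.empty(4)
        rep_hi = np.empty(4)
        for q in (1, 2, 3, 4):
            m = labels == q
            a = arm[main][m]
            if not ((a == 1).any() and (a == 0).any()):
                ok = False
                break
            t1 = main[m][a == 1]
            t0 = main[m][a == 0]
            d = rmst_difference(time[t1], event[t1], time[t0], event[t0],
                                tau, alpha=alpha / 2)   # level 1 - alpha/2
            rep_est[q - 1] = d.difference
            rep_lo[q - 1] = d.ci_low
            rep_hi[q - 1] = d.ci_high
        if not ok:
            n_dropped += 1
            logger.info("repetition %d dropped: single-arm quartile", s)
            continue
        est[s], lo[s], hi[s] = rep_est, rep_lo, rep_hi
        importances.append(variable_importance(forest))

    used = ~np.isnan(est[:, 0])
    if n_dropped > 0.2 * S:
        raise RuntimeError(f"{n_dropped}/{S} repetitions dropped (> 20%)")

    rows = []
    for q in range(4):
        rows.append({"group": f"Q{q + 1}",
                     "estimate": float(np.median(est[used, q])),
                     "ci_low": float(np.median(lo[used, q])),
                     "ci_high": float(np.median(hi[used, q])),
                     "n_reps": int(used.sum())})
    d = rmst_difference(time[arm == 1], event[arm == 1],
                        time[arm == 0], event[arm == 0], tau, alpha=alpha)
    rows.append({"group": "ATE", "estimate": d.difference, "ci_low": d.ci_low,
                 "ci_high": d.ci_high, "n_reps": int(used.sum())})

    per_rep = pd.DataFrame(est[used], columns=["Q1", "Q2", "Q3", "Q4"])
    patient_ite = pd.Series([float(np.median(v)) if v else np.nan for v in ite_acc],
                            index=data.index, name="ite")
    return GatesResult(summary=pd.DataFrame(rows), per_rep=per_rep,
                       importance=aggregate_importance(importances),
                       patient_ite=patient_ite, n_dropped=n_dropped,
                       tau=tau, alpha=alpha, outcome=outcome)


def aggregate_importance(per_rep: list[pd.Series]) -> pd.Series:
    """Per-variable median across repetitions, renormalized to sum to 1."""
    if not per_rep:
        raise ValueError("need at least one repetition")
    idx = per_rep[0].index
    for s in per_rep[1:]:
        if not s.index.equals(idx):
            raise ValueError("inconsistent variable sets across repetitions")
    med = pd.concat(per_rep, axis=1).median(axis=1)
    total = med.sum()
    return (med / total if total > 0 else med).rename("importance")


def ite_quartile_profiles(table: pd.DataFrame, ite, covariates: list[str]) -> pd.DataFrame:
    """Covariate summaries by ITE quartile (Q1 lowest predicted effect).

    Categorical/binary variables: count and percent per level (percentages
    over non-missing values sum to 100 per quartile). Continuous variables:
    median and IQR. Patients with NaN ITE are excluded.
    """
    ite = pd.Series(np.asarray(ite, dtype=float), index=table.index)
    keep = ite.notna()
    sub = table.loc[keep]
    labels = assign_quartiles(ite[keep].to_numpy())

    rows = []
    for q in (1, 2, 3, 4):
        grp = sub.iloc[labels == q]
        for v in covariates:
            col = grp[v]
            if col.dtype == object or col.dropna().nunique() <= 2:
                nn = col.notna().sum()
                for lev, cnt in col.value_counts().sort_index().items():
                    rows.append({"quartile": q, "variable": v, "level": str(lev),
                                 "statistic": "count_percent", "count": int(cnt),
                                 "value": 100.0 * cnt / nn if nn else np.nan})
            else:
                rows.append({"quartile": q, "variable": v, "level": "",
                             "statistic": "median", "count": int(col.notna().sum()),
                             "value": float(col.median())})
                rows.append({"quartile": q, "variable": v, "level": "",
                             "statistic": "iqr_low", "count": int(col.notna().sum()),
                             "value": float(col.quantile(0.25))})
                rows.append({"quartile": q, "variable": v, "level": "",
                             "statistic": "iqr_high", "count": int(col.notna().sum()),
                             "value": float(col.quantile(0.75))})
    return pd.DataFrame(rows)
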