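"""Honest causal survival forest on the restricted-mean-survival scale.

Estimates per-patient treatment effects tau(x) = E[min(T1, tau) - min(T0, tau) | x]
(months of restricted survival gained under treatment) from right-censored
two-arm RCT data:

* Censoring is handled by inverse-probability-of-censoring weighting (IPCW):
  a subject whose tau-restricted outcome is observed (event before tau, or
  followed past tau) contributes min(T, tau) with weight 1/G(min(T,tau)-),
  where G is the Kaplan-Meier estimate of the censoring survival function;
  subjects censored before tau get weight 0 but still route through splits.
* Trees are double-sample honest: each tree draws a subsample without
  replacement, splits it into a structure half (placing splits) and an
  honesty half (estimating leaf effects), so leaf estimates are free of
  adaptive-selection bias.
* Splits maximize effect heterogeneity: sum over children of
  n_child * (delta_child - delta_parent)^2, where delta is the IPCW-weighted
  treated-minus-control mean of min(T, tau).
* Variable importance is the split-frequency share per variable, with no
  depth weighting.

The tree grower and predictor are numba-compiled; a forest of 2000 trees on
a 4000-patient trial fits in seconds on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._forest_core import grow_forest, predict_forest, MAX_RETRIES

logger = logging.getLogger(__name__)

__all__ = [
    "ForestConfig",
    "Forest",
    "censoring_weights",
    "fit_forest",
    "predict_ite",
    "variable_importance",
]


class PositivityError(RuntimeError):
    """Censoring survival G reached 0 before tau with unobserved outcomes left."""


@dataclass
class ForestConfig:
    """Hyperparameters of the honest causal survival forest.

    The propensity is known from randomization (0.5 for 1:1 allocation); it
    documents the design and validates the data but does not enter the
    arm-wise mean contrasts, which are unbiased for any constant propensity.
    """

    tau: float
    num_trees: int = 2000
    subsample_fraction: float = 0.5
    honesty_fraction: float = 0.5
    mtry: int | None = None          # default ceil(sqrt(p))
    min_leaf: int = 5                # per arm, in both halves
    max_depth: int = -1              # unbounded
    propensity: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if not 0 < self.honesty_fraction < 1:
            raise ValueError("honesty_fraction must be in (0, 1)")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not 0 < self.propensity < 1:
            raise ValueError("propensity must be in (0, 1)")
        if self.num_trees < 1:
            raise ValueError("num_trees must be >= 1")


@dataclass
class Forest:
    """Fitted forest: flat node arrays per tree plus subsample bookkeeping."""

    config: ForestConfig
    feature_names: list[str]
    feat: np.ndarray       # (trees, max_nodes) split variable, -1 = leaf
    thr: np.ndarray        # split thresholds (x < thr goes left)
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray      # leaf delta estimates (honesty half)
    inbag: np.ndarray      # (trees, n_train) bool
    structure: np.ndarray  # (trees, n_train) bool: in structure half
    n_train: int
    X_train: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"config": {**self.config.__dict__}, "feature_names": self.feature_names,
                "trees": [{"feat": self.feat[t].tolist(), "thr": self.thr[t].tolist(),
                           "left": self.left[t].tolist(), "right": self.right[t].tolist(),
                           "value": self.value[t].tolist()}
                          for t in range(self.feat.shape[0])]}


def censoring_weights(time, event, tau: float) -> np.ndarray:
    """IPCW weights for the tau-restricted outcome min(T, tau).

    G is the Kaplan-Meier estimate of the censoring distribution (event and
    censoring roles swapped; deaths at t stay at risk for censoring at t).
    Weight = 1/G(min(T, tau)-) when the restricted outcome is observed
    (event before tau, or followed to tau), else 0.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = time.size
    observed = (event == 1) | (time >= tau)
    if (1 - event).sum() == 0:
        return np.ones(n)

    # KM of censoring: "events" are censorings
    order = np.argsort(time, kind="stable")
    ts, cs = time[order], (1 - event[order])
    utimes = np.unique(ts)
    d = np.zeros(utimes.size)
    tot = np.zeros(utimes.size)
    idx = np.searchsorted(utimes, ts)
    np.add.at(d, idx, cs)
    np.add.at(tot, idx, 1)
    at_risk = n - np.concatenate(([0.0], np.cumsum(tot)[:-1]))
    frac = 1.0 - d / at_risk
    G = np.cumprod(frac)                      # G(t) right after each utime

    # G(u-): product over censoring times strictly before u
    eval_t = np.minimum(time, tau)
    pos = np.searchsorted(utimes, eval_t, side="left") - 1   # last utime < eval_t
    Gm = np.where(pos >= 0, G[np.clip(pos, 0, None)], 1.0)
    w = np.zeros(n)
    bad = observed & (Gm <= 0)
    if bad.any():
        t_bad = float(eval_t[bad].min())
        raise PositivityError(
            f"censoring survival reaches 0 before t={t_bad:.4g} <= tau={tau:g} "
            "with restricted outcomes still to be weighted")
    w[observed] = 1.0 / Gm[observed]
    return w


def _encode(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str], dict]:
    """One-hot encode object/categorical columns; keep numerics as-is."""
    parts, names, levels = [], [], {}
    for c in covariates.columns:
        col = covariates[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levs = sorted(x for x in col.dropna().unique())
            levels[c] = levs
            for lev in levs[1:]:
                parts.append((col == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
        else:
            parts.append(col.to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(parts) if parts else np.empty((len(covariates), 0))
    return X, names, levels


def fit_forest(covariates: pd.DataFrame, arm, time, event,
               config: ForestConfig, _swap_halves: bool = False) -> Forest:
    """Grow an honest causal survival forest. Deterministic given config.seed.

    ``covariates`` must be complete (no NaN); categorical columns are
    one-hot encoded. ``_swap_halves`` exchanges the structure and honesty
    halves of every tree (testing hook for the honesty property).
    """
    config.validate()
    X, names, levels = _encode(covariates)
    if X.shape[1] < 1:
        raise ValueError("need at least one covariate")
    if np.isnan(X).any():
        raise ValueError("covariates contain missing values; complete-case first")
    arm = np.asarray(arm, dtype=np.int64)
    if set(np.unique(arm)) - {0, 1}:
        raise ValueError("arm must be 0/1")
    if not ((arm == 1).any() and (arm == 0).any()):
        raise ValueError("both arms must be present")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)

    w = censoring_weights(time, event, config.tau)
    y = np.minimum(time, config.tau)

    n, p = X.shape
    n_sub = max(4 * config.min_leaf, int(round(n * config.subsample_fraction)))
    n_sub = min(n_sub, n)
    n_struct = max(2 * config.min_leaf, int(round(n_sub * (1 - config.honesty_fraction))))
    n_struct = min(n_struct, n_sub - 2 * config.min_leaf)
    if n_struct < 2:
        raise ValueError("subsample too small for honest splitting")
    mtry = config.mtry if config.mtry is not None else int(np.ceil(np.sqrt(p)))
    mtry = min(max(1, mtry), p)
    max_depth = config.max_depth if config.max_depth >= 0 else 10**6

    feat, thr, left, right, value, inbag, structure, n_retry_fail = grow_forest(
        np.ascontiguousarray(X), arm, y, w,
        config.num_trees, n_sub, n_struct, mtry, config.min_leaf,
        max_depth, config.seed, 1 if _swap_halves else 0)
    if n_retry_fail > 0:
        raise RuntimeError(
            f"{n_retry_fail} trees could not draw a subsample with both arms "
            f"represented after {MAX_RETRIES} retries")
    return Forest(config=replace(config), feature_names=names, feat=feat, thr=thr,
                  left=left, right=right, value=value, inbag=inbag,
                  X_train=X, structure=structure, n_train=n)


def predict_ite(forest: Forest, covariates: pd.DataFrame | None = None,
                oob: bool = False) -> np.ndarray:
    """Per-patient predicted RMST difference at tau (months).

    With ``oob=True`` (training rows only) each prediction averages only the
    trees whose subsample excluded that patient.
    """
    if oob:
        if covariates is not None:
            raise ValueError("oob predictions are for the training rows; omit covariates")
        raise_if = forest.inbag
        X = forest.X_train
    else:
        if covariates is None:
            X = forest.X_train
        else:
            X, names, _ = _encode(covariates)
            if names != forest.feature_names:
                raise ValueError(
                    f"covariates do not match training schema: {names} vs "
                    f"{forest.feature_names} (unseen categorical level?)")
        raise_if = np.zeros((forest.feat.shape[0], X.shape[0]), dtype=np.bool_)
    out = predict_forest(forest.feat, forest.thr, forest.left, forest.right,
                         forest.value, np.ascontiguousarray(X), raise_if)
    return out


def variable_importance(forest: Forest) -> pd.Series:
    """Share of all splits placed on each variable (no depth weighting);
    sums to 1. A forest with no splits returns zeros with a warning."""
    counts = np.zeros(len(forest.feature_names))
    f = forest.feat[forest.feat >= 0]
    if f.size == 0:
        logger.warning("forest has no splits; importance undefined (all zeros)")
        return pd.Series(counts, index=forest.feature_names, name="importance")
    np.add.at(counts, f, 1)
    vi = counts / counts.sum()
    _make_sum_exact(vi)
    return pd.Series(vi, index=forest.feature_names, name="importance")


def _make_sum_exact(vi: np.ndarray) -> None:
    """Absorb the float summation residual (a few ulps) so np.sum(vi) == 1.0.

    Tries each weight in ascending order (finest ulp first) and keeps the
    first adjustment that makes the pairwise-summed total exact; pairwise
    rounding can swallow a single-element change, so a search is needed.
    """
    for _ in range(4):
        r = 1.0 - np.sum(vi)
        if r == 0.0:
            return
        for j in np.argsort(vi):
            old = vi[j]
            if old + r < 0:
                continue
            vi[j] = old + r
            if np.sum(vi) == 1.0:
                return
            vi[j] = old
        j = int(np.argmax(vi))
        vi[j] = np.nextafter(vi[j], vi[j] + r)
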