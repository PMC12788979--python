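"""End-to-end orchestration: configuration, both HTE stages, reporting.

``run_pipeline`` executes (optionally) simulate -> risk modeling -> effect
modeling -> report, writing every result as a tidy CSV plus a JSON manifest
(versions, seeds, analysis-set sizes) so that each reported number is
traceable to a file. ``render_report`` only reshapes already-computed result
tables into figure-analog tables and a plain-text summary; it never
recomputes.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .effects import SplitPlan, ite_quartile_profiles, monte_carlo_gates
from .forest import ForestConfig
from .risk import (assign_quartiles, best_subset_cox, finalize_risk_model,
                   quartile_cate, risk_scores, safety_by_quartile,
                   validate_external)
from .synthetic import default_scenario, default_schema, simulate_trial

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_report", "demo_config"]

DEFAULT_TAUS = {"os": 24.0, "pfs": 6.0}

# low-missingness, prognostically active subset of the 17 baseline
# characteristics; small enough that the exhaustive 2^p AIC search stays
# interactive (the full 17-variable search is supported but slow)
DEFAULT_CANDIDATES = ["ecog_ge1", "opioid_use", "bone_metastasis",
                      "visceral_metastasis", "hemoglobin", "nlr"]
DEFAULT_FOREST_COVARIATES = ["ecog_ge1", "pain_intensity", "opioid_use",
                             "prior_arpi", "bone_metastasis",
                             "lymph_node_metastasis", "visceral_metastasis",
                             "hemoglobin", "nlr", "alp", "psa"]


@dataclass
class RunConfig:
    input: str | None = None            # trial CSV; None -> simulate
    external: str | None = None         # external-cohort CSV for validation
    outcomes: list[str] = field(default_factory=lambda: ["os", "pfs"])
    taus: dict = field(default_factory=lambda: dict(DEFAULT_TAUS))
    candidates: list[str] = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    forest_covariates: list[str] = field(default_factory=lambda: list(DEFAULT_FOREST_COVARIATES))
    num_trees: int = 2000
    min_leaf: int = 5
    mtry: int | None = None
    max_depth: int = -1
    repetitions: int = 100
    aux_fraction: float = 0.5
    n_boot: int = 500
    alpha: float = 0.05
    simulate_n: int = 1200
    seed: int = 0
    out: str = "results"

    def validate(self) -> None:
        for oc in self.outcomes:
            if oc not in ("os", "pfs"):
                raise ValueError(f"unknown outcome {oc!r}")
            if self.taus.get(oc, 0) <= 0:
                raise ValueError(f"tau for {oc} must be positive")
        if self.repetitions < 1 or self.num_trees < 1:
            raise ValueError("repetitions and num_trees must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def demo_config(out: str = "results", seed: int = 0, reduced: bool = True) -> RunConfig:
    """Bundled demo: simulated 1200-patient trial; reduced forest/bootstrap
    sizes so the full pipeline completes in a couple of minutes."""
    cfg = RunConfig(out=out, seed=seed)
    if reduced:
        cfg.num_trees = 200
        cfg.repetitions = 10
        cfg.n_boot = 100
    return cfg


def _stage_seed(base: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the single base seed."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % 1_000_003
    return (base * 1_000_003 + h) % (2**31)


def load_trial(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"patient_id", "arm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trial table lacks required columns: {sorted(missing)}")
    if set(table["arm"].dropna().unique()) - {0, 1}:
        raise ValueError("arm must be coded 0 (control) / 1 (treated)")
    return table


def run_pipeline(config: RunConfig) -> dict:
    """Run both HTE analyses and write the result bundle under config.out.

    Returns the bundle as a dict of DataFrames/objects. On a stage failure,
    results written so far are preserved next to a FAILED marker naming the
    stage.
    """
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "run.log")
    (outdir / "config.json").write_text(config.to_json())

    bundle: dict = {"config": config}
    manifest = {"package_version": __version__, "seed": config.seed,
                "python": sys.version.split()[0], "stages": {}}
    stage = "load"
    try:
        if config.input:
            table = load_trial(config.input)
            truth = None
        else:
            stage = "simulate"
            scenario = default_scenario(n=config.simulate_n,
                                        seed=_stage_seed(config.seed, "simulate"))
            trial = simulate_trial(default_schema(), scenario)
            trial.write(outdir / "synthetic")
            table, truth = trial.table, trial.truth
        bundle["table"] = table
        manifest["n_patients"] = int(len(table))
        manifest["n_treated"] = int((table["arm"] == 1).sum())

        external = load_trial(config.external) if config.external else None

        for outcome in config.outcomes:
            tau = float(config.taus[outcome])
            stage = f"risk:{outcome}"
            bundle[stage] = _risk_stage(table, external, outcome, tau, config,
                                        outdir, manifest)
            stage = f"effect:{outcome}"
            bundle[stage] = _effect_stage(table, outcome, tau, config, outdir, manifest)

        stage = "report"
        report = render_report(bundle)
        for name, df in report["tables"].items():
            df.to_csv(outdir / f"report_{name}.csv", index=False)
        (outdir / "report_summary.txt").write_text(report["summary"])
        bundle["report"] = report
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\n{exc!r}\n")
        raise
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


def _risk_stage(table, external, outcome, tau, config: RunConfig, outdir, manifest):
    search = best_subset_cox(table, outcome, config.candidates, keep_ledger=False)
    model = finalize_risk_model(table, outcome, search.selected)
    scores = risk_scores(model, table)
    scored = scores.dropna()
    labels = assign_quartiles(scored.to_numpy())
    sub = table.loc[scored.index]
    effects = quartile_cate(sub, labels, outcome, tau, alpha=config.alpha)

    from .survival import calibration_by_quartile, harrell_c
    tcol, ecol = f"{outcome}_time", f"{outcome}_event"
    c_dev = harrell_c(scored, sub[tcol], sub[ecol])
    cal = calibration_by_quartile(model.fit, sub.assign(arm=0), outcome, tau,
                                  n_boot=config.n_boot,
                                  seed=_stage_seed(config.seed, f"cal:{outcome}"))

    result = {"search": search, "model": model, "scores": scores,
              "labels": pd.Series(labels, index=scored.index),
              "effects": effects, "calibration": cal, "c_statistic": c_dev}

    prefix = outdir / f"risk_{outcome}"
    (Path(f"{prefix}_model.json")).write_text(json.dumps(
        {"outcome": outcome, "selected": list(search.selected),
         "selected_aic": search.selected_aic,
         "subsets_evaluated": search.n_candidates_evaluated,
         "analysis_n": search.analysis_n, "c_statistic": c_dev,
         **model.fit.to_dict()}, indent=2))
    scores.rename("risk_score").to_frame().assign(
        patient_id=table["patient_id"]).to_csv(f"{prefix}_scores.csv", index=False)
    effects.table.to_csv(f"{prefix}_quartile_effects.csv", index=False)
    cal.to_csv(f"{prefix}_calibration.csv", index=False)

    has_safety = {"trae_g3_nonheme", "discontinuation_reason"} <= set(table.columns)
    if has_safety:
        inc, disc, n_excl = safety_by_quartile(sub, labels)
        inc.to_csv(f"{prefix}_safety_incidence.csv", index=False)
        disc.to_csv(f"{prefix}_discontinuation.csv", index=False)
        result["safety"] = (inc, disc, n_excl)
        manifest["stages"][f"risk:{outcome}"] = {"safety_n": int(len(sub) - n_excl)}
    manifest["stages"].setdefault(f"risk:{outcome}", {}).update(
        {"analysis_n": search.analysis_n, "scored_n": int(len(scored)),
         "selected": list(search.selected), "c_statistic": c_dev})

    if external is not None:
        c_ext, cal_ext = validate_external(model, external, tau,
                                           n_boot=config.n_boot,
                                           seed=_stage_seed(config.seed, f"ext:{outcome}"))
        cal_ext.to_csv(f"{prefix}_external_calibration.csv", index=False)
        result["external"] = {"c_statistic": c_ext, "calibration": cal_ext}
        manifest["stages"][f"risk:{outcome}"]["external_c"] = c_ext
    return result


def _effect_stage(table, outcome, tau, config: RunConfig, outdir, manifest):
    fcfg = ForestConfig(tau=tau, num_trees=config.num_trees, mtry=config.mtry,
                        min_leaf=config.min_leaf, max_depth=config.max_depth,
                        seed=_stage_seed(config.seed, f"forest:{outcome}"))
    plan = SplitPlan(repetitions=config.repetitions, aux_fraction=config.aux_fraction,
                     seed=_stage_seed(config.seed, f"split:{outcome}"))
    covs = [c for c in config.forest_covariates if c in table.columns]
    gates = monte_carlo_gates(table, outcome, tau, covs, fcfg, plan,
                              alpha=config.alpha)
    cols = [f"{outcome}_time", f"{outcome}_event", "arm"] + covs
    complete = table[cols].dropna()
    profiles = ite_quartile_profiles(table.loc[complete.index].reset_index(drop=True),
                                     gates.patient_ite, covs)

    prefix = outdir / f"effect_{outcome}"
    gates.summary.to_csv(f"{prefix}_gates.csv", index=False)
    gates.per_rep.to_csv(f"{prefix}_per_rep_estimates.csv", index=False)
    gates.importance.rename_axis("variable").reset_index().to_csv(
        f"{prefix}_importance.csv", index=False)
    profiles.to_csv(f"{prefix}_ite_profiles.csv", index=False)
    manifest["stages"][f"effect:{outcome}"] = {
        "n_reps_used": int(gates.summary["n_reps"].iloc[0]),
        "n_dropped": gates.n_dropped}
    return {"gates": gates, "profiles": profiles}


def render_report(bundle: dict) -> dict:
    """Figure-analog tidy tables + a plain-text quartile-vs-ATE summary.

    fig1: RMST difference by risk quartile (per outcome, 4 quartiles + ATE);
    fig2: discontinuation reasons by risk quartile x arm;
    fig3: RMST difference by ITE quartile; s4: severe-toxicity incidence by
    risk quartile x arm; s5: variable importance.
    """
    config: RunConfig = bundle["config"]
    tables: dict[str, pd.DataFrame] = {}
    lines = []
    for outcome in config.outcomes:
        risk = bundle.get(f"risk:{outcome}")
        eff = bundle.get(f"effect:{outcome}")
        if risk is None or eff is None:
            raise KeyError(f"bundle incomplete: missing stage for {outcome}")
        tau = config.taus[outcome]

        fig1 = risk["effects"].table.copy()
        fig1.insert(0, "outcome", outcome)
        tables[f"fig1_{outcome}"] = fig1

        if "safety" in risk:
            inc, disc, _ = risk["safety"]
            s4 = inc.copy()
            s4.insert(0, "outcome", outcome)
            tables[f"s4_{outcome}"] = s4
            f2 = disc.copy()
            f2.insert(0, "outcome", outcome)
            tables[f"fig2_{outcome}"] = f2

        fig3 = eff["gates"].summary.copy()
        fig3.insert(0, "outcome", outcome)
        tables[f"fig3_{outcome}"] = fig3

        s5 = eff["gates"].importance.rename_axis("variable").reset_index()
        s5.insert(0, "outcome", outcome)
        tables[f"s5_{outcome}"] = s5

        ate = fig1.loc[fig1["group"] == "ATE"].iloc[0]
        lines.append(f"[{outcome.upper()}] tau = {tau:g} months")
        lines.append(f"  ATE (RMST difference, treated - control): "
                     f"{ate['estimate']:.2f} months (95% CI {ate['ci_low']:.2f} "
                     f"to {ate['ci_high']:.2f})")
        lines.append(f"  risk model: {', '.join(risk['search'].selected) or '(empty)'}; "
                     f"c = {risk['c_statistic']:.3f}")
        for _, r in fig1[fig1["group"] != "ATE"].iterrows():
            lines.append(f"    risk {r['group']}: {r['estimate']:+.2f} "
                         f"({r['ci_low']:.2f} to {r['ci_high']:.2f}) n={r['n']}")
        for _, r in fig3[fig3["group"] != "ATE"].iterrows():
            lines.append(f"    ITE  {r['group']}: {r['estimate']:+.2f} "
                         f"({r['ci_low']:.2f} to {r['ci_high']:.2f})")
        top = eff["gates"].importance.sort_values(ascending=False).head(3)
        lines.append("  top effect-modifier importance: " +
                     ", ".join(f"{k} {v:.1%}" for k, v in top.items()))
    return {"tables": tables, "summary": "\n".join(lines) + "\n"}


def _setup_logging(path: Path) -> None:
    root = logging.getLogger("survhte")
    root.setLevel(logging.INFO)
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
    fh = logging.FileHandler(path, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root.addHandler(fh)
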