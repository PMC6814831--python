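"""End-to-end workflow: trial tables in, study-style report tables out.

Stages mirror the study's analysis sequence: (1) fit and classify
functional responses per predator-prey group, with bootstrap confidence
bands; (2) summarise Manly preferences from the two-prey trials; (3)
combine relative FRRs, fecundity proxies and mean preferences into BR and
pairwise RBR scores, plus triplot coordinates.  Control trials are
validated first (all control prey must survive) and a failure blocks the
run unless overridden.

A metrics-only mode skips raw-trial fitting: it accepts a parameter table
(predator, prey, a, h) and a preference table (predator,
prop_invader, mean_alpha) and runs only the derived-metric arithmetic —
the mode used to recompute published summary tables from their printed
inputs.

Outputs are written atomically at the end of a successful run; any stage
error aborts before anything is written.  Given the same configuration
and seed, outputs are byte-identical between runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import StudyConfig
from .functional_response import (
    RogersModel,
    determine_fr_type,
    functional_response_ratio,
    max_feeding_rate,
)
from .io import read_fr_trials, read_switch_trials, validate_controls
from .preference import preference_bootstrap_test, summarize_preferences
from .resistance import PredatorProfile, compute_br, triplot_data

__all__ = [
    "PipelineError",
    "run_full_analysis",
    "metrics_only_analysis",
    "derived_fit_columns",
]

logger = logging.getLogger("bioticres")


class PipelineError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def derived_fit_columns(params: pd.DataFrame) -> pd.DataFrame:
    """Append max feeding rate (1/h) and FRR (a/h) to an (a, h) table."""
    out = params.copy()
    out["max_feeding_rate"] = [max_feeding_rate(h) for h in out["h"]]
    out["frr"] = [functional_response_ratio(a, h) for a, h in zip(out["a"], out["h"])]
    return out


def _fit_stage(fr_df: pd.DataFrame, config: StudyConfig, seed_seq):
    trials = fr_df[fr_df["is_control"] == 0]
    fits = []
    bands = []
    groups = sorted(trials.groupby(["predator", "prey"]).groups)
    seeds = iter(seed_seq.spawn(len(groups)))
    for predator, prey in groups:
        grp = trials[(trials["predator"] == predator) & (trials["prey"] == prey)]
        sub_seed = next(seeds)
        try:
            fr_type, shape = determine_fr_type(grp, config.alpha_level)
            res = RogersModel.from_dataframe(grp, T=config.duration).fit()
            band = res.bootstrap(n_boot=config.n_boot, conf=config.confidence, seed=sub_seed)
        except Exception as exc:
            raise PipelineError("fit-fr", f"group ({predator}, {prey}): {exc}") from exc
        pv = res.pvalues
        fits.append(
            {
                "predator": predator,
                "prey": prey,
                "linear_coef": shape.coef1,
                "linear_p": shape.p1,
                "fr_type": fr_type,
                "a": res.attack_rate,
                "a_p": pv["a"],
                "a_ci_low": band.a_ci[0],
                "a_ci_high": band.a_ci[1],
                "h": res.handling_time,
                "h_p": pv["h"],
                "h_ci_low": band.h_ci[0],
                "h_ci_high": band.h_ci[1],
                "max_feeding_rate": res.max_feeding_rate,
                "frr": res.frr,
                "frr_ci_low": band.frr_ci[0],
                "frr_ci_high": band.frr_ci[1],
                "boot_failed": band.n_failed,
            }
        )
        bf = band.band_frame()
        bf.insert(0, "prey", prey)
        bf.insert(0, "predator", predator)
        bands.append(bf)
    return pd.DataFrame(fits), pd.concat(bands, ignore_index=True)


def _preference_stage(switch_df: pd.DataFrame, config: StudyConfig, seed):
    summaries = summarize_preferences(switch_df, logger=logger)
    if not summaries:
        raise PipelineError("preference", "no valid switching trials in any group")
    tables = []
    for predator, summ in summaries.items():
        t = summ.table.copy()
        t.insert(0, "predator", predator)
        tables.append(t)
    pref_table = pd.concat(tables, ignore_index=True)
    tests = preference_bootstrap_test(
        switch_df, n_boot=config.n_boot, conf=config.confidence, seed=seed
    )
    test_table = pd.DataFrame(
        [
            {
                "predator": r.predator,
                "n_trials": r.n_trials,
                "mean_alpha_t": r.mean_alpha_t,
                "ci_low": r.ci[0] if r.ci else np.nan,
                "ci_high": r.ci[1] if r.ci else np.nan,
                "prefers_invader": r.prefers_invader,
                "conclusive": r.conclusive,
            }
            for r in tests.values()
        ]
    )
    overall = {p: s.overall_mean_alpha for p, s in summaries.items()}
    return pref_table, test_table, overall


def _resistance_stage(fits: pd.DataFrame, overall_alpha: dict, config: StudyConfig):
    invader = config.invader_prey
    profiles = []
    for predator, grp in fits.groupby("predator"):
        by_prey = grp.set_index("prey")
        if invader not in by_prey.index:
            raise PipelineError("resistance", f"predator {predator!r}: no fit for invader prey")
        natives = [p for p in by_prey.index if p != invader]
        if len(natives) != 1:
            raise PipelineError(
                "resistance", f"predator {predator!r}: need exactly one native prey fit"
            )
        if predator not in config.fecundity:
            raise PipelineError("resistance", f"no fecundity proxy configured for {predator!r}")
        if predator not in overall_alpha:
            raise PipelineError("resistance", f"no preference summary for {predator!r}")
        profiles.append(
            PredatorProfile(
                predator=predator,
                frr_invader=float(by_prey.loc[invader, "frr"]),
                frr_native=float(by_prey.loc[natives[0], "frr"]),
                fecundity=float(config.fecundity[predator]),
                mean_alpha=float(overall_alpha[predator]),
            )
        )
    result = compute_br(profiles)
    return result


def run_full_analysis(
    config: StudyConfig,
    fr_path,
    switch_path,
    out_dir,
    allow_control_failure: bool = False,
) -> dict:
    """Run the whole pipeline and write the report bundle to ``out_dir``.

    Returns a dict with the in-memory tables (``fits``, ``bands``,
    ``preference``, ``preference_test``, ``resistance``, ``triplot``,
    ``validation``).  Writes fits.csv, bands.csv, preference.csv,
    preference_test.csv, resistance.csv, triplot.csv and run_log.json.
    """
    out_dir = Path(out_dir)

    try:
        fr_df = read_fr_trials(fr_path)
        switch_df = read_switch_trials(switch_path)
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc

    fr_report = validate_controls(fr_df, eaten_cols=("eaten",))
    sw_report = validate_controls(switch_df, eaten_cols=("eaten_invader", "eaten_native"))
    for name, rep in (("fr_trials", fr_report), ("switch_trials", sw_report)):
        for w in rep.warnings:
            logger.warning("%s: %s", name, w)
        if not rep.passed and not allow_control_failure:
            raise PipelineError(
                "validate",
                f"{name}: control prey died in file rows {rep.control_violations}; "
                "experimental deaths cannot be attributed to predation",
            )

    master = np.random.SeedSequence(config.seed)
    fit_seq, pref_seq = master.spawn(2)
    fits, bands = _fit_stage(fr_df, config, fit_seq)
    pref_table, test_table, overall_alpha = _preference_stage(
        switch_df, config, pref_seq
    )
    br_result = _resistance_stage(fits, overall_alpha, config)
    tri = triplot_data(br_result)

    out_dir.mkdir(parents=True, exist_ok=True)
    nd = config.round_decimals
    outputs = {
        "fits.csv": fits.round(nd),
        "bands.csv": bands.round(nd),
        "preference.csv": pref_table.round(nd),
        "preference_test.csv": test_table.round(nd),
        "resistance.csv": br_result.pairwise.round(nd),
        "resistance_per_predator.csv": br_result.per_predator.round(nd),
        "triplot.csv": tri.round(nd),
    }
    for name, df in outputs.items():
        df.to_csv(out_dir / name, index=False)
    run_log = {
        "version": __version__,
        "seed": int(config.seed),
        "n_boot": int(config.n_boot),
        "confidence": config.confidence,
        "alpha_level": config.alpha_level,
        "duration": config.duration,
        "validation": {
            "fr_controls_ok": fr_report.passed,
            "switch_controls_ok": sw_report.passed,
            "fr_row_counts": fr_report.row_counts,
            "switch_row_counts": sw_report.row_counts,
        },
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n")

    return {
        "fits": fits,
        "bands": bands,
        "preference": pref_table,
        "preference_test": test_table,
        "resistance": br_result,
        "triplot": tri,
        "validation": {"fr_trials": fr_report, "switch_trials": sw_report},
    }


def metrics_only_analysis(
    params: pd.DataFrame,
    preference: pd.DataFrame,
    fecundity: dict,
    invader_prey: str = "A. albopictus",
    out_dir=None,
    round_decimals: int = 3,
) -> dict:
    """Derived metrics straight from parameter and preference tables.

    ``params``: columns predator, prey, a, h (one row per group).
    ``preference``: columns predator, prop_invader, mean_alpha (one row
    per availability level).  The per-predator overall preference is the
    unweighted mean over availability levels.  Computes 1/h, FRR, relative
    FRR, BR and pairwise RBR without touching raw trials.
    """
    for col in ("predator", "prey", "a", "h"):
        if col not in params.columns:
            raise PipelineError("metrics", f"parameter table missing column {col!r}")
    for col in ("predator", "prop_invader", "mean_alpha"):
        if col not in preference.columns:
            raise PipelineError("metrics", f"preference table missing column {col!r}")

    fit_table = derived_fit_columns(params)
    overall_alpha = preference.groupby("predator")["mean_alpha"].mean().to_dict()

    profiles = []
    for predator, grp in fit_table.groupby("predator"):
        by_prey = grp.set_index("prey")
        if invader_prey not in by_prey.index:
            raise PipelineError("metrics", f"predator {predator!r}: no row for invader prey")
        natives = [p for p in by_prey.index if p != invader_prey]
        if len(natives) != 1:
            raise PipelineError("metrics", f"predator {predator!r}: need exactly one native prey")
        profiles.append(
            PredatorProfile(
                predator=predator,
                frr_invader=float(by_prey.loc[invader_prey, "frr"]),
                frr_native=float(by_prey.loc[natives[0], "frr"]),
                fecundity=float(fecundity[predator]),
                mean_alpha=float(overall_alpha[predator]),
            )
        )
    br_result = compute_br(profiles)
    tri = triplot_data(br_result)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fit_table.round(round_decimals).to_csv(out_dir / "fits.csv", index=False)
        br_result.pairwise.round(round_decimals).to_csv(out_dir / "resistance.csv", index=False)
        br_result.per_predator.round(round_decimals).to_csv(
            out_dir / "resistance_per_predator.csv", index=False
        )
        tri.round(round_decimals).to_csv(out_dir / "triplot.csv", index=False)
    return {"fits": fit_table, "resistance": br_result, "triplot": tri}
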