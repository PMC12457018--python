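"""End-to-end desk-scale study orchestration.

simulate (or ingest) -> respirometry processing -> birth-date estimation ->
repeatability -> nine association models -> three path models -> robustness
variants, with session filtering, provenance and tidy CSV/JSON outputs
mirroring the study's result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig, BEHAVIOURS, MR_RESPONSES
from .growth import add_birth_columns
from .inference import (
    ModelSpec,
    RepeatabilityResult,
    association_models,
    prepare_analysis_table,
    repeatability,
)
from .path import build_dag, fit_path_model
from .respirometry import CorruptTraceError, summarize_session
from .synthetic import SyntheticBundle, generate_dataset

__all__ = ["StudyReport", "run_pipeline", "robustness_suite"]

logger = logging.getLogger("paceline")

_REPEATABLE = {
    "entry": ("entry", "binomial-logit"),
    "distance": ("distance_z", "gaussian"),
    "exploration": ("exploration_z", "gaussian"),
    "rmr": ("rmr_z", "gaussian"),
    "stress_max": ("stress_max_z", "gaussian"),
    "stress_integral": ("stress_integral_z", "gaussian"),
}


@dataclass
class StudyReport:
    """Every table of one pipeline run plus provenance."""

    repeatability: pd.DataFrame
    association: pd.DataFrame
    path_results: dict  # response -> PathModelResults
    robustness: pd.DataFrame | None
    session_filter: dict
    provenance: dict
    analysis: pd.DataFrame = field(repr=False, default=None)
    cohort: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "session_filter": self.session_filter,
            "repeatability": self.repeatability.to_dict(orient="records"),
            "association": self.association.to_dict(orient="records"),
            "path_models": {k: v.to_dict() for k, v in self.path_results.items()},
            "robustness": (self.robustness.to_dict(orient="records")
                           if self.robustness is not None else None),
        }


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump({"generator": config.generator.to_dict(),
                           "n_permutations": config.n_permutations,
                           "n_bootstrap": config.n_bootstrap,
                           "mode": config.mode,
                           "rng_seed": config.rng_seed}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)


def _measure_traces(bundle: SyntheticBundle) -> pd.DataFrame:
    """Replace generated metabolic columns by trace-derived measurements."""
    cohort = bundle.cohort.copy()
    for idx, row in cohort.iterrows():
        key = (row["individual_id"], int(row["session"]))
        trace = bundle.traces.get(key)
        if trace is None:
            cohort.loc[idx, ["rmr", "stress_max_pct", "stress_integral_pct"]] = np.nan
            continue
        try:
            s = summarize_session(trace, row["body_mass_g"])
        except CorruptTraceError as err:
            logger.warning("session %s: %s", key, err)
            cohort.loc[idx, ["rmr", "stress_max_pct", "stress_integral_pct"]] = np.nan
            continue
        cohort.loc[idx, "rmr"] = s.rmr
        cohort.loc[idx, "stress_max_pct"] = s.stress_max if s.stress_max is not None else np.nan
        cohort.loc[idx, "stress_integral_pct"] = (
            s.stress_integral if s.stress_integral is not None else np.nan
        )
    return cohort


def _filter_sessions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep sessions with both behaviour and metabolic data; count exclusions."""
    required_beh = ["entered_arena", "distance_cm", "exploration_pct"]
    required_mr = ["rmr", "stress_max_pct", "stress_integral_pct"]
    missing_beh = cohort[required_beh].isna().any(axis=1)
    missing_mr = cohort[required_mr].isna().any(axis=1) & ~missing_beh
    keep = ~(missing_beh | missing_mr)
    counts = {
        "rows_in": int(len(cohort)),
        "rows_used": int(keep.sum()),
        "excluded_missing_behaviour": int(missing_beh.sum()),
        "excluded_missing_metabolic": int(missing_mr.sum()),
    }
    return cohort[keep].reset_index(drop=True), counts


def _repeatability_tables(analysis: pd.DataFrame, config: PipelineConfig,
                          seeds) -> pd.DataFrame:
    rows = []
    horizons = {"short_term": analysis[analysis["session"] <= 2], "long_term": analysis}
    for (horizon, sub), seed_pair in zip(horizons.items(), seeds):
        for (variable, (col, family)), child in zip(_REPEATABLE.items(),
                                                    seed_pair.spawn(len(_REPEATABLE))):
            spec = ModelSpec(response=col, fixed_terms=["test_number"],
                             categorical=("test_number",), family=family,
                             random_intercept_groups=["individual_id"])
            if (sub["individual_id"].value_counts() >= 2).sum() == 0:
                logger.warning("%s/%s: no repeated measures, skipping", horizon, variable)
                continue
            res = repeatability(spec, sub, n_perm=config.n_permutations,
                                n_boot=config.n_bootstrap, seed=child)
            rows.append({
                "horizon": horizon, "variable": variable, "R": res.R,
                "ci_lo": res.ci95[0], "ci_hi": res.ci95[1], "p_perm": res.p_perm,
                "n_permutations": res.n_permutations, "scale": res.scale,
                "n_individuals": res.n_individuals, "n_observations": res.n_observations,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, write_outputs: bool = True,
                 include_robustness: bool = True) -> StudyReport:
    """Execute the whole analysis; see module docstring for the stages."""
    cfg_hash = _config_hash(config)
    ss = np.random.SeedSequence(config.rng_seed)
    s_rep_short, s_rep_long, s_assoc, s_rest = ss.spawn(4)

    stage = "simulate"
    try:
        if config.mode == "simulate":
            bundle = generate_dataset(config.generator, with_traces=config.process_traces)
            cohort = bundle.cohort
            stage = "respirometry"
            if config.process_traces:
                cohort = _measure_traces(bundle)
        else:
            if not getattr(config, "input_dir", None):
                raise ValueError("ingest mode needs config.input_dir with cohort.csv")
            cohort = pd.read_csv(Path(config.input_dir) / "cohort.csv")

        stage = "session_filter"
        cohort, counts = _filter_sessions(cohort)

        stage = "life_history"
        cohort = add_birth_columns(cohort, intervals=config.coarsen_intervals)

        stage = "analysis_table"
        analysis = prepare_analysis_table(cohort, use_paper_offsets=config.use_paper_offsets)

        stage = "repeatability"
        rep_table = _repeatability_tables(analysis, config, (s_rep_short, s_rep_long))

        stage = "association"
        assoc = association_models(analysis, n_perm=config.n_permutations, seed=s_assoc)

        stage = "path_analysis"
        path_results = {}
        for mr in MR_RESPONSES:
            path_results[mr] = fit_path_model(build_dag(response=mr), analysis)

        report = StudyReport(
            repeatability=rep_table,
            association=assoc,
            path_results=path_results,
            robustness=None,
            session_filter=counts,
            provenance={
                "config_hash": cfg_hash,
                "rng_seed": config.rng_seed,
                "mode": config.mode,
                "n_permutations": config.n_permutations,
                "n_bootstrap": config.n_bootstrap,
            },
            analysis=analysis,
            cohort=cohort,
        )
        if include_robustness:
            stage = "robustness"
            report.robustness = robustness_suite(config, report)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    if write_outputs:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        head = f"config_hash={cfg_hash} seed={config.rng_seed}"
        _write_csv(report.repeatability, out / "repeatability.csv", head)
        _write_csv(report.association, out / "association.csv", head)
        for mr, res in report.path_results.items():
            _write_csv(res.coefficients, out / f"path_{mr}_coefficients.csv", head)
            with open(out / f"path_{mr}.json", "w") as fh:
                json.dump(res.to_dict(), fh, indent=1, default=float)
        if report.robustness is not None:
            _write_csv(report.robustness, out / "robustness.csv", head)
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1, default=float)
        config.to_yaml(out / "config_used.yaml")
    return report


def robustness_suite(config: PipelineConfig, report: StudyReport) -> pd.DataFrame:
    """Re-run the path analyses under coarsened birth dates and inverted DAGs.

    For each metabolic response and variant, records whether the sign and
    the significance verdict (alpha = 0.05) of every birth-date edge agree
    with the main (daily-scale, forward) analysis.
    """
    if report.analysis is None or report.cohort is None:
        raise ValueError("robustness requires a completed main run (in-memory report)")
    rows = []
    for mr in MR_RESPONSES:
        base = report.path_results[mr]
        variants = {}
        for interval in config.coarsen_intervals:
            col = f"birth_date_{interval}d"
            if report.cohort[col].nunique() <= 1:
                raise ValueError(
                    f"coarsening to {interval}-day bins leaves a single birth-date bin; "
                    "the predictor is degenerate"
                )
            analysis_c = prepare_analysis_table(report.cohort, birth_column=col,
                                                use_paper_offsets=config.use_paper_offsets)
            variants[f"coarse_{interval}d"] = fit_path_model(build_dag(response=mr), analysis_c)
        variants["inverted"] = fit_path_model(build_dag(response=mr, direction="inverted"),
                                              report.analysis)
        for name, res in variants.items():
            agree = True
            for target in (*BEHAVIOURS, mr):
                try:
                    b0 = base.coefficient("birth_date", target)
                    p0 = float(base.coefficients.query(
                        "source=='birth_date' and target==@target")["p"].iloc[0])
                    b1 = res.coefficient("birth_date", target)
                    p1 = float(res.coefficients.query(
                        "source=='birth_date' and target==@target")["p"].iloc[0])
                except KeyError:
                    continue
                agree &= (np.sign(b0) == np.sign(b1)) and ((p0 < 0.05) == (p1 < 0.05))
            rows.append({"response": mr, "variant": name, "agrees_with_main": bool(agree),
                         "fisher_p": res.fisher_p})
    return pd.DataFrame(rows)
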