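"""End-to-end orchestration: simulate, fit reporting model, select
specification, correct prevalence, fit risk model.

A single global seed is fanned out deterministically to per-stage child seeds
(via ``numpy.random.SeedSequence(seed).spawn``), so a stage can be rerun in
isolation and still reproduce the full-pipeline output.  Every stage logs row
counts and exclusions into a JSON run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import btzip, correction, io, risk, selection, synthetic

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit_reporting", "select_model", "correct", "fit_risk")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic child seed (< 2**31) for a named stage."""
    idx = STAGES.index(stage)
    child = np.random.SeedSequence(global_seed).spawn(len(STAGES))[idx]
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Paths, stage toggles and model blocks for one pipeline run."""

    out_dir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: synthetic.SimConfig | None = None
    respondents_path: str | None = None  # alternative to simulating
    pregnancies_path: str | None = None
    reporting_spec: btzip.BTZIPSpec | None = None
    candidates: selection.CandidateSet | None = None
    risk_spec: risk.MNLSpec | None = None
    reporting_rates: dict[str, float] | None = None  # percent, for `correct`

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown} (valid: {list(STAGES)})")
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if "simulate" not in self.stages:
            for p, stage in ((self.respondents_path, "fit_reporting"),
                             (self.pregnancies_path, "fit_risk")):
                if stage in self.stages and (p is None or not Path(p).exists()):
                    raise FileNotFoundError(
                        f"stage {stage!r} needs an input table; missing path {p!r}"
                    )


def _default_reporting_spec() -> btzip.BTZIPSpec:
    return btzip.BTZIPSpec(
        count_covariates=["education", "age_group_survey", "parity_survey",
                          "infertility_treatment", "ever_smoked", "bmi_category"],
        zero_covariates=["education"],
        report_covariates=["education", "marital_status", "health", "income"],
    )


def _default_risk_spec(seed: int) -> risk.MNLSpec:
    return risk.MNLSpec(
        covariates=["age_group_at_start", "prior_miscarriages", "parity_at_start",
                    "education", "cohort"],
        chains=2,
        iterations=2000,
        seed=seed,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages in order; returns the run report dict.

    A stage failure halts the run with the stage named; outputs of completed
    stages are retained on disk.  The report reconciles row counts
    (input = used + excluded) per stage.
    """
    config.validate()
    out = Path(config.out_dir)
    report: dict = {"seed": config.seed, "stages": {}, "versions": _versions()}
    respondents = None
    pregnancies = None
    fit = None

    try:
        if "simulate" in config.stages:
            sim = config.sim or synthetic.fecond_like_preset(seed=stage_seed(config.seed, "simulate"))
            respondents = synthetic.simulate_respondents(sim)
            pregnancies = synthetic.simulate_pregnancies(sim)
            synthetic.write_respondents(respondents, out / "respondents.csv")
            synthetic.write_pregnancies(pregnancies, out / "pregnancies.csv")
            report["stages"]["simulate"] = {
                "n_women": int(sim.n_women),
                "n_respondent_rows": len(respondents),
                "n_pregnancies": len(pregnancies),
            }
        if respondents is None and config.respondents_path:
            respondents, rrep = io.read_respondents(config.respondents_path)
            report["stages"]["read_respondents"] = dataclasses.asdict(rrep)
        if pregnancies is None and config.pregnancies_path:
            pregnancies, prep = io.read_pregnancies(config.pregnancies_path)
            report["stages"]["read_pregnancies"] = dataclasses.asdict(prep)

        if "fit_reporting" in config.stages:
            spec = config.reporting_spec or _default_reporting_spec()
            fit = btzip.fit(respondents, spec, seed=stage_seed(config.seed, "fit_reporting"))
            fit.to_json(out / "reporting_fit.json")
            used = fit.n_obs
            table = btzip.average_reporting_rate(fit, respondents.iloc[:used] if fit.n_dropped == 0 else respondents, by="education")
            table.to_csv(out / "reporting_rates.csv")
            report["stages"]["fit_reporting"] = {
                "n_input": len(respondents),
                "n_used": fit.n_obs,
                "n_excluded": fit.n_dropped,
                "converged": fit.converged,
                "avg_reporting_rate_pct": float(table.rows.iloc[0]["rate_pct"]),
            }

        if "select_model" in config.stages:
            cands = config.candidates or _default_candidates()
            results = selection.fit_candidates(
                respondents, cands, seed=stage_seed(config.seed, "select_model"))
            table = selection.robustness_table(results, respondents)
            selection.write_robustness_table(table, out / "robustness.csv")
            report["stages"]["select_model"] = {
                "n_candidates": len(cands.candidates),
                "n_converged": int(table["converged"].sum()),
                "best_bic": table.loc[table["best_bic"], "label"].iloc[0],
            }

        if "correct" in config.stages:
            dist = correction.tabulate_outcomes(
                pregnancies, order=list(synthetic.OUTCOMES))
            if config.reporting_rates is not None:
                rates = correction.RateVector(dict(config.reporting_rates))
            elif fit is not None:
                avg = btzip.average_reporting_rate(fit, respondents).rows.iloc[0]["rate_pct"]
                rates = correction.RateVector({"miscarriage": float(avg)})
            else:
                rates = correction.RateVector({})
            correction.write_correction_table(dist, rates, out / "corrected_outcomes.csv")
            corrected = correction.correct_distribution(dist, rates)
            report["stages"]["correct"] = {
                "n_pregnancies": dist.total_pregnancies,
                "reported": dist.rounded(),
                "corrected": corrected.rounded(),
            }

        if "fit_risk" in config.stages:
            rspec = config.risk_spec or _default_risk_spec(stage_seed(config.seed, "fit_risk"))
            rfit = risk.fit_mcmc(pregnancies, rspec)
            rfit.to_csv(out / "risk_posterior.csv")
            report["stages"]["fit_risk"] = {
                "n_pregnancies": len(pregnancies),
                "n_women": int(pregnancies["woman_id"].nunique()),
                "diagnostics_ok": bool(rfit.diagnostics_ok),
            }
    except Exception as exc:
        failed_stage = _current_stage(report, config)
        report["failed_stage"] = failed_stage
        report["error"] = str(exc)
        _write_report(report, out)
        raise RuntimeError(f"pipeline stage {failed_stage!r} failed: {exc}") from exc

    _write_report(report, out)
    return report


def _current_stage(report: dict, config: PipelineConfig) -> str:
    done = set(report["stages"])
    for s in config.stages:
        key = s if s != "simulate" else "simulate"
        if key not in done:
            return s
    return "unknown"


def _default_candidates() -> selection.CandidateSet:
    full = _default_reporting_spec()
    no_income = btzip.BTZIPSpec(
        count_covariates=list(full.count_covariates),
        zero_covariates=list(full.zero_covariates),
        report_covariates=[c for c in full.report_covariates if c != "income"],
    )
    slim = btzip.BTZIPSpec(
        count_covariates=["education", "age_group_survey", "parity_survey"],
        zero_covariates=["education"],
        report_covariates=["education", "marital_status", "health", "income"],
    )
    return selection.CandidateSet(
        candidates=[("full", full), ("no_income", no_income), ("slim_count", slim)]
    )


def _versions() -> dict:
    import numpy, pandas, scipy

    from . import __version__

    return {
        "misreport": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }


def _write_report(report: dict, out: Path) -> None:
    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from YAML.

    Blocks ``sim``, ``reporting_spec``, ``candidates`` and ``risk_spec`` map
    onto the corresponding dataclasses; everything else is passed through.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "sim" in raw and raw["sim"] is not None:
        raw["sim"] = synthetic.SimConfig.from_dict(raw["sim"])
    if "reporting_spec" in raw and raw["reporting_spec"] is not None:
        raw["reporting_spec"] = btzip.BTZIPSpec(**raw["reporting_spec"])
    if "candidates" in raw and raw["candidates"] is not None:
        raw["candidates"] = selection.CandidateSet(
            candidates=[(c["label"], btzip.BTZIPSpec(**c["spec"]))
                        for c in raw["candidates"]]
        )
    if "risk_spec" in raw and raw["risk_spec"] is not None:
        raw["risk_spec"] = risk.MNLSpec(**raw["risk_spec"])
    return PipelineConfig(**raw)
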