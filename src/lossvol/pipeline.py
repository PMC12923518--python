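"""Configuration, dataset round-tripping, and the end-to-end pipeline driver.

Stages: simulate -> fit -> compare (BMS) -> analyze (stay/shift and parameter
regressions) -> report.  Every output directory gets the fully resolved
config plus its hash and seed as a sidecar, and all randomness flows from
named stage seeds derived from the global seed by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, inference, task

__all__ = [
    "PipelineConfig",
    "read_dataset",
    "write_dataset",
    "read_covariates",
    "write_covariates",
    "run_pipeline",
]

_TRIAL_COLUMNS = [
    "subject_id", "trial", "context", "block_order", "p_loss_card1",
    "mag_card1", "mag_card2", "correct_card", "choice", "outcome", "loss_amount",
]

_STAGE_OFFSETS = {"simulate": 0, "fit": 1, "compare": 2, "analyze": 3, "power": 4}


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 20
    model: str = "hgf2_loss"                      # generating model for synthetic cohorts
    models: list = field(default_factory=lambda: ["hgf2", "hgf2_loss"])
    n_restarts: int = 5
    cohort: dict = field(default_factory=dict)    # overrides for task.CohortConfig
    priors: dict | None = None                    # name -> [mean, var] overrides
    write_trajectories: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + _STAGE_OFFSETS[stage]

    def validate(self) -> None:
        if not self.models:
            raise ValueError("config error: empty model list")
        from .models import MODELS

        unknown = [m for m in list(self.models) + [self.model] if m not in MODELS]
        if unknown:
            raise ValueError(f"config error: unknown models {unknown}")
        if self.n_subjects < 1:
            raise ValueError("config error: n_subjects must be >= 1")


def write_dataset(datasets, path) -> None:
    """Write subjects to the trial-level CSV schema (1-based trial index)."""
    rows = []
    for ds in datasets:
        s = ds.schedule
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": ds.subject_id,
                    "trial": np.arange(1, s.n_trials + 1),
                    "context": s.context,
                    "block_order": s.block_order,
                    "p_loss_card1": s.p_loss_card1,
                    "mag_card1": s.mag_card1,
                    "mag_card2": s.mag_card2,
                    "correct_card": s.correct_card,
                    "choice": ds.choice,
                    "outcome": ds.outcome,
                    "loss_amount": ds.loss_amount,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_dataset(path) -> list:
    """Read the trial-level CSV back into SubjectDataset objects.

    Schema violations are collected into a single itemized error naming rows
    and columns; out-of-order trials are accepted and sorted by
    (subject, trial).
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    problems = []

    def check(mask, message):
        for i in df.index[mask][:20]:
            problems.append(f"row {i + 2}: {message}")  # +2: header + 1-based

    check(~df["choice"].isin([1, 2]), "choice must be 1 or 2")
    check(~df["correct_card"].isin([1, 2]), "correct_card must be 1 or 2")
    check(~df["outcome"].isin([0, 1]), "outcome must be 0 or 1")
    for col in ("mag_card1", "mag_card2"):
        check((df[col] < 1) | (df[col] > 5), f"{col} outside [1, 5]")
    check((df["p_loss_card1"] < 0) | (df["p_loss_card1"] > 1), "p_loss_card1 outside [0, 1]")
    check(~df["context"].isin(["stable", "volatile"]), "context must be stable/volatile")
    if problems:
        raise ValueError(f"{path}: schema violations:\n" + "\n".join(problems))

    df = df.sort_values(["subject_id", "trial"], kind="mergesort").reset_index(drop=True)
    datasets = []
    for sub, grp in df.groupby("subject_id", sort=False):
        sched = task.TrialSchedule(
            context=grp["context"].to_numpy(),
            p_loss_card1=grp["p_loss_card1"].to_numpy(float),
            mag_card1=grp["mag_card1"].to_numpy(float),
            mag_card2=grp["mag_card2"].to_numpy(float),
            correct_card=grp["correct_card"].to_numpy(int),
            block_order=str(grp["block_order"].iloc[0]),
        )
        datasets.append(
            task.SubjectDataset(
                subject_id=str(sub),
                schedule=sched,
                choice=grp["choice"].to_numpy(int),
                outcome=grp["outcome"].to_numpy(int),
                loss_amount=grp["loss_amount"].to_numpy(float),
            )
        )
    return datasets


def write_covariates(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "asix_years", "age", "randomization"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing covariate columns {sorted(missing)}")
    return df


def _write_sidecar(out: Path, config: PipelineConfig) -> None:
    (out / "config.yaml").write_text(config.to_yaml())
    (out / "provenance.json").write_text(
        json.dumps({"config_hash": config.digest(), "seed": config.seed}, indent=2)
    )


def run_pipeline(config: PipelineConfig, out_dir, datasets=None, covariates=None) -> dict:
    """Execute simulate -> fit -> compare -> analyze and write the report bundle.

    Pass ``datasets``/``covariates`` to analyze supplied data instead of
    simulating.  Identical configs (and seeds) give identical outputs.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_sidecar(out, config)
    priors = (
        {k: tuple(v) for k, v in config.priors.items()} if config.priors else None
    )

    stage = "simulate"
    try:
        if datasets is None:
            cohort_cfg = task.CohortConfig(
                n_subjects=config.n_subjects, model=config.model,
                seed=config.stage_seed("simulate"), **config.cohort,
            )
            datasets, covariates = task.generate_cohort(cohort_cfg)
            write_dataset(datasets, out / "trials.csv")
            write_covariates(covariates, out / "covariates.csv")

        stage = "fit"
        fits_table, fits = inference.fit_cohort(
            datasets, config.models, priors=priors,
            n_restarts=config.n_restarts, seed=config.stage_seed("fit"),
        )
        fits_table.to_csv(out / "fits.csv", index=False)
        if config.write_trajectories:
            traj_dir = out / "trajectories"
            traj_dir.mkdir(exist_ok=True)
            best_model = config.models[-1]
            for ds in datasets:
                fit = fits[(ds.subject_id, best_model)]
                from .observation import trial_choice_probabilities

                p1, traj = trial_choice_probabilities(best_model, fit.params, ds.schedule)
                frame = traj.to_frame()
                frame["p_choice1"] = p1
                frame.to_csv(traj_dir / f"{ds.subject_id}.tsv", sep="\t", index=False)

        stage = "compare"
        lme = fits_table.pivot(index="subject_id", columns="model", values="log_evidence")
        lme = lme[config.models]
        bms_result = inference.bms(
            lme.to_numpy(), models=config.models, seed=config.stage_seed("compare")
        )
        (out / "bms.json").write_text(json.dumps(bms_result.to_dict(), indent=2))

        stage = "analyze"
        best = bms_result.best_model
        best_fits = fits_table[fits_table["model"] == best].set_index("subject_id")
        cov = covariates.set_index("subject_id")
        cohort_table = cov.join(best_fits, how="inner").reset_index()
        results = {"bms": bms_result.to_dict(), "best_model": best}

        stay = behavior.build_stay_table(datasets, covariates)
        stay.to_csv(out / "stay_table.csv", index=False)
        eq1 = behavior.fit_mixed_logistic(stay, "eq1")
        results["eq1"] = eq1.to_dict()
        if "asix_z" in cohort_table.columns and cohort_table["asix_z"].nunique() > 1:
            eq2 = behavior.fit_mixed_logistic(stay, "eq2")
            results["eq2"] = eq2.to_dict()
            param_results = {}
            for name in ("omega", "beta", "rho"):
                if name not in cohort_table.columns:
                    continue
                col = name
                if name == "beta":
                    adjusted, report = inference.winsorize_extreme(cohort_table["beta"])
                    cohort_table["beta_w"] = adjusted
                    col = "beta_w"
                    param_results["winsorization"] = report
                reg = behavior.fit_parameter_regression(cohort_table, col)
                param_results[name] = reg.to_dict()
            results["parameter_regressions"] = param_results
        cohort_table.to_csv(out / "cohort_table.csv", index=False)

        for key in ("eq1", "eq2"):
            if key in results:
                (out / f"{key}.json").write_text(json.dumps(results[key], indent=2))
        if "parameter_regressions" in results:
            (out / "parameter_regressions.json").write_text(
                json.dumps(results["parameter_regressions"], indent=2)
            )
        summary = {
            "config_hash": config.digest(),
            "seed": config.seed,
            "n_subjects": len(datasets),
            "best_model": best,
            "exceedance": dict(zip(bms_result.models, bms_result.exceedance.tolist())),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        results["summary"] = summary
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
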