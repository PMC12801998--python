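"""File formats: survival tables (CSV), run configuration (YAML), reports.

Times are serialized in months, hazards reported per year; both unit labels
appear in report headers.  Reports are plain delimited text plus a
machine-readable JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .conjugate import GammaParams, SurvivalRecord, prior_from_mean_sd
from .interim import DEFAULT_ANALYSIS_TIMES, InterimPlan, StageResult
from .simulate import SimConfig, TrialDataset

__all__ = [
    "read_survival_table",
    "write_survival_table",
    "load_run_config",
    "RunConfig",
    "stage_report_frame",
    "write_stage_report",
]

_REQUIRED_COLUMNS = ("patient_id", "enroll_time_months", "followup_months", "event")


class ConfigError(ValueError):
    pass


def read_survival_table(path: str | Path, horizon: float | None = None) -> TrialDataset:
    """Parse a delimited survival table into a validated dataset.

    Expected header columns: patient_id, enroll_time_months, followup_months,
    event.  Lines starting with '#' are comments.  Unknown columns are
    ignored on read (and preserved by round-tripping through pandas).  The
    horizon defaults to max(enroll + followup) when not given.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")

    records = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            records.append(
                SurvivalRecord(
                    patient_id=str(row["patient_id"]),
                    enroll_time=float(row["enroll_time_months"]),
                    followup_time=float(row["followup_months"]),
                    event=int(row["event"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{line_no}: invalid row: {exc}") from None

    if horizon is None:
        horizon = max(r.enroll_time + r.followup_time for r in records)
    return TrialDataset(records=records, horizon=horizon,
                        config_fingerprint=f"file:{path.name}")


def write_survival_table(dataset: TrialDataset, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in dataset.records],
            "enroll_time_months": [r.enroll_time for r in dataset.records],
            "followup_months": [r.followup_time for r in dataset.records],
            "event": [r.event for r in dataset.records],
        }
    )
    with open(path, "w") as fh:
        fh.write("# adaptrial survival table; times in months\n")
        df.to_csv(fh, index=False, float_format="%.17g")  # round-trippable floats


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration assembled from the YAML document."""

    prior: GammaParams
    plan: InterimPlan
    sim: SimConfig
    oc: dict
    seed: int | None = None
    raw: dict = dataclasses.field(default_factory=dict)


_KNOWN = {
    "prior": {"mean", "sd", "jeffreys"},
    "design": {"efs0", "tau_years", "alpha", "analysis_times", "spending",
               "futility_threshold"},
    "simulation": {f.name for f in dataclasses.fields(SimConfig)},
    "oc": {"reps", "sample_sizes", "prior_grid", "decision_prob", "target_power"},
}


def _check_keys(section: str, d: dict) -> None:
    unknown = set(d) - _KNOWN[section]
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}; "
            f"allowed: {', '.join(sorted(_KNOWN[section]))}"
        )


def parse_prior(d: dict) -> GammaParams:
    _check_keys("prior", d)
    if d.get("jeffreys"):
        return GammaParams.jeffreys()
    if "mean" not in d or "sd" not in d:
        raise ConfigError("prior needs either jeffreys: true or mean and sd")
    return prior_from_mean_sd(float(d["mean"]), float(d["sd"]))


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate the YAML run configuration.

    Sections: prior, design, simulation, oc, seed.  Unknown keys are
    rejected with a message naming the allowed ones.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    top_unknown = set(doc) - {"prior", "design", "simulation", "oc", "seed"}
    if top_unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(top_unknown))}")

    prior = parse_prior(doc.get("prior", {"jeffreys": True}))

    design = doc.get("design", {}) or {}
    _check_keys("design", design)
    plan = InterimPlan(
        prior=prior,
        efs0=float(design.get("efs0", 0.92)),
        horizon_tau=float(design.get("tau_years", 2.0)),
        alpha=float(design.get("alpha", 0.05)),
        analysis_times=tuple(design.get("analysis_times", DEFAULT_ANALYSIS_TIMES)),
        spending=design.get("spending", "linear-posterior-threshold"),
        futility_threshold=design.get("futility_threshold"),
    )

    sim_d = doc.get("simulation", {}) or {}
    _check_keys("simulation", sim_d)
    if "hazard_range" in sim_d:
        sim_d["hazard_range"] = tuple(sim_d["hazard_range"])
    if "event_rate_range" in sim_d:
        sim_d["event_rate_range"] = tuple(sim_d["event_rate_range"])
    sim = SimConfig(**sim_d)
    sim.validate()

    oc_d = doc.get("oc", {}) or {}
    _check_keys("oc", oc_d)

    return RunConfig(prior=prior, plan=plan, sim=sim, oc=oc_d,
                     seed=doc.get("seed"), raw=doc)


def stage_report_frame(stages: list[StageResult]) -> pd.DataFrame:
    """One row per interim stage (times in months, hazards per year)."""
    rows = []
    for s in stages:
        rows.append(
            {
                "stage": s.stage,
                "analysis_month": s.analysis_time,
                "n_enrolled": s.n_enrolled,
                "n_events": s.n_events,
                "exposure_years": round(s.exposure_years, 4),
                "post_shape": s.posterior.shape if s.posterior else float("nan"),
                "post_rate_per_year": s.posterior.rate if s.posterior else float("nan"),
                "efs_hat": s.efs_hat,
                "efs_sd": s.efs_sd,
                "z_score": s.z_score,
                "efficacy_criterion": s.efficacy_criterion,
                "posterior_prob_meets_target": s.posterior_prob_meets_target,
                "decision": s.decision,
                "note": s.note,
            }
        )
    return pd.DataFrame(rows)


def write_stage_report(stages: list[StageResult], path: str | Path,
                       config_echo: dict | None = None) -> None:
    """CSV stage report plus a JSON summary next to it (.json suffix)."""
    path = Path(path)
    df = stage_report_frame(stages)
    with open(path, "w") as fh:
        fh.write("# adaptrial interim stage report; months calendar, hazards per year\n")
        df.to_csv(fh, index=False)
    summary = {
        "n_stages_run": len(stages),
        "final_decision": stages[-1].decision if stages else None,
        "stopped_at_month": (
            stages[-1].analysis_time if stages and stages[-1].decision != "continue" else None
        ),
        "config": config_echo or {},
    }
    path.with_suffix(".json").write_text(json.dumps(summary, indent=2))
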