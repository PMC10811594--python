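"""Run orchestration: simulate -> score -> filter -> fit -> report.

Stages communicate through plain-text files (JSON-lines event logs, CSV
tables) so each stage is independently re-runnable; every artifact embeds
the game version, a hash of the run configuration and the root seed.  All
randomness flows from the single root seed, split per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import models as _models
from .cohort import (
    CohortConfig,
    FixedEffects,
    sample_cohort,
    simulate_longitudinal,
    simulate_session_events,
)
from .curriculum import build_curriculum
from .schedule import Density, apply_rhythm_change, build_schedule, schedule_to_frame
from .scoring import correct_latency, match_inputs, score_session, DEFAULT_LATENCY_S
from .tasks import Version, get_task_spec, registry_to_config

__all__ = ["RunConfig", "load_run_config", "run_pipeline", "make_fixtures",
           "write_events_jsonl", "read_events_jsonl"]

log = logging.getLogger("rhythmlearn")

DEFAULT_MODELS = ("progress", "diagnosis", "interaction:adhd", "interaction:dyslexia")


@dataclass(frozen=True)
class RunConfig:
    version: Version = Version.FINAL
    cohort: CohortConfig = field(default_factory=CohortConfig)
    latency_s: float = DEFAULT_LATENCY_S
    min_games: int = _models.DEFAULT_MIN_GAMES
    models: tuple[str, ...] = DEFAULT_MODELS
    out_dir: str = "rhythmlearn_run"
    seed: int = 0
    #: number of players whose first session is additionally realised at
    #: the event level and scored through the engine, as an audit
    event_path_players: int = 3


def _config_dict(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (Version, Density)):
            return obj.value
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, frozenset):
            return sorted(obj)
        return obj

    return enc(config)


def _config_hash(config: RunConfig) -> str:
    doc = _config_dict(config)
    doc.pop("out_dir", None)  # where results land is not part of the run identity
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    """Load a run configuration from a YAML document."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    cohort_doc = doc.pop("cohort", {})
    coef_doc = cohort_doc.pop("coefficients", {})
    coef = FixedEffects(**coef_doc)
    cohort = CohortConfig(coefficients=coef, **cohort_doc)
    if "version" in doc:
        doc["version"] = Version(doc["version"])
    if "models" in doc:
        doc["models"] = tuple(doc["models"])
    return RunConfig(cohort=cohort, **doc)


def write_events_jsonl(path: str | Path, rows: Sequence[dict]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write(json.dumps(row) + "\n")


def read_events_jsonl(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        return pd.DataFrame([json.loads(line) for line in fh if line.strip()])


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("simulate", "events", "fixtures")
    ss = np.random.SeedSequence(seed).spawn(len(names))
    return {
        n: int(s.generate_state(1)[0] % (2**31 - 1)) for n, s in zip(names, ss)
    }


def _fit_table(fit: _models.ModelFit) -> pd.DataFrame:
    out = fit.fixed_effects.copy()
    out.insert(0, "term", out.index)
    return out.reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts under
    ``config.out_dir``.  Returns the run report (also written as JSON).

    Identical config + seed produce identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    meta = {
        "version": config.version.value,
        "seed": config.seed,
        "config_hash": _config_hash(config),
    }
    report: dict = dict(meta)

    # --- simulate (score-level path) ---
    try:
        records, profiles = simulate_longitudinal(config.cohort, seeds["simulate"])
    except Exception as exc:  # pragma: no cover - stage tagging
        raise RuntimeError(f"[simulate] stage failed: {exc}") from exc
    records.to_csv(out / "records.csv", index=False)
    profiles.to_csv(out / "profiles.csv", index=False)
    report["n_players"] = int(profiles.shape[0])
    report["n_records"] = int(records.shape[0])
    report["clip_rate"] = records.attrs.get("clip_rate", 0.0)
    log.info("simulated %d records for %d players", len(records), len(profiles))

    # --- event-path audit on a few sessions ---
    if config.event_path_players > 0:
        audit = _event_path_audit(config, seeds["events"])
        audit_df = pd.DataFrame(audit)
        audit_df.to_csv(out / "event_audit.csv", index=False)
        report["event_audit"] = {
            "n_sessions": len(audit),
            "n_events": int(sum(a["n_events"] for a in audit)),
            "n_spurious": int(sum(a["n_spurious"] for a in audit)),
        }

    # --- engagement filter ---
    filtered = _models.engagement_filter(records, config.min_games)
    if filtered.empty:
        raise RuntimeError(
            f"[filter] stage failed: empty cohort — no player reached "
            f"{config.min_games} games"
        )
    kept_players = filtered["player_id"].nunique()
    report["n_players_kept"] = int(kept_players)
    report["n_records_kept"] = int(len(filtered))
    profiles_kept = profiles[profiles["player_id"].isin(filtered["player_id"])]
    log.info("engagement filter kept %d players", kept_players)

    # --- model fits ---
    report["models"] = {}
    for name in config.models:
        try:
            if name == "progress":
                fit = _models.fit_progress_model(filtered)
            elif name == "diagnosis":
                fit = _models.fit_diagnosis_model(filtered, profiles_kept)
            elif name.startswith("interaction:"):
                fit = _models.fit_interaction_model(
                    filtered, profiles_kept, name.split(":", 1)[1]
                )
            else:
                raise ValueError(f"unknown model {name!r}")
        except Exception as exc:
            raise RuntimeError(f"[fit:{name}] stage failed: {exc}") from exc
        table = _fit_table(fit)
        fname = name.replace(":", "_")
        table.to_csv(out / f"model_{fname}.csv", index=False)
        report["models"][name] = {
            "formula": fit.formula,
            "converged": fit.converged,
            "n_obs": fit.n_obs,
            "fixed_effects": {
                t: round(float(v), 6)
                for t, v in fit.fixed_effects["estimate"].items()
            },
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _event_path_audit(config: RunConfig, seed: int) -> list[dict]:
    """Realise a few first sessions at the event level and score them."""
    rng = np.random.default_rng(seed)
    cohort = sample_cohort(config.cohort, rng)
    plans = build_curriculum((), config.version)
    rows = []
    for profile in cohort[: config.event_path_players]:
        plan = next(p for p in plans if p.task != "Sing Lab")
        spec = get_task_spec(plan.task, config.version)
        schedule = build_schedule(
            spec, plan.tempo_bpm, plan.duration_s, plan.density
        )
        events = simulate_session_events(
            profile, plan, schedule, 1, config.cohort,
            int(rng.integers(2**31 - 1)),
        )
        events = correct_latency(
            [e for e in events], 0.0
        )  # simulated events are already on the action clock
        classified = match_inputs(events, schedule, spec.tolerance)
        result = score_session(classified, config.version, 1, plan.task)
        rows.append(
            {
                "player_id": profile.player_id,
                "task": plan.task,
                "n_events": len(events),
                "n_expected": result.n_expected,
                "n_spurious": result.n_spurious,
                "acceptable_ratio": result.acceptable_ratio,
                "mean_score": result.mean_score,
                "stars": result.stars,
            }
        )
    return rows


def make_fixtures(seed: int = 0, out_dir: str | Path = "fixtures") -> dict:
    """Write the small canonical inputs used by the tests and docs.

    Produces a schedule CSV, a JSON-lines event log for that schedule, a
    small cohort (records + profiles CSV) and the task registry of both
    versions as YAML.  Regenerates identically under the same seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)
    rng = np.random.default_rng(seeds["fixtures"])

    spec = get_task_spec("Clap Hero", Version.FINAL)
    schedule = build_schedule(spec, 100.0, 80.0, Density.EVERY_BEAT)
    schedule_to_frame(schedule).to_csv(out / "schedule.csv", index=False)

    events = []
    for t in schedule.expected_times:
        if rng.random() < 0.05:
            continue
        events.append(
            {
                "player": 0,
                "level": "Clap Hero:ch01",
                "task": "Clap Hero",
                "timestamp_s": round(max(0.0, t + rng.normal(0, 0.05)), 4),
                "modality": spec.interaction.value,
            }
        )
    write_events_jsonl(out / "events.jsonl", events)

    small = CohortConfig(n_players=10)
    records, profiles = simulate_longitudinal(small, seeds["simulate"])
    records.to_csv(out / "records.csv", index=False)
    profiles.to_csv(out / "profiles.csv", index=False)

    for version in Version:
        (out / f"tasks_{version.value}.yaml").write_text(
            yaml.safe_dump(registry_to_config(version), sort_keys=False)
        )
    return {
        "out_dir": str(out),
        "seed": seed,
        "files": sorted(p.name for p in out.iterdir()),
    }
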