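"""End-to-end experiment orchestration.

One config drives the whole comparison: simulate re-aiming sessions across
the rotation series, train and retrain the RL agent, run the manifold
analysis on both, and write a report JSON plus tidy CSV tables.  Stages run
in dependency order; a completed stage (outputs present, config hash
unchanged) is skipped on re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import manifold as mf
from . import experiments as ex
from .env import CenterOutEnv
from .io import write_activity_csv, write_trials_csv
from .rl import collect_activations, retrain_rotated, train_agent, save_agent

logger = logging.getLogger("bciadapt")

__all__ = ["ExperimentConfig", "validate_config", "run_experiment", "RunManifest"]


@dataclass
class ExperimentConfig:
    rotations_deg: list[float] = field(
        default_factory=lambda: [50.0, -50.0, 90.0, -90.0, 110.0, -110.0]
    )
    compensation: float = 1.0
    n_units: int = 40
    trials_per_target: int = 20
    sessions_per_rotation: int = 3
    n_baseline_sessions: int = 10
    rl_rotations_deg: list[float] = field(
        default_factory=lambda: [50.0, -50.0, 90.0, -110.0]
    )
    rl_baseline_steps: int = 150_000
    rl_retrain_steps: int = 50_000
    rl_episodes_per_target: int = 20
    master_seed: int = 0
    out_dir: str = "bciadapt_run"

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)


def normalize_rotation_deg(theta: float) -> float:
    """Map any degree encoding to signed degrees in (-180, 180] (310 -> -50)."""
    t = float(theta) % 360.0
    return t - 360.0 if t > 180.0 else t


def validate_config(raw: dict | ExperimentConfig) -> ExperimentConfig:
    """Normalize and validate a config; raises ValueError listing all problems."""
    if isinstance(raw, ExperimentConfig):
        raw = dataclasses.asdict(raw)
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    errors = [f"unknown config key: {k!r}" for k in raw if k not in known]
    cfg_kwargs = {k: v for k, v in raw.items() if k in known}
    cfg = ExperimentConfig(**cfg_kwargs)
    cfg.rotations_deg = [normalize_rotation_deg(t) for t in cfg.rotations_deg]
    cfg.rl_rotations_deg = [normalize_rotation_deg(t) for t in cfg.rl_rotations_deg]
    if not cfg.rotations_deg:
        errors.append("rotation list must not be empty")
    if not 0.0 <= cfg.compensation <= 1.0:
        errors.append(f"compensation must be in [0, 1], got {cfg.compensation}")
    for t in cfg.rotations_deg:
        if t != 0.0 and not 50.0 <= abs(t) <= 110.0:
            errors.append(
                f"rotation {t:+g} deg outside the studied magnitude range 50-110"
            )
    if cfg.n_units < 3:
        errors.append("n_units must be >= 3")
    if errors:
        raise ValueError("invalid experiment config:\n- " + "\n- ".join(errors))
    return cfg


@dataclass
class RunManifest:
    config_hash: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, seed: int, outputs: list[Path]) -> None:
        self.stages[stage] = {
            "seed": seed,
            "outputs": {
                str(p): hashlib.sha256(p.read_bytes()).hexdigest()[:16]
                for p in outputs
            },
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def save(self, path: Path) -> None:
        path.write_text(
            json.dumps({"config_hash": self.config_hash, "stages": self.stages}, indent=2)
        )


def _stage_complete(manifest_path: Path, stage: str, config_hash: str) -> bool:
    if not manifest_path.exists():
        return False
    data = json.loads(manifest_path.read_text())
    if data.get("config_hash") != config_hash:
        return False
    entry = data.get("stages", {}).get(stage)
    if not entry:
        return False
    return all(Path(p).exists() for p in entry["outputs"])


def run_experiment(config: ExperimentConfig | dict) -> RunManifest:
    """Execute all stages; returns the manifest (also written to disk)."""
    cfg = validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    chash = cfg.config_hash()
    manifest = RunManifest(config_hash=chash)
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == chash:
            manifest.stages = prev.get("stages", {})

    report: dict = {"config": dataclasses.asdict(cfg)}
    report_path = out / "report.json"

    # --- stage: closed-loop sessions + manifold statistics ----------------
    stage = "sessions"
    seed = cfg.stage_seed(stage)
    if _stage_complete(manifest_path, stage, chash) and report_path.exists():
        logger.info("stage %s up to date; skipping", stage)
        report = json.loads(report_path.read_text())
    else:
        logger.info("stage %s: seed %d", stage, seed)
        gaps = ex.adjacent_gap_experiment(
            cfg.n_baseline_sessions, seed, cfg.n_units, cfg.trials_per_target
        )
        disp = ex.displacement_regression_experiment(
            cfg.rotations_deg,
            cfg.sessions_per_rotation,
            seed,
            cfg.compensation,
            cfg.n_units,
            cfg.trials_per_target,
        )
        example = ex.simulate_session(
            seed, cfg.rotations_deg[0], cfg.compensation, cfg.n_units,
            cfg.trials_per_target,
        )
        write_trials_csv(example, out / "example_session_trials.csv")
        for block in example.block_labels:
            from .task import session_activity_matrix

            write_activity_csv(
                session_activity_matrix(example, block),
                out / f"example_session_{block}.csv",
                metadata={"seed": seed, "theta_deg": cfg.rotations_deg[0]},
            )
        nhp_pres = ex.preservation_experiment(
            cfg.rotations_deg, seed, cfg.compensation, cfg.n_units,
            cfg.trials_per_target,
        )
        report["adjacent_gaps"] = {
            "mean_deg": float(np.mean(gaps)),
            "sd_deg": float(np.std(gaps)),
            "pooled_gaps_deg": gaps.tolist(),
        }
        report["displacement_regression"] = {
            "thetas_deg": disp.thetas_deg.tolist(),
            "mean_displacement_deg": disp.mean_displacement_deg.tolist(),
            "slope": disp.regression.slope,
            "intercept": disp.regression.intercept,
            "r_squared": disp.regression.r_squared,
            "p_value": disp.regression.p_value,
        }
        report["nhp_preservation"] = [s.summary() for s in nhp_pres]
        report_path.write_text(json.dumps(report, indent=2))
        outputs = [report_path, out / "example_session_trials.csv"]
        manifest.record(stage, seed, outputs)
        manifest.save(manifest_path)

    # --- stage: RL training / retraining / activation analysis -----------
    stage = "rl"
    seed = cfg.stage_seed(stage)
    if _stage_complete(manifest_path, stage, chash) and "rl_preservation" in report:
        logger.info("stage %s up to date; skipping", stage)
    else:
        logger.info("stage %s: seed %d", stage, seed)
        env = CenterOutEnv(seed=seed)
        base = train_agent(env, cfg.rl_baseline_steps, seed=seed)
        save_agent(base, out / "rl_baseline_agent.json")
        acts_base = collect_activations(
            base,
            CenterOutEnv(seed=seed + 1),
            cfg.rl_episodes_per_target,
            condition="baseline",
            seed=seed + 1,
        )
        write_activity_csv(acts_base, out / "rl_activations_baseline.csv")
        before, after, rl_disp = [], [], []
        for j, th in enumerate(cfg.rl_rotations_deg):
            ret = retrain_rotated(
                base, th, cfg.rl_retrain_steps, seed=seed + 100 * (j + 1)
            )
            acts = collect_activations(
                ret,
                CenterOutEnv(theta_deg=th, seed=seed + 2),
                cfg.rl_episodes_per_target,
                condition=f"rot{th:+g}",
                seed=seed + 2,
            )
            write_activity_csv(
                acts, out / f"rl_activations_rot{th:+g}.csv"
            )
            b = mf.ActivityMatrix.from_spike_counts(acts_base)
            a = mf.ActivityMatrix.from_spike_counts(acts)
            before.append(b)
            after.append(a)
            # shared-basis centroid displacement of the RL activations
            pooled = mf.ActivityMatrix(
                np.hstack([b.values, a.values]),
                np.concatenate([b.target_id, a.target_id]),
                np.concatenate([b.condition, a.condition]),
            )
            basis = mf.ensure_task_orientation(mf.fit_pca(pooled), b)
            cb = mf.target_centroids(mf.project(basis, b), b.target_id)
            ca = mf.target_centroids(mf.project(basis, a), a.target_id)
            rl_disp.append(mf.centroid_angular_displacement(cb, ca).mean_deg)
        rl_pres = mf.manifold_preservation_report(before, after)
        report["rl_preservation"] = [s.summary() for s in rl_pres]
        report["rl_displacement"] = {
            "thetas_deg": list(cfg.rl_rotations_deg),
            "mean_displacement_deg": rl_disp,
        }
        if len(cfg.rl_rotations_deg) >= 3:
            reg = mf.regress_displacement(
                np.array(rl_disp), np.array(cfg.rl_rotations_deg)
            )
            report["rl_displacement"]["slope"] = reg.slope
            report["rl_displacement"]["r_squared"] = reg.r_squared
        # group contrast of normalized mean-activity differences
        nhp_vals = [s["mean_normdiff"] for s in report["nhp_preservation"]]
        rl_vals = [s["mean_normdiff"] for s in report["rl_preservation"]]
        if len(nhp_vals) >= 2 and len(rl_vals) >= 2:
            f, p = mf.compare_group_means(np.array(nhp_vals), np.array(rl_vals))
            report["mean_normdiff_anova"] = {"F": f, "p": p}
        report_path.write_text(json.dumps(report, indent=2))
        manifest.record(
            stage, seed, [report_path, out / "rl_activations_baseline.csv"]
        )
        manifest.save(manifest_path)
    return manifest
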