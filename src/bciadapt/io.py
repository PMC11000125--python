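"""Columnar text serialization shared by spike counts and RL activations.

One CSV row per bin/step: unit columns (``u000``, ``u001``, ...) followed by
``target_id``, ``trial_id`` and ``condition``.  A sidecar JSON carries the
bin width, seeds, and any extra metadata so the CSV stays purely tabular.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rl import RolloutActivations
from .synthetic import SpikeCountMatrix

__all__ = [
    "write_activity_csv",
    "read_activity_csv",
    "write_trials_csv",
]


def _unit_columns(n: int) -> list[str]:
    return [f"u{i:03d}" for i in range(n)]


def write_activity_csv(
    matrix, path: str | Path, metadata: dict | None = None
) -> None:
    """Write a SpikeCountMatrix or RolloutActivations plus a sidecar JSON."""
    path = Path(path)
    values = np.asarray(matrix.counts)
    df = pd.DataFrame(values.T, columns=_unit_columns(values.shape[0]))
    df["target_id"] = matrix.target_id
    df["trial_id"] = getattr(matrix, "trial_id", np.arange(values.shape[1]))
    df["condition"] = matrix.condition
    df.to_csv(path, index=False)
    meta = dict(metadata or {})
    meta.setdefault("n_units", int(values.shape[0]))
    bw = getattr(matrix, "bin_width", None)
    if bw is not None:
        meta.setdefault("bin_width", bw)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_activity_csv(path: str | Path):
    """Read the CSV dialect back; returns (matrix, metadata).

    The matrix is a SpikeCountMatrix when the sidecar records a bin width
    (spike counts), otherwise a RolloutActivations.
    """
    path = Path(path)
    df = pd.read_csv(path)
    unit_cols = [c for c in df.columns if c.startswith("u") and c[1:].isdigit()]
    values = df[unit_cols].to_numpy().T
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    target_id = df["target_id"].to_numpy()
    condition = df["condition"].to_numpy(dtype=object)
    if "bin_width" in meta:
        matrix = SpikeCountMatrix(
            counts=values.astype(np.int64),
            bin_width=float(meta["bin_width"]),
            target_id=target_id,
            trial_id=df["trial_id"].to_numpy(),
            condition=condition,
        )
    else:
        matrix = RolloutActivations(
            activations=values,
            target_id=target_id,
            condition=condition,
        )
    return matrix, meta


def write_trials_csv(session, path: str | Path) -> None:
    """Per-trial summary table: trial_id, target_id, theta_deg, success, duration."""
    rows = [
        {
            "trial_id": i,
            "target_id": t.target_id,
            "theta_deg": t.theta_deg,
            "block": t.block_label,
            "success": t.success,
            "duration_bins": t.duration_bins,
        }
        for i, t in enumerate(session.trials)
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
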