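"""One-command orchestration: simulate -> stage -> preprocess -> detect
-> per-state rates -> group statistics, over a whole synthetic cohort.

A manifest row is one session (mouse x treatment); treatments follow
the drug panel (two intermingled saline controls, ESM, LEV, DPZ, ATR,
CGP, BHB, PYR, LAC), and every mouse must carry a first saline session,
which serves as the paired-test control.  Per-session seeds are spawned
deterministically from the experiment seed, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as swdio
from .detection import DetectorConfig, assign_event_states, detect_swds, per_state_rates
from .experiment import TREATMENTS
from .preprocess import ARTIFACT_THRESHOLD_MV2HZ, build_sweep_set
from .staging import stage_trajectory
from .stats import decision_procedure
from .synthetic import SessionConfig, simulate_session

__all__ = ["ExperimentConfig", "build_manifest", "validate_manifest", "run_pipeline", "report"]

log = logging.getLogger("swdscope")

MEASURES = ["swd_count_per_hour", "total_swd_s_per_hour", "mean_single_duration_s"]
RATE_STATES = ["sleep", "waking_immobility", "mixed"]


@dataclass
class ExperimentConfig:
    """Whole-experiment settings; thresholds default to the printed rules."""

    n_mice: int = 9
    treatments: list = field(default_factory=lambda: list(TREATMENTS))
    effects: dict = field(default_factory=dict)  # treatment -> rate multiplier
    duration_s: float = 1800.0
    seed: int = 0
    k_sd: float = 2.5
    artifact_threshold: float = ARTIFACT_THRESHOLD_MV2HZ
    session_overrides: dict = field(default_factory=dict)  # extra SessionConfig fields

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_manifest(config: ExperimentConfig) -> pd.DataFrame:
    rows = []
    for mi in range(config.n_mice):
        for order, treatment in enumerate(config.treatments):
            rows.append(
                {
                    "mouse_id": f"mouse{mi:02d}",
                    "treatment": treatment,
                    "order": order,
                }
            )
    return pd.DataFrame(rows)


def validate_manifest(manifest: pd.DataFrame) -> None:
    key = manifest[["mouse_id", "treatment", "order"]]
    if key.duplicated().any():
        raise ValueError("manifest rows (mouse, treatment, order) must be unique")
    for mouse, grp in manifest.groupby("mouse_id"):
        if "saline1" not in set(grp["treatment"]):
            raise ValueError(f"{mouse} lacks a first saline session")


def _session_seed(base_seed: int, mouse_id: str, treatment: str) -> int:
    h = hashlib.sha256(f"{base_seed}:{mouse_id}:{treatment}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def run_session(config: ExperimentConfig, mouse_id: str, treatment: str, out_dir=None):
    """Simulate and fully analyze one session; returns the per-state rates."""
    effect = config.effects.get(treatment, 1.0)
    rates = {s: 100.0 * effect for s in RATE_STATES}
    scfg = SessionConfig(
        duration_s=config.duration_s,
        swd_rate_per_state=rates,
        seed=_session_seed(config.seed, mouse_id, treatment),
        **config.session_overrides,
    )
    eeg, traj, gt = simulate_session(scfg)
    signal = eeg.channel(0)
    _, frames, sweeps = stage_trajectory(traj)
    sweep_set = build_sweep_set(signal, eeg.fs, config.artifact_threshold)
    events = detect_swds(signal, eeg.fs, sweep_set.artifact, DetectorConfig(k_sd=config.k_sd))
    events = assign_event_states(events, sweeps, sweep_set.artifact)
    result = per_state_rates(events, sweeps, sweep_set.artifact)
    log.info(
        "%s/%s: %d sweeps (%d artifact), %d candidates, %d accepted",
        mouse_id, treatment, len(sweep_set), sweep_set.n_noisy(), len(events),
        int(events["accepted"].sum()) if len(events) else 0,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        swdio.write_trajectory_csv(traj, out_dir / "trajectory.csv")
        swdio.write_frame_states_csv(frames, out_dir / "frame_states.csv")
        swdio.write_sweep_labels_csv(sweeps, out_dir / "sweeps.csv")
        swdio.write_events_csv(events, out_dir / "events.csv")
        result.to_csv(out_dir / "session_result.csv")
    return result


def run_pipeline(config: ExperimentConfig, out_dir, write_sessions: bool = False):
    """Run the whole synthetic experiment; writes measures and statistics.

    Produces ``measures.csv`` (long format: mouse, treatment, state,
    measure, value), ``anova.csv``, ``pairwise.csv`` and a provenance
    record, all under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = build_manifest(config)
    validate_manifest(manifest)
    manifest.to_csv(out_dir / "manifest.csv", index=False)

    rows = []
    for _, sess in manifest.iterrows():
        sdir = out_dir / "sessions" / f"{sess.mouse_id}_{sess.treatment}" if write_sessions else None
        try:
            result = run_session(config, sess.mouse_id, sess.treatment, sdir)
        except Exception as exc:  # pragma: no cover - abort with the stage named
            raise RuntimeError(
                f"session {sess.mouse_id}/{sess.treatment} failed: {exc}"
            ) from exc
        for state in RATE_STATES:
            for measure in MEASURES:
                rows.append(
                    {
                        "mouse": sess.mouse_id,
                        "treatment": sess.treatment,
                        "state": state,
                        "measure": measure,
                        "value": result.loc[state, measure],
                    }
                )
    measures = pd.DataFrame(rows)
    measures.to_csv(out_dir / "measures.csv", index=False, float_format="%.8g")

    anova_rows, pair_rows = [], []
    for (measure, state), grp in measures.groupby(["measure", "state"]):
        wide = grp.pivot(index="mouse", columns="treatment", values="value")
        wide = wide[[t for t in config.treatments if t in wide.columns]]
        try:
            an, pairs = decision_procedure(wide)
        except ValueError:
            continue
        anova_rows.append(
            {
                "measure": measure,
                "state": state,
                "F": an.F,
                "df1": an.df1,
                "df2": an.df2,
                "epsilon": an.epsilon,
                "p": an.p,
            }
        )
        if pairs is not None:
            pairs = pairs.assign(measure=measure, state=state)
            pair_rows.append(pairs)
    anova = pd.DataFrame(anova_rows)
    pairwise = pd.concat(pair_rows, ignore_index=True) if pair_rows else pd.DataFrame(
        columns=["measure", "state", "drug", "n_pairs", "t", "p", "q", "significant"]
    )
    anova.to_csv(out_dir / "anova.csv", index=False, float_format="%.8g")
    pairwise.to_csv(out_dir / "pairwise.csv", index=False, float_format="%.8g")

    provenance = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return measures, anova, pairwise


def report(anova: pd.DataFrame, pairwise: pd.DataFrame) -> pd.DataFrame:
    """Per-state summary table of measures with significance flags."""
    rows = []
    for _, a in anova.iterrows():
        sub = pairwise[(pairwise["measure"] == a["measure"]) & (pairwise["state"] == a["state"])]
        flagged = sorted(sub.loc[sub["significant"], "drug"].tolist()) if len(sub) else []
        rows.append(
            {
                "measure": a["measure"],
                "state": a["state"],
                "omnibus_p": a["p"],
                "flagged_drugs": ",".join(flagged),
            }
        )
    return pd.DataFrame(rows)
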