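"""End-to-end orchestration: simulate → measure → analyze.

A :class:`RunConfig` (a flat, YAML-serializable mapping) fixes every knob of
a run — seed, experiment layout, generator response models and measurement
parameters — so that identical configs produce identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import acoustics, audio_io, call_synth, stats, stimuli

log = logging.getLogger("lombardlab")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class RunConfig:
    """Flat pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    n_subjects: int = 3
    trial_s: float = 60.0
    ambient_db: float = stimuli.AMBIENT_DB
    levels_db: tuple[float, float, float] = stimuli.DEFAULT_LEVELS
    clcs_per_trial: int = 4
    chirps_per_trial: int = 6
    clc_model: call_synth.ResponseModel = dataclasses.field(
        default_factory=lambda: call_synth.ResponseModel(**dataclasses.asdict(call_synth.CLC_RESPONSE)))
    chirp_model: call_synth.ResponseModel = dataclasses.field(
        default_factory=lambda: call_synth.ResponseModel(**dataclasses.asdict(call_synth.CHIRP_RESPONSE)))
    window_len: int = acoustics.WINDOW_LEN
    overlap: float = acoustics.OVERLAP
    dft_len: int = acoustics.DFT_LEN
    edge_db: float = acoustics.EDGE_DB

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels_db"] = list(self.levels_db)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("clc_model", "chirp_model"):
            if isinstance(d.get(key), dict):
                d[key] = call_synth.ResponseModel(**d[key])
        if "levels_db" in d:
            d["levels_db"] = tuple(d["levels_db"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sim_config(cfg: RunConfig) -> call_synth.SimConfig:
    sim = call_synth.make_default_config(
        n_subjects=cfg.n_subjects, seed=cfg.seed, trial_s=cfg.trial_s,
        ambient_db=cfg.ambient_db,
        treatments=stimuli.treatment_bank(cfg.levels_db),
        clc_model=cfg.clc_model, chirp_model=cfg.chirp_model,
    )
    for s in sim.subjects:
        s.clcs_per_trial = cfg.clcs_per_trial
        s.chirps_per_trial = cfg.chirps_per_trial
    return sim


def measure_experiment(exp_dir, manifest: Optional[list[audio_io.TrialRecord]] = None,
                       annotations=None, edge_db: float = acoustics.EDGE_DB,
                       ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Measure every annotated call of an experiment directory.

    Returns the per-call measurement table and the per-trial measured noise
    levels (dB re 20 μPa).
    """
    exp_dir = Path(exp_dir)
    if manifest is None:
        manifest = audio_io.load_manifest(exp_dir / "manifest.csv")
    if annotations is None:
        annotations = audio_io.load_annotations(exp_dir / "annotations.csv")
    per_trial: dict[str, list] = {}
    noise_levels: dict[str, float] = {}
    for rec in manifest:
        clip = audio_io.read_wav(exp_dir / rec.wav_path, rec.calibration)
        anns = annotations.get(rec.wav_path, [])
        noise_db, noise_stats = acoustics.trial_noise_level(clip, anns)
        noise_levels[rec.wav_path] = noise_db
        per_trial[rec.wav_path] = [
            acoustics.measure_call(clip, a, noise_stats, edge_db=edge_db) for a in anns
        ]
    return stats.measurements_to_frame(per_trial), noise_levels


def analyze(measurements: pd.DataFrame, manifest: list[audio_io.TrialRecord],
            bank: list[stimuli.NoiseTreatment], ambient_db: float,
            trial_noise_db: Optional[dict[str, float]] = None):
    """Aggregate to trial means and fit the ANCOVA grid for both call types."""
    summaries = stats.aggregate(measurements, manifest, bank, ambient_db, trial_noise_db)
    results = []
    for call_type, response, _label in stats.REPORT_ROWS:
        sub = summaries[summaries["call_type"] == call_type]
        if sub.empty or sub[response].notna().sum() < 8:
            continue
        try:
            results.append(stats.fit_ancova(sub, response, call_type=call_type))
        except stats.DesignError as exc:
            log.warning("skipping %s/%s: %s", call_type, response, exc)
    return summaries, results


def run_pipeline(cfg: RunConfig, out_dir) -> Path:
    """simulate → measure → aggregate → fit → report, all under one seed.

    Writes trial audio plus ``trial_summaries.csv``, ``results_table.csv``,
    ``results_table.txt``, ``delta_table.csv`` and ``run.log`` to
    ``out_dir``; identical config + seed reproduce identical tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
        try:
            sim = _sim_config(cfg)
            exp = call_synth.simulate_experiment(sim, out / "audio")
        except Exception as exc:
            raise StageError(f"simulate: {exc}") from exc
        try:
            measurements, noise_levels = measure_experiment(
                out / "audio", exp["manifest"], exp["annotations"], edge_db=cfg.edge_db)
            measurements.to_csv(out / "measurements.csv", index=False)
        except Exception as exc:
            raise StageError(f"measure: {exc}") from exc
        try:
            summaries, results = analyze(measurements, exp["manifest"],
                                         stimuli.treatment_bank(cfg.levels_db),
                                         cfg.ambient_db, noise_levels)
            summaries.to_csv(out / "trial_summaries.csv", index=False)
            grid, text = stats.report(results)
            grid.to_csv(out / "results_table.csv", index=False)
            (out / "results_table.txt").write_text(text)
            deltas = stats.delta_table(summaries, "min_f0", call_type="CLC")
            deltas.to_csv(out / "delta_table.csv", index=False)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"analyze: {exc}") from exc
        log.info("pipeline complete: %s", out)
        return out
    finally:
        log.removeHandler(handler)
        handler.close()
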