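"""End-to-end orchestration: simulate (or ingest) → process → detect →
classify → profile, with a fully serialized configuration.

One root seed deterministically derives the generator stream, so identical
config + seed produces byte-identical tabular outputs. Every output table
is accompanied by a manifest carrying the config hash.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .classify import ResponseParams, classification_table, classify_recording, tumor_summary
from .events import detect_baseline_events, summarize_spontaneous
from .processing import correct_photobleach, gate_viability, normalize_dff, qc_table
from .profiling import RecurrenceThresholds, predict_recurrence, profiles_to_table
from .protocol import SECRETAGOGUES, build_protocol
from .synth import PopulationSpec, simulate_recording

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending entity."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run. Absent YAML keys fall
    back to the defaults defined here; the resolved config is written
    beside the outputs."""

    seed: int = 0
    out_dir: str = "pitcalc_run"
    tumor_id: str = "synthetic"
    # protocol
    stimulus_order: tuple[str, ...] = SECRETAGOGUES
    baseline_s: float = 180.0
    pulse_s: float = 30.0
    wash_s: float = 900.0
    frame_interval_s: float = 0.2
    compress: float = 1.0
    # input: either a population spec (simulate) or an external recording
    population: dict = field(default_factory=lambda: {"n_cells": 100})
    recording_path: str | None = None
    # processing
    fmin_percentile: float = 5.0
    viability_k: float = 5.0
    viability_floor: float = 0.05
    # detection / response
    threshold_k: float = 3.5
    min_duration_s: float = 0.6
    merge_gap_s: float = 0.4
    prolonged_cutoff_s: float = 10.0
    post_window_s: float = 30.0
    collapse_trh_da: bool = False
    # recurrence rule
    min_spontaneous_pct: float = 0.0
    min_multi_pct: float = 20.0
    max_non_pct: float = 50.0

    def to_yaml(self) -> str:
        d = asdict(self)
        d["stimulus_order"] = list(self.stimulus_order)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        if "stimulus_order" in d:
            d["stimulus_order"] = tuple(d["stimulus_order"])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the scientific configuration; where outputs land
        (out_dir) does not affect it."""
        d = yaml.safe_load(self.to_yaml())
        d.pop("out_dir", None)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]

    def response_params(self) -> ResponseParams:
        return ResponseParams(
            threshold_k=self.threshold_k,
            min_duration_s=self.min_duration_s,
            merge_gap_s=self.merge_gap_s,
            prolonged_cutoff_s=self.prolonged_cutoff_s,
            post_window_s=self.post_window_s,
            collapse_trh_da=self.collapse_trh_da,
        )


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (output paths plus
    the config hash). Identical config + seed gives identical outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    (out / "config.yaml").write_text(config.to_yaml())
    paths: dict[str, str] = {"config": str(out / "config.yaml")}

    if config.recording_path is not None:
        rec = _stage("ingest", pio.read_recording, config.recording_path)
    else:
        protocol = _stage(
            "protocol",
            build_protocol,
            list(config.stimulus_order),
            config.baseline_s,
            config.pulse_s,
            config.wash_s / config.compress,
            config.frame_interval_s,
        )
        spec = _stage("population", PopulationSpec.from_dict, {**config.population, "seed": config.seed})
        rec = _stage("simulate", simulate_recording, spec, protocol)
        written = pio.write_recording(rec, out / "recording.tsv")
        paths.update({k: str(v) for k, v in written.items()})

    corrected = _stage("process", correct_photobleach, rec)
    traces = _stage("process", normalize_dff, corrected, config.fmin_percentile)
    traces = _stage("viability", gate_viability, traces, config.viability_k, config.viability_floor)
    qc = qc_table(traces)
    qc.insert(0, "config_hash", chash)
    qc.to_csv(out / "qc.tsv", sep="\t", float_format=pio.FLOAT_FMT)
    paths["qc"] = str(out / "qc.tsv")

    events = _stage(
        "detect",
        detect_baseline_events,
        traces,
        config.threshold_k,
        config.min_duration_s,
        config.merge_gap_s,
        config.prolonged_cutoff_s,
    )
    ev_rows = [
        {
            "cell_id": e.cell_id,
            "onset_s": e.onset_s,
            "peak_s": e.peak_s,
            "end_s": e.end_s,
            "peak_dff": e.peak_dff,
            "duration_s": e.duration_s,
            "shape_class": e.shape_class,
        }
        for evs in events.values()
        for e in evs
    ]
    ev_df = pd.DataFrame(ev_rows, columns=["cell_id", "onset_s", "peak_s", "end_s", "peak_dff", "duration_s", "shape_class"])
    ev_df.insert(0, "config_hash", chash)
    ev_df.to_csv(out / "events.tsv", sep="\t", index=False, float_format=pio.FLOAT_FMT)
    paths["events"] = str(out / "events.tsv")

    summaries = summarize_spontaneous(events, traces.protocol.baseline)
    summ_df = pd.DataFrame(
        [{"cell_id": s.cell_id, "n_events": s.n_events, "rate_per_min": s.rate_per_min, "is_spontaneous": s.is_spontaneous} for s in summaries]
    )
    summ_df.insert(0, "config_hash", chash)
    summ_df.to_csv(out / "spontaneous.tsv", sep="\t", index=False, float_format=pio.FLOAT_FMT)
    paths["spontaneous"] = str(out / "spontaneous.tsv")

    classifications = _stage("classify", classify_recording, traces, config.response_params())
    cls_df = classification_table(classifications)
    cls_df.insert(0, "config_hash", chash)
    cls_df.to_csv(out / "classifications.tsv", sep="\t", float_format=pio.FLOAT_FMT)
    paths["classifications"] = str(out / "classifications.tsv")

    profile = _stage("profile", tumor_summary, classifications, config.tumor_id)
    predicted, clauses = predict_recurrence(
        profile,
        RecurrenceThresholds(config.min_spontaneous_pct, config.min_multi_pct, config.max_non_pct),
    )
    profile.recurrent_predicted = predicted
    prof_df = profiles_to_table([profile])
    prof_df.insert(0, "config_hash", chash)
    prof_df.to_csv(out / "tumor_profile.tsv", sep="\t", float_format=pio.FLOAT_FMT)
    paths["tumor_profile"] = str(out / "tumor_profile.tsv")

    manifest = {
        "config_hash": chash,
        "outputs": paths,
        "n_cells": rec.n_cells,
        "n_viable": int(traces.viable_mask.sum()),
        "recurrence_clauses": clauses,
        "recurrent_predicted": bool(predicted),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest
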