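"""Detection of spontaneous calcium transients in the baseline epoch.

An event is a maximal run of frames whose ΔF/Fmin stays at or above a
threshold expressed as a multiple of the cell's robust noise SD. Runs
separated by a short gap are merged (a noisy dip inside one transient is
not two transients), and runs shorter than a minimum duration are dropped.
Events are classed fast or prolonged by their duration, mirroring the two
transient morphologies observed in these recordings: brief repetitive
spikes versus a single long-lasting mobilization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .processing import NormalizedTraceSet, baseline_center, robust_noise_sd
from .protocol import Epoch

__all__ = [
    "CalciumEvent",
    "SpontaneousSummary",
    "detect_events",
    "detect_baseline_events",
    "summarize_spontaneous",
    "spontaneous_fraction",
    "brute_force_oracle",
]

THRESHOLD_K = 3.5
MIN_DURATION_S = 0.6  # 3 frames at 5 Hz
MERGE_GAP_S = 0.4
PROLONGED_CUTOFF_S = 10.0
THRESHOLD_FLOOR = 0.02  # minimum dff excursion, guards degenerate noise estimates


@dataclass(frozen=True)
class CalciumEvent:
    """One detected transient: a maximal above-threshold excursion."""

    cell_id: int
    onset_s: float
    peak_s: float
    end_s: float
    peak_dff: float
    duration_s: float
    shape_class: str

    def __post_init__(self) -> None:
        if not self.onset_s <= self.peak_s <= self.end_s:
            raise ValueError("event times out of order")
        if self.duration_s <= 0:
            raise ValueError("event duration must be > 0")


@dataclass(frozen=True)
class SpontaneousSummary:
    """Per-cell count and rate of baseline transients."""

    cell_id: int
    n_events: int
    rate_per_min: float
    is_spontaneous: bool


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_events(
    dff: np.ndarray,
    frame_interval_s: float,
    epoch: Epoch | tuple[float, float],
    noise_sd: float,
    threshold_k: float = THRESHOLD_K,
    min_duration_s: float = MIN_DURATION_S,
    merge_gap_s: float = MERGE_GAP_S,
    prolonged_cutoff_s: float = PROLONGED_CUTOFF_S,
    cell_id: int = 0,
    absolute_threshold: float | None = None,
    center_dff: float = 0.0,
    threshold_floor: float = THRESHOLD_FLOOR,
) -> list[CalciumEvent]:
    """Detect transients of one cell inside one epoch.

    The threshold is ``center_dff + threshold_k × noise_sd`` (or
    ``absolute_threshold`` when given). ``center_dff`` is the cell's
    quiescent ΔF/Fmin level: because Fmin is a low percentile of the
    baseline, quiescent ΔF/Fmin sits slightly above zero, and the k·σ
    excursion criterion is counted from that level. Runs separated by less
    than ``merge_gap_s`` are merged; merged runs shorter than
    ``min_duration_s`` are discarded. Duration is counted as frames-in-run
    × frame interval; an event is prolonged iff its duration reaches
    ``prolonged_cutoff_s``.
    """
    if isinstance(epoch, Epoch):
        start_s, end_s = epoch.start_s, epoch.end_s
    else:
        start_s, end_s = epoch
    dt = frame_interval_s
    if end_s - start_s < min_duration_s:
        raise ValueError("analysis epoch shorter than the minimum event duration")
    i0 = int(np.ceil(start_s / dt - 1e-9))
    i1 = min(int(np.floor(end_s / dt + 1e-9)), dff.shape[0])
    seg = dff[i0:i1]
    thr = (
        absolute_threshold
        if absolute_threshold is not None
        else center_dff + max(threshold_k * noise_sd, threshold_floor)
    )
    runs = _runs_above(seg >= thr)

    # merge runs separated by a sub-gap dip
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and (a - merged[-1][1]) * dt < merge_gap_s:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    events: list[CalciumEvent] = []
    for a, b in merged:
        duration = (b - a) * dt
        if duration < min_duration_s - 1e-9:
            continue
        peak_rel = a + int(np.argmax(seg[a:b]))
        events.append(
            CalciumEvent(
                cell_id=cell_id,
                onset_s=(i0 + a) * dt,
                peak_s=(i0 + peak_rel) * dt,
                end_s=(i0 + b) * dt,
                peak_dff=float(seg[peak_rel]),
                duration_s=duration,
                shape_class="prolonged" if duration >= prolonged_cutoff_s else "fast",
            )
        )
    return events


def brute_force_oracle(
    dff: np.ndarray,
    threshold: float,
    frame_interval_s: float = 1.0,
    epoch: tuple[float, float] | None = None,
) -> list[tuple[int, int]]:
    """Exhaustive frame-by-frame reference scan: maximal above-threshold
    runs, no merging, no minimum duration. Intended for short traces as an
    independent check of the vectorized detector."""
    if dff.shape[0] > 5000:
        raise ValueError("oracle is for short traces (<= 5000 frames)")
    if epoch is None:
        i0, i1 = 0, dff.shape[0]
    else:
        dt = frame_interval_s
        i0 = int(np.ceil(epoch[0] / dt - 1e-9))
        i1 = min(int(np.floor(epoch[1] / dt + 1e-9)), dff.shape[0])
    runs: list[tuple[int, int]] = []
    in_run = False
    start = 0
    for i in range(i0, i1):
        above = dff[i] >= threshold
        if above and not in_run:
            in_run, start = True, i
        elif not above and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, i1))
    return runs


def detect_baseline_events(
    traces: NormalizedTraceSet,
    threshold_k: float = THRESHOLD_K,
    min_duration_s: float = MIN_DURATION_S,
    merge_gap_s: float = MERGE_GAP_S,
    prolonged_cutoff_s: float = PROLONGED_CUTOFF_S,
) -> dict[int, list[CalciumEvent]]:
    """Run the detector over the baseline epoch of every valid cell."""
    base = traces.protocol.baseline
    sigma = robust_noise_sd(traces)
    center = baseline_center(traces)
    out: dict[int, list[CalciumEvent]] = {}
    for ci in range(traces.n_cells):
        if not traces.valid_mask[ci]:
            continue
        out[ci] = detect_events(
            traces.dff[ci],
            traces.frame_interval_s,
            base,
            noise_sd=float(sigma[ci]),
            center_dff=float(center[ci]),
            threshold_k=threshold_k,
            min_duration_s=min_duration_s,
            merge_gap_s=merge_gap_s,
            prolonged_cutoff_s=prolonged_cutoff_s,
            cell_id=ci,
        )
    return out


def summarize_spontaneous(
    events_by_cell: dict[int, list[CalciumEvent]],
    baseline: Epoch,
) -> list[SpontaneousSummary]:
    """Per-cell spontaneous-activity summaries over the baseline epoch."""
    minutes = baseline.duration_s / 60.0
    out = []
    for cell_id in sorted(events_by_cell):
        n = len(events_by_cell[cell_id])
        out.append(
            SpontaneousSummary(
                cell_id=cell_id,
                n_events=n,
                rate_per_min=n / minutes,
                is_spontaneous=n >= 1,
            )
        )
    return out


def spontaneous_fraction(
    summaries: list[SpontaneousSummary],
    viable_cells: set[int] | np.ndarray,
) -> float:
    """Fraction of viable cells with any baseline transient."""
    if isinstance(viable_cells, np.ndarray):
        viable_cells = set(np.flatnonzero(viable_cells).tolist())
    viable = [s for s in summaries if s.cell_id in viable_cells]
    if not viable:
        raise ValueError("no viable cells: spontaneous fraction undefined")
    return sum(s.is_spontaneous for s in viable) / len(viable)
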