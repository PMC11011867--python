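"""Per-stimulus response calls and non-/mono-/multi-responsive categories.

A viable cell responds to a secretagogue pulse when a detected transient
*begins* inside the response window (the 30-s application plus a
configurable post-window), with peak ΔF/Fmin above the same noise-scaled
threshold used for spontaneous events. Cells are then partitioned by their
response count: non-responsive (0 — depolarized by high K+ only),
mono-responsive (exactly 1), multi-responsive (2 or more). Spontaneous
baseline activity is tracked as a separate attribute, never folded into
the category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import (
    MERGE_GAP_S,
    MIN_DURATION_S,
    PROLONGED_CUTOFF_S,
    THRESHOLD_K,
    SpontaneousSummary,
    detect_baseline_events,
    detect_events,
    summarize_spontaneous,
)
from .processing import NormalizedTraceSet, baseline_center, robust_noise_sd
from .protocol import Epoch

__all__ = [
    "CellClassification",
    "ResponseParams",
    "call_response",
    "classify_cell",
    "classify_recording",
    "tumor_summary",
]

POST_WINDOW_S = 30.0
LOOKBACK_S = 30.0

CATEGORIES = ("non_responsive", "mono_responsive", "multi_responsive")


@dataclass(frozen=True)
class ResponseParams:
    """Knobs of the response caller.

    ``post_window_s`` extends the window past the pulse end. With
    ``collapse_trh_da`` the TRH and TRH+DA channels count as a single TRH
    axis in the response count (default off: they are distinct stimuli).
    ``poisson_alpha``, when set, additionally requires the coincidence of a
    spontaneously active cell's event with the window to be unlikely under
    a Poisson null at that significance level (default off).
    """

    threshold_k: float = THRESHOLD_K
    min_duration_s: float = MIN_DURATION_S
    merge_gap_s: float = MERGE_GAP_S
    prolonged_cutoff_s: float = PROLONGED_CUTOFF_S
    post_window_s: float = POST_WINDOW_S
    lookback_s: float = LOOKBACK_S
    collapse_trh_da: bool = False
    poisson_alpha: float | None = None


@dataclass(frozen=True)
class CellClassification:
    """Viability, spontaneity, per-stimulus responses and category of one cell."""

    cell_id: int
    viable: bool
    spontaneous: bool
    response_vector: dict[str, bool]
    response_amplitudes: dict[str, float]
    category: str | None

    def __post_init__(self) -> None:
        if not self.viable:
            if self.category is not None:
                raise ValueError("non-viable cells carry no category")
            return
        n = sum(self.response_vector.values())
        expected = "non_responsive" if n == 0 else ("mono_responsive" if n == 1 else "multi_responsive")
        if self.category != expected:
            raise ValueError(f"category {self.category!r} inconsistent with {n} responses")


def call_response(
    dff: np.ndarray,
    frame_interval_s: float,
    stim_epoch: Epoch,
    noise_sd: float,
    params: ResponseParams = ResponseParams(),
    cell_id: int = 0,
    spontaneous_rate_per_s: float = 0.0,
    center_dff: float = 0.0,
) -> tuple[bool, float]:
    """Call one cell's response to one secretagogue pulse.

    The window is [pulse start, pulse end + post_window_s], truncated at
    the recording end (recorded via the returned peak either way). The
    detector is run from ``lookback_s`` before the window so that a
    transient already in progress at the window start is anchored at its
    true onset — only events *beginning* inside the window count.
    Returns (flag, window peak ΔF/Fmin).
    """
    dt = frame_interval_s
    total_s = dff.shape[0] * dt
    win_start = stim_epoch.start_s
    win_end = min(stim_epoch.end_s + params.post_window_s, total_s)
    scan_start = max(win_start - params.lookback_s, 0.0)
    events = detect_events(
        dff,
        dt,
        (scan_start, win_end),
        noise_sd=noise_sd,
        threshold_k=params.threshold_k,
        min_duration_s=params.min_duration_s,
        merge_gap_s=params.merge_gap_s,
        prolonged_cutoff_s=params.prolonged_cutoff_s,
        cell_id=cell_id,
        center_dff=center_dff,
    )
    sl = slice(int(np.ceil(win_start / dt - 1e-9)), int(np.floor(win_end / dt + 1e-9)))
    peak = float(dff[sl].max()) if sl.stop > sl.start else 0.0
    onsets_in = [e for e in events if e.onset_s >= win_start - 1e-9]
    flag = bool(onsets_in)
    if flag and params.poisson_alpha is not None and spontaneous_rate_per_s > 0:
        # Poisson null: probability that >= n spontaneous onsets coincide
        # with the window by chance, given the cell's baseline rate.
        lam = spontaneous_rate_per_s * (win_end - win_start)
        n = len(onsets_in)
        p = 1.0 - sum(math.exp(-lam) * lam**k / math.factorial(k) for k in range(n))
        flag = p < params.poisson_alpha
    return flag, peak


def classify_cell(
    cell_id: int,
    summary: SpontaneousSummary | None,
    response_vector: dict[str, bool],
    response_amplitudes: dict[str, float],
    protocol_stimuli: tuple[str, ...],
    viable: bool = True,
) -> CellClassification:
    """Assign the non-/mono-/multi-responsive category from the response
    vector; spontaneity is copied from the baseline analysis."""
    missing = set(protocol_stimuli) - set(response_vector)
    if missing:
        raise ValueError(f"response_vector missing stimuli: {sorted(missing)}")
    if not viable:
        return CellClassification(cell_id, False, False, dict(response_vector), dict(response_amplitudes), None)
    n = sum(bool(response_vector[s]) for s in protocol_stimuli)
    category = "non_responsive" if n == 0 else ("mono_responsive" if n == 1 else "multi_responsive")
    return CellClassification(
        cell_id=cell_id,
        viable=True,
        spontaneous=bool(summary.is_spontaneous) if summary is not None else False,
        response_vector=dict(response_vector),
        response_amplitudes=dict(response_amplitudes),
        category=category,
    )


def classify_recording(
    traces: NormalizedTraceSet,
    params: ResponseParams = ResponseParams(),
) -> list[CellClassification]:
    """Classify every cell of a gated recording.

    Requires :func:`pitcalc.processing.gate_viability` to have run. Returns
    one :class:`CellClassification` per cell (non-viable cells carry no
    category and all-false vectors).
    """
    if traces.viable_mask is None:
        raise ValueError("viability must be gated before classification")
    protocol = traces.protocol
    stimuli = protocol.stimuli
    stim_labels = tuple(e.label for e in stimuli)
    sigma = robust_noise_sd(traces)
    center = baseline_center(traces)
    baseline_events = detect_baseline_events(
        traces,
        threshold_k=params.threshold_k,
        min_duration_s=params.min_duration_s,
        merge_gap_s=params.merge_gap_s,
        prolonged_cutoff_s=params.prolonged_cutoff_s,
    )
    summaries = {s.cell_id: s for s in summarize_spontaneous(baseline_events, protocol.baseline)}

    out: list[CellClassification] = []
    for ci in range(traces.n_cells):
        if not traces.viable_mask[ci]:
            out.append(
                CellClassification(ci, False, False, {s: False for s in stim_labels}, {s: 0.0 for s in stim_labels}, None)
            )
            continue
        summ = summaries.get(ci)
        rate_per_s = (summ.n_events / protocol.baseline.duration_s) if summ else 0.0
        vector: dict[str, bool] = {}
        amps: dict[str, float] = {}
        for ep in stimuli:
            flag, peak = call_response(
                traces.dff[ci],
                traces.frame_interval_s,
                ep,
                noise_sd=float(sigma[ci]),
                params=params,
                cell_id=ci,
                spontaneous_rate_per_s=rate_per_s,
                center_dff=float(center[ci]),
            )
            vector[ep.label] = flag
            amps[ep.label] = peak
        if params.collapse_trh_da and "TRH" in vector and "TRH_DA" in vector:
            merged = vector["TRH"] or vector["TRH_DA"]
            vector = {**{k: v for k, v in vector.items() if k != "TRH_DA"}, "TRH": merged}
            amps = {**{k: v for k, v in amps.items() if k != "TRH_DA"}, "TRH": max(amps["TRH"], amps["TRH_DA"])}
            labels = tuple(k for k in stim_labels if k != "TRH_DA")
        else:
            labels = stim_labels
        out.append(classify_cell(ci, summ, vector, amps, labels, viable=True))
    return out


def tumor_summary(classifications: list[CellClassification], tumor_id: str):
    """Aggregate per-cell calls into a tumor responsiveness profile.

    All percentages are over viable cells — the high-K+ responders are the
    100% denominator. Raises on zero viable cells.
    """
    from .profiling import TumorProfile  # deferred: avoid import cycle

    viable = [c for c in classifications if c.viable]
    if not viable:
        raise ValueError(f"tumor {tumor_id}: zero viable cells, proportions undefined")
    n = len(viable)
    counts = {cat: sum(c.category == cat for c in viable) for cat in CATEGORIES}
    stim_labels = sorted({s for c in viable for s in c.response_vector})
    per_stim = {
        s: 100.0 * sum(c.response_vector.get(s, False) for c in viable) / n for s in stim_labels
    }
    return TumorProfile(
        tumor_id=tumor_id,
        pct_spontaneous=100.0 * sum(c.spontaneous for c in viable) / n,
        pct_non=100.0 * counts["non_responsive"] / n,
        pct_mono=100.0 * counts["mono_responsive"] / n,
        pct_multi=100.0 * counts["multi_responsive"] / n,
        per_stimulus_pct=per_stim,
        n_viable=n,
    )


def classification_table(classifications: list[CellClassification]) -> pd.DataFrame:
    """Flat per-cell table mirroring the category × stimulus layout."""
    rows = []
    for c in classifications:
        row = {
            "cell_id": c.cell_id,
            "viable": c.viable,
            "spontaneous": c.spontaneous,
            "category": c.category if c.category is not None else "",
        }
        for s, v in sorted(c.response_vector.items()):
            row[f"resp_{s}"] = v
        for s, v in sorted(c.response_amplitudes.items()):
            row[f"peak_{s}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_id")
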