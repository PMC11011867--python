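"""Photobleach correction, ΔF/Fmin normalization, and viability gating.

Raw fluorescence rides on a slowly decaying multiplicative baseline caused
by photobleaching of the dye. The correction fits a mono-exponential plus
offset to a running lower envelope of each trace (so calcium transients do
not bias the fit) and divides it out. Traces are then normalized as
ΔF/Fmin = (F − Fmin)/Fmin with Fmin a low percentile of the baseline epoch,
and viability is gated on the response to the terminal high-potassium
depolarization: only cells that depolarize enter any downstream denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter
from scipy.optimize import curve_fit

from .protocol import StimulusProtocol
from .synth import RecordingMatrix

__all__ = [
    "NormalizedTraceSet",
    "EmptyRecordingError",
    "correct_photobleach",
    "normalize_dff",
    "gate_viability",
    "robust_noise_sd",
]

ENVELOPE_PERCENTILE = 10.0
ENVELOPE_WINDOW_FRAC = 0.05
FMIN_PERCENTILE = 5.0
VIABILITY_K = 5.0
VIABILITY_FLOOR = 0.05
HIGH_K_TAIL_S = 10.0


class EmptyRecordingError(RuntimeError):
    """No viable (or valid) cells remain; downstream proportions undefined."""


@dataclass
class NormalizedTraceSet:
    """ΔF/Fmin traces plus per-cell QC state.

    ``valid_mask`` marks cells whose normalization succeeded (Fmin > 0);
    ``viable_mask`` is None until :func:`gate_viability` has run, after
    which it is True only for cells that passed the high-K+ gate (and are
    valid). ``bleach_params`` holds the fitted decay per cell.
    """

    dff: np.ndarray  # cells x frames, dimensionless
    fmin: np.ndarray  # per-cell denominator, arbitrary units
    bleach_params: pd.DataFrame
    protocol: StimulusProtocol
    valid_mask: np.ndarray
    viable_mask: np.ndarray | None = None
    ground_truth: list | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def frame_interval_s(self) -> float:
        return self.protocol.frame_interval_s

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.dff.shape[1]) * self.frame_interval_s

    def epoch_slice(self, start_s: float, end_s: float) -> slice:
        dt = self.frame_interval_s
        return slice(int(np.ceil(start_s / dt - 1e-9)), int(np.floor(end_s / dt + 1e-9)))


def _exp_offset(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def lower_envelope(trace: np.ndarray, window: int, percentile: float = ENVELOPE_PERCENTILE) -> np.ndarray:
    """Running low-percentile envelope; tracks the bleaching baseline while
    ignoring positive-going calcium transients."""
    window = max(int(window), 3)
    return percentile_filter(trace, percentile, size=window, mode="nearest")


def _fit_bleach(t: np.ndarray, env: np.ndarray, min_tau_s: float = 1e-3) -> tuple[float, float, float, bool]:
    """Fit a·exp(−t/τ)+c to the envelope. Returns (a, tau, c, fell_back);
    on non-convergence falls back to a linear detrend of the envelope
    expressed in the same parameter slots (tau=inf encodes the line).

    The fit is asymmetric: after an initial pass, envelope stretches still
    sitting clearly above the curve (long transients that survived the
    percentile filter) are discarded and the curve refit, so the model
    tracks the true photobleaching floor."""
    total = t[-1] - t[0] if len(t) > 1 else 1.0
    a0 = max(env[0] - env[-1], 1e-6)
    p0 = (a0, max(total / 3.0, 2.0 * min_tau_s), max(env[-1], 1e-6))
    bounds = ([0.0, min_tau_s, 0.0], [np.inf, 1e4 * max(total, 1.0), np.inf])
    try:
        keep = np.ones_like(env, dtype=bool)
        popt = p0
        for _ in range(3):
            popt, _ = curve_fit(_exp_offset, t[keep], env[keep], p0=popt, bounds=bounds, maxfev=2000)
            resid = env - _exp_offset(t, *popt)
            scale = 1.4826 * np.median(np.abs(resid[keep] - np.median(resid[keep])))
            new_keep = resid < max(2.0 * scale, 1e-3 * max(env.mean(), 1e-9))
            if new_keep.sum() < max(10, 0.1 * env.size) or np.array_equal(new_keep, keep):
                break
            keep = new_keep
        a, tau, c = (float(x) for x in popt)
        fitted = _exp_offset(t[keep], a, tau, c)
        resid = np.abs(fitted - env[keep]).mean()
        if not np.isfinite(resid) or resid > 0.2 * max(env.mean(), 1e-9):
            raise RuntimeError("poor fit")
        return a, tau, c, False
    except (RuntimeError, ValueError):
        slope, intercept = np.polyfit(t, env, 1)
        return float(slope), np.inf, float(intercept), True


def _eval_bleach(t: np.ndarray, a: float, tau: float, c: float) -> np.ndarray:
    if np.isinf(tau):  # linear fallback: slope in `a`, intercept in `c`
        return a * t + c
    return _exp_offset(t, a, tau, c)


def correct_photobleach(raw: RecordingMatrix) -> RecordingMatrix:
    """Divide out the fitted photobleaching decay, cell by cell.

    The corrected trace is ``F(t) · g(0)/g(t)`` with ``g`` the fitted
    envelope model, so the initial fluorescence level is preserved. Fit
    parameters (and any linear-detrend fallbacks) are stored in
    ``meta['bleach_params']``.
    """
    if raw.n_frames < 60:
        raise ValueError("photobleach correction requires >= 60 frames")
    t = raw.frame_times
    window = max(int(ENVELOPE_WINDOW_FRAC * raw.n_frames), 3)
    # A centered rolling percentile of a monotone-decaying floor lags it:
    # env(t) = floor(t + (0.5 - p/100)·window). Undo that known shift after
    # fitting so the divided-out curve is unbiased at the trace ends.
    lag_s = (0.5 - ENVELOPE_PERCENTILE / 100.0) * window * raw.frame_interval_s
    corrected = np.empty_like(raw.fluorescence)
    rows = []
    for ci in range(raw.n_cells):
        trace = raw.fluorescence[ci]
        env = lower_envelope(trace, window)
        # tau below the envelope window is unresolvable by this estimator
        a, tau, c, fallback = _fit_bleach(t, env, min_tau_s=window * raw.frame_interval_s)
        if fallback:
            c = c - a * lag_s  # line: shift intercept
        else:
            a = a * np.exp(lag_s / tau)
        g = _eval_bleach(t, a, tau, c)
        g0 = g[0] if g[0] > 0 else 1.0
        g = np.where(g > 1e-9 * g0, g, 1e-9 * g0)
        corrected[ci] = trace * (g0 / g)
        rows.append({"cell_id": ci, "amplitude": a, "tau_s": tau, "offset": c, "linear_fallback": fallback})
    np.clip(corrected, 0.0, None, out=corrected)
    meta = dict(raw.meta)
    meta["bleach_params"] = pd.DataFrame(rows).set_index("cell_id")
    meta["bleach_corrected"] = True
    return RecordingMatrix(
        fluorescence=corrected,
        frame_interval_s=raw.frame_interval_s,
        protocol=raw.protocol,
        ground_truth=raw.ground_truth,
        meta=meta,
    )


def normalize_dff(corrected: RecordingMatrix, fmin_percentile: float = FMIN_PERCENTILE) -> NormalizedTraceSet:
    """ΔF/Fmin normalization against a per-cell baseline-epoch percentile.

    Fmin is the ``fmin_percentile``-th percentile (lower-sample convention,
    so some frame attains it exactly) of the corrected trace over the
    baseline epoch — robust to noise undershoot, unlike the global minimum.
    Cells with Fmin ≤ 0 are flagged invalid and excluded downstream.
    """
    base = corrected.protocol.baseline
    dt = corrected.frame_interval_s
    sl = slice(int(np.ceil(base.start_s / dt - 1e-9)), int(np.floor(base.end_s / dt + 1e-9)))
    seg = corrected.fluorescence[:, sl]
    if seg.shape[1] < 1:
        raise ValueError("baseline epoch contains no frames")
    fmin = np.percentile(seg, fmin_percentile, axis=1, method="lower")
    valid = fmin > 0
    dff = np.zeros_like(corrected.fluorescence)
    if valid.any():
        dff[valid] = corrected.fluorescence[valid] / fmin[valid, None] - 1.0
    meta = dict(corrected.meta)
    meta["fmin_percentile"] = fmin_percentile
    meta["processing_order"] = "correct_photobleach -> normalize_dff"
    n_invalid = int((~valid).sum())
    if n_invalid:
        meta["invalid_cells"] = np.flatnonzero(~valid).tolist()
    bleach = meta.pop("bleach_params", pd.DataFrame())
    return NormalizedTraceSet(
        dff=dff,
        fmin=fmin,
        bleach_params=bleach,
        protocol=corrected.protocol,
        valid_mask=valid,
        ground_truth=corrected.ground_truth,
        meta=meta,
    )


def robust_noise_sd(traces: NormalizedTraceSet) -> np.ndarray:
    """Per-cell noise SD from the baseline epoch, insensitive to events:
    1.4826 · MAD of the first-differenced baseline ΔF/F, divided by √2."""
    base = traces.protocol.baseline
    sl = traces.epoch_slice(base.start_s, base.end_s)
    diff = np.diff(traces.dff[:, sl], axis=1)
    mad = np.median(np.abs(diff - np.median(diff, axis=1, keepdims=True)), axis=1)
    return 1.4826 * mad / np.sqrt(2.0)


def baseline_center(traces: NormalizedTraceSet) -> np.ndarray:
    """Per-cell quiescent ΔF/Fmin level: the median over the baseline
    epoch. Non-zero by construction (Fmin is a low percentile, so the
    typical quiescent frame sits slightly above it); excursion thresholds
    are counted from this level."""
    base = traces.protocol.baseline
    sl = traces.epoch_slice(base.start_s, base.end_s)
    return np.median(traces.dff[:, sl], axis=1)


def gate_viability(
    traces: NormalizedTraceSet,
    k: float = VIABILITY_K,
    floor: float = VIABILITY_FLOOR,
    tail_s: float = HIGH_K_TAIL_S,
) -> NormalizedTraceSet:
    """Mark cells viable iff they depolarize under the high-K+ pulse.

    A cell is viable when its peak ΔF/Fmin inside [high-K start,
    high-K end + ``tail_s``] exceeds its quiescent baseline level plus
    max(``k`` × its robust noise SD, ``floor``). Raises
    :class:`EmptyRecordingError` when no cell passes — all population
    denominators are defined over viable cells.
    """
    hk = traces.protocol.high_k
    end = min(hk.end_s + tail_s, traces.dff.shape[1] * traces.frame_interval_s)
    sl = traces.epoch_slice(hk.start_s, end)
    if sl.stop <= sl.start:
        raise ValueError("high_K window contains no frames")
    peak = traces.dff[:, sl].max(axis=1)
    sigma = robust_noise_sd(traces)
    threshold = baseline_center(traces) + np.maximum(k * sigma, floor)
    viable = (peak > threshold) & traces.valid_mask
    if not viable.any():
        raise EmptyRecordingError("no cells passed the high-K viability gate")
    meta = dict(traces.meta)
    meta["viability"] = {"k": k, "floor": floor, "tail_s": tail_s, "n_viable": int(viable.sum())}
    return replace(traces, viable_mask=viable, meta=meta)


def qc_table(traces: NormalizedTraceSet) -> pd.DataFrame:
    """Per-cell QC: Fmin, bleach fit, validity, viability, noise level."""
    sigma = robust_noise_sd(traces)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(traces.n_cells),
            "fmin": traces.fmin,
            "valid": traces.valid_mask,
            "viable": traces.viable_mask if traces.viable_mask is not None else np.full(traces.n_cells, np.nan),
            "noise_sd": sigma,
        }
    ).set_index("cell_id")
    if len(traces.bleach_params):
        df = df.join(traces.bleach_params)
    return df
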