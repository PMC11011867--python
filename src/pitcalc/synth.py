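"""Synthetic multi-cell calcium recordings with known per-cell ground truth.

The generator emulates perifusion epifluorescence recordings of dissociated
pituitary-adenoma tissue loaded with a calcium-sensitive dye: an ROI-by-time
matrix of raw fluorescence sampled at a fixed frame interval, with an
unstimulated baseline, five secretagogue pulses separated by washes, and a
terminal high-potassium depolarization. Each synthetic cell carries hidden
labels (viability, spontaneous baseline activity, the subset of secretagogues
it responds to) so every downstream stage can be scored against ground truth.

Population composition is realized exactly (largest-remainder allocation of
the requested fractions), so recovery experiments are limited by detection
error only, not by sampling error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .protocol import SECRETAGOGUES, Epoch, StimulusProtocol

__all__ = [
    "CellGroundTruth",
    "PopulationSpec",
    "RecordingMatrix",
    "TruncationWarning",
    "largest_remainder",
    "render_transient",
    "sample_population",
    "simulate_recording",
]


class TruncationWarning(UserWarning):
    """A transient did not fit inside its designated time span."""


# Difference-of-exponentials kinetics for the two transient morphologies
# seen in these recordings: brief spikes vs single prolonged mobilizations.
KERNEL_TAUS = {
    "fast": (0.2, 1.2),  # (rise tau_s, decay tau_s)
    "prolonged": (2.0, 30.0),
}


@dataclass(frozen=True)
class CellGroundTruth:
    """Hidden labels of one synthetic cell.

    ``shape_class`` applies to the cell's spontaneous baseline transients;
    stimulus-evoked and high-K+ responses are always rendered fast.
    ``baseline_event_onsets_s`` / ``response_onsets_s`` record the realized
    transient placements so detectors can be scored frame-accurately.
    """

    viable: bool
    spontaneous: bool
    n_spontaneous_events: int
    responds_to: frozenset[str]
    amplitude_scale: float = 1.0
    shape_class: str = "fast"
    baseline_event_onsets_s: tuple[float, ...] = ()
    response_onsets_s: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.viable and (self.responds_to or self.spontaneous):
            raise ValueError("non-viable cells cannot respond or be spontaneous")
        if self.spontaneous != (self.n_spontaneous_events >= 1):
            raise ValueError("spontaneous flag inconsistent with event count")
        if not 0 <= self.n_spontaneous_events <= 12:
            raise ValueError("n_spontaneous_events must be in [0, 12]")
        if self.shape_class not in KERNEL_TAUS:
            raise ValueError(f"unknown shape_class {self.shape_class!r}")
        unknown = set(self.responds_to) - set(SECRETAGOGUES)
        if unknown:
            raise ValueError(f"unknown stimuli in responds_to: {sorted(unknown)}")

    @property
    def category(self) -> str | None:
        """Ground-truth response category; None for non-viable cells."""
        if not self.viable:
            return None
        k = len(self.responds_to)
        return "non_responsive" if k == 0 else ("mono_responsive" if k == 1 else "multi_responsive")


@dataclass(frozen=True)
class PopulationSpec:
    """Composition and acquisition parameters of a synthetic tumor population.

    Fractions are proportions of *viable* cells except ``frac_viable``
    itself. ``noise_sd`` is the per-frame Gaussian noise in ΔF/F units;
    ``bleach_depth`` is the fraction of the initial fluorescence lost to
    photobleaching over the recording (mono-exponential with time constant
    ``bleach_tau_s``). Amplitudes are ΔF/F peak scales and are free
    parameters of the generator.
    """

    n_cells: int
    frac_viable: float = 1.0
    frac_spontaneous: float = 0.0
    frac_non_responsive: float = 1.0
    frac_mono: float = 0.0
    frac_multi: float = 0.0
    per_stimulus_weights: tuple[float, float, float, float, float] | None = None
    noise_sd: float = 0.02
    bleach_tau_s: float = 300.0
    bleach_depth: float = 0.2
    spont_amplitude: float = 0.5
    response_amplitude: float = 1.0
    high_k_amplitude: float = 2.0
    prolonged_prob: float = 0.3
    f0_range: tuple[float, float] = (80.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("frac_viable", "frac_spontaneous", "frac_non_responsive", "frac_mono", "frac_multi", "prolonged_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        s = self.frac_non_responsive + self.frac_mono + self.frac_multi
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"category fractions sum to {s}, expected 1")
        if self.per_stimulus_weights is not None:
            w = np.asarray(self.per_stimulus_weights, dtype=float)
            if w.shape != (5,) or (w < 0).any() or w.sum() <= 0:
                raise ValueError("per_stimulus_weights must be 5 non-negative weights")
        if self.noise_sd < 0 or not 0.0 <= self.bleach_depth < 1.0 or self.bleach_tau_s <= 0:
            raise ValueError("invalid noise/bleach parameters")
        if min(self.spont_amplitude, self.response_amplitude, self.high_k_amplitude) <= 0:
            raise ValueError("amplitudes must be > 0")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["per_stimulus_weights"] = None if self.per_stimulus_weights is None else list(self.per_stimulus_weights)
        d["f0_range"] = list(self.f0_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        d = dict(d)
        if d.get("per_stimulus_weights") is not None:
            d["per_stimulus_weights"] = tuple(d["per_stimulus_weights"])
        if "f0_range" in d:
            d["f0_range"] = tuple(d["f0_range"])
        return cls(**d)


@dataclass
class RecordingMatrix:
    """Raw fluorescence of many cells over time, plus acquisition metadata."""

    fluorescence: np.ndarray  # cells x frames, arbitrary units, >= 0
    frame_interval_s: float
    protocol: StimulusProtocol
    ground_truth: list[CellGroundTruth] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 2:
            raise ValueError("fluorescence must be a cells x frames matrix")
        if (self.fluorescence < 0).any():
            raise ValueError("fluorescence intensities must be >= 0")
        span = self.fluorescence.shape[1] * self.frame_interval_s
        if span < self.protocol.total_duration_s - 1e-6:
            raise ValueError("recording shorter than the protocol it claims to follow")
        if self.ground_truth is not None and len(self.ground_truth) != self.n_cells:
            raise ValueError("ground_truth length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


def largest_remainder(fractions, n: int) -> np.ndarray:
    """Allocate ``n`` items to categories in proportion to ``fractions``.

    Floors of ``f_i * n`` are taken first; the remaining items go to the
    categories with the largest fractional remainders, ties broken by
    lowest category index. The result always sums to ``n``.
    """
    f = np.asarray(fractions, dtype=float)
    if (f < -1e-12).any():
        raise ValueError("fractions must be non-negative")
    total = f.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"fractions sum to {total}, expected 1")
    exact = f * n
    counts = np.floor(exact + 1e-9).astype(int)
    remainder = exact - counts
    short = n - counts.sum()
    if short > 0:
        # stable sort => lowest index wins ties
        order = np.argsort(-remainder, kind="stable")
        counts[order[:short]] += 1
    return counts


def render_transient(
    shape_class: str,
    amplitude: float,
    onset_s: float,
    frame_interval_s: float,
    duration_s: float,
) -> np.ndarray:
    """Render one calcium transient as a ΔF/F segment on the frame grid.

    The kernel is a difference of exponentials ``exp(-t/tau_d) -
    exp(-t/tau_r)`` scaled so its peak equals ``amplitude``; the segment
    covers ``[onset_s, onset_s + duration_s)``. If the requested duration
    cuts the kernel off before it has decayed to 1% of its peak, a
    :class:`TruncationWarning` is emitted (never silent truncation).
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    if shape_class not in KERNEL_TAUS:
        raise ValueError(f"unknown shape_class {shape_class!r}")
    if frame_interval_s <= 0 or duration_s <= 0:
        raise ValueError("frame_interval_s and duration_s must be > 0")
    tau_r, tau_d = KERNEL_TAUS[shape_class]
    support = _kernel_support_s(shape_class)
    if duration_s < support:
        warnings.warn(
            f"{shape_class} transient truncated at {duration_s:.1f} s "
            f"(kernel support {support:.1f} s)",
            TruncationWarning,
            stacklevel=2,
        )
    n = int(round(duration_s / frame_interval_s))
    t = np.arange(n) * frame_interval_s
    return amplitude * _kernel(t, tau_r, tau_d)


def _kernel(t: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    t_peak = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    peak = np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_r)
    out = (np.exp(-t / tau_d) - np.exp(-t / tau_r)) / peak
    return np.clip(out, 0.0, None)


def _kernel_support_s(shape_class: str) -> float:
    """Time for the unit kernel to rise and decay below 1% of its peak."""
    tau_r, tau_d = KERNEL_TAUS[shape_class]
    t_peak = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    return t_peak + tau_d * np.log(100.0)


def _rng_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    pop_ss, sim_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(pop_ss), np.random.default_rng(sim_ss)


def sample_population(spec: PopulationSpec) -> list[CellGroundTruth]:
    """Draw the hidden per-cell labels for one synthetic tumor.

    Counts of viable cells, response categories and spontaneously active
    cells equal the largest-remainder allocation of the spec fractions
    exactly; only the assignment of labels to cell indices, the response
    stimulus subsets and the event counts are random (deterministic given
    ``spec.seed``).
    """
    rng, _ = _rng_streams(spec.seed)
    n = spec.n_cells
    n_viable = int(largest_remainder([spec.frac_viable, 1.0 - spec.frac_viable], n)[0])
    cat_counts = largest_remainder(
        [spec.frac_non_responsive, spec.frac_mono, spec.frac_multi], n_viable
    )
    n_spont = int(largest_remainder([spec.frac_spontaneous, 1.0 - spec.frac_spontaneous], n_viable)[0])

    weights = (
        np.full(5, 0.2)
        if spec.per_stimulus_weights is None
        else np.asarray(spec.per_stimulus_weights, dtype=float)
    )
    weights = weights / weights.sum()

    viable_flags = np.zeros(n, dtype=bool)
    viable_flags[rng.permutation(n)[:n_viable]] = True
    viable_idx = np.flatnonzero(viable_flags)

    categories = np.repeat(
        ["non_responsive", "mono_responsive", "multi_responsive"], cat_counts
    )
    rng.shuffle(categories)
    spont_flags = np.zeros(n_viable, dtype=bool)
    spont_flags[rng.permutation(n_viable)[:n_spont]] = True

    cells: list[CellGroundTruth] = []
    vpos = 0
    for i in range(n):
        if not viable_flags[i]:
            cells.append(CellGroundTruth(viable=False, spontaneous=False, n_spontaneous_events=0, responds_to=frozenset()))
            continue
        cat = categories[vpos]
        spont = bool(spont_flags[vpos])
        vpos += 1
        if cat == "non_responsive":
            responds: frozenset[str] = frozenset()
        elif cat == "mono_responsive":
            responds = frozenset([SECRETAGOGUES[_weighted_choice(rng, weights, 1)[0]]])
        else:
            k = int(rng.integers(2, 6))
            responds = frozenset(SECRETAGOGUES[j] for j in _weighted_choice(rng, weights, k))
        n_events = int(rng.integers(1, 13)) if spont else 0
        shape = "fast"
        if spont and n_events == 1 and rng.random() < spec.prolonged_prob:
            shape = "prolonged"
        cells.append(
            CellGroundTruth(
                viable=True,
                spontaneous=spont,
                n_spontaneous_events=n_events,
                responds_to=responds,
                amplitude_scale=float(rng.uniform(0.8, 1.2)),
                shape_class=shape,
            )
        )
    return cells


def _weighted_choice(rng: np.random.Generator, weights: np.ndarray, k: int) -> list[int]:
    """Draw k distinct indices with probability ~ weights, falling back to
    uniform over the remainder once all positive-weight indices are used."""
    w = weights.copy()
    picked: list[int] = []
    for _ in range(k):
        if w.sum() <= 0:
            w = np.array([0.0 if i in picked else 1.0 for i in range(len(weights))])
        p = w / w.sum()
        j = int(rng.choice(len(weights), p=p))
        picked.append(j)
        w[j] = 0.0
    return picked


def _spaced_onsets(rng: np.random.Generator, n: int, span: float, sep: float) -> np.ndarray:
    """n sorted onsets in [0, span] with pairwise separation >= sep (sep is
    reduced if n events cannot otherwise fit)."""
    if n == 0:
        return np.empty(0)
    if span <= 0:
        return np.zeros(n)
    sep = min(sep, span / n)
    free = span - (n - 1) * sep
    u = np.sort(rng.uniform(0.0, free, size=n))
    return u + sep * np.arange(n)


def _bleach_curve(t: np.ndarray, depth: float, tau_s: float, total_s: float) -> np.ndarray:
    """Mono-exponential-plus-offset multiplicative bleach: 1 at t=0,
    1 - depth at the end of the recording."""
    if depth == 0:
        return np.ones_like(t)
    a = depth / (1.0 - np.exp(-total_s / tau_s))
    return (1.0 - a) + a * np.exp(-t / tau_s)


def simulate_recording(spec: PopulationSpec, protocol: StimulusProtocol) -> RecordingMatrix:
    """Simulate a full recording: F(t) = F0 · bleach(t) · (1 + ΔF/F(t)) + noise.

    Spontaneous transients are placed only inside the baseline epoch (and
    truncated at its end); each responding cell gets one transient with
    onset within 5 s of the corresponding pulse start, truncated before the
    next pulse; every viable cell gets a high-amplitude transient at the
    high-K+ pulse. Noise is per-frame Gaussian in ΔF/F units. Fully
    deterministic given ``spec.seed``.
    """
    protocol.high_k  # raises if absent (viability gating impossible without it)
    _, rng = _rng_streams(spec.seed)
    cells = sample_population(spec)
    dt = protocol.frame_interval_s
    n_frames = protocol.n_frames
    t = np.arange(n_frames) * dt
    baseline = protocol.baseline
    hk = protocol.high_k
    truncations: list[str] = []

    fast_sep = _kernel_support_s("fast")
    signal = np.zeros((spec.n_cells, n_frames))
    placed: list[CellGroundTruth] = []
    for ci, cell in enumerate(cells):
        if not cell.viable:
            placed.append(cell)
            continue
        onsets: list[float] = []
        if cell.spontaneous:
            if cell.shape_class == "prolonged":
                span = max(baseline.duration_s * 0.3, dt)
                onsets = [float(rng.uniform(0.0, span))]
            else:
                span = max(baseline.duration_s - fast_sep, dt)
                onsets = list(_spaced_onsets(rng, cell.n_spontaneous_events, span, fast_sep))
            for onset in onsets:
                trunc = _add_transient(
                    signal[ci], dt, cell.shape_class,
                    spec.spont_amplitude * cell.amplitude_scale,
                    baseline.start_s + onset, baseline.end_s,
                )
                if trunc:
                    truncations.append(f"cell {ci}: baseline event truncated at {baseline.end_s:.1f} s")
        responses: dict[str, float] = {}
        for stim in protocol.stimuli:
            if stim.label not in cell.responds_to:
                continue
            onset = stim.start_s + float(rng.uniform(0.0, 5.0))
            # truncate before the next pulse, i.e. at the end of the wash
            end = _next_pulse_start(protocol, stim)
            responses[stim.label] = onset
            if _add_transient(signal[ci], dt, "fast", spec.response_amplitude * cell.amplitude_scale, onset, end):
                truncations.append(f"cell {ci}: {stim.label} response truncated at {end:.1f} s")
        hk_onset = hk.start_s + float(rng.uniform(0.0, 2.0))
        if _add_transient(signal[ci], dt, "fast", spec.high_k_amplitude * cell.amplitude_scale, hk_onset, protocol.total_duration_s):
            truncations.append(f"cell {ci}: high_K response truncated at recording end")
        placed.append(
            replace(cell, baseline_event_onsets_s=tuple(baseline.start_s + o for o in onsets), response_onsets_s=responses)
        )

    f0 = rng.uniform(*spec.f0_range, size=spec.n_cells)
    bleach = _bleach_curve(t, spec.bleach_depth, spec.bleach_tau_s, protocol.total_duration_s)
    dff = signal
    if spec.noise_sd > 0:
        dff = dff + rng.normal(0.0, spec.noise_sd, size=signal.shape)
    fluo = f0[:, None] * bleach[None, :] * (1.0 + dff)
    np.clip(fluo, 0.0, None, out=fluo)
    return RecordingMatrix(
        fluorescence=fluo,
        frame_interval_s=dt,
        protocol=protocol,
        ground_truth=placed,
        meta={
            "seed": spec.seed,
            "spec": spec.to_dict(),
            "truncations": truncations,
        },
    )


def _next_pulse_start(protocol: StimulusProtocol, stim: Epoch) -> float:
    """Start of the stimulus (or high-K+) pulse following `stim`."""
    for e in protocol.epochs:
        if e.start_s > stim.start_s + 1e-9 and e.label != "wash":
            return e.start_s
    return protocol.total_duration_s


def _add_transient(
    row: np.ndarray, dt: float, shape: str, amplitude: float, onset_s: float, end_s: float
) -> bool:
    """Add one kernel to a ΔF/F row in place, truncated at ``end_s``.

    Returns True if the truncation clipped the kernel before it decayed
    below 1% of its peak.
    """
    i0 = int(np.ceil(onset_s / dt - 1e-9))
    i1 = min(int(np.floor(end_s / dt + 1e-9)), row.shape[0])
    if i1 <= i0:
        return True
    tau_r, tau_d = KERNEL_TAUS[shape]
    tt = np.arange(i0, i1) * dt - onset_s
    row[i0:i1] += amplitude * _kernel(tt, tau_r, tau_d)
    return (end_s - onset_s) < _kernel_support_s(shape)
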