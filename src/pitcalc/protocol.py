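"""Stimulation protocols for perifusion calcium-imaging recordings.

A recording session consists of an unstimulated baseline, a sequence of
brief secretagogue pulses each followed by a wash, and a terminal
high-potassium depolarization pulse that defines cell viability. All
epochs live on a common clock sampled at a fixed frame interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

SECRETAGOGUES = ("CRH", "GHRH", "GnRH", "TRH", "TRH_DA")
EPOCH_LABELS = SECRETAGOGUES + ("baseline", "wash", "high_K")


class ProtocolError(ValueError):
    """Raised for structurally invalid stimulation protocols."""


@dataclass(frozen=True)
class Epoch:
    label: str
    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class StimulusProtocol:
    """Timed epochs (baseline, secretagogue pulses, washes, high K+).

    Parameters
    ----------
    frame_interval_s
        Seconds per acquired frame (0.2 s for the reference acquisition).
    epochs
        Ordered, non-overlapping epochs covering the session.
    total_duration_s
        Total recorded span; at least the end of the last epoch.
    """

    frame_interval_s: float
    epochs: tuple[Epoch, ...]
    total_duration_s: float

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ProtocolError("frame_interval_s must be > 0")
        prev_end = 0.0
        for ep in self.epochs:
            if ep.label not in EPOCH_LABELS:
                raise ProtocolError(f"unknown epoch label {ep.label!r}")
            if ep.duration_s <= 0:
                raise ProtocolError(f"epoch {ep.label} has non-positive duration")
            if ep.start_s < prev_end - 1e-9:
                raise ProtocolError("epochs overlap or are out of order")
            prev_end = ep.end_s
        if self.total_duration_s < prev_end - 1e-9:
            raise ProtocolError("total_duration_s shorter than last epoch end")
        if sum(1 for e in self.epochs if e.label == "baseline") != 1:
            raise ProtocolError("protocol requires exactly one baseline epoch")
        n_highk = sum(1 for e in self.epochs if e.label == "high_K")
        if n_highk != 1:
            raise ProtocolError("protocol requires exactly one high_K epoch")
        stim_epochs = [e for e in self.epochs if e.label in SECRETAGOGUES or e.label == "high_K"]
        if stim_epochs and stim_epochs[-1].label != "high_K":
            raise ProtocolError("high_K must be the last stimulus")
        seen: set[str] = set()
        for e in self.epochs:
            if e.label in SECRETAGOGUES:
                if e.label in seen:
                    raise ProtocolError(f"duplicate secretagogue {e.label}")
                seen.add(e.label)

    # -- lookup helpers -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration_s / self.frame_interval_s))

    @property
    def baseline(self) -> Epoch:
        return next(e for e in self.epochs if e.label == "baseline")

    @property
    def high_k(self) -> Epoch:
        return next(e for e in self.epochs if e.label == "high_K")

    @property
    def stimuli(self) -> tuple[Epoch, ...]:
        """Secretagogue pulse epochs in application order."""
        return tuple(e for e in self.epochs if e.label in SECRETAGOGUES)

    def epoch(self, label: str) -> Epoch:
        for e in self.epochs:
            if e.label == label:
                return e
        raise KeyError(label)

    def next_epoch_start(self, epoch: Epoch) -> float:
        """Start of the epoch following `epoch`, or total duration if last."""
        for e in self.epochs:
            if e.start_s > epoch.start_s + 1e-9:
                return e.start_s
        return self.total_duration_s

    def frame_times(self):
        import numpy as np

        return np.arange(self.n_frames) * self.frame_interval_s

    def to_dict(self) -> dict:
        return {
            "frame_interval_s": self.frame_interval_s,
            "total_duration_s": self.total_duration_s,
            "epochs": [[e.label, e.start_s, e.duration_s] for e in self.epochs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            frame_interval_s=float(d["frame_interval_s"]),
            epochs=tuple(Epoch(str(l), float(s), float(dur)) for l, s, dur in d["epochs"]),
            total_duration_s=float(d["total_duration_s"]),
        )


def _snap(t: float, dt: float) -> float:
    """Round a time down to an integral number of frames."""
    return math.floor(t / dt + 1e-9) * dt


def build_protocol(
    stimulus_order: list[str] | tuple[str, ...],
    baseline_s: float = 180.0,
    pulse_s: float = 30.0,
    wash_s: float = 900.0,
    frame_interval_s: float = 0.2,
    high_k_s: float | None = None,
) -> StimulusProtocol:
    """Assemble a baseline / pulse+wash / high-K+ protocol.

    `stimulus_order` is a permutation of a subset of the five secretagogue
    labels. Each pulse is followed by a wash; the high-K+ viability pulse
    (same duration as a secretagogue pulse unless `high_k_s` is given)
    comes last. Epoch boundaries are snapped down to integral multiples
    of the frame interval.
    """
    if frame_interval_s <= 0:
        raise ProtocolError("frame_interval_s must be > 0")
    if min(baseline_s, pulse_s, wash_s, 1.0) <= 0:
        raise ProtocolError("all durations must be > 0")
    order = tuple(stimulus_order)
    for s in order:
        if s not in SECRETAGOGUES:
            raise ProtocolError(f"unknown secretagogue {s!r}")
    if len(set(order)) != len(order):
        raise ProtocolError("duplicate stimulus label in stimulus_order")

    dt = frame_interval_s
    baseline_s = _snap(baseline_s, dt)
    pulse_s = _snap(pulse_s, dt)
    wash_s = _snap(wash_s, dt)
    hk = _snap(high_k_s if high_k_s is not None else pulse_s, dt)

    epochs = [Epoch("baseline", 0.0, baseline_s)]
    t = baseline_s
    for s in order:
        epochs.append(Epoch(s, t, pulse_s))
        t += pulse_s
        epochs.append(Epoch("wash", t, wash_s))
        t += wash_s
    epochs.append(Epoch("high_K", t, hk))
    t += hk
    return StimulusProtocol(frame_interval_s=dt, epochs=tuple(epochs), total_duration_s=t)


def default_protocol(frame_interval_s: float = 0.2, compress: float = 1.0) -> StimulusProtocol:
    """The reference acquisition protocol: 3-min baseline, five 30-s
    secretagogue pulses separated by 15-min washes, terminal 30-s high-K+.

    `compress` > 1 shrinks only the washes (by that factor) for fast
    tests and simulations; baseline, pulses and high-K+ keep their
    stated durations.
    """
    if compress < 1:
        raise ProtocolError("compress must be >= 1")
    return build_protocol(
        list(SECRETAGOGUES),
        baseline_s=180.0,
        pulse_s=30.0,
        wash_s=900.0 / compress,
        frame_interval_s=frame_interval_s,
    )
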