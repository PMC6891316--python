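"""Lateral eye-movement detection from the frontal F3/F4 channel pair.

A horizontal gaze shift produces opposite-sign voltage deflections on the
symmetric frontal electrodes F3 and F4.  The detector slides a 20-sample
window along the raw (unfiltered) pair and computes the slope statistic

    K_i = (y(x_{i+w}) - y(x_i)) / w      [uV per sample, w = window]

on each channel.  A window is a detection when |K| exceeds the threshold on
both channels with opposite signs and the Pearson correlation of the two
segments over the window is strongly negative (r < -0.85 by default; the
common-mode deflections of blinks correlate positively and are rejected).
Runs of detections separated by less than a refractory gap merge into one
event; the per-minute event rate is the vigilance measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_signals import Recording, ValidationError


@dataclass
class DetectorParams:
    """Tunables of the eye-movement detector.

    window
        Slope/correlation span in samples (the deflection's rise time).
    k_threshold
        |K| gate in uV/sample at the recording's native rate.
    r_threshold
        Magnitude of the (negative) window correlation gate.
    refractory
        Detections closer than this many seconds merge into one event.
    both_channels
        Require |K| above threshold on both F3 and F4 (else either).
    f3_positive_direction
        Gaze direction assigned when the F3 deflection is positive.
    """

    window: int = 20
    k_threshold: float = 2.0
    r_threshold: float = 0.85
    refractory: float = 0.2
    both_channels: bool = True
    f3_positive_direction: str = "left"

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValidationError("window must be >= 2 samples")
        if self.k_threshold <= 0 or self.r_threshold <= 0:
            raise ValidationError("thresholds must be positive")


@dataclass
class EyeMovementEvent:
    onset_sample: int
    offset_sample: int
    direction: str
    K_f3: float
    K_f4: float
    r_window: float

    def onset_seconds(self, fs: float) -> float:
        return self.onset_sample / fs


def slope_series(signal: np.ndarray, window: int = 20) -> np.ndarray:
    """K_i = (y[i+window] - y[i]) / window for every valid i.

    Output length is ``len(signal) - window``.
    """
    y = np.asarray(signal, dtype=float)
    if y.ndim != 1:
        raise ValidationError("slope_series expects a single channel")
    if y.size <= window:
        raise ValidationError(
            f"signal length {y.size} must exceed the window {window}")
    return (y[window:] - y[:-window]) / float(window)


def _rolling_corr(a: np.ndarray, b: np.ndarray, width: int) -> np.ndarray:
    """Pearson r of aligned length-``width`` windows of a and b."""
    kernel = np.ones(width)
    sa = np.convolve(a, kernel, mode="valid")
    sb = np.convolve(b, kernel, mode="valid")
    saa = np.convolve(a * a, kernel, mode="valid")
    sbb = np.convolve(b * b, kernel, mode="valid")
    sab = np.convolve(a * b, kernel, mode="valid")
    cov = sab - sa * sb / width
    var_a = saa - sa ** 2 / width
    var_b = sbb - sb ** 2 / width
    denom = np.sqrt(np.clip(var_a, 0, None) * np.clip(var_b, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def detect_events(rec: Recording,
                  params: DetectorParams | None = None) -> list[EyeMovementEvent]:
    """Run the slope + anticorrelation detector on a recording's F3/F4 pair."""
    params = params or DetectorParams()
    if not rec.has_channels(("F3", "F4")):
        raise ValidationError("recording must contain channels F3 and F4")
    f3 = rec.channel("F3")
    f4 = rec.channel("F4")
    w = params.window
    k3 = slope_series(f3, w)
    k4 = slope_series(f4, w)
    # correlation over the same span [i, i+window] as the slope (w+1 samples)
    r = _rolling_corr(f3, f4, w + 1)[: len(k3)]

    big3 = np.abs(k3) > params.k_threshold
    big4 = np.abs(k4) > params.k_threshold
    amp = big3 & big4 if params.both_channels else big3 | big4
    hits = amp & (np.sign(k3) == -np.sign(k4)) & (k3 != 0) \
        & (r < -params.r_threshold)

    idx = np.flatnonzero(hits)
    if idx.size == 0:
        return []
    gap = max(1, int(round(params.refractory * rec.fs)))
    breaks = np.flatnonzero(np.diff(idx) > gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))

    if params.f3_positive_direction == "left":
        dirmap = {1: "left", -1: "right"}
    else:
        dirmap = {1: "right", -1: "left"}

    events = []
    for s, e in zip(starts, ends):
        run = idx[s: e + 1]
        peak = run[np.argmax(np.abs(k3[run]) + np.abs(k4[run]))]
        events.append(EyeMovementEvent(
            onset_sample=int(run[0]),
            offset_sample=int(run[-1] + w),
            direction=dirmap[int(np.sign(k3[peak]))],
            K_f3=float(k3[peak]), K_f4=float(k4[peak]),
            r_window=float(r[peak])))
    return events


def eye_rate(events, duration: float) -> float:
    """Events per minute: 60 * count / duration[s]."""
    if duration <= 0:
        raise ValidationError("duration must be positive")
    return 60.0 * len(events) / duration


def events_to_rows(events, fs: float) -> list[dict]:
    """Flatten events for CSV export (onset_s, offset_s, direction, K, r)."""
    return [{
        "onset_s": ev.onset_sample / fs,
        "offset_s": ev.offset_sample / fs,
        "direction": ev.direction,
        "K_f3": ev.K_f3, "K_f4": ev.K_f4, "r_window": ev.r_window,
    } for ev in events]
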