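"""Relative power spectrum fatigue index beta/(theta+alpha).

Rising theta/alpha power and falling beta power accompany deepening fatigue,
so the ratio of beta band power to the summed theta and alpha band powers
decreases as vigilance declines.  Band powers come from the wavelet-packet
reconstructions of :mod:`fatiguenet.band_decomposition`, so the network
analysis and the spectral index share a single band definition.  The default
channel subset is the posterior pair {P3, P4}, where fatigue-related
spectral changes are most readily detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .band_decomposition import BandSet, band_power
from .io_signals import ValidationError

DEFAULT_RATIO_CHANNELS = ("P3", "P4")


@dataclass
class PowerRatioResult:
    per_channel: dict[str, float]      # NaN where theta+alpha power is 0
    selected: float                    # mean over the channel subset
    band_powers: dict[str, dict[str, float]]
    channels: tuple[str, ...]

    @property
    def undefined_channels(self) -> list[str]:
        return [ch for ch, v in self.per_channel.items() if not np.isfinite(v)]


def power_ratio(bands: BandSet, channels=DEFAULT_RATIO_CHANNELS) -> PowerRatioResult:
    """beta / (theta + alpha) band-power ratio per channel and averaged.

    A channel whose theta+alpha power is zero gets a NaN ratio (flagged via
    ``undefined_channels``), not an exception.
    """
    for name in ("theta", "alpha", "beta"):
        if name not in bands.band_signals:
            raise ValidationError(f"band {name!r} missing from BandSet")
    labels = bands.source.channel_labels
    missing = [ch for ch in channels if ch not in labels]
    if missing:
        raise ValidationError(f"requested channel(s) not present: {missing}")

    per_channel: dict[str, float] = {}
    band_powers: dict[str, dict[str, float]] = {}
    for ch in channels:
        idx = labels.index(ch)
        p = {name: band_power(bands.band_signals[name][idx: idx + 1])
             for name in ("theta", "alpha", "beta")}
        band_powers[ch] = p
        denom = p["theta"] + p["alpha"]
        per_channel[ch] = p["beta"] / denom if denom > 0 else float("nan")

    finite = [v for v in per_channel.values() if np.isfinite(v)]
    selected = float(np.mean(finite)) if finite else float("nan")
    return PowerRatioResult(per_channel=per_channel, selected=selected,
                            band_powers=band_powers, channels=tuple(channels))


def band_combination_ratio(bands: BandSet, numerator: tuple[str, ...],
                           denominator: tuple[str, ...],
                           channels=DEFAULT_RATIO_CHANNELS) -> float:
    """Generic sum(numerator bands) / sum(denominator bands) power ratio,
    averaged over the channel subset (e.g. theta/beta, (theta+alpha)/beta)."""
    labels = bands.source.channel_labels
    idx = [labels.index(ch) for ch in channels]
    num = sum(band_power(bands.band_signals[b], channel_idx=idx) for b in numerator)
    den = sum(band_power(bands.band_signals[b], channel_idx=idx) for b in denominator)
    return num / den if den > 0 else float("nan")
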