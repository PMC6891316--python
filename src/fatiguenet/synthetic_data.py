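"""Study-shaped synthetic EEG generator.

No public recordings exist for the driving study this pipeline analyses, so
every stage of the pipeline is exercised on synthetic datasets that carry
the statistical structure the analysis assumes:

* 12 subjects x 2 driving modes (normal, man-machine response mode "mrm")
  x 7 half-hourly stages, one multichannel epoch each;
* per-channel band-limited theta/alpha/beta components whose powers drift
  with stage (theta/alpha up, beta down as fatigue deepens);
* a shared theta-band source mixed across channels so the inter-channel
  theta correlation rises with stage (the substrate of the brain-network
  trend);
* lateral eye movements injected on F3/F4 only, as anti-correlated
  20-sample ramps to a plateau followed by a slow return, at a per-stage
  rate that declines with fatigue;
* subjective fatigue scores (7-point scale) and response error counts
  (mrm only) drawn around per-stage schedules.

Under the man-machine response mode every schedule drifts more slowly than
under normal driving, emulating the intervention's fatigue-delaying effect.
Schedules are free parameters; the defaults were fixed by forward design so
the default study reproduces the qualitative stage trends and a detectable
mode separation (see docs/methods.md).

Determinism: one epoch's random stream is keyed by (seed, subject index,
condition, stage), so identical configs and seeds give bit-identical data
and subjects are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io_signals import Recording, StudyTable, ValidationError, STUDY_CHANNELS, \
    write_recording

CONDITION_CODE = {"normal": 0, "mrm": 1}

#: Generation bands in Hz (the analysis' own band definitions).
GEN_BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 14.0), "beta": (14.0, 32.0)}


def _linear(a: float, b: float, n: int) -> tuple[float, ...]:
    return tuple(np.linspace(a, b, n))


def _default_band_power_schedule() -> dict:
    # power multipliers relative to the stage-independent base band powers;
    # fatigue raises theta/alpha and lowers beta, more slowly under mrm
    return {
        "normal": {"theta": _linear(1.0, 1.7, 7),
                   "alpha": _linear(1.0, 1.6, 7),
                   "beta": _linear(1.0, 0.5, 7)},
        "mrm": {"theta": _linear(1.0, 1.2, 7),
                "alpha": _linear(1.0, 1.15, 7),
                "beta": _linear(1.0, 0.9, 7)},
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the full-scale study (12 subjects, 3-minute epochs at
    1000 Hz); ``fs=128`` with shorter epochs is the reduced analysis size
    used for fast end-to-end runs.
    """

    n_subjects: int = 12
    stages: int = 7
    fs: float = 1000.0
    epoch_seconds: float = 180.0
    seed: int = 0
    channels: tuple[str, ...] = STUDY_CHANNELS
    # base per-band signal scale (uV, standard deviation at multiplier 1)
    band_base_sd: dict = field(default_factory=lambda: {
        "theta": 4.0, "alpha": 3.0, "beta": 3.0})
    noise_sd: float = 2.0
    band_power_schedule: dict = field(default_factory=_default_band_power_schedule)
    # target inter-channel theta correlation per stage
    coupling_schedule: dict = field(default_factory=lambda: {
        "normal": _linear(0.22, 0.46, 7),
        "mrm": _linear(0.22, 0.30, 7)})
    # expected lateral eye movements per minute per stage
    eye_rate_schedule: dict = field(default_factory=lambda: {
        "normal": _linear(12.0, 3.0, 7),
        "mrm": _linear(11.5, 9.5, 7)})
    eye_amplitude: float = 80.0      # uV deflection, opposite signs on F3/F4
    eye_ramp_samples: int = 20       # rise time of the deflection
    eye_hold_seconds: float = 0.1
    eye_return_seconds: float = 1.0  # slow sub-threshold return to baseline
    # mean subjective fatigue score (1-7) per stage
    sq_schedule: dict = field(default_factory=lambda: {
        "normal": (2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 6.5),
        "mrm": (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)})
    # response error probability per stage (mrm only) and trials per stage
    error_rate_schedule: tuple = (0.05, 0.08, 0.11, 0.14, 0.17, 0.21, 0.25)
    n_response_trials: int = 30
    blink_rate: float = 0.0          # common-mode blinks/min (specificity fixture)
    blink_amplitude: float = 80.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.stages < 1:
            raise ValidationError("need at least one subject and one stage")
        if self.fs <= 0 or self.epoch_seconds <= 0:
            raise ValidationError("fs and epoch_seconds must be positive")
        for cond in ("normal", "mrm"):
            for band, sched in self.band_power_schedule[cond].items():
                self._check_len(f"band_power_schedule[{cond}][{band}]", sched)
                if any(m < 0 for m in sched):
                    raise ValidationError("power multipliers must be >= 0")
            self._check_len(f"coupling_schedule[{cond}]",
                            self.coupling_schedule[cond])
            if any(not (0.0 <= c < 1.0) for c in self.coupling_schedule[cond]):
                raise ValidationError("coupling targets must lie in [0, 1)")
            self._check_len(f"eye_rate_schedule[{cond}]",
                            self.eye_rate_schedule[cond])
            if any(r < 0 for r in self.eye_rate_schedule[cond]):
                raise ValidationError("eye rates must be >= 0")
            self._check_len(f"sq_schedule[{cond}]", self.sq_schedule[cond])
        self._check_len("error_rate_schedule", self.error_rate_schedule)
        if any(not 0.0 <= p <= 1.0 for p in self.error_rate_schedule):
            raise ValidationError("error probabilities must lie in [0, 1]")

    def _check_len(self, name: str, sched) -> None:
        if len(sched) != self.stages:
            raise ValidationError(
                f"{name} has length {len(sched)}, expected stages={self.stages}")


@dataclass
class GroundTruthEvent:
    onset_sample: int
    direction: str   # "left" (F3 positive) or "right"


@dataclass
class StudyDataset:
    """Everything :func:`simulate_study` produces."""

    config: SimulationConfig
    recordings: dict            # (subject_id, condition, stage) -> Recording
    events: dict                # same key -> list[GroundTruthEvent]
    sq_scores: dict             # same key -> int
    error_counts: dict          # (subject_id, "mrm", stage) -> (errors, trials)

    def subjects(self) -> list[str]:
        return sorted({k[0] for k in self.recordings})


# ---------------------------------------------------------------------------
# signal components
# ---------------------------------------------------------------------------

def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float], shape=()) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` by a zero-phase filter."""
    lo, hi = band
    hi = min(hi, 0.499 * fs)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # pad so filter transients do not bias the epoch's variance
    pad = int(fs)
    x = rng.standard_normal(shape + (n + 2 * pad,))
    y = sosfiltfilt(sos, x, axis=-1)[..., pad:-pad]
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _eye_waveform(fs: float, ramp: int, hold_s: float, return_s: float) -> np.ndarray:
    """Unit deflection: linear rise over ``ramp`` samples, plateau, then a
    slow linear return whose slope stays below the detector's K gate."""
    hold = max(1, int(round(hold_s * fs)))
    ret = max(1, int(round(return_s * fs)))
    return np.concatenate([
        np.linspace(0.0, 1.0, ramp + 1)[1:],
        np.ones(hold),
        np.linspace(1.0, 0.0, ret + 1)[1:],
    ])


def _place_events(rng: np.random.Generator, n_events: int, n_samples: int,
                  event_len: int) -> np.ndarray:
    """Event onsets, one per equal time slot with jitter (non-overlapping)."""
    if n_events == 0:
        return np.empty(0, dtype=int)
    slot = n_samples // n_events
    if slot <= event_len:
        raise ValidationError(
            "eye-event rate too high for the epoch length (events overlap)")
    jitter = rng.integers(0, slot - event_len, size=n_events)
    return np.arange(n_events) * slot + jitter


def simulate_epoch(cfg: SimulationConfig, subject: int, condition: str,
                   stage: int,
                   rng: np.random.Generator | None = None
                   ) -> tuple[Recording, list[GroundTruthEvent]]:
    """Generate one epoch plus its ground-truth eye-event list.

    ``subject`` is the 0-based subject index; the returned Recording carries
    the 1-based id ``S01``-style.  When ``rng`` is omitted the stream is
    derived deterministically from (seed, subject, condition, stage).
    """
    if condition not in CONDITION_CODE:
        raise ValidationError(f"unknown condition {condition!r}")
    if not 1 <= stage <= cfg.stages:
        raise ValidationError(f"stage must be in 1..{cfg.stages}")
    if rng is None:
        rng = np.random.default_rng(
            [cfg.seed, subject, CONDITION_CODE[condition], stage])

    n = int(round(cfg.epoch_seconds * cfg.fs))
    n_ch = len(cfg.channels)
    st = stage - 1
    samples = np.zeros((n_ch, n))

    # theta: shared source (coupling) + independent remainder
    coupling = cfg.coupling_schedule[condition][st]
    theta_sd = cfg.band_base_sd["theta"] * np.sqrt(
        cfg.band_power_schedule[condition]["theta"][st])
    shared = _band_noise(rng, n, cfg.fs, GEN_BANDS["theta"])
    indep = _band_noise(rng, n, cfg.fs, GEN_BANDS["theta"], shape=(n_ch,))
    samples += theta_sd * (np.sqrt(coupling) * shared
                           + np.sqrt(1.0 - coupling) * indep)

    # independent alpha and beta components
    for band in ("alpha", "beta"):
        sd = cfg.band_base_sd[band] * np.sqrt(
            cfg.band_power_schedule[condition][band][st])
        samples += sd * _band_noise(rng, n, cfg.fs, GEN_BANDS[band],
                                    shape=(n_ch,))

    # broadband sensor noise
    samples += cfg.noise_sd * rng.standard_normal((n_ch, n))

    # ocular events on F3/F4 only: anti-correlated deflections
    labels = list(cfg.channels)
    i_f3, i_f4 = labels.index("F3"), labels.index("F4")
    wave = cfg.eye_amplitude * _eye_waveform(
        cfg.fs, cfg.eye_ramp_samples, cfg.eye_hold_seconds,
        cfg.eye_return_seconds)
    rate = cfg.eye_rate_schedule[condition][st]
    n_events = int(round(rate * cfg.epoch_seconds / 60.0))
    onsets = _place_events(rng, n_events, n, len(wave))
    events: list[GroundTruthEvent] = []
    for onset in onsets:
        sign = 1 if rng.random() < 0.5 else -1   # F3 deflection sign
        seg = slice(onset, onset + len(wave))
        samples[i_f3, seg] += sign * wave
        samples[i_f4, seg] -= sign * wave
        events.append(GroundTruthEvent(
            onset_sample=int(onset), direction="left" if sign > 0 else "right"))

    # optional common-mode blinks (same sign on both frontal channels):
    # a specificity fixture for the detector's anticorrelation gate
    if cfg.blink_rate > 0:
        n_blinks = int(round(cfg.blink_rate * cfg.epoch_seconds / 60.0))
        bw = cfg.blink_amplitude * _eye_waveform(
            cfg.fs, cfg.eye_ramp_samples, cfg.eye_hold_seconds,
            cfg.eye_return_seconds)
        for onset in _place_events(rng, n_blinks, n, len(bw)):
            seg = slice(onset, onset + len(bw))
            samples[i_f3, seg] += bw
            samples[i_f4, seg] += bw

    rec = Recording(
        subject_id=f"S{subject + 1:02d}", condition=condition, stage=stage,
        fs=cfg.fs, channel_labels=labels, samples=samples)
    return rec, events


def simulate_study(cfg: SimulationConfig) -> StudyDataset:
    """Generate the full design: every subject x condition x stage epoch,
    subjective scores, and response error counts (mrm only)."""
    recordings, events, sq_scores, error_counts = {}, {}, {}, {}
    for subj in range(cfg.n_subjects):
        sid = f"S{subj + 1:02d}"
        for cond in ("normal", "mrm"):
            for stage in range(1, cfg.stages + 1):
                rec, evs = simulate_epoch(cfg, subj, cond, stage)
                key = (sid, cond, stage)
                recordings[key] = rec
                events[key] = evs
                # side-stream for questionnaire / response draws
                rng = np.random.default_rng(
                    [cfg.seed, subj, CONDITION_CODE[cond], stage, 7919])
                mean_sq = cfg.sq_schedule[cond][stage - 1]
                sq = int(np.clip(round(mean_sq + rng.integers(-1, 2)), 1, 7))
                sq_scores[key] = sq
                if cond == "mrm":
                    p = cfg.error_rate_schedule[stage - 1]
                    errs = int(rng.binomial(cfg.n_response_trials, p))
                    error_counts[key] = (errs, cfg.n_response_trials)
    return StudyDataset(config=cfg, recordings=recordings, events=events,
                        sq_scores=sq_scores, error_counts=error_counts)


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def write_dataset(ds: StudyDataset, out_dir: str | Path,
                  format: str = "csv") -> Path:
    """Write a dataset as one epoch file per recording plus
    ``ground_truth.json`` and ``study_meta.csv``."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_rows, truth = [], {}
    for (sid, cond, stage), rec in ds.recordings.items():
        stem = f"{sid}_{cond}_stage{stage}"
        write_recording(rec, out / f"{stem}.{format}", format=format)
        key = f"{sid}/{cond}/{stage}"
        truth[key] = {
            "events": [asdict(ev) for ev in ds.events[(sid, cond, stage)]],
            "sq_score": ds.sq_scores[(sid, cond, stage)],
        }
        row = {"subject": sid, "condition": cond, "stage": stage,
               "file": f"{stem}.{format}",
               "sq_score": ds.sq_scores[(sid, cond, stage)]}
        if (sid, cond, stage) in ds.error_counts:
            errs, trials = ds.error_counts[(sid, cond, stage)]
            row["response_errors"], row["response_trials"] = errs, trials
        meta_rows.append(row)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    pd.DataFrame(meta_rows).to_csv(out / "study_meta.csv", index=False)
    return out


def dataset_study_table_fields(ds: StudyDataset) -> StudyTable:
    """Seed a StudyTable with the generator-known fields (sq, error rate);
    analysis fields (C, G, power_ratio, eye_rate) stay NaN until the
    pipeline fills them."""
    table = StudyTable()
    for (sid, cond, stage) in ds.recordings:
        errs = ds.error_counts.get((sid, cond, stage))
        table.add_row(sid, cond, stage,
                      sq_score=ds.sq_scores[(sid, cond, stage)],
                      error_rate=(errs[0] / errs[1]) if errs else np.nan)
    return table
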