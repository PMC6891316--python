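"""End-to-end analysis pipeline.

simulate (or load) -> resample + wavelet-packet band extraction -> theta
correlation networks (threshold sweep or fixed T) -> spectral fatigue ratio
-> eye-movement detection -> aggregated study table -> group statistics.

A run directory receives the study table, the threshold-sweep tables, the
per-epoch eye-event table, the statistics report, the resolved config, a log
and a manifest of output file hashes; identical config + seed reproduce the
study table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import band_decomposition, brain_network, group_stats, oculomotor, \
    spectral_ratio, synthetic_data
from .io_signals import Recording, StudyTable, ValidationError, \
    read_recording, write_study_table

log = logging.getLogger("fatiguenet")


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run (YAML-serialisable)."""

    input_dir: str | None = None        # None -> simulate
    out_dir: str = "fatiguenet_run"
    seed: int = 0
    # simulation (used when input_dir is None); overrides for SimulationConfig
    simulation: dict = field(default_factory=dict)
    # decomposition
    working_fs: float = band_decomposition.DEFAULT_WORKING_FS
    wavelet: str = band_decomposition.DEFAULT_WAVELET
    level: int = band_decomposition.DEFAULT_LEVEL
    bands: dict = field(default_factory=lambda: {
        k: list(v) for k, v in band_decomposition.DEFAULT_BANDS.items()})
    overlap_rule: str = "majority"
    # network
    threshold: float | None = None      # fixed T; None -> significance sweep
    threshold_grid: list = field(default_factory=lambda: list(
        brain_network.DEFAULT_THRESHOLD_GRID))
    abs_corr: bool = False
    # spectral ratio
    ratio_channels: list = field(default_factory=lambda: ["P3", "P4"])
    # detector
    detector: dict = field(default_factory=dict)
    # statistics
    alpha: float = 0.05
    stats_design: str = "independent_pooled"
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def simulation_config(self) -> synthetic_data.SimulationConfig:
        return synthetic_data.SimulationConfig(seed=self.seed, **self.simulation)

    def detector_params(self) -> oculomotor.DetectorParams:
        return oculomotor.DetectorParams(**self.detector)


@dataclass
class RunResult:
    out_dir: Path
    table: StudyTable
    sweep: brain_network.ThresholdSweepResult | None
    selected_T: float
    report: dict
    warnings: list[str]


# ---------------------------------------------------------------------------
# dataset loading
# ---------------------------------------------------------------------------

def load_dataset_dir(input_dir: str | Path) -> tuple[dict, dict, dict]:
    """Read a dataset directory written by ``write_dataset``.

    Returns (recordings, sq_scores, error_counts) keyed by
    (subject, condition, stage).
    """
    input_dir = Path(input_dir)
    meta_path = input_dir / "study_meta.csv"
    if not meta_path.exists():
        raise ValidationError(f"no recordings found: missing {meta_path}")
    meta = pd.read_csv(meta_path)
    recordings, sq_scores, error_counts = {}, {}, {}
    for row in meta.itertuples(index=False):
        key = (str(row.subject), str(row.condition), int(row.stage))
        recordings[key] = read_recording(input_dir / row.file)
        if hasattr(row, "sq_score") and not pd.isna(row.sq_score):
            sq_scores[key] = int(row.sq_score)
        if hasattr(row, "response_errors") and not pd.isna(row.response_errors):
            error_counts[key] = (int(row.response_errors),
                                 int(row.response_trials))
    if not recordings:
        raise ValidationError(f"no recordings found in {input_dir}")
    return recordings, sq_scores, error_counts


# ---------------------------------------------------------------------------
# per-epoch analysis
# ---------------------------------------------------------------------------

@dataclass
class EpochAnalysis:
    key: tuple
    corr: brain_network.CorrelationMatrix
    ratio: float
    n_events: int
    rate: float
    events: list


def analyze_epoch(rec: Recording, cfg: PipelineConfig) -> EpochAnalysis:
    bands = band_decomposition.wpd_decompose(
        rec, level=cfg.level, wavelet_name=cfg.wavelet,
        working_fs=cfg.working_fs,
        bands={k: tuple(v) for k, v in cfg.bands.items()},
        overlap_rule=cfg.overlap_rule)
    corr = brain_network.correlation_matrix(
        bands.band_signals["theta"], rec.channel_labels)
    ratio = spectral_ratio.power_ratio(
        bands, channels=tuple(cfg.ratio_channels)).selected
    events = oculomotor.detect_events(rec, cfg.detector_params())
    rate = oculomotor.eye_rate(events, rec.duration)
    return EpochAnalysis(
        key=(rec.subject_id, rec.condition, rec.stage), corr=corr,
        ratio=ratio, n_events=len(events), rate=rate, events=events)


def _metric_grids(analyses: dict, grid, condition: str, abs_corr: bool
                  ) -> tuple[np.ndarray, np.ndarray, list, list]:
    """C and G arrays shaped (n_T, n_subjects, n_stages) for one condition."""
    subjects = sorted({k[0] for k in analyses if k[1] == condition})
    stages = sorted({k[2] for k in analyses if k[1] == condition})
    C = np.full((len(grid), len(subjects), len(stages)), np.nan)
    G = np.full_like(C, np.nan)
    for ti, T in enumerate(grid):
        for si, subj in enumerate(subjects):
            for ki, stage in enumerate(stages):
                m = brain_network.network_metrics(
                    analyses[(subj, condition, stage)].corr, T,
                    abs_corr=abs_corr)
                C[ti, si, ki] = m.C
                G[ti, si, ki] = m.G
    return C, G, subjects, stages


def run_sweep(analyses: dict, cfg: PipelineConfig,
              condition: str = "normal") -> brain_network.ThresholdSweepResult:
    """Threshold significance sweep on one condition's epochs (the sweep
    contrasts stage 1 with stages 2..7 across subjects)."""
    C, G, _, _ = _metric_grids(analyses, cfg.threshold_grid, condition,
                               cfg.abs_corr)
    return brain_network.sweep_threshold(
        C, G, thresholds=cfg.threshold_grid, alpha=cfg.alpha,
        design=cfg.stats_design)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> RunResult:
    """Execute the full pipeline and write the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    warnings: list[str] = []

    try:
        if cfg.input_dir is None:
            log.info("simulating study (seed=%d)", cfg.seed)
            ds = synthetic_data.simulate_study(cfg.simulation_config())
            recordings = ds.recordings
            sq_scores = ds.sq_scores
            error_counts = ds.error_counts
        else:
            log.info("loading dataset from %s", cfg.input_dir)
            recordings, sq_scores, error_counts = load_dataset_dir(cfg.input_dir)
    except Exception as exc:
        raise RuntimeError(f"stage 'load': {exc}") from exc

    analyses: dict = {}
    try:
        for i, (key, rec) in enumerate(sorted(recordings.items())):
            analyses[key] = analyze_epoch(rec, cfg)
            if (i + 1) % 25 == 0:
                log.info("analyzed %d/%d epochs", i + 1, len(recordings))
    except Exception as exc:
        raise RuntimeError(f"stage 'epoch-analysis': {exc}") from exc

    sweep = None
    if cfg.threshold is None:
        try:
            sweep = run_sweep(analyses, cfg)
        except Exception as exc:
            raise RuntimeError(f"stage 'threshold-sweep': {exc}") from exc
        if sweep.selected_T is None:
            warnings.append("threshold sweep found no significant interval; "
                            "falling back to the grid midpoint")
            selected_T = float(np.median(np.asarray(cfg.threshold_grid)))
        else:
            selected_T = float(sweep.selected_T)
        log.info("sweep selected T=%.4f (C interval %s, G interval %s)",
                 selected_T, sweep.significant_interval_C,
                 sweep.significant_interval_G)
    else:
        selected_T = float(cfg.threshold)

    table = StudyTable()
    event_rows = []
    try:
        for key in sorted(analyses):
            subj, cond, stage = key
            an = analyses[key]
            m = brain_network.network_metrics(an.corr, selected_T,
                                              abs_corr=cfg.abs_corr)
            if not np.isfinite(an.ratio):
                warnings.append(f"undefined power ratio for {key}")
            errs = error_counts.get(key)
            table.add_row(
                subj, cond, stage, C=m.C, G=m.G, power_ratio=an.ratio,
                eye_rate=an.rate, sq_score=sq_scores.get(key, np.nan),
                error_rate=(errs[0] / errs[1]) if errs else np.nan)
            fs = recordings[key].fs
            for row in oculomotor.events_to_rows(an.events, fs):
                event_rows.append({"subject": subj, "condition": cond,
                                   "stage": stage, **row})
    except Exception as exc:
        raise RuntimeError(f"stage 'aggregate': {exc}") from exc

    try:
        report = build_report(table, cfg, selected_T, warnings)
    except Exception as exc:
        raise RuntimeError(f"stage 'statistics': {exc}") from exc

    # ---- artifacts ----
    write_study_table(table, out / "study_table.csv")
    pd.DataFrame(event_rows).to_csv(out / "eye_events.csv", index=False)
    if sweep is not None:
        sweep.stat_table.to_csv(out / "threshold_sweep.csv", index=False)
        (out / "threshold_sweep.json").write_text(json.dumps({
            "significant_interval_C": sweep.significant_interval_C,
            "significant_interval_G": sweep.significant_interval_G,
            "selected_T": sweep.selected_T}, indent=1))
    (out / "report.json").write_text(json.dumps(report, indent=1))
    cfg_resolved = dataclasses.replace(cfg, threshold=selected_T)
    cfg_resolved.to_yaml(out / "resolved_config.yaml")
    manifest = {p.name: _sha256(p) for p in sorted(out.iterdir())
                if p.is_file() and p.name != "manifest.json"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("run complete: %s (%d epochs, T=%.4f)", out, len(analyses),
             selected_T)
    return RunResult(out_dir=out, table=table, sweep=sweep,
                     selected_T=selected_T, report=report, warnings=warnings)


def build_report(table: StudyTable, cfg: PipelineConfig, selected_T: float,
                 warnings: list[str]) -> dict:
    """Stage trends per condition and the normal-vs-mrm comparisons."""
    report: dict = {"selected_T": selected_T, "warnings": list(warnings),
                    "trends": {}, "condition_comparisons": {}}
    conditions = sorted(table.data["condition"].unique())
    metrics = ["C", "G", "power_ratio", "eye_rate", "sq_score"]
    for cond in conditions:
        report["trends"][cond] = {}
        for col in metrics + (["error_rate"] if cond == "mrm" else []):
            if table.data.loc[table.data["condition"] == cond, col].isna().all():
                continue
            tr = group_stats.stage_trend(table, col, cond)
            report["trends"][cond][col] = {
                "means": [round(float(v), 6) for v in tr.means],
                "sds": [None if not np.isfinite(v) else round(float(v), 6)
                        for v in tr.sds],
                "spearman_rho": round(tr.spearman_rho, 4),
            }
    if set(conditions) == {"normal", "mrm"}:
        for col in metrics:
            cc = group_stats.compare_conditions(
                table, col, design=cfg.stats_design, alpha=cfg.alpha)
            report["condition_comparisons"][col] = {
                "t": round(cc.result.t, 4), "df": cc.result.df,
                "p": round(cc.result.p, 5), "t_crit": round(cc.result.t_crit, 4),
                "significant": cc.result.significant,
            }
    return report
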