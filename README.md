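# fatiguenet

EEG analysis of driving fatigue and of interventions meant to delay it.

Long monotonous driving degrades vigilance. `fatiguenet` implements a
four-measure EEG/EOG pipeline for tracking that decline across the stages
of a long drive and for comparing driving modes — e.g. ordinary driving
against a *man-machine response mode* (MRM) in which the driver
periodically answers spoken arithmetic prompts via steering-wheel buttons:

1. **Brain networks** — θ-band (4–8 Hz) inter-channel Pearson correlations,
   thresholded at T into a binary graph; fatigue raises the mean clustering
   coefficient C and the global efficiency G. The threshold is selected by
   a significance sweep: over a grid of T values, stage 1 is t-tested
   against every later stage, and T is the midpoint of the interval where
   all comparisons are significant for both C and G.
2. **Spectral fatigue index** — the band-power ratio β/(θ+α) over the
   posterior channels P3/P4, which falls as fatigue deepens.
3. **Eye-movement rate** — lateral saccades detected on the frontal F3/F4
   pair via the window slope statistic K_i = (y(x_{i+20}) − y(x_i))/20 with
   the gate |K| > 2 (both channels, opposite signs) and window correlation
   r < −0.85; the per-minute rate falls with fatigue.
4. **Behavioural/subjective measures** — 7-point subjective fatigue scores
   and response error rates, compared stage-wise.

Bands come from a depth-4 wavelet packet decomposition at a 128 Hz working
rate (sixteen 4-Hz nodes; θ is exactly one node). Group comparisons are
two-tailed t-tests; mode comparisons use the 7 per-stage means per
condition (pooled variance, df = 12).

Because no public recordings exist for this paradigm, the package includes
a first-class synthetic-study generator (12 subjects × 2 modes × 7 stages)
with fatigue-dependent band-power drift, rising θ-band coupling, declining
eye-movement rates, and questionnaire/error schedules — the test bed for
the whole pipeline. See `docs/methods.md` for the model and its limits.

## Worked example

```python
from fatiguenet.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="run", seed=3, threshold=0.3475,
                     simulation={"fs": 128.0, "epoch_seconds": 30.0})
res = run_pipeline(cfg)
print(res.report["condition_comparisons"]["C"])
print(res.report["condition_comparisons"]["eye_rate"])
```

prints

```
{'t': 2.5779, 'df': 12.0, 'p': 0.02419, 't_crit': 2.1788, 'significant': True}
{'t': -2.7358, 'df': 12.0, 'p': 0.01807, 't_crit': 2.1788, 'significant': True}
```

i.e. on this simulated study the mean clustering coefficient is higher
under normal driving than under MRM (t = 2.58 > t_crit = 2.179 at df = 12,
p = 0.024) — fatigue-related network densification is delayed by the
intervention — and the eye-movement rate is correspondingly *lower* under
normal driving (negative t: normal minus MRM), since fatigue suppresses
saccades faster without the intervention. `run/study_table.csv` holds one
row per subject × condition × stage with columns
`C, G, power_ratio, eye_rate, sq_score, error_rate`, and `run/report.json`
the per-condition stage trends (means, SDs, Spearman ρ).

The same pipeline is scriptable from the shell:

```sh
fatiguenet simulate --seed 42 --out data/            # write a dataset
fatiguenet analyze --in data/ --out run/             # full analysis (sweep)
fatiguenet analyze --in data/ --out run/ --threshold 0.3475
fatiguenet sweep-threshold --in data/ --out sweep/   # threshold sweep only
fatiguenet detect-eyes data/S01_normal_stage1.csv    # one-epoch detector
fatiguenet report run/ --plots                       # re-render summaries
```

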