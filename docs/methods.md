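# Methods

`fatiguenet` implements a driving-fatigue analysis pipeline for multichannel
EEG: four complementary fatigue measures are extracted per 3-minute epoch and
compared across seven half-hourly stages of a simulated 3-hour drive, and
between two driving modes — ordinary monotonous driving (`normal`) and a
man-machine response mode (`mrm`) in which the driver periodically answers
spoken arithmetic prompts via steering-wheel buttons. Because no recordings
from such a study are publicly available, the package ships a synthetic-data
generator that reproduces the study's design and the statistical structure
the analysis relies on; all tests and the acceptance script run against it.

## Signal model and band extraction

Each epoch is a channels × time matrix in microvolts at sampling rate `fs`
(1000 Hz in the emulated study), with 14 scalp channels (F3, F4, F7, F8,
FT7, FT8, C3, C4, TP7, TP8, P3, P4, O1, O2). The rhythm bands are
θ = 4–8 Hz, α = 8–14 Hz, β = 14–32 Hz. (Some fatigue literature uses
α = 8–13 Hz and β = 13–35 Hz; this package uses one band definition
everywhere so the network analysis and the spectral index cannot drift
apart.)

Bands are obtained by a depth-4 **wavelet packet decomposition** (WPD):
the signal is split into `2^4 = 16` equal-width terminal nodes,
`f(t) = Σ_j f_{4,j}(t_j)`, with node energies `E_{4,j} = Σ_k x_{j,k}²`
satisfying Parseval's identity against the raw energy. Two numerical
choices matter:

* **Working rate 128 Hz.** A 4-level WPD at 1000 Hz has 31.25-Hz nodes and
  cannot resolve θ. Epochs are resampled (polyphase, zero-phase) to 128 Hz,
  where the 16 nodes are exactly 4 Hz wide: θ is the single node [4, 8) and
  β stays below Nyquist. The rate is configurable.
* **Node-membership rule.** α = 8–14 Hz does not align to the dyadic 4-Hz
  grid. A node belongs to a band when **more than half** of its interval
  lies inside the band, so α = [8, 12) (the [12, 16) node overlaps on
  exactly half its width and is excluded) and β = [16, 32). An
  "any-overlap" rule is available; with it bands overlap and double-count
  boundary nodes, which is why majority is the default. Because the same
  truncation applies at every stage, stage *ratios* of band powers are
  unaffected by the truncation.
* **Wavelet `db16`** (configurable). Short wavelets have wide transition
  bands: with `db4` a mid-band 6 Hz tone keeps only ~85% of its energy in
  its node, which defeats the point of band extraction; `db16` keeps ≥98%.
  Symmetric boundary extension; reconstructions truncated to input length.

Band power is the mean squared amplitude of the reconstructed band signal
(µV²). Broadband sensor noise contributes a small additive floor to every
node (white noise of variance σ² at working rate `f_w` adds
σ²·(4 Hz)/(f_w/2) per node); power-ratio trends are insensitive to it, but
exact multiplier recovery is tested noise-free for this reason.

## Brain networks

Functional networks are built from the θ-band signals: the N×N Pearson
correlation matrix (sample formula with n−1 normalisation) is thresholded
at T ∈ (0, 1) — an edge joins i and j iff `r_ij > T`, strictly, signed
(an `abs_corr` option gives the |r| variant). Channels with zero variance
are reported by name rather than silently yielding NaN.

Metrics on the binary graph:

* clustering coefficient `C_i = E_i / (D_i(D_i−1)/2)` (edges among
  neighbours over possible pairs), with `C_i = 0` for degree < 2 (the 0/0
  case), averaged over all nodes;
* characteristic path length L = mean BFS distance over *connected* ordered
  pairs (disconnected pairs excluded and counted separately);
* global efficiency G = mean of `1/d_ij` over all ordered pairs with
  `1/∞ = 0`, so G = 1 for a complete graph and 0 for an empty one.

These are validated against brute-force enumeration (exhaustively for all
graphs on ≤ 6 nodes, and on random graphs up to 10 nodes).

**Threshold selection.** Networks are formed at every grid threshold
(0.01 to 0.485 in steps of 0.025). At each T, stage 1 is compared with each
stage k = 2..7 by a two-tailed t-test on the per-subject metric values; a
grid point is *significant* when all six comparisons reach p < α = 0.05.
The longest contiguous significant run forms an interval, separately for C
and for G, and the selected T is the midpoint of the intersection of the
two intervals. (The published analysis this emulates reports the interval
0.26–0.435, whose midpoint is 0.3475.) The pipeline runs the sweep on the
normal-mode epochs — the condition with the largest stage contrast — and
applies the selected T to both conditions; a fixed T can be supplied
instead. An empty sweep result is flagged and falls back to the grid
median.

## Spectral fatigue index

`β/(θ+α)` band-power ratio, computed per channel from the WPD
reconstructions and averaged over a configurable subset (default {P3, P4},
the posterior sites where fatigue-related spectral change is most visible).
Fatigue raises θ/α and lowers β, so the index falls as fatigue deepens.
A zero denominator yields a flagged NaN, not an exception. A generic
band-combination utility covers the other ratios in the literature
(θ/β, (θ+α)/β, …) without separate validation.

## Eye-movement detection

Lateral gaze shifts appear as opposite-sign deflections on the symmetric
frontal pair F3/F4. On the *raw* (unfiltered, native-rate) pair, the
detector computes the window slope `K_i = (y(x_{i+20}) − y(x_i))/20`
(µV/sample, 20-sample window) for both channels, and the Pearson
correlation of the two segments over the same span. A window is a detection
when |K| > 2 on both channels (configurable to either-channel), the signs
oppose, and r < −0.85. Blinks deflect both channels with the *same* sign,
correlate positively, and are rejected by construction. Detections closer
than a 0.2 s refractory gap merge into one event; the fatigue measure is
events per minute (60 × count / duration). The |K| > 2 threshold is read in
µV per sample at the native rate; both thresholds are configurable.

## Group statistics

All comparisons are two-tailed Student t-tests at α = 0.05, default
independent pooled-variance design (mode comparisons use the 7 per-stage
means per condition, giving df = 7+7−2 = 12; paired and Welch designs are
config options). Critical values are the (1 − α/2) t quantiles. No
multiple-testing correction by default (a Bonferroni option exists). Stage
trends are summarised by per-stage means/SDs and the Spearman ρ of stage
vs mean; constant columns are flagged tie-degenerate. Response error rates
count timeouts as errors: (incorrect + timeout)/total per stage, NaN when
no responses were recorded. Degenerate t-test inputs (zero variance in both
samples) give t = 0, p = 1 for equal means and a flagged infinite-t result
otherwise.

## Synthetic-data generator

Each epoch is a sum of: (i) per-channel band-limited θ/α/β components
(4th-order zero-phase Butterworth-filtered white noise), with base
standard deviations 4/3/3 µV scaled by per-stage power multipliers;
(ii) a shared θ-band source mixed into every channel so the pairwise θ
correlation equals the scheduled coupling level c (channel θ =
√c·shared + √(1−c)·independent); (iii) 2 µV white sensor noise; and
(iv) ocular events on F3/F4 only — anti-correlated 80 µV deflections that
ramp up over 20 samples, hold 0.1 s, and return to baseline over 1 s (the
slow return stays below the detector's slope gate, so each gaze shift is
one event). Event *counts* per epoch are deterministic
(round(rate × minutes)); their timing and direction are random. A
common-mode blink option exists solely as a specificity fixture. Scores on
the 7-point subjective fatigue scale are drawn within ±1 of the scheduled
mean and clipped to 1..7; response errors (mrm only) are binomial draws
over 30 prompts per stage.

Randomness is keyed by (seed, subject, condition, stage), so identical
configs are bit-reproducible and subjects are independent.

**Default schedules.** The emulated study reports directions and
significance but no effect sizes, so the schedules are free parameters.
They were fixed once, by forward design: θ/α multipliers rise to 1.7/1.6
(normal) vs 1.2/1.15 (mrm), β falls to 0.5 vs 0.9; θ coupling rises
0.22→0.46 (normal) vs 0.22→0.30 (mrm) — the mapping from coupling to C/G
at T = 0.3475 is a steep sigmoid centred near c ≈ 0.32, so the normal
schedule traverses it while the mrm schedule climbs its lower slope; eye
rates fall 12→3 vs 11.5→9.5 per minute. These choices make every measure
drift in the fatigue direction in both modes, more slowly under mrm, with
the mode difference detectable by the df = 12 stage-mean t-test — the
regime the emulated study reports. The amplitude choices (band SDs of a
few µV, 80 µV ocular deflections) reflect that frontal ocular potentials
dominate background EEG in real recordings; they are what makes the
|K| > 2 gate meaningful.

**What the generator does not emulate:** volume conduction and reference
effects (channels share only the θ source), 1/f spectral background and δ
band content, EMG/blink artifacts beyond the specificity fixture,
non-stationarity within an epoch, and any physiological link between the
four measures beyond their common stage schedules. Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes, not that
real recordings contain that structure.

## Problem sizes and run times

The test suite and the acceptance script use a reduced study — 30 s epochs
at 128 Hz, 12 subjects × 2 conditions × 7 stages, 20 seeds for
simulation-level claims — which keeps a full run to a few minutes while
leaving every estimator comfortably above its noise floor (a 30 s θ-band
correlation has standard error ≈ 0.065, small against the scheduled
coupling range). Detector operating characteristics are measured at full
scale (3-minute epochs at 1000 Hz). The type-I-error calibration uses 2000
null replicates of the pooled t-test at n = 12 per group.

## Known limitations

* The significance sweep inherits the multiple-comparison optimism of its
  source design; it is a selection heuristic, not an inference procedure.
* The stage-mean mode comparison (df = 12) treats stage means as
  independent observations; a mixed-effects model would respect the
  repeated-measures structure but is out of scope.
* EDF output quantises to 16 bits over each channel's observed range;
  round-trips are exact only to that step. Epoch metadata travels in a
  JSON sidecar for both CSV and EDF.
* With the majority node rule, the [12, 16) node (half inside α, under
  half inside β) belongs to neither band; its content is simply not used.
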