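# Methods

This note documents the models, algorithms and numerical choices behind
`shuttlekit`, and what the synthetic benchmark does and does not establish
about recorded data.

## Task and data model

Signaled two-way active avoidance (2AA): a session is a sequence of trials,
each opened by an auditory warning signal (WS) lasting up to 15 s. If the
animal shuttles over the hurdle of a two-chamber box during the WS, the WS
terminates at the crossing and the footshock (US) is prevented — an
*avoidance* trial. Otherwise the US comes on at WS end and stays on until
the animal crosses — an *escape* trial (escape is obligatory; a US with no
subsequent crossing is treated as a data error). Trials are separated by a
30 s inter-trial interval (ITI). The session endpoint is the avoidance
rate, 100·n_avoid/n_trials; the subject-inclusion rule excludes animals
that never reach 30 % avoidance within the first five daily sessions.

Three data streams share a session clock after alignment: pose tracking of
the nose and body center (mm, fixed frame rate, default 30 Hz),
a typed event log (WS/US/OPTO intervals), and an optional two-channel
demodulated fiber-photometry trace (calcium-dependent signal channel plus
calcium-independent isosbestic control channel, default 100 Hz). Streams
carry independent start offsets; alignment shifts every timestamp by the
earliest instant covered by any stream, so relative intervals are
preserved exactly.

## Freeze detection

Freezing is detected from pose tracking alone, by a fixed rule sequence:

1. **Gap interpolation.** Runs of up to 10 consecutive missing frames are
   filled by per-coordinate linear interpolation between the flanking
   observed frames; longer runs, and runs touching a series boundary, stay
   missing. The operation is idempotent.
2. **Movement threshold.** Frame-by-frame Euclidean displacements of nose
   and body center are pooled, and the session threshold is their 40 %
   quantile (linear-interpolation convention at h = (n−1)q). One threshold
   per session.
3. **Coincident immobility.** A binary vector marks frames where *both*
   body parts moved ≤ the threshold (inclusive comparison).
4. **Changepoint segmentation** of that vector, minimum segment length 30
   video frames (kept in frames, not rescaled, when the frame rate is
   changed — the rule is defined on video frames).
5. **Bout extraction.** Candidate bouts are maximal runs of consecutive
   segments with mean immobility > 0.5. The 0.5 rule is this package's
   choice; the segmentation itself marks transitions into and out of
   coincident non-movement without a numeric criterion.
6. **Truncation.** If a bout contains a movement run strictly longer than
   5 consecutive frames, the bout ends at the first frame of the earliest
   such run.
7. **Duration filter.** Bouts lasting ≥ 1 s (inclusive) are freezing.
8. **Context.** A bout is WS freezing if its onset lies inside a WS
   interval, ITI freezing if its onset lies inside a trial's post-WS
   interval; straddling bouts follow their onset.

Detection runs once over the whole session rather than per trial window;
this is configurable but the default, since the threshold and the
segmentation are session-level statistics.

### Changepoint solver

Segmentation minimises a penalized Gaussian mean-shift cost
Σ_j Σ_{i∈seg j} (x_i − μ_j)²/σ² + m·β over segmentations with every
segment ≥ 30 frames, with a single session-level variance estimate σ²
(floored at 1e−8 so near-constant binary input stays defined). The
penalty is the MBIC magnitude for one mean parameter per extra segment,
β = 3·log n, applied as a constant per-changepoint penalty. Keeping β
constant (rather than adding per-segment log-length terms to the cost)
preserves cost subadditivity, which is what makes PELT pruning provably
exact; the package therefore ships two solvers of the *same* objective —
PELT, and the un-pruned O(n²) dynamic program — and property-tests their
equality. One subtlety: with a minimum segment length, a candidate last
changepoint shown dominated at time t is only provably dominated from
t + min_seg onward (the dominating configuration needs an admissible final
segment), so candidate removal is delayed by min_seg steps.

## Trial endpoints

* **Crossings** are detected on the body-center x trajectory with a ±10 mm
  hysteresis band around the hurdle: a crossing is the first sample on the
  far side after the animal has been beyond the band on the near side.
  The band prevents jitter double-counts over the 60 mm-wide hurdle; the
  body center (not the nose) defines the crossing, configurable.
* **Latency to avoid** = crossing − WS onset; **latency to escape** =
  crossing − US onset.
* **Shuttle initiate** backtracks from the crossing through consecutive
  body-center displacements above the session movement threshold (the
  freeze detector's threshold, for consistency); the run starts at the
  first frame after the last immobile frame.
* **Max velocity** is the argmax of the body-center speed inside the WS,
  after a centered 5-frame moving average; ties break to the earliest
  frame.

## Photometry

The isosbestic channel tracks bleaching and motion but not calcium. The
correction fits the signal channel on the isosbestic channel by ordinary
least squares over the whole session (fit direction is a package choice;
per-trial fitting is available via the API), producing a fitted control
F_fit = a·F_iso + b, and

    dF/F = (F_signal − F_fit) / F_fit,

with samples masked where F_fit ≤ 0. Event-locked analysis z-scores each
extracted trial window against its own pre-event samples; the wide WS
heatmap window is (−10, +30) s with the 10 s pre-WS segment as baseline.
Peri-event windows are ±2 s around WS onset and ±5 s around max-velocity,
shuttle-initiate, shuttle and WS-freezing onsets (symmetric windows are
the default reading; asymmetric windows can be passed explicitly).

Quantification integrates z in contiguous 1-s bins by the trapezoidal
rule. Adjacent bins share their edge sample so bin AUCs sum exactly to the
whole-window trapezoid; the final bin lacks its right-edge sample (its
support is 1 s minus one sample period). Epoch AUCs (pre / during / post a
light or WS interval) use the same quadrature over named, non-overlapping
epochs. Heatmap rows are ordered by ascending latency for avoidance trials
and by ascending WS-minus-baseline mean z (reduced → increased) for escape
trials.

## Statistics

Per-bin comparisons are trial-level tests: Welch two-sample t-tests
between trial types or light conditions, and paired t-tests of each bin
against its predecessor within a trial type. Each event type and
comparison class forms one family, corrected by the Benjamini–Krieger–
Yekutieli two-stage linear step-up procedure: stage 1 is a BH step-up at
α′ = α/(1+α) giving r1 rejections; stage 2 is a BH step-up at
α′·m/(m−r1), whose rejections are reported (all rejected if r1 = m). The
"first significant change" is the later bin of the earliest rejected
adjacent pair. Trial-level t-tests stand in deliberately for mixed-model
(REML) omnibus fits — variance components and omnibus F statistics are out
of scope; the correction procedure itself is implemented exactly and is
cross-checked against an independent implementation
(`statsmodels` `fdr_tsbky`) in the test suite.

A caution documented by the tests: the two-stage procedure is *not*
uniformly at least as powerful as plain BH at the same α. In knife-edge
cases (≈0.3 % of random p-vectors) BH at α rejects a p-value that stage 1
at the stricter α′ misses, leaving r1 = 0. The guaranteed facts are that
the rejection set is a down-set in sorted-p order and contains every
stage-1 rejection.

## Quantification utilities

PSC amplitudes are measured as the extremum of the chosen polarity within
20 ms after the stimulus, relative to the mean of the 5 ms pre-stimulus
baseline (both windows are package choices); the local baseline makes the
second pulse of a 50 ms paired-pulse protocol measurable on the first
pulse's decay. PPR = amp2/amp1 and is scale-invariant. The rabies
connectivity index is (region count / total labeled) / starter cells; layer
profiles normalize distance-binned counts within each projector type to
sum to 1.

## Synthetic sessions: what they emulate, and what they do not

The generator's defaults are the study conditions: 30 trials per session,
WS up to 15 s, ITI 30 s, 30 Hz video, 100 Hz photometry, a
360 × 180 mm box with the hurdle at 180 mm. Defaults chosen where the
task description is silent: avoidance probability 0.8 per trial
(well-trained animals avoid on most trials), avoidance latency
N(5.0, 1.5²) s clipped to [1.5, 14.5], escape latency N(0.8, 0.2²) s
(escapes typically within the first second of shock onset), freezing rate
6 bouts/min with durations N(3.0, 1.0²) s clipped to [1.2, 8] — about
30 % of session time immobile, so the 40 % displacement quantile falls
between freezing jitter and locomotor steps. Position dropouts occur at
1 gap/min, up to 6 frames, clear of shuttle runs.

Trajectories are piecewise behavioral states: freezing (per-coordinate
positional jitter SD 0.007 mm for both body parts), ambulation (a bounded
random walk, step length N(3, 1²) mm/frame clipped to [0.5, 7], heading
random walk, reflected inside the current chamber and clear of the hurdle
band), and shuttle runs (smooth accelerating profiles engineered so the
first sample past the hurdle is exactly the planned crossing frame). The
nose leads the body center by 25 mm along the heading with extra jitter.

Photometry: signal = F₀·bleach(t)·(1 + Σ transients) + artifact + noise;
isosbestic = 0.6·(F₀·bleach + artifact) + 0.2 + noise, carrying no
transients. Bleaching is a 30 % exponential decay with τ = 300 s; the
shared motion artifact is a smooth Gaussian process (SD 0.05 a.u.);
channel noise SD is 0.004 a.u. on a baseline of 2 a.u. Transients use a
difference-of-exponentials kernel (rise 0.2 s, decay 1.5 s, unit peak):
an outcome-dependent WS-onset response (5 % dF/F on avoidance trials, 2 %
on escapes), a pre-shuttle dip (−4 %, leading the movement onset by 1 s),
a sustained −50 % suppression during the optogenetic light (which spans
WS −5 s to WS offset +5 s when enabled) and a +40 % rebound transient
starting exactly at light offset.

What passing the benchmark shows: the detectors implement their rules
exactly and recover the generator's labels under realistic noise,
bleaching and shared artifacts. What it does not show: robustness to
tracking identity swaps, camera-perspective distortion, non-stationary
freezing postures, hemodynamic or pH confounds in the photometry, sensor
nonlinearity, or artifact components that do not enter both channels
through the assumed affine map. Real-data thresholds (notably the 40 %
quantile) should be inspected per session.

## Problem sizes and determinism

All randomness flows through one `numpy` Generator seeded from the session
config; identical configurations produce byte-identical session bundles
and analysis reports. The shipped benchmark (`scripts/acceptance.py`) uses
20 sessions of 30 trials for freeze-detection recovery and trial
classification, 200 random vectors (length ≤ 300) for solver equality,
20 ten-trial optogenetic sessions for the suppression/rebound ordering,
1000 random p-vectors plus a 1000-replicate label-permutation null for the
FDR procedure, and two full pipeline runs for byte-determinism; it
completes in well under a minute per component on one CPU.
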