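# Methods

## The generative model

The synthetic fish is a renewal point process modified by three stimulus
response mechanisms.  Baseline IPIs are drawn from a log-normal mixture

&nbsp;&nbsp;IPI ~ Σ_k w_k · LogNormal(log m_k, σ_k²),

rejected below the refractory floor.  Defaults: two components with
medians 140 and 300 ms, weights 0.65/0.35 and log-σ 0.25, reproducing the
bimodal resting distributions of *Gnathonemus petersii* with its dominant
~140 ms mode and secondary ~300 ms mode; refractory floor 8 ms, just
below the shortest IPIs the species produces (~8–10 ms).  A mixture
renewal process is the simplest generative structure consistent with a
bimodal stationary IPI histogram; real fish additionally show serial
correlation and slow behavioral drift, which this model deliberately
omits (see *Limitations*).

The closed-loop stimulation session is a discrete-event simulation.
Every fish pulse at time *t* schedules a stimulus at
*t* + latency + *d* (latency default 0.5 ms, standing in for real-time
detection lag; stimuli scheduled past the session end are dropped).  An
arriving stimulus is **perceived** only if at least `blind_ms` has passed
since the fish's last pulse — the post-discharge "blind period" during
which pulse-type fish cannot sense external stimuli.  A perceived
stimulus does two things:

1. **Echo response** — with probability `p_echo` the next pulse is
   advanced to stimulus time + 12 ms, provided that is earlier than the
   currently scheduled pulse and respects the refractory floor.  The echo
   *replaces* the scheduled pulse rather than inserting an extra one,
   preserving the renewal structure (the species fires a *single* pulse
   ~12 ms after an external pulse).
2. **Delay-dependent rescaling** — the next baseline IPI draw is
   multiplied by `effect_scale(d)`: a step function equal to
   `scale_short` (default 0.5) for *d* below the critical delay
   D_c = 100 ms and `scale_long` (default 1.0) at or above it.  The
   boundary delay takes the long side, consistent with 102 ms experiments
   behaving like long delays.  A logistic option
   (`response_smoothness_ms > 0`) replaces the step when a graded
   response is wanted; the default stays a step because the empirical
   phenomenon is two clusters, not a gradient.

Parameters without an empirical value anywhere were fixed once:
`blind_ms = 4 ms` (above the ~1 ms pulse width, below the shortest
scheduled delay plus latency, so every protocol delay of 5 ms and up is
perceivable) and `p_echo = 0.35` (echo responses are probabilistic and
context-dependent in this genus; 0.35 yields a visible ~12 ms latency
mode without locking the fish into echo chains).  Control and
stimulation sessions use independent child streams of one root seed, so
artifact-removal errors can never couple the two sessions and every
`SessionPair` is bit-reproducible from its seed.

The canonical delay schedule is the study's enumerated per-fish
assignment: five fish, 16 distinct delays from 5 to 282 ms, the 102 ms
delay repeated across four fish — 19 experiments in total.  Analyses
here default to 5-minute sessions (the package's own desk-scale choice;
~1500 control pulses per session gives stable quantile estimates) with
the experimental 30-minute length available by configuration.

## Raw-signal synthesis and detection

The measurement model mimics a multi-dipole tank: each pulse is placed on
each of 5 channels with an independent uniform amplitude in [0.3, 1.0] ×
peak (fish position varying relative to the dipoles), white Gaussian
noise (sd 0.02) is added per channel, channels are squared and summed,
giving the single nonnegative 25 kHz signal the experimental rig stores.
The ~1 ms template is an asymmetric biphasic pulse with a dominant
positive phase, so the squared signal has one unambiguous peak per pulse
and detection timestamps are stable to one sample (0.04 ms).

Detection thresholds at median + k·MAD of the whole signal.  The noise
floor of a squared sum of C Gaussian channels is chi-square(C)-shaped,
whose upper tail on the MAD scale is heavy: ~1e-3 of samples exceed
8 MADs *regardless of the noise amplitude*, so a spike-sorting-style
k ≈ 5–8 would produce thousands of false events on a megasample
recording.  The default is k = 25 (tail probability ~3 × 10⁻¹⁰ per
sample, i.e. zero expected false crossings per session) — pulse peaks sit
3–4 orders of magnitude above the floor, so sensitivity is unaffected.
Each contiguous above-threshold excursion yields one detection at its
maximum; a 5 ms refractory window (above the pulse width, below the
shortest IPIs) suppresses double counts.

Stimulus-artifact removal replays the experimental "both files" rule:
every detection within ±1.5 ms (configurable; the original
synchronization tolerance is unstated) of a logged stimulus time is
removed, each stimulus removing at most the nearest one detection.  A
fish pulse genuinely coincident with a stimulus is unavoidably discarded
— the same blind spot as the original procedure.  On simulations this
loss is negligible (< 0.1%) at short delays, where the IPI density near
*d* is essentially zero, but grows to a few percent when *d* falls inside
the bulk of the (possibly rescaled) IPI distribution (e.g. 60–70 ms at
scale 0.5, or 100–200 ms unscaled), because the renewal draw then lands
within the detector's dead time after a stimulus at a rate of order
density × 5 ms.  The detection validation therefore uses the five
shortest scheduled delays, where ground truth and detections are
cleanly matchable; the coincidence loss at bulk delays is a quantified,
documented limitation of the removal rule itself, not of the detector.

## Distribution statistics

Quantiles use linear interpolation of the order statistics
(h = (n−1)p + 1).  qq curves pair the two samples at plotting positions
(i − ½)/m with m = min(n_X, n_Y) — the conventional treatment when the
two sessions produced different pulse counts; for equal counts this is
sorted-vs-sorted up to the interpolation rule.  The area under the curve
is the trapezoidal integral of Q_Y against Q_X (ms²).  Raw areas depend
on each fish's IPI range, so a normalized variant divides by the
reference-line area (x_max² − x_min²)/2 over the same support;
1 = no change.  Histograms use 20 ms bins on [0, 500) ms (the granularity
at which published IPI histograms are readable; configurable), with
overflow pooled into the last bin; Pearson correlation compares two
histograms on identical edges and is declared undefined (an error, not a
NaN) for zero-variance inputs.  KS is computed on the raw samples, not
the binned ones; the exact (permutation-equivalent) null distribution is
used up to max(n, m) = 100 and the asymptotic Kolmogorov distribution
with effective n = n_X n_Y/(n_X + n_Y) above.  IPIs never span a session
boundary.

## Delay clustering and Tukey profiles

Each usable experiment contributes (delay, qq-area).  Delay (ms) and
area (ms²) are incommensurate, so both axes are z-scored before Lloyd's
K-means (k = 2, best of 32 restarts).  Cluster A is canonically the
lower-mean-delay cluster.  The silhouette coefficient is computed in the
same standardized space, with singleton clusters and degenerate 0/0
points scoring 0.  The critical delay is reported two ways — the midpoint
of the gap between A's largest and B's smallest delay (principled on a
sparse grid), and A's largest delay (the headline convention) — to avoid
over-reading a grid with a 30 ms hole around the true boundary.

Outlier handling is manual: an experiment flagged `excluded` (the kind of
animal-health judgment no algorithm should replicate) stays in the
summary table and is reported with the cluster result, but takes no part
in clustering or profiles.

Per-cluster Tukey profiles pool all member experiments' quantile pairs,
bin them in 3 ms steps of the pair mean, and report the pooled per-bin
mean difference.  The error bars are the across-experiment mean of the
per-experiment within-bin standard deviations (experiments with < 2
pairs in a bin contribute no SD); a pooled-SD alternative and
equal-experiment (instead of equal-pair) weighting are available by
argument.  Empty bins carry n_pairs = 0 and NaN values rather than being
dropped, keeping the 3 ms grid contiguous.

## What the synthetic tests do and do not show

Passing the recovery tests shows the chain is *internally correct*: the
statistics match independent oracles, the detector recovers what the
synthesizer placed, and the clustering finds a two-scale structure that
is genuinely present in the generator.  It does not show that real fish
have a step response at 100 ms — the generator *assumes* that structure.
The null-calibration runs guard the converse error: with no simulated
effect the normalized area stays at 1 within sampling error and KS
rejects at its nominal rate, so the pipeline does not manufacture a
critical delay from noise.

Problem sizes in the shipped tests and the acceptance script — 5-minute
sessions, 19 experiments × 20 seeds, ten synthesized recordings, 40 null
seeds — are the package's own desk-scale defaults; all lengths and
counts are parameters.

## Known limitations

* The renewal assumption ignores serial IPI correlation, novelty-response
  transients and day/night behavioral states; whole-session distributions
  are the only analysis target, matching the analysis chain's scope.
* The step delay-response is a caricature; the logistic option exists but
  no data here constrains its smoothness.
* Coincident fish/stimulus pulses are lost by construction of the removal
  rule (quantified above).
* The amplitude model (uniform per-pulse gains) stands in for fish
  motion; it produces realistic SNR variation but no spatial
  information, and the detector makes no use of multi-channel structure.
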