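# eodloop

Closed-loop electric-fish stimulation simulator and inter-pulse-interval
(IPI) distribution analysis.

Pulse-type weakly electric fish such as *Gnathonemus petersii* emit
stereotyped ~1 ms electric organ discharges (EODs); the intervals between
them (IPIs, roughly 10–400 ms) carry behavioral information.  In an
activity-dependent (closed-loop) experiment every detected EOD triggers a
stimulus pulse delivered after a fixed delay *d*, and the question is how
the fish's IPI distribution in the stimulation session differs from its
spontaneous (control) session as a function of *d*.  `eodloop` is aimed at
researchers running or re-analyzing such experiments: it provides a fully
synthetic but mechanistically explicit stand-in for the animal plus the
complete analysis chain, so the whole pipeline is testable without
recordings.

## What it computes

For control IPIs X and stimulation IPIs Y the package builds the qq curve
(Q_X(p_i), Q_Y(p_i)) at plotting positions p_i = (i − ½)/m,
m = min(n_X, n_Y), and summarizes each experiment by the area under it,

&nbsp;&nbsp;A = ∫ Q_Y d Q_X &nbsp;(trapezoidal, ms²),

optionally normalized by the reference-line area (x_max² − x_min²)/2 so
that 1 means "no change" and values < 1 mean shortened IPIs.  Per-point
Tukey mean-differences ((x+y)/2, y − x), binned in 3 ms steps of the pair
mean, give the IPI-change profile; two-sample KS tests (raw samples) and
Pearson correlations (binned histograms) complete the per-experiment
summary.  Across a batch, K-means with k = 2 on the standardized
(delay, area) points separates strongly from weakly affected experiments,
the silhouette coefficient scores the split, and the gap between the two
delay groups locates the **critical delay**.

The built-in generator is a renewal process with a log-normal mixture of
baseline IPIs (bimodal, medians 140/300 ms), a post-discharge blind
period, a probabilistic ~12 ms echo response to perceived stimuli, and a
step delay-response (IPIs rescaled by 0.5 below the 100 ms critical delay,
unchanged above).  A 25 kHz "squared-sum" tank recording can be
synthesized per session so the robust-threshold pulse detector and the
stimulus-artifact removal stage can be validated against ground truth.

## Worked example

```python
import eodloop as el

pairs = el.simulate_batch(minutes=5.0, seed=1)   # 19-experiment schedule
result = el.analyze_batch(pairs)
for key, val in result.report.items():
    print(f"{key:28s} {val}")
```

prints (seed 1, 5-minute sessions):

```
boundary_delay_ms            85.0
cluster_a_max_delay_ms       70.0
cluster_b_min_delay_ms       100.0
cluster_a_size               10
cluster_b_size               9
silhouette_mean              0.656...
cluster_a_mean_area_norm     0.488...
cluster_b_mean_area_norm     0.882...
```

Cluster A (delays 5–70 ms) has normalized qq areas near 0.5 — the
generator's short-delay IPI scale factor — and cluster B (100–282 ms)
sits near 1; the clustering recovers the simulated 100 ms critical delay
as a boundary inside the (70, 100) ms gap.  The per-cluster Tukey
profiles give overall mean IPI changes of −118.5 ms (A) versus
−37.1 ms (B): short-delay stimulation shortens IPIs strongly, long-delay
stimulation only mildly (mostly via the echo response).

The `examples/` scripts walk each capability (single experiment and echo
response, detection round trip, distribution comparison, critical-delay
study), and a thin CLI wraps the pipeline:

```sh
eodloop simulate --out bundle --seed 3 --sessions-min 5
eodloop analyze --bundle bundle --out analysis --plots
eodloop report --analysis-dir analysis
```

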