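"""Synthetic pulse-fish generator and closed-loop stimulation protocol.

The generator is a renewal point process whose baseline inter-pulse
intervals (IPIs) come from a log-normal mixture, which reproduces the
bimodal ~10-400 ms IPI distributions of resting *Gnathonemus petersii*
(modes near 140 and 300 ms).  On top of the renewal process it models the
three response mechanisms relevant to closed-loop stimulation:

* a **blind period** after each discharge during which an arriving stimulus
  is not perceived;
* a probabilistic **echo response** — a perceived stimulus can advance the
  next pulse to fire ~12 ms after the stimulus;
* a delay-dependent **IPI rescaling**: a perceived stimulus multiplies the
  next IPI draw by ``scale_short`` when the protocol delay is below the
  critical delay D_c and by ``scale_long`` otherwise.

The closed-loop protocol mirrors the experimental one: every fish pulse
triggers a stimulus pulse delivered after ``detect_latency_ms + delay_ms``;
a spontaneous control session is simulated with an independent random
stream.  Optionally the raw 25 kHz squared-sum tank recording can be
synthesized so the detection stage is testable end to end.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .core import PulseTrain, SessionPair

__all__ = [
    "FishParams",
    "ProtocolConfig",
    "EodWaveform",
    "RawRecording",
    "default_eod_waveform",
    "sample_baseline_ipi",
    "effect_scale",
    "simulate_control",
    "simulate_closed_loop",
    "synthesize_recording",
    "squared_sum_signal",
]

_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class FishParams:
    """Generative parameters of one synthetic fish.

    Defaults describe a resting adult: bimodal baseline IPIs (median
    140 ms / 300 ms mixture, log-sigma 0.25, weights 0.65 / 0.35), an 8 ms
    refractory floor, a 4 ms blind period, a 12 ms echo latency fired with
    probability ``p_echo``, and a step delay-response that halves IPIs for
    stimulation delays below the 100 ms critical delay.
    ``response_smoothness_ms = 0`` keeps the step; a positive value blends
    the two scales logistically around D_c.
    """

    mix_weights: tuple[float, ...] = (0.65, 0.35)
    mix_medians_ms: tuple[float, ...] = (140.0, 300.0)
    mix_shapes: tuple[float, ...] = (0.25, 0.25)
    refractory_ms: float = 8.0
    blind_ms: float = 4.0
    p_echo: float = 0.35
    echo_latency_ms: float = 12.0
    critical_delay_ms: float = 100.0
    scale_short: float = 0.5
    scale_long: float = 1.0
    response_smoothness_ms: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.mix_weights, float)
        m = np.asarray(self.mix_medians_ms, float)
        s = np.asarray(self.mix_shapes, float)
        if not (w.size == m.size == s.size) or w.size == 0:
            raise ValueError("mixture arrays must share a common nonzero length")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mix_weights must be nonnegative and sum to 1")
        if np.any(m <= 0) or np.any(s < 0):
            raise ValueError("medians must be positive, shapes nonnegative")
        if not (0 < self.refractory_ms <= m.min()):
            raise ValueError("0 < refractory_ms <= min(mix_medians_ms) required")
        if not (0 <= self.p_echo <= 1):
            raise ValueError("p_echo must be in [0, 1]")
        if self.echo_latency_ms <= 0 or self.blind_ms < 0:
            raise ValueError("echo_latency_ms > 0 and blind_ms >= 0 required")
        if self.scale_short <= 0 or self.scale_long <= 0:
            raise ValueError("IPI scale factors must be positive")
        if self.critical_delay_ms <= 0 or self.response_smoothness_ms < 0:
            raise ValueError("critical_delay_ms > 0 and smoothness >= 0 required")


@dataclass(frozen=True)
class ProtocolConfig:
    """Closed-loop protocol: stimulus delay, session lengths and seed.

    ``detect_latency_ms`` is the simulated real-time detection lag between a
    fish pulse and the start of the programmed delay.  Session lengths
    default to the experimental 30 min.
    """

    delay_ms: float
    control_min: float = 30.0
    stim_min: float = 30.0
    detect_latency_ms: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delay_ms < 0:
            raise ValueError("delay_ms must be nonnegative")
        if self.control_min <= 0 or self.stim_min <= 0:
            raise ValueError("session lengths must be positive")
        if self.detect_latency_ms < 0:
            raise ValueError("detect_latency_ms must be nonnegative")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_baseline_ipi(params: FishParams, rng) -> float:
    """Draw one spontaneous IPI from the log-normal mixture (ms).

    Draws are rejected until the IPI respects the refractory floor; after
    1000 rejections the parameters are considered degenerate.
    """
    rng = _as_rng(rng)
    w = np.asarray(params.mix_weights, float)
    for _ in range(_MAX_REJECTIONS):
        k = rng.choice(w.size, p=w)
        ipi = params.mix_medians_ms[k] * np.exp(params.mix_shapes[k] * rng.standard_normal())
        if ipi >= params.refractory_ms:
            return float(ipi)
    raise RuntimeError("rejection sampling failed: refractory_ms excludes nearly all mass")


def _sample_baseline_batch(params: FishParams, rng: np.random.Generator, n: int) -> np.ndarray:
    """Vectorized equivalent of repeated :func:`sample_baseline_ipi` draws."""
    w = np.asarray(params.mix_weights, float)
    med = np.asarray(params.mix_medians_ms, float)
    sig = np.asarray(params.mix_shapes, float)
    out = np.empty(n)
    need = np.arange(n)
    for _ in range(_MAX_REJECTIONS):
        k = rng.choice(w.size, size=need.size, p=w)
        draw = med[k] * np.exp(sig[k] * rng.standard_normal(need.size))
        ok = draw >= params.refractory_ms
        out[need[ok]] = draw[ok]
        need = need[~ok]
        if need.size == 0:
            return out
    raise RuntimeError("rejection sampling failed: refractory_ms excludes nearly all mass")


def effect_scale(delay_ms: float, params: FishParams) -> float:
    """Multiplicative IPI scale applied after a perceived stimulus.

    A step at the critical delay by default (the boundary delay itself takes
    the long-side scale); with ``response_smoothness_ms > 0`` the step is
    replaced by a logistic blend of the two scales.
    """
    if delay_ms < 0:
        raise ValueError("delay_ms must be nonnegative")
    s = params.response_smoothness_ms
    if s == 0:
        return params.scale_short if delay_ms < params.critical_delay_ms else params.scale_long
    z = (delay_ms - params.critical_delay_ms) / s
    frac = 1.0 / (1.0 + np.exp(-z))  # 0 well below D_c, 1 well above
    return float(params.scale_short + (params.scale_long - params.scale_short) * frac)


def simulate_control(params: FishParams, minutes: float, seed) -> PulseTrain:
    """Simulate a spontaneous (no stimulation) session as a renewal process."""
    if minutes <= 0:
        raise ValueError("minutes must be positive")
    rng = _as_rng(seed)
    duration = minutes * 60_000.0
    mean_ipi = float(np.dot(params.mix_weights,
                            np.asarray(params.mix_medians_ms)
                            * np.exp(0.5 * np.asarray(params.mix_shapes) ** 2)))
    times: list[np.ndarray] = []
    t = 0.0
    while t <= duration:
        n = max(32, int(1.2 * (duration - t) / mean_ipi) + 16)
        chunk = t + np.cumsum(_sample_baseline_batch(params, rng, n))
        times.append(chunk)
        t = chunk[-1]
    all_t = np.concatenate(times)
    return PulseTrain(all_t[all_t <= duration], duration_ms=duration, source="fish")


def simulate_closed_loop(params: FishParams, protocol: ProtocolConfig,
                         fish_id: str = "sim") -> SessionPair:
    """Run the full two-session closed-loop experiment.

    The stimulation session is a discrete-event loop: each fish pulse at
    ``t`` schedules a stimulus at ``t + detect_latency_ms + delay_ms``
    (dropped past the session end).  A stimulus is perceived iff it arrives
    at least ``blind_ms`` after the last fish pulse.  A perceived stimulus
    (i) with probability ``p_echo`` advances the next pulse to
    ``t_s + echo_latency_ms`` when that is earlier than the scheduled pulse
    and respects the refractory floor, and (ii) multiplies the next IPI draw
    by :func:`effect_scale`.  The control session uses an independent child
    stream of the same root seed, so the two sessions never share draws.
    """
    ss = np.random.SeedSequence(protocol.seed)
    ctrl_ss, stim_ss = ss.spawn(2)
    control = simulate_control(params, protocol.control_min, np.random.default_rng(ctrl_ss))

    rng = np.random.default_rng(stim_ss)
    duration = protocol.stim_min * 60_000.0
    offset = protocol.detect_latency_ms + protocol.delay_ms
    scale = effect_scale(protocol.delay_ms, params)

    fish: list[float] = []
    stim_log: list[float] = []
    pending: deque[float] = deque()  # scheduled stimuli, FIFO == time order
    last: float | None = None
    pending_scale = 1.0
    t_next = sample_baseline_ipi(params, rng)

    while True:
        t_stim = pending[0] if pending else np.inf
        if t_next <= t_stim:  # fish pulse first; ties resolved to the fish
            if t_next > duration:
                break
            fish.append(t_next)
            last = t_next
            if t_next + offset <= duration:
                pending.append(t_next + offset)
            ipi = sample_baseline_ipi(params, rng) * pending_scale
            pending_scale = 1.0
            t_next = t_next + max(ipi, params.refractory_ms)
        else:
            t_s = pending.popleft()
            stim_log.append(t_s)
            perceived = last is None or (t_s - last) >= params.blind_ms
            if perceived:
                pending_scale = scale
                if params.p_echo > 0 and rng.random() < params.p_echo:
                    t_echo = t_s + params.echo_latency_ms
                    if t_echo < t_next and (last is None
                                            or t_echo - last >= params.refractory_ms):
                        t_next = t_echo
    # stimuli scheduled before the last pulse but delivered after it
    stim_log.extend(pending)

    return SessionPair(
        fish_id=fish_id,
        delay_ms=protocol.delay_ms,
        control=control,
        stim_fish=PulseTrain(np.asarray(fish), duration_ms=duration, source="fish"),
        stimulus_log=PulseTrain(np.asarray(stim_log), duration_ms=duration,
                                source="stimulus"),
        seed=protocol.seed,
        meta={"detect_latency_ms": protocol.detect_latency_ms,
              "control_min": protocol.control_min, "stim_min": protocol.stim_min},
    )


# ---------------------------------------------------------------------------
# raw squared-sum recording synthesis

@dataclass(frozen=True)
class EodWaveform:
    """Amplitude template of one ~1 ms EOD pulse, peak-normalized."""

    samples: np.ndarray
    fs_hz: float = 25_000.0
    peak_amplitude: float = 1.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 1 or s.size == 0 or not np.all(np.isfinite(s)):
            raise ValueError("waveform samples must be a finite 1-D array")
        if self.fs_hz <= 0 or self.peak_amplitude <= 0:
            raise ValueError("fs_hz and peak_amplitude must be positive")

    @property
    def peak_index(self) -> int:
        """Sample index of the dominant (absolute) peak; pulses are placed so
        this sample lands at the nominal pulse time."""
        return int(np.argmax(np.abs(self.samples)))

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.fs_hz


def default_eod_waveform(fs_hz: float = 25_000.0) -> EodWaveform:
    """Asymmetric biphasic ~1 ms template: a dominant head-positive phase
    followed by a smaller negative phase, peak-normalized to 1."""
    n = max(int(round(fs_hz / 1000.0)), 5)  # ~1 ms support
    t = (np.arange(n) + 0.5) / n  # in pulse-lengths
    w = np.exp(-((t - 0.42) / 0.12) ** 2) - 0.45 * np.exp(-((t - 0.72) / 0.14) ** 2)
    w /= np.max(np.abs(w))
    return EodWaveform(samples=w, fs_hz=fs_hz, peak_amplitude=1.0)


@dataclass(frozen=True)
class RawRecording:
    """Single-channel squared-sum tank signal, sampled at ``fs_hz``."""

    samples: np.ndarray
    fs_hz: float = 25_000.0
    duration_ms: float = 0.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        dur = self.duration_ms or 1000.0 * s.size / self.fs_hz
        object.__setattr__(self, "duration_ms", float(dur))
        if np.any(s < 0):
            raise ValueError("squared-sum samples must be nonnegative")


def squared_sum_signal(times_ms: np.ndarray, amplitudes: np.ndarray,
                       waveform: EodWaveform, n_samples: int,
                       noise: np.ndarray | None = None,
                       noise_sd: float = 0.0,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Core synthesis: per-channel superposition, then square and sum.

    ``amplitudes`` has shape (n_pulses, n_channels): one gain per pulse per
    dipole channel (fish position relative to each dipole).  ``noise`` may
    supply explicit per-channel noise of shape (n_channels, n_samples);
    otherwise white noise with sd ``noise_sd`` is drawn from ``rng`` one
    channel at a time.  Overlapping pulses add before squaring.
    """
    times_ms = np.asarray(times_ms, float)
    amplitudes = np.atleast_2d(np.asarray(amplitudes, float))
    if times_ms.size != amplitudes.shape[0]:
        raise ValueError("amplitudes must have one row per pulse")
    n_channels = amplitudes.shape[1]
    wf = waveform.samples
    starts = np.round(times_ms * waveform.fs_hz / 1000.0).astype(int) - waveform.peak_index
    out = np.zeros(n_samples)
    for c in range(n_channels):
        if noise is not None:
            ch = noise[c].astype(float).copy()
        elif noise_sd > 0:
            if rng is None:
                raise ValueError("rng required when noise_sd > 0 and no explicit noise")
            ch = rng.normal(0.0, noise_sd, n_samples)
        else:
            ch = np.zeros(n_samples)
        for i, s in enumerate(starts):
            lo, hi = max(s, 0), min(s + wf.size, n_samples)
            if lo < hi:
                ch[lo:hi] += amplitudes[i, c] * wf[lo - s:hi - s]
        out += ch * ch
    return out


def synthesize_recording(fish: PulseTrain, stimuli: PulseTrain | None = None,
                         waveform: EodWaveform | None = None,
                         noise_sd: float = 0.02, fs_hz: float | None = None,
                         n_channels: int = 5,
                         amp_range: tuple[float, float] = (0.3, 1.0),
                         seed=0) -> RawRecording:
    """Synthesize the squared-sum tank recording for a session.

    Each fish and stimulus pulse is placed at its event time with an
    independent per-channel amplitude drawn uniformly from ``amp_range``
    times the waveform peak (standing in for fish movement across the five
    dipoles); zero-mean white noise is added per channel before squaring, so
    the output carries a positive chi-square noise floor.
    """
    waveform = waveform or default_eod_waveform(fs_hz or 25_000.0)
    if fs_hz is not None and abs(fs_hz - waveform.fs_hz) > 1e-9:
        raise ValueError("fs_hz inconsistent with waveform sampling rate")
    rng = _as_rng(seed)
    times = fish.times_ms
    duration = fish.duration_ms
    if stimuli is not None:
        times = np.sort(np.concatenate([times, stimuli.times_ms]))
        duration = max(duration, stimuli.duration_ms)
    n_samples = int(round(duration / 1000.0 * waveform.fs_hz))
    amps = rng.uniform(amp_range[0], amp_range[1], size=(times.size, n_channels))
    amps *= waveform.peak_amplitude
    sig = squared_sum_signal(times, amps, waveform, n_samples,
                             noise_sd=noise_sd, rng=rng)
    return RawRecording(samples=sig, fs_hz=waveform.fs_hz, duration_ms=duration)
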