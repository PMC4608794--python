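"""Distribution-comparison statistics for IPI samples.

The per-experiment question is whether the stimulation-session IPI
distribution (Y) differs from the control-session one (X).  The toolkit:

* quantile-quantile (qq) curves of X vs Y against the y = x reference,
* the area under the qq curve — the per-experiment effect scalar (shorter
  stimulation IPIs pull the curve below y = x and shrink the area),
* Tukey mean-difference pairs ((x+y)/2, y-x) derived from the qq curve,
* probability-normalized IPI histograms and their Pearson correlation,
* the two-sample Kolmogorov-Smirnov test on the raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "IPISample", "QQCurve", "Histogram", "TukeyPairs",
    "empirical_quantile", "qq_curve", "qq_area", "qq_area_norm",
    "tukey_pairs", "ipi_histogram", "hist_pearson", "ks_two_sample",
]


@dataclass(frozen=True)
class IPISample:
    """Positive intervals from one session; order is irrelevant."""

    values_ms: np.ndarray
    label: str = "control"

    def __post_init__(self) -> None:
        v = np.asarray(self.values_ms, float)
        object.__setattr__(self, "values_ms", v)
        if v.ndim != 1:
            raise ValueError("values_ms must be 1-D")
        if v.size and (not np.all(np.isfinite(v)) or np.any(v <= 0)):
            raise ValueError("IPIs must be finite and positive")

    def __len__(self) -> int:
        return int(self.values_ms.size)


@dataclass(frozen=True)
class QQCurve:
    """Paired empirical quantiles of control (x) vs stimulation (y) IPIs."""

    x_ms: np.ndarray
    y_ms: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        x, y, p = (np.asarray(a, float) for a in (self.x_ms, self.y_ms, self.probs))
        object.__setattr__(self, "x_ms", x)
        object.__setattr__(self, "y_ms", y)
        object.__setattr__(self, "probs", p)
        if not (x.size == y.size == p.size) or x.size < 2:
            raise ValueError("qq curve needs >= 2 points of equal length")
        if np.any(np.diff(x) < 0) or np.any(np.diff(y) < 0):
            raise ValueError("quantiles must be nondecreasing")
        if np.any(p <= 0) or np.any(p >= 1) or np.any(np.diff(p) <= 0):
            raise ValueError("probs must be strictly increasing in (0, 1)")


@dataclass(frozen=True)
class Histogram:
    """Probability-normalized histogram on strictly increasing edges."""

    edges_ms: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges_ms, float)
        p = np.asarray(self.probs, float)
        object.__setattr__(self, "edges_ms", e)
        object.__setattr__(self, "probs", p)
        if e.size != p.size + 1 or np.any(np.diff(e) <= 0):
            raise ValueError("need strictly increasing edges, len(edges) = len(probs)+1")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be nonnegative and sum to 1")


@dataclass(frozen=True)
class TukeyPairs:
    """Per-quantile-pair mean (x+y)/2 and difference y-x, in ms."""

    mean_ms: np.ndarray
    diff_ms: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_ms, float)
        d = np.asarray(self.diff_ms, float)
        object.__setattr__(self, "mean_ms", m)
        object.__setattr__(self, "diff_ms", d)
        if m.size != d.size:
            raise ValueError("mean_ms and diff_ms must have equal length")


def _values(sample) -> np.ndarray:
    v = sample.values_ms if isinstance(sample, IPISample) else np.asarray(sample, float)
    if v.size == 0:
        raise ValueError("empty sample")
    return v


def empirical_quantile(sample, p) -> float | np.ndarray:
    """Linear-interpolation empirical quantile of the order statistics.

    With sorted values v_1..v_n and h = (n-1)p + 1 this returns
    v_floor(h) + (h - floor(h)) (v_floor(h)+1 - v_floor(h)) — numpy's
    ``linear`` rule.  Accepts scalar or vector p in (0, 1).
    """
    v = _values(sample)
    p_arr = np.asarray(p, float)
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise ValueError("p must lie strictly inside (0, 1)")
    q = np.quantile(v, p_arr, method="linear")
    return float(q) if np.isscalar(p) else q


def qq_curve(control, stim) -> QQCurve:
    """Pair the two samples quantile-by-quantile.

    With m = min(n_x, n_y) plotting positions p_i = (i - 0.5)/m, the curve
    is (Q_x(p_i), Q_y(p_i)).  For equal sample sizes this reduces to
    sorted-vs-sorted (up to the interpolation rule at the extremes), the
    classical treatment when one session produced more pulses than the
    other.
    """
    xv, yv = _values(control), _values(stim)
    m = min(xv.size, yv.size)
    if m < 2:
        raise ValueError("need at least 2 intervals per sample")
    probs = (np.arange(1, m + 1) - 0.5) / m
    return QQCurve(x_ms=np.quantile(xv, probs, method="linear"),
                   y_ms=np.quantile(yv, probs, method="linear"),
                   probs=probs)


def qq_area(qq: QQCurve) -> float:
    """Trapezoidal area under the qq curve (ms^2): sum of
    (x_{i+1}-x_i)(y_i+y_{i+1})/2.  Zero-width segments contribute zero."""
    return float(np.trapezoid(qq.y_ms, qq.x_ms))


def qq_area_norm(qq: QQCurve) -> float:
    """Area divided by the reference-line (y = x) area over the same
    x-range, i.e. (x_max^2 - x_min^2)/2.  Dimensionless; 1 means no change,
    < 1 means stimulation IPIs ran shorter than control."""
    ref = (qq.x_ms[-1] ** 2 - qq.x_ms[0] ** 2) / 2.0
    if ref <= 0:
        raise ValueError("degenerate x-range: reference area is zero")
    return qq_area(qq) / ref


def tukey_pairs(qq: QQCurve) -> TukeyPairs:
    """Tukey mean-difference pairs from a qq curve, order preserved."""
    return TukeyPairs(mean_ms=(qq.x_ms + qq.y_ms) / 2.0, diff_ms=qq.y_ms - qq.x_ms)


def ipi_histogram(sample, bin_ms: float = 20.0, max_ms: float = 500.0) -> Histogram:
    """Probability histogram on half-open bins [0, max_ms); values at or
    beyond ``max_ms`` pool into the final bin."""
    if bin_ms <= 0 or max_ms <= bin_ms:
        raise ValueError("need 0 < bin_ms < max_ms")
    v = _values(sample)
    edges = np.arange(0.0, max_ms + bin_ms / 2, bin_ms)
    if edges[-1] < max_ms:  # max_ms not a multiple of bin_ms: extend
        edges = np.append(edges, max_ms)
    clipped = np.minimum(v, np.nextafter(max_ms, 0.0))
    counts, _ = np.histogram(clipped, bins=edges)
    return Histogram(edges_ms=edges, probs=counts / v.size)


def hist_pearson(h1: Histogram, h2: Histogram) -> float:
    """Pearson correlation of two probability vectors on identical edges."""
    if h1.edges_ms.size != h2.edges_ms.size or not np.allclose(h1.edges_ms, h2.edges_ms):
        raise ValueError("histograms must share identical edges")
    if np.ptp(h1.probs) == 0 or np.ptp(h2.probs) == 0:
        raise ValueError("Pearson correlation undefined for a zero-variance histogram")
    return float(sps.pearsonr(h1.probs, h2.probs).statistic)


def ks_two_sample(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on raw IPI samples.

    D is the sup-distance between the two empirical CDFs.  ``method="auto"``
    uses the exact null distribution (equivalent to full permutation for
    continuous data) when max(n, m) <= 100 and the asymptotic Kolmogorov
    distribution with effective n = n_x n_y/(n_x + n_y) otherwise; "exact"
    and "asymp" force either choice.
    """
    xv, yv = _values(x), _values(y)
    if method == "auto":
        method = "exact" if max(xv.size, yv.size) <= 100 else "asymp"
    res = sps.ks_2samp(xv, yv, method=method)
    return float(res.statistic), float(res.pvalue)
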