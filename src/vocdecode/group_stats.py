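"""Delay-window averaging, group tests, FDR correction and plot smoothing.

Statistical windows exclude the first 250 ms after each cue (the period a
cue-driven visual confound would affect): delay 1 runs from 250 ms after the
first cue's offset to the second cue's onset, delay 2 from 250 ms after the
second cue's offset to the go cue. On the canonical timeline that is
[350, 2100] and [2450, 4200] ms. Cross-time window averages exclude the
diagonal band |t_train - t_test| <= 100 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .cvmanova import InformationResult
from .task_design import CUE1_OFFSET_MS, CUE2_OFFSET_MS, CUE2_ONSET_MS, GO_ONSET_MS

CUE_EXCLUSION_MS = 250.0


@dataclass(frozen=True)
class DelayWindows:
    """The two statistical delay windows (ms relative to first-cue onset)."""

    delay1: tuple = (CUE1_OFFSET_MS + CUE_EXCLUSION_MS, float(CUE2_ONSET_MS))
    delay2: tuple = (CUE2_OFFSET_MS + CUE_EXCLUSION_MS, float(GO_ONSET_MS))

    def __post_init__(self):
        if self.delay1[1] <= self.delay1[0] or self.delay2[1] <= self.delay2[0]:
            raise ValueError("empty delay window")
        if self.delay1[1] > self.delay2[0]:
            raise ValueError("delay 1 must precede delay 2")

    def as_list(self):
        return [self.delay1, self.delay2]


@dataclass
class GroupTestResult:
    t: float
    p_raw: float
    tail: str
    n: int
    p_fdr: float = np.nan


def average_delay(info: InformationResult, windows) -> np.ndarray:
    """Mean D over each (start_ms, stop_ms) window of a time-resolved result."""
    if info.values.ndim != 1:
        raise ValueError("average_delay needs a 1-D time course; "
                         "use average_cross_time_window for matrices")
    t = info.times_ms
    out = []
    for start, stop in windows:
        mask = (t >= start) & (t <= stop)
        if not mask.any():
            raise ValueError(f"window [{start}, {stop}] ms holds no samples")
        out.append(float(info.values[mask].mean()))
    return np.array(out)


def average_cross_time_window(matrix: np.ndarray, train_times_ms: np.ndarray,
                              test_times_ms: np.ndarray, train_window, test_window,
                              diagonal_exclusion_ms: float = 100.0) -> float:
    """Mean over a train x test rectangle, excluding the near-diagonal band."""
    tr = np.asarray(train_times_ms)
    te = np.asarray(test_times_ms)
    mtr = (tr >= train_window[0]) & (tr <= train_window[1])
    mte = (te >= test_window[0]) & (te <= test_window[1])
    if not mtr.any() or not mte.any():
        raise ValueError("window outside matrix time axes")
    sub = np.asarray(matrix)[np.ix_(mtr, mte)]
    dt = np.abs(tr[mtr][:, None] - te[mte][None, :])
    keep = dt > diagonal_exclusion_ms
    if not keep.any():
        raise ValueError("diagonal exclusion removed every cell")
    return float(sub[keep].mean())


def _check_values(values):
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(v) == 0:
        raise ValueError("zero variance; t statistic undefined")
    return v


def one_sample_t(values, tail: str = "greater") -> GroupTestResult:
    """One-sample t test of the mean against zero."""
    v = _check_values(values)
    res = sstats.ttest_1samp(v, 0.0, alternative=_alt(tail))
    return GroupTestResult(t=float(res.statistic), p_raw=float(res.pvalue),
                           tail=tail, n=v.size)


def paired_t(values_a, values_b, tail: str = "two-sided") -> GroupTestResult:
    """Paired t test (t on the within-subject differences)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, tail=tail)


def _alt(tail: str) -> str:
    if tail in ("greater", "less", "two-sided"):
        return tail
    raise ValueError("tail must be 'greater', 'less' or 'two-sided'")


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def correct_family(results: list) -> list:
    """FDR-correct a family of GroupTestResults in place and return it."""
    adj = fdr_bh([r.p_raw for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
    return results


def hanning_smooth(series, width_ms: float, fs: float) -> np.ndarray:
    """Hann-kernel smoothing with the given full width at half maximum.

    A Hann window's FWHM is half its support, so the kernel spans
    2 * width_ms. Edges are handled by renormalizing the kernel mass inside
    the series (constant series pass through unchanged). Visualization only —
    never applied before statistics.
    """
    x = np.asarray(series, dtype=float)
    n_kernel = int(round(2.0 * width_ms / 1000.0 * fs)) | 1
    if n_kernel < 3:
        raise ValueError("smoothing width below 2 samples")
    kernel = np.hanning(n_kernel + 2)[1:-1]  # nonzero interior
    kernel /= kernel.sum()
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den
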