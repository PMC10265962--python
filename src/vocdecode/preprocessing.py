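"""Epoch and audio preprocessing.

The canonical order, enforced by :func:`preprocess`, is
jump repair -> 30 Hz zero-phase low-pass -> resample to 300 Hz ->
10 Hz low-pass -> baseline correction on the 500 ms before the first cue.
Both low-pass stages share the same sixth-order zero-phase Butterworth design.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps

from .epochs import EpochArray
from .synth import AUDIO_SFREQ
from .task_design import CUE1_ONSET_MS, GO_ONSET_MS


@dataclass
class VocalOnset:
    """Detected vocal onset, latency relative to the go cue (ms)."""

    latency_ms: float
    detected: bool
    threshold: float


def repair_channel_jumps(epochs: EpochArray, jump_sd_factor: float = 20.0) -> EpochArray:
    """Remove step-like offsets caused by technical channel jumps.

    A sample whose first difference exceeds ``jump_sd_factor`` times the
    robust SD (1.4826 * MAD) of that trace's differences is treated as a step
    onset; the step offset is subtracted from that sample onward. Clean traces
    pass through unchanged.
    """
    if epochs.n_samples < 2:
        raise ValueError("need at least 2 samples")
    data = epochs.data.copy()
    d = np.diff(data, axis=-1)
    mad = np.median(np.abs(d - np.median(d, axis=-1, keepdims=True)), axis=-1, keepdims=True)
    robust_sd = 1.4826 * mad + 1e-30
    bad = np.abs(d) > jump_sd_factor * robust_sd
    if bad.any():
        steps = np.where(bad, d, 0.0)
        data[..., 1:] -= np.cumsum(steps, axis=-1)
    return epochs.copy_with(data=data)


def zero_phase_lowpass(epochs: EpochArray, cutoff_hz: float, order: int = 6) -> EpochArray:
    """Zero-phase (forward-backward) Butterworth low-pass per channel/trial."""
    nyq = epochs.sfreq / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    # forward-backward pass squares the magnitude response of the stated design
    sos = sps.butter(order, cutoff_hz, btype="low", fs=epochs.sfreq, output="sos")
    data = sps.sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.copy_with(data=np.ascontiguousarray(data))


def resample_to(epochs: EpochArray, target_hz: float) -> EpochArray:
    """Anti-aliased polyphase resampling to ``target_hz`` (downsampling only)."""
    if target_hz > epochs.sfreq:
        raise ValueError("upsampling not supported")
    if target_hz == epochs.sfreq:
        return epochs.copy_with(data=epochs.data.copy())
    frac = Fraction(target_hz / epochs.sfreq).limit_denominator(10000)
    data = sps.resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1)
    return EpochArray(data=np.ascontiguousarray(data), sfreq=epochs.sfreq * frac.numerator / frac.denominator,
                      tmin_ms=epochs.tmin_ms, ch_names=list(epochs.ch_names),
                      ch_pos=epochs.ch_pos, ch_hemisphere=epochs.ch_hemisphere)


def baseline_correct(epochs: EpochArray, window_ms=(-500.0, 0.0)) -> EpochArray:
    """Subtract the per-trial/channel mean over ``window_ms`` (rel. cue 1)."""
    start, stop = window_ms
    times = epochs.times_ms
    if start < times[0] - 0.51 * 1000 / epochs.sfreq or stop > times[-1]:
        raise ValueError(f"baseline window {window_ms} outside epoch")
    mask = (times >= start) & (times <= stop)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


def ica_artifact_removal(epochs: EpochArray) -> EpochArray:
    """Optional artifact-removal hook; identity for synthetic data, which
    carries no biological artifact components."""
    return epochs


def preprocess(epochs: EpochArray, lp1_hz: float | None = 30.0,
               resample_hz: float = 300.0, lp2_hz: float | None = 10.0,
               baseline_ms=(-500.0, 0.0), jump_sd_factor: float = 20.0) -> EpochArray:
    """Full pipeline in the canonical order.

    A low-pass stage may be ``None`` to skip it (e.g. when the input is
    already sampled below twice that cutoff, so the stage's band is empty).
    """
    out = repair_channel_jumps(epochs, jump_sd_factor)
    if lp1_hz is not None:
        out = zero_phase_lowpass(out, lp1_hz)
    out = resample_to(out, resample_hz)
    if lp2_hz is not None:
        out = zero_phase_lowpass(out, lp2_hz)
    out = ica_artifact_removal(out)
    return baseline_correct(out, baseline_ms)


def detect_vocal_onset(audio: np.ndarray, reference_imagined_audio: np.ndarray,
                       fs: float = AUDIO_SFREQ, window_ms: float = 42.66,
                       sd_factor: float = 8.0) -> VocalOnset:
    """Envelope-threshold vocal onset detection.

    The trace is rectified and median-filtered (42.66 ms window). The
    threshold is the RMS of a 1000 ms reference segment from an imagined
    trial plus ``sd_factor`` times that segment's SD (both computed on the
    smoothed envelope). The first threshold crossing after the first cue is
    reported as the onset, as latency relative to the go cue (negative if
    the voice started early); no crossing means no detection.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.size == 0:
        raise ValueError("empty audio")
    ref = np.asarray(reference_imagined_audio, dtype=float)
    if ref.size < fs:  # 1000 ms
        raise ValueError("reference segment must be at least 1000 ms")
    win = max(3, int(round(window_ms / 1000.0 * fs)) | 1)  # odd
    env = ndimage.median_filter(np.abs(audio), size=win, mode="reflect")
    ref_env = ndimage.median_filter(np.abs(ref[: int(fs)]), size=win, mode="reflect")
    threshold = float(np.sqrt(np.mean(ref_env**2)) + sd_factor * np.std(ref_env))
    start = int(round(CUE1_ONSET_MS / 1000.0 * fs))
    above = np.flatnonzero(env[start:] > threshold)
    if above.size == 0:
        return VocalOnset(latency_ms=np.nan, detected=False, threshold=threshold)
    t_ms = (start + above[0]) / fs * 1000.0
    return VocalOnset(latency_ms=t_ms - GO_ONSET_MS, detected=True, threshold=threshold)


def select_valid_trials(trial_table: pd.DataFrame) -> np.ndarray:
    """Boolean mask of analyzable trials.

    A trial is kept iff its production type was correct and, for vocalized
    trials, the vowel was correct and the vocal onset came after the go cue.
    If the session has no audio (``vocal_onset_ms`` column missing or the
    ``audio_missing`` flag set), vowel correctness alone qualifies vocalized
    trials.
    """
    required = {"production", "production_correct", "vowel_correct"}
    missing = required - set(trial_table.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    voc = trial_table["production"].to_numpy() == "vocalized"
    prod_ok = trial_table["production_correct"].to_numpy(dtype=bool)
    vowel_ok = trial_table["vowel_correct"].to_numpy(dtype=bool)
    have_audio = "vocal_onset_ms" in trial_table.columns and not bool(
        trial_table.get("audio_missing", pd.Series([False])).any()
    )
    if have_audio:
        onset = trial_table["vocal_onset_ms"].to_numpy(dtype=float)
        onset_ok = np.isfinite(onset) & (onset > 0)
    else:
        onset_ok = np.ones(len(trial_table), dtype=bool)
    return prod_ok & (~voc | (vowel_ok & onset_ok))


def select_sensor_subset(channel_positions: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point (maximin) subset of ``k`` channels.

    Starts from the most superior channel (largest z) and greedily adds the
    channel farthest from the chosen set, yielding an approximately equally
    distributed subset.
    """
    pos = np.asarray(channel_positions, dtype=float)
    n = pos.shape[0]
    if k > n:
        raise ValueError(f"requested {k} of {n} channels")
    chosen = [int(np.argmax(pos[:, 2]))]
    dist = np.linalg.norm(pos - pos[chosen[0]], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(pos - pos[nxt], axis=1))
    return np.array(sorted(chosen))
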