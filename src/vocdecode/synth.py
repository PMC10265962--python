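"""Forward simulation of the rule-based vocalization experiment.

Simulates source-level condition patterns with the representational structure
the analyses are designed to detect, projects them to sensors through a
synthetic leadfield, and adds spatially and temporally correlated noise:

* a *content* axis (vowel /u/ vs. /ə/) that ramps up once the content cue is
  shown and then stays stable,
* an *early production* axis (vocalized vs. imagined) ramping from the
  production cue,
* a *late motor-program* axis that only builds up once both variables are
  known (from the second cue), making the production representation transform
  between delays,
* a shared *effort* axis whose amplitude tracks the degree of motor
  involvement of the levels known so far (/u/ > /ə/, vocalized > imagined) —
  the planted cause of content-production representational overlap,
* optional cue-glyph confound patterns: per-(glyph, block) random pattern
  shifts emulating slow nonstationarities interacting with the blocked design,
* a session-2 perturbation (head repositioning): small rigid rotation of the
  source cloud relative to the sensors plus per-channel gain jitter.

The default dimensional profile is desk scale (64 channels, 60 sources,
300 Hz); the full-scale geometry (273 channels, 457 sources) is available by
argument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial import cKDTree

from .epochs import EpochArray
from .task_design import (
    CUE1_ONSET_MS,
    CUE2_ONSET_MS,
    GO_ONSET_MS,
    TRIAL_END_MS,
    SessionDesign,
    TrialSpec,
)

AUDIO_SFREQ = 2343.75  # Hz, microphone rate the onset detector is specified for


# ---------------------------------------------------------------------------
# geometry

@dataclass
class SourceSpace:
    """Quasi-uniform source locations on a shell, mirror-symmetric in x.

    ``hemisphere`` is 'L' (x < 0) or 'R'; ``neighbors[i]`` lists the immediate
    neighbours of source ``i`` (distance-threshold graph).
    """

    pos: np.ndarray  # (S, 3), metres
    hemisphere: np.ndarray  # (S,) 'L'/'R'
    neighbors: list

    @property
    def n_sources(self) -> int:
        return self.pos.shape[0]


@dataclass
class Leadfield:
    """Gain tensor from source orientations to channels, with the geometry
    it was computed from (so session perturbations can recompute it)."""

    gain: np.ndarray  # (S, 3, C)
    source_pos: np.ndarray
    ch_pos: np.ndarray
    ch_names: list

    @property
    def n_channels(self) -> int:
        return self.gain.shape[2]


def _fibonacci_hemisphere(m: int, radius: float) -> np.ndarray:
    """m quasi-uniform points on the x<0 half of a sphere of given radius."""
    i = np.arange(m)
    # cos(polar angle from the -x axis) in (0, 1): stays strictly left
    u = (i + 0.5) / m
    theta = np.arccos(u)  # angle from -x axis, < 90 deg
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    x = -radius * np.cos(theta)
    y = radius * np.sin(theta) * np.cos(phi)
    z = radius * np.sin(theta) * np.sin(phi)
    return np.column_stack([x, y, z])


def make_source_space(n_sources: int = 457, seed: int = 0, radius: float = 0.08) -> SourceSpace:
    """Mirror-symmetric quasi-uniform shell of ``n_sources`` locations.

    Left and right hemispheres (sign of the lateral x coordinate) differ in
    count by at most 1. Immediate neighbours are sources within 1.6x the
    median nearest-neighbour distance.
    """
    if n_sources < 10:
        raise ValueError("need at least 10 sources")
    n_left = (n_sources + 1) // 2
    rng = np.random.default_rng(seed)
    left = _fibonacci_hemisphere(n_left, radius)
    # small tangential jitter, identical for the mirrored pair
    jitter = rng.normal(scale=0.02 * radius, size=left.shape)
    jitter[:, 0] = 0.0
    left = left + jitter
    right = left * np.array([-1.0, 1.0, 1.0])
    pos = np.vstack([left, right[: n_sources - n_left]])
    hemisphere = np.where(pos[:, 0] < 0, "L", "R")

    tree = cKDTree(pos)
    nn_dist, _ = tree.query(pos, k=2)
    thresh = 1.6 * np.median(nn_dist[:, 1])
    pairs = tree.query_pairs(thresh)
    neighbors: list = [[] for _ in range(n_sources)]
    for a, b in pairs:
        neighbors[a].append(b)
        neighbors[b].append(a)
    for i, nb in enumerate(neighbors):  # guarantee >=1 neighbour
        if not nb:
            j = int(tree.query(pos[i], k=2)[1][1])
            neighbors[i].append(j)
            neighbors[j].append(i)
    neighbors = [sorted(set(nb)) for nb in neighbors]
    return SourceSpace(pos=pos, hemisphere=hemisphere, neighbors=neighbors)


def _gain_tensor(source_pos: np.ndarray, ch_pos: np.ndarray) -> np.ndarray:
    """Smooth distance-decaying gains, (S, 3, C), RMS-normalized."""
    d = ch_pos[None, :, :] - source_pos[:, None, :]  # (S, C, 3)
    dist = np.linalg.norm(d, axis=2)  # (S, C)
    dhat = d / dist[:, :, None]
    decay = 1.0 / dist**2
    # orientation sensitivity bounded away from zero so magnitude decays with distance
    gain = np.empty((source_pos.shape[0], 3, ch_pos.shape[0]))
    for o in range(3):
        gain[:, o, :] = decay * (0.75 + 0.25 * dhat[:, :, o])
    gain /= np.sqrt(np.mean(gain**2))
    return gain


def make_leadfield(space: SourceSpace, n_channels: int = 273, seed: int = 0,
                   helmet_radius: float = 0.12) -> Leadfield:
    """Synthetic leadfield for ``n_channels`` sensors on an upper-helmet shell."""
    if n_channels < 3:
        raise ValueError("need at least 3 channels")
    rng = np.random.default_rng(seed)
    i = np.arange(n_channels)
    u = (i + 0.5) / n_channels  # cos(angle from +z): upper hemisphere
    theta = np.arccos(u)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    ch_pos = np.column_stack([
        helmet_radius * np.sin(theta) * np.cos(phi),
        helmet_radius * np.sin(theta) * np.sin(phi),
        helmet_radius * np.cos(theta),
    ])
    ch_pos += rng.normal(scale=0.01 * helmet_radius, size=ch_pos.shape)
    names = [f"MEG{i:03d}" for i in range(n_channels)]
    return Leadfield(gain=_gain_tensor(space.pos, ch_pos), source_pos=space.pos.copy(),
                     ch_pos=ch_pos, ch_names=names)


def perturb_leadfield(lf: Leadfield, rotation_deg: float, gain_scale_sd: float,
                      rng: np.random.Generator) -> Leadfield:
    """Head-repositioning model: rotate sources about z, jitter channel gains."""
    angle = np.deg2rad(rotation_deg) * rng.standard_normal()
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    src = lf.source_pos @ rot.T
    gain = _gain_tensor(src, lf.ch_pos)
    gain *= np.maximum(rng.normal(1.0, gain_scale_sd, size=lf.n_channels), 0.1)[None, None, :]
    return Leadfield(gain=gain, source_pos=src, ch_pos=lf.ch_pos, ch_names=list(lf.ch_names))


# ---------------------------------------------------------------------------
# planted effects

EFFORT_DEFAULTS = {"u": 1.6, "schwa": 1.0, "vocalized": 1.6, "imagined": 1.0}


@dataclass
class EffectSpec:
    """Ground-truth pattern geometry and amplitudes of the simulation.

    Amplitudes are in source-activity units relative to unit sensor noise;
    the defaults are tuned so a 24-subject desk-scale experiment exhibits
    the qualitative significance pattern this task design predicts (they
    are the package's own working point, not measured values).
    """

    a_content: float = 0.12
    a_prod: float = 0.18
    a_late: float = 0.30
    a_effort: float = 0.52
    a_cue: float = 0.0
    effort: dict = field(default_factory=lambda: dict(EFFORT_DEFAULTS))
    tau_ms: float = 300.0  # ramp time constant
    lam: float = 0.8  # left-hemisphere pattern mass weight (0.5 = symmetric)
    overlap_content_production: bool = False  # plant both variables on one axis
    # materialized geometry (filled by materialize_effect)
    u_content: np.ndarray | None = None
    u_prod_early: np.ndarray | None = None
    u_prod_late: np.ndarray | None = None
    u_effort: np.ndarray | None = None
    orient: np.ndarray | None = None  # (S, 3) fixed source orientations

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items()
             if not isinstance(v, np.ndarray) and v is not None}
        return json.dumps(d, default=float)


def _lateralized_unit(rng: np.random.Generator, space: SourceSpace, lam: float) -> np.ndarray:
    v = rng.standard_normal(space.n_sources)
    w = np.where(space.hemisphere == "L", lam, 1.0 - lam)
    v = v * w
    return v / np.linalg.norm(v)


def materialize_effect(effect: EffectSpec, space: SourceSpace, seed: int) -> EffectSpec:
    """Draw the planted pattern vectors and source orientations.

    u_content, u_prod_early and u_prod_late are mutually orthogonal unless
    ``overlap_content_production`` is set (then the early production axis *is*
    the content axis). The effort axis is an independent draw.
    """
    rng = np.random.default_rng(seed)
    u_c = _lateralized_unit(rng, space, effect.lam)
    u_pe = _lateralized_unit(rng, space, effect.lam)
    u_pl = _lateralized_unit(rng, space, effect.lam)
    u_pe -= (u_pe @ u_c) * u_c
    u_pe /= np.linalg.norm(u_pe)
    u_pl -= (u_pl @ u_c) * u_c + (u_pl @ u_pe) * u_pe
    u_pl /= np.linalg.norm(u_pl)
    if effect.overlap_content_production:
        u_pe = u_c.copy()
    u_e = _lateralized_unit(rng, space, effect.lam)
    orient = rng.standard_normal((space.n_sources, 3))
    orient /= np.linalg.norm(orient, axis=1, keepdims=True)
    return replace(effect, u_content=u_c, u_prod_early=u_pe, u_prod_late=u_pl,
                   u_effort=u_e, orient=orient)


def ramp(dt_ms: np.ndarray, tau_ms: float) -> np.ndarray:
    """Logistic saturation starting at 0: 0 before the event, -> 1 for t >> tau."""
    dt = np.asarray(dt_ms, dtype=float)
    out = 2.0 / (1.0 + np.exp(-np.clip(dt, 0, None) / tau_ms)) - 1.0
    return np.where(dt < 0, 0.0, out)


def _cue_transient(dt_ms: np.ndarray, tau_ms: float = 150.0) -> np.ndarray:
    """Alpha-function visual transient, peak 1 at tau."""
    dt = np.asarray(dt_ms, dtype=float)
    x = np.clip(dt, 0, None) / tau_ms
    return np.where(dt < 0, 0.0, x * np.exp(1.0 - x))


def condition_mean(effect: EffectSpec, trial: TrialSpec, t_ms) -> np.ndarray:
    """Noise-free source pattern of a trial's condition at time(s) ``t_ms``.

    The effort amplitude is causal: during delay 1 it tracks the effort level
    of the variable instructed first, and rises (or falls) to the product of
    both levels once the second cue reveals the other variable.
    """
    if effect.u_content is None:
        raise ValueError("EffectSpec not materialized; call materialize_effect first")
    t = np.atleast_1d(np.asarray(t_ms, dtype=float))
    content_first = trial.rule.order == "content_first"
    content_cue = CUE1_ONSET_MS if content_first else CUE2_ONSET_MS
    prod_cue = CUE2_ONSET_MS if content_first else CUE1_ONSET_MS
    s_c = 1.0 if trial.vowel == "u" else -1.0
    s_p = 1.0 if trial.production == "vocalized" else -1.0

    g_c = ramp(t - content_cue, effect.tau_ms)
    g_p = ramp(t - prod_cue, effect.tau_ms)
    g_2 = ramp(t - CUE2_ONSET_MS, effect.tau_ms)

    m = (s_c * effect.a_content) * np.outer(effect.u_content, g_c)
    m += (s_p * effect.a_prod) * np.outer(effect.u_prod_early, g_p)
    m += (s_p * effect.a_late) * np.outer(effect.u_prod_late, g_2)

    if effect.a_effort != 0.0:
        e_v = effect.effort[trial.vowel]
        e_p = effect.effort[trial.production]
        e1 = e_v if content_first else e_p
        g_1 = ramp(t - CUE1_ONSET_MS, effect.tau_ms)
        amp = e1 * g_1 + (e_v * e_p - e1) * g_2
        m += effect.a_effort * np.outer(effect.u_effort, amp)
    return m[:, 0] if np.ndim(t_ms) == 0 else m


# ---------------------------------------------------------------------------
# noise

@dataclass
class NoiseSpec:
    """Sensor/source noise model and session-2 perturbation magnitudes."""

    sensor_noise_sd: float = 1.0
    source_noise_sd: float = 0.5
    ar_coef: float = 0.9  # AR(1) temporal autocorrelation of sensor noise
    cond_cap: float = 10.0  # condition-number cap of the spatial mixing
    amp_jitter_sd: float = 0.15  # per-trial multiplicative amplitude jitter
    gain_scale_sd: float = 0.03  # session-2 per-channel gain SD
    rotation_deg: float = 3.0  # session-2 source rotation SD (degrees)

    def __post_init__(self):
        if not abs(self.ar_coef) < 1:
            raise ValueError("AR coefficient must satisfy |phi| < 1")

    def spatial_mixing(self, n_channels: int, rng: np.random.Generator) -> np.ndarray:
        """Random spatial mixing with capped condition number, unit mean power."""
        a = rng.standard_normal((n_channels, n_channels))
        u, s, vt = np.linalg.svd(a)
        s = np.clip(s, s.max() / self.cond_cap, None)
        m = (u * s) @ vt
        return m / np.sqrt(np.mean(np.sum(m**2, axis=1)))

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _ar1_noise(rng: np.random.Generator, shape, phi: float) -> np.ndarray:
    """AR(1) noise along the last axis with unit marginal variance."""
    white = rng.standard_normal(shape)
    if phi == 0.0:
        return white
    out = sps.lfilter([1.0], [1.0, -phi], white * np.sqrt(1 - phi**2), axis=-1)
    # stationary start
    out[..., 0] = white[..., 0]
    return out


# ---------------------------------------------------------------------------
# session simulation

@dataclass
class SimulatedDataset:
    """Sensor epochs plus design table and planted ground truth."""

    epochs: EpochArray
    design: SessionDesign
    design_table: pd.DataFrame
    effect: EffectSpec
    noise: NoiseSpec
    source_epochs: EpochArray | None = None
    audio: np.ndarray | None = None  # (n_trials, n_audio_samples)
    audio_sfreq: float = AUDIO_SFREQ
    seed: int = 0


def simulate_session(design: SessionDesign, effect: EffectSpec, noise: NoiseSpec,
                     leadfield: Leadfield, seed: int, space: SourceSpace | None = None,
                     sfreq: float = 300.0, tmin_ms: float = -500.0, tmax_ms: float = 4500.0,
                     with_audio: bool = False, keep_sources: bool = False) -> SimulatedDataset:
    """Simulate one session's sensor epochs from the planted effect geometry.

    Session 2 applies the leadfield perturbation (head repositioning); the
    cue-glyph confound (``a_cue > 0``) adds per-(glyph, block) random pattern
    shifts at cue onsets, drawn fresh per session.
    """
    if effect.u_content is None:
        raise ValueError("EffectSpec not materialized; call materialize_effect first")
    n_sources = effect.u_content.shape[0]
    if leadfield.gain.shape[0] != n_sources:
        raise ValueError("leadfield and effect source counts differ")
    rng = np.random.default_rng([seed, design.session_index])

    lf = leadfield
    if design.session_index == 2 and (noise.rotation_deg > 0 or noise.gain_scale_sd > 0):
        lf = perturb_leadfield(lf, noise.rotation_deg, noise.gain_scale_sd, rng)
    # fixed-orientation effective gain (S, C)
    g_eff = np.einsum("so,soc->sc", effect.orient, lf.gain)

    n_samples = int(round((tmax_ms - tmin_ms) / 1000.0 * sfreq)) + 1
    times = tmin_ms + np.arange(n_samples) * 1000.0 / sfreq
    trials = design.flat_trials()
    n_trials = len(trials)

    # condition-mean source time courses, one per distinct condition
    cond_means: dict[int, np.ndarray] = {}
    for t in trials:
        cid = t.condition_id
        if cid not in cond_means:
            cond_means[cid] = condition_mean(effect, t, times)

    # per-(glyph, block) confound patterns, fresh each session
    cue_patterns: dict[tuple, np.ndarray] = {}
    if effect.a_cue > 0:
        for block_pos in range(len(design.trials)):
            for glyph in ("forward_slash", "backward_slash"):
                v = rng.standard_normal(n_sources)
                cue_patterns[(glyph, block_pos)] = effect.a_cue * v / np.linalg.norm(v)
        cue1_tc = _cue_transient(times - CUE1_ONSET_MS)
        cue2_tc = _cue_transient(times - CUE2_ONSET_MS)

    mix = noise.spatial_mixing(lf.n_channels, rng)
    data = np.empty((n_trials, lf.n_channels, n_samples))
    src_data = np.empty((n_trials, n_sources, n_samples)) if keep_sources else None
    for i, trial in enumerate(trials):
        amp = max(0.1, 1.0 + noise.amp_jitter_sd * rng.standard_normal())
        x = amp * cond_means[trial.condition_id]
        if cue_patterns:
            x = x + np.outer(cue_patterns[(trial.cue1_glyph, trial.block_index)], cue1_tc)
            x = x + np.outer(cue_patterns[(trial.cue2_glyph, trial.block_index)], cue2_tc)
        if noise.source_noise_sd > 0:
            x = x + noise.source_noise_sd * _ar1_noise(rng, (n_sources, n_samples), noise.ar_coef)
        y = g_eff.T @ x
        y += noise.sensor_noise_sd * (mix @ _ar1_noise(rng, (lf.n_channels, n_samples), noise.ar_coef))
        data[i] = y
        if keep_sources:
            src_data[i] = x

    table = design.to_frame()
    audio = None
    if with_audio:
        n_audio = int(round(TRIAL_END_MS / 1000.0 * AUDIO_SFREQ))
        audio = np.empty((n_trials, n_audio))
        onsets = np.full(n_trials, np.nan)
        for i, trial in enumerate(trials):
            tr = simulate_audio(trial, seed=int(rng.integers(2**31)))
            audio[i] = tr.waveform[:n_audio]
            onsets[i] = tr.onset_ms
        table["true_onset_ms"] = onsets

    epochs = EpochArray(data=data, sfreq=sfreq, tmin_ms=tmin_ms,
                        ch_names=list(lf.ch_names), ch_pos=lf.ch_pos.copy())
    sources = None
    if keep_sources and space is not None:
        sources = EpochArray(data=src_data, sfreq=sfreq, tmin_ms=tmin_ms,
                             ch_names=[f"SRC{i:03d}" for i in range(n_sources)],
                             ch_pos=space.pos.copy(), ch_hemisphere=space.hemisphere.copy())
    return SimulatedDataset(epochs=epochs, design=design, design_table=table,
                            effect=effect, noise=noise, source_epochs=sources,
                            audio=audio, seed=seed)


# ---------------------------------------------------------------------------
# audio

@dataclass
class TrialAudio:
    waveform: np.ndarray
    sfreq: float
    onset_ms: float  # NaN on imagined trials


def simulate_audio(trial: TrialSpec, seed: int, sfreq: float = AUDIO_SFREQ,
                   mean_latency_s: float = 0.58, latency_sd_s: float = 0.12,
                   background_sd: float = 0.01, burst_amplitude: float = 1.0,
                   burst_ms: float = 500.0) -> TrialAudio:
    """Microphone trace of one trial.

    Vocalized trials get a vocalization burst whose onset is drawn
    N(0.58, 0.12^2) s after the go cue (truncated at >= 0.05 s); imagined
    trials carry only low-amplitude background noise. Time zero of the
    waveform is the first-cue onset.
    """
    rng = np.random.default_rng(seed)
    n = int(round(TRIAL_END_MS / 1000.0 * sfreq)) + 1
    wave = background_sd * rng.standard_normal(n)
    onset_ms = np.nan
    if trial.production == "vocalized":
        lat = rng.normal(mean_latency_s, latency_sd_s)
        while lat < 0.05:
            lat = rng.normal(mean_latency_s, latency_sd_s)
        onset_ms = 1000.0 * lat
        start = int(round((GO_ONSET_MS + onset_ms) / 1000.0 * sfreq))
        dur = int(round(burst_ms / 1000.0 * sfreq))
        stop = min(n, start + dur)
        if start < n:
            k = stop - start
            env = np.ones(k)
            attack = max(1, int(round(0.005 * sfreq)))
            env[:attack] = np.linspace(0, 1, attack)
            release = max(1, int(round(0.05 * sfreq)))
            if k > release:
                env[-release:] *= np.linspace(1, 0, release)
            wave[start:stop] += burst_amplitude * env * (
                0.6 * np.sin(2 * np.pi * 220.0 * np.arange(k) / sfreq)
                + 0.4 * rng.standard_normal(k)
            )
    return TrialAudio(waveform=wave, sfreq=sfreq, onset_ms=onset_ms)
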