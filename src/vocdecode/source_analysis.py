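"""Source projection, searchlight decoding and the lateralization index.

Sensor epochs are projected to source space with a unit-gain LCMV spatial
filter (W = (L' C^-1 L)^-1 L' C^-1 per source). The searchlight repeats the
cvMANOVA at every source over a local channel set — the three dipole
directions of the centre source and of its immediate graph neighbours — and
the lateralization index (LI) is the mean left-hemisphere information minus
the mean right-hemisphere information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cvmanova import Contrast, CVManova, FoldScheme, DEFAULT_NOISE_WINDOW_MS
from .epochs import EpochArray
from .synth import Leadfield, SourceSpace


@dataclass
class SpatialFilter:
    """Unit-gain linear spatial filter, (sources, 3, channels)."""

    weights: np.ndarray
    source_pos: np.ndarray
    unit_gain: bool = True


@dataclass
class SearchlightResult:
    """Per-source pattern distinctness (optionally per time point).

    ``values`` is (n_sources,) or (n_sources, T); NaN marks locations whose
    searchlight was rank-insufficient for the trial count.
    """

    values: np.ndarray
    times_ms: np.ndarray | None
    hemisphere: np.ndarray
    source_pos: np.ndarray
    variable: str = ""
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        vals = np.atleast_2d(self.values.T).T
        rows = []
        for s in range(vals.shape[0]):
            for w in range(vals.shape[1]):
                rows.append(dict(source_id=s, x=self.source_pos[s, 0],
                                 y=self.source_pos[s, 1], z=self.source_pos[s, 2],
                                 hemisphere=self.hemisphere[s], window=w,
                                 D=vals[s, w]))
        return pd.DataFrame(rows)


def lcmv_weights(leadfield: Leadfield, data_covariance: np.ndarray,
                 regularization: float = 0.05) -> SpatialFilter:
    """Unit-gain LCMV beamformer weights for every source.

    ``regularization`` is diagonal loading as a fraction of the mean sensor
    variance; with the identity covariance the filter reduces to the
    pseudoinverse (L'L)^-1 L'.
    """
    C = np.asarray(data_covariance, dtype=float)
    n_ch = C.shape[0]
    if regularization > 0:
        C = C + regularization * np.trace(C) / n_ch * np.eye(n_ch)
    try:
        C_inv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular covariance; increase regularization") from err
    S = leadfield.gain.shape[0]
    W = np.empty((S, 3, n_ch))
    for s in range(S):
        L = leadfield.gain[s].T  # (channels, 3)
        A = L.T @ C_inv
        W[s] = np.linalg.solve(A @ L, A)
    return SpatialFilter(weights=W, source_pos=leadfield.source_pos.copy())


def project_to_sources(epochs: EpochArray, spatial_filter: SpatialFilter,
                       combine_orientations: bool = False,
                       hemisphere: np.ndarray | None = None) -> EpochArray:
    """Apply the spatial filter to sensor epochs.

    Returns source epochs with 3 orientation channels per source
    (channel order: source-major), or one summed trace per source when
    ``combine_orientations`` is set (the cross-session profile).
    """
    W = spatial_filter.weights
    S, _, n_ch = W.shape
    if epochs.n_channels != n_ch:
        raise ValueError("channel count mismatch between filter and epochs")
    flat = W.reshape(S * 3, n_ch)
    data = np.einsum("qc,nct->nqt", flat, epochs.data)
    if combine_orientations:
        data = data.reshape(epochs.n_trials, S, 3, -1).sum(axis=2)
        names = [f"SRC{s:03d}" for s in range(S)]
        hemi = hemisphere
        pos = spatial_filter.source_pos
    else:
        names = [f"SRC{s:03d}o{o}" for s in range(S) for o in range(3)]
        hemi = None if hemisphere is None else np.repeat(hemisphere, 3)
        pos = np.repeat(spatial_filter.source_pos, 3, axis=0)
    return EpochArray(data=data, sfreq=epochs.sfreq, tmin_ms=epochs.tmin_ms,
                      ch_names=names, ch_pos=pos, ch_hemisphere=hemi)


def searchlight_information(source_epochs: EpochArray, space: SourceSpace, y,
                            contrast: Contrast, fold_scheme: FoldScheme | None = None,
                            noise_window_ms=DEFAULT_NOISE_WINDOW_MS, decim: int = 1,
                            time_average: bool = True) -> SearchlightResult:
    """cvMANOVA within each source's searchlight.

    ``source_epochs`` must be orientation-resolved (3 channels per source,
    source-major order). The searchlight of source ``s`` comprises the dipole
    directions of ``s`` and of its immediate neighbours. Locations whose
    channel count is too large for the trial count get NaN.
    """
    fs = fold_scheme or FoldScheme()
    S = space.n_sources
    if source_epochs.n_channels != 3 * S:
        raise ValueError("source epochs must carry 3 orientation channels per source")
    vals = None
    times = None
    for s in range(S):
        members = [s] + list(space.neighbors[s])
        ch = np.concatenate([3 * np.asarray(members) + o for o in range(3)])
        ch.sort()
        est = CVManova(contrast=contrast, n_folds=fs.n_folds, n_reps=fs.n_repetitions,
                       noise_window_ms=noise_window_ms, decim=decim,
                       random_state=fs.seed)
        try:
            est.fit(source_epochs.pick_channels(ch), y)
            d = est.information_.values
            times = est.information_.times_ms
        except ValueError as err:
            if "insufficient trials for channel count" not in str(err):
                raise  # stratification/shape problems affect every location
            d = None
        if vals is None:
            T = 1 if (time_average or d is None) else d.size
            vals = np.full((S,) if time_average else (S, T), np.nan)
        if d is not None:
            vals[s] = d.mean() if time_average else d
    return SearchlightResult(values=vals, times_ms=None if time_average else times,
                             hemisphere=space.hemisphere.copy(),
                             source_pos=space.pos.copy(), variable=contrast.name,
                             meta=dict(n_folds=fs.n_folds, n_reps=fs.n_repetitions))


def select_source_subset(space: SourceSpace, k: int) -> np.ndarray:
    """Approximately equally spaced subset of ``k`` sources (farthest-point),
    e.g. the reduced source set used for cross-session decoding."""
    from .preprocessing import select_sensor_subset
    return select_sensor_subset(space.pos, k)


def lateralization_index(result: SearchlightResult) -> float:
    """LI = mean(left-hemisphere D) - mean(right-hemisphere D)."""
    left = result.hemisphere == "L"
    right = result.hemisphere == "R"
    if not left.any() or not right.any():
        raise ValueError("both hemispheres must contain sources")
    vals = result.values if result.values.ndim == 1 else result.values.mean(axis=1)
    return float(np.nanmean(vals[left]) - np.nanmean(vals[right]))
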