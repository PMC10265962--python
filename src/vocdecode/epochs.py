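"""Epoched multichannel data container and HDF5 round-trip."""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np
import pandas as pd


@dataclass
class EpochArray:
    """Trials x channels x samples with sampling metadata.

    ``tmin_ms`` is the time of the first sample relative to the onset of the
    first visual cue; the time axis is implied by ``sfreq``.
    """

    data: np.ndarray  # (n_trials, n_channels, n_samples)
    sfreq: float
    tmin_ms: float
    ch_names: list = field(default_factory=list)
    ch_pos: np.ndarray | None = None  # (n_channels, 3)
    ch_hemisphere: np.ndarray | None = None  # 'L'/'R' per channel (source level)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in epoch data")
        if not self.ch_names:
            self.ch_names = [f"CH{i:03d}" for i in range(self.data.shape[1])]
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.n_samples) * 1000.0 / self.sfreq

    def time_index(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times_ms - t_ms)))

    def time_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        t = self.times_ms
        mask = (t >= start_ms) & (t <= stop_ms)
        if not mask.any():
            raise ValueError(f"window [{start_ms}, {stop_ms}] ms outside epoch")
        return mask

    def copy_with(self, **kw) -> "EpochArray":
        return replace(self, **kw)

    def pick_channels(self, idx: Sequence[int]) -> "EpochArray":
        idx = np.asarray(idx, dtype=int)
        return EpochArray(
            data=self.data[:, idx],
            sfreq=self.sfreq,
            tmin_ms=self.tmin_ms,
            ch_names=[self.ch_names[i] for i in idx],
            ch_pos=None if self.ch_pos is None else self.ch_pos[idx],
            ch_hemisphere=None if self.ch_hemisphere is None else self.ch_hemisphere[idx],
        )

    def pick_trials(self, idx) -> "EpochArray":
        return self.copy_with(data=self.data[np.asarray(idx)])


def write_dataset(path, epochs: EpochArray, design: pd.DataFrame | None = None,
                  audio: np.ndarray | None = None, audio_sfreq: float | None = None,
                  truth: dict | None = None, sources: EpochArray | None = None) -> None:
    """Write an epoch container (plus design table / audio / ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        _write_epochs_group(f.create_group("epochs"), epochs)
        if sources is not None:
            _write_epochs_group(f.create_group("sources"), sources)
        if design is not None:
            buf = io.StringIO()
            design.to_csv(buf, sep="\t", index=False)
            f.create_dataset("design", data=buf.getvalue())
        if audio is not None:
            g = f.create_dataset("audio", data=audio)
            g.attrs["sfreq"] = float(audio_sfreq or 0.0)
        if truth is not None:
            f.attrs["truth"] = json.dumps(truth)


def read_dataset(path) -> dict:
    """Read a container written by :func:`write_dataset`."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        out["epochs"] = _read_epochs_group(f["epochs"])
        if "sources" in f:
            out["sources"] = _read_epochs_group(f["sources"])
        if "design" in f:
            out["design"] = pd.read_csv(io.StringIO(f["design"][()].decode()), sep="\t")
        if "audio" in f:
            out["audio"] = f["audio"][()]
            out["audio_sfreq"] = float(f["audio"].attrs.get("sfreq", 0.0))
        if "truth" in f.attrs:
            out["truth"] = json.loads(f.attrs["truth"])
    return out


def _write_epochs_group(g, epochs: EpochArray) -> None:
    g.create_dataset("data", data=epochs.data)
    g.attrs["sfreq"] = epochs.sfreq
    g.attrs["tmin_ms"] = epochs.tmin_ms
    g.create_dataset("ch_names", data=np.array(epochs.ch_names, dtype="S"))
    if epochs.ch_pos is not None:
        g.create_dataset("ch_pos", data=epochs.ch_pos)
    if epochs.ch_hemisphere is not None:
        g.create_dataset("ch_hemisphere", data=np.array(epochs.ch_hemisphere, dtype="S"))


def _read_epochs_group(g) -> EpochArray:
    return EpochArray(
        data=g["data"][()],
        sfreq=float(g.attrs["sfreq"]),
        tmin_ms=float(g.attrs["tmin_ms"]),
        ch_names=[n.decode() for n in g["ch_names"][()]],
        ch_pos=g["ch_pos"][()] if "ch_pos" in g else None,
        ch_hemisphere=(np.array([h.decode() for h in g["ch_hemisphere"][()]])
                       if "ch_hemisphere" in g else None),
    )
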