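"""Core containers and shared plumbing.

Spike times live in milliseconds relative to trial start.  Spike counts are
taken in fixed-width, half-open bins ``[start + b*w, start + (b+1)*w)``; the
trailing partial bin is dropped so every bin has equal width (the HMM
requires it).  Emission parameters elsewhere in the package are expected
counts per bin; conversion to spikes/s uses the factor ``1000 / w_bin``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

CONDITIONS = ("attend_rf", "attend_away1", "attend_away2")

TRIAL_COLUMNS = [
    "trial_id", "condition", "t_fixation", "t_stim_on", "t_cue",
    "t_dim1", "t_dim2", "t_dim3", "target_dim", "target_in_rf",
    "rt", "pupil_baseline",
]


@dataclass
class SpikeTrainSet:
    """Spike times per (trial, channel), with a channel -> area map.

    ``spikes[i][j]`` is a sorted, non-negative float array of spike times
    (ms, trial-relative) for trial ``i`` and channel ``j``.
    """

    spikes: list[list[np.ndarray]]
    areas: np.ndarray          # (n_channels,) of str
    trial_ids: np.ndarray      # (n_trials,) of int

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=object)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        for i, trial in enumerate(self.spikes):
            if len(trial) != self.n_channels:
                raise ValueError(
                    f"trial {self.trial_ids[i]}: {len(trial)} channel lists, "
                    f"expected {self.n_channels}")
            for j, st in enumerate(trial):
                st = np.asarray(st, dtype=float)
                if st.size and (np.any(st < 0) or np.any(np.diff(st) < 0)):
                    raise ValueError(
                        f"trial {self.trial_ids[i]} channel {j}: spike times "
                        "must be non-negative and sorted")
                trial[j] = st

    @property
    def n_trials(self) -> int:
        return len(self.spikes)

    @property
    def n_channels(self) -> int:
        return len(self.areas)

    def channels_of(self, area: str) -> np.ndarray:
        return np.flatnonzero(self.areas == area)


@dataclass
class BinnedCounts:
    """Trials x channels x bins spike counts at fixed bin width.

    Trials may have different window lengths, so ``counts`` is a ragged list
    of integer arrays of shape (n_channels, n_bins_trial).
    """

    counts: list[np.ndarray]
    w_bin: float               # ms
    windows: np.ndarray        # (n_trials, 2) start/end in ms
    areas: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.areas = np.asarray(self.areas, dtype=object)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        for i, c in enumerate(self.counts):
            c = np.asarray(c)
            if c.ndim != 2 or c.shape[0] != len(self.areas):
                raise ValueError(f"trial index {i}: counts must be "
                                 "(n_channels, n_bins)")
            if np.any(c < 0):
                raise ValueError(f"trial index {i}: negative counts")
            self.counts[i] = c.astype(np.int64)

    @property
    def n_trials(self) -> int:
        return len(self.counts)

    @property
    def n_channels(self) -> int:
        return len(self.areas)

    @property
    def n_bins(self) -> np.ndarray:
        return np.array([c.shape[1] for c in self.counts])

    def select_channels(self, idx: np.ndarray) -> "BinnedCounts":
        idx = np.asarray(idx)
        return BinnedCounts([c[idx] for c in self.counts], self.w_bin,
                            self.windows.copy(), self.areas[idx],
                            self.trial_ids.copy())

    def select_trials(self, idx: np.ndarray) -> "BinnedCounts":
        idx = np.asarray(idx)
        return BinnedCounts([self.counts[i] for i in idx], self.w_bin,
                            self.windows[idx], self.areas.copy(),
                            self.trial_ids[idx])

    def channel_means(self) -> np.ndarray:
        """Mean count per bin for each channel, pooled over trials."""
        tot = np.sum([c.sum(axis=1) for c in self.counts], axis=0)
        return tot / max(int(self.n_bins.sum()), 1)


def make_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and order a trial table.

    Event times must be strictly increasing within each trial; reaction time
    is present only on response trials (others are NaN).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    df = df[TRIAL_COLUMNS].reset_index(drop=True)
    ev = ["t_fixation", "t_stim_on", "t_cue", "t_dim1", "t_dim2", "t_dim3"]
    for _, row in df.iterrows():
        times = [row[c] for c in ev if np.isfinite(row[c])]
        if np.any(np.diff(times) <= 0):
            raise ValueError(
                f"trial {row['trial_id']}: event times not strictly increasing")
    return df


@dataclass
class SessionBundle:
    """One recording: spikes, binned counts per window, events, aux signals.

    Ground-truth fields from the synthetic generator (latent paths,
    generative parameters, injected microsaccade times) ride along in
    ``meta`` so every estimator downstream can be scored.
    """

    spikes: SpikeTrainSet
    trials: pd.DataFrame
    counts: dict[str, BinnedCounts] = field(default_factory=dict)
    eye: list[np.ndarray] | None = None     # per trial (2, n_samples), deg
    eye_fs: float = 220.0
    lfp: "LfpArray | None" = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.trials) != self.spikes.n_trials:
            raise ValueError("trial table and spike set disagree on trial count")
        if not np.array_equal(self.trials["trial_id"].to_numpy(),
                              self.spikes.trial_ids):
            raise ValueError("trial ids differ between table and spikes")

    @property
    def conditions(self) -> np.ndarray:
        return self.trials["condition"].to_numpy()


@dataclass
class LfpArray:
    """Laminar voltage traces: per trial (n_channels, n_samples) at ``fs``.

    Channels are ordered superficial to deep; ``reference`` records the
    re-referencing applied ("raw", "car" or "bipolar").
    """

    data: list[np.ndarray]
    fs: float = 1000.0
    reference: str = "raw"
    depth_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        ns = {d.shape for d in self.data}
        if len({d.shape[0] for d in self.data}) > 1:
            raise ValueError("channel count differs across trials")
        if self.depth_um is not None:
            self.depth_um = np.asarray(self.depth_um, float)
            if np.any(np.diff(self.depth_um) <= 0):
                raise ValueError("channel depths must be strictly increasing")


# ---------------------------------------------------------------------------
# binning and windows

def bin_spikes(spikes: SpikeTrainSet, windows: np.ndarray,
               w_bin: float = 10.0,
               channel_mask: np.ndarray | None = None) -> BinnedCounts:
    """Discretize spike trains into fixed-width counts.

    ``windows`` is (n_trials, 2) of [start, end) in ms.  Bin ``b`` covers
    ``[start + b*w, start + (b+1)*w)``; spikes outside the window (or in a
    trailing partial bin) are discarded.  ``channel_mask`` optionally keeps a
    boolean subset of channels (e.g. the SNR>3 inclusion flags).
    """
    if w_bin <= 0:
        raise ValueError("w_bin must be positive")
    windows = np.asarray(windows, dtype=float)
    if windows.shape != (spikes.n_trials, 2):
        raise ValueError("windows must be (n_trials, 2)")
    ch_idx = np.arange(spikes.n_channels)
    if channel_mask is not None:
        ch_idx = np.flatnonzero(np.asarray(channel_mask, bool))
    counts = []
    for i, (start, end) in enumerate(windows):
        n_bins = int(np.floor((end - start) / w_bin))
        if n_bins < 1:
            raise ValueError(
                f"trial {spikes.trial_ids[i]}: window [{start}, {end}) "
                f"shorter than one {w_bin} ms bin")
        c = np.zeros((len(ch_idx), n_bins), dtype=np.int64)
        for row, j in enumerate(ch_idx):
            st = spikes.spikes[i][j]
            if st.size:
                # strict half-open bins (np.histogram closes the last bin)
                b = np.floor((st - start) / w_bin).astype(np.int64)
                ok = (b >= 0) & (b < n_bins)
                np.add.at(c[row], b[ok], 1)
        counts.append(c)
    return BinnedCounts(counts, w_bin, windows, spikes.areas[ch_idx],
                        spikes.trial_ids.copy())


WINDOW_SPECS = ("fixation", "cue_to_dim1", "cue_to_dim2")


def analysis_window(trials: pd.DataFrame, spec: str,
                    cue_offset: float = 400.0,
                    dim_offset: float = 30.0) -> np.ndarray:
    """Per-trial [start, end) analysis windows for a named task period.

    ``fixation``: fixation onset to stimulus onset (no visual drive).
    ``cue_to_dim1``: cue onset + 400 ms to first dimming + 30 ms.
    ``cue_to_dim2``: as above but extended to the second dimming + 30 ms
    (for the behavioral analysis of trials whose target dimmed second).
    """
    if spec not in WINDOW_SPECS:
        raise ValueError(f"unknown window spec {spec!r}; one of {WINDOW_SPECS}")
    need = {"fixation": ["t_fixation", "t_stim_on"],
            "cue_to_dim1": ["t_cue", "t_dim1"],
            "cue_to_dim2": ["t_cue", "t_dim2"]}[spec]
    bad = trials.loc[~np.isfinite(trials[need]).all(axis=1), "trial_id"]
    if len(bad):
        raise ValueError(
            f"window {spec!r}: missing events on trials {list(bad)}")
    if spec == "fixation":
        start = trials["t_fixation"].to_numpy(float)
        end = trials["t_stim_on"].to_numpy(float)
    elif spec == "cue_to_dim1":
        start = trials["t_cue"].to_numpy(float) + cue_offset
        end = trials["t_dim1"].to_numpy(float) + dim_offset
    else:
        start = trials["t_cue"].to_numpy(float) + cue_offset
        end = trials["t_dim2"].to_numpy(float) + dim_offset
    return np.column_stack([start, end])


# ---------------------------------------------------------------------------
# HDF5 bundle I/O

def _write_ragged(grp: h5py.Group, name: str, arrays: Sequence[np.ndarray]) -> None:
    g = grp.create_group(name)
    g.attrs["n"] = len(arrays)
    for i, a in enumerate(arrays):
        g.create_dataset(str(i), data=np.asarray(a))


def _read_ragged(grp: h5py.Group, name: str) -> list[np.ndarray]:
    g = grp[name]
    return [np.asarray(g[str(i)]) for i in range(int(g.attrs["n"]))]


def write_bundle(bundle: SessionBundle, path: str) -> None:
    """Serialize a session to the documented HDF5 layout."""
    with h5py.File(path, "w") as f:
        sp = f.create_group("spikes")
        sp.attrs["areas"] = json.dumps(list(map(str, bundle.spikes.areas)))
        sp.attrs["trial_ids"] = bundle.spikes.trial_ids
        for i, trial in enumerate(bundle.spikes.spikes):
            _write_ragged(sp, f"trial{i}", trial)
        cg = f.create_group("counts")
        for wname, bc in bundle.counts.items():
            g = cg.create_group(wname)
            g.attrs["w_bin"] = bc.w_bin
            g.attrs["areas"] = json.dumps(list(map(str, bc.areas)))
            g.create_dataset("windows", data=bc.windows)
            g.create_dataset("trial_ids", data=bc.trial_ids)
            _write_ragged(g, "counts", bc.counts)
        tg = f.create_group("trials")
        for col in TRIAL_COLUMNS:
            vals = bundle.trials[col]
            if vals.dtype == object:
                tg.create_dataset(col, data=[str(v) for v in vals])
            else:
                tg.create_dataset(col, data=vals.to_numpy(float))
        if bundle.eye is not None:
            eg = f.create_group("eye")
            eg.attrs["fs"] = bundle.eye_fs
            present = [i for i, e in enumerate(bundle.eye) if e is not None]
            eg.attrs["present"] = present
            _write_ragged(eg, "traces", [bundle.eye[i] for i in present])
        if bundle.lfp is not None:
            lg = f.create_group("lfp")
            lg.attrs["fs"] = bundle.lfp.fs
            lg.attrs["reference"] = bundle.lfp.reference
            if bundle.lfp.depth_um is not None:
                lg.create_dataset("depth_um", data=bundle.lfp.depth_um)
            _write_ragged(lg, "data", bundle.lfp.data)
        mg = f.create_group("meta")
        mg.attrs["json"] = json.dumps(bundle.meta, default=_json_fallback)


def _json_fallback(o):
    if isinstance(o, np.ndarray):
        return {"__ndarray__": o.tolist(), "dtype": str(o.dtype)}
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _json_revive(d):
    if isinstance(d, dict):
        if "__ndarray__" in d:
            return np.asarray(d["__ndarray__"], dtype=d["dtype"])
        return {k: _json_revive(v) for k, v in d.items()}
    if isinstance(d, list):
        return [_json_revive(v) for v in d]
    return d


def read_bundle(path: str) -> SessionBundle:
    """Read a session written by :func:`write_bundle`."""
    with h5py.File(path, "r") as f:
        for req in ("spikes", "trials", "meta"):
            if req not in f:
                raise ValueError(f"bundle missing required group /{req}")
        sp = f["spikes"]
        areas = np.array(json.loads(sp.attrs["areas"]), dtype=object)
        trial_ids = np.asarray(sp.attrs["trial_ids"], dtype=int)
        spikes = [ _read_ragged(sp, f"trial{i}") for i in range(len(trial_ids))]
        sts = SpikeTrainSet(spikes, areas, trial_ids)
        counts = {}
        for wname, g in f["counts"].items():
            counts[wname] = BinnedCounts(
                _read_ragged(g, "counts"), float(g.attrs["w_bin"]),
                np.asarray(g["windows"]),
                np.array(json.loads(g.attrs["areas"]), dtype=object),
                np.asarray(g["trial_ids"], dtype=int))
        tg = f["trials"]
        cols = {}
        for col in TRIAL_COLUMNS:
            data = tg[col][()]
            if data.dtype.kind in "SO":
                cols[col] = [v.decode() if isinstance(v, bytes) else v
                             for v in data]
            else:
                cols[col] = data
        trials = pd.DataFrame(cols)
        trials["trial_id"] = trials["trial_id"].astype(int)
        trials["target_dim"] = trials["target_dim"].astype(int)
        trials["target_in_rf"] = trials["target_in_rf"].astype(bool)
        eye = None
        eye_fs = 220.0
        if "eye" in f:
            eg = f["eye"]
            eye_fs = float(eg.attrs["fs"])
            present = list(np.asarray(eg.attrs["present"], dtype=int))
            traces = _read_ragged(eg, "traces")
            eye = [None] * len(trial_ids)
            for i, tr in zip(present, traces):
                eye[i] = tr
        lfp = None
        if "lfp" in f:
            lg = f["lfp"]
            lfp = LfpArray(_read_ragged(lg, "data"), float(lg.attrs["fs"]),
                           str(lg.attrs["reference"]),
                           np.asarray(lg["depth_um"]) if "depth_um" in lg else None)
        meta = _json_revive(json.loads(f["meta"].attrs["json"]))
    return SessionBundle(sts, make_trial_table(trials), counts, eye, eye_fs,
                         lfp, meta)
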