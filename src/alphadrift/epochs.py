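"""Epoched EEG container and on-disk fixture format.

The pipeline consumes artifact-free epochs; preprocessing (filtering,
artifact rejection, re-referencing) happens upstream and is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EpochSet", "save_epochs", "load_epochs"]


@dataclass
class EpochSet:
    """Epoched multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_trials, n_samples)
        Epoch voltages (arbitrary units; downstream analyses z-score).
    fs_hz : float
        Sampling rate in Hz.
    times : ndarray, shape (n_samples,)
        Time axis in seconds relative to nominal stimulus onset.  The
        pre-stimulus baseline is the half-open interval [-1, 0).
    trial_order : ndarray, shape (n_trials,)
        Acquisition order (1..N), strictly ascending.  Trials may have been
        rejected upstream, so the sequence need not be contiguous.
    ch_names : list of str
    ch_pos : ndarray, shape (n_channels, 3)
        Electrode positions in centimetres (used for the spatial
        neighbourhood of the cluster test).
    """

    data: np.ndarray
    fs_hz: float
    times: np.ndarray
    trial_order: np.ndarray
    ch_names: list[str] = field(default_factory=list)
    ch_pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.trial_order = np.asarray(self.trial_order)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_channels, n_trials, n_samples)")
        nc, nt, ns = self.data.shape
        if self.times.shape != (ns,):
            raise ValueError("times length must match n_samples")
        if self.trial_order.shape != (nt,):
            raise ValueError("trial_order length must match n_trials")
        if np.any(np.diff(self.trial_order) <= 0):
            raise ValueError("trial_order must be strictly ascending")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not self.ch_names:
            self.ch_names = [f"E{i + 1:02d}" for i in range(nc)]
        if len(self.ch_names) != nc:
            raise ValueError("ch_names length must match n_channels")
        if self.ch_pos is not None:
            self.ch_pos = np.asarray(self.ch_pos, dtype=float)
            if self.ch_pos.shape[0] != nc:
                raise ValueError("ch_pos rows must match n_channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def sample_mask(self, tmin: float, tmax: float) -> np.ndarray:
        """Boolean mask of samples with tmin <= t < tmax."""
        return (self.times >= tmin) & (self.times < tmax)

    def baseline_mask(self) -> np.ndarray:
        """Samples in the pre-stimulus baseline [-1, 0) s."""
        return self.sample_mask(-1.0, 0.0)

    def baseline(self) -> np.ndarray:
        """Baseline voltages, shape (n_channels, n_trials, n_baseline)."""
        m = self.baseline_mask()
        if not m.any():
            raise ValueError("epoch time axis does not cover the [-1, 0) s baseline")
        return self.data[:, :, m]

    def select_trials(self, idx: np.ndarray) -> "EpochSet":
        """Return a copy restricted to the given trial indices (positional)."""
        idx = np.asarray(idx)
        order = np.argsort(self.trial_order[idx])
        idx = idx[order]
        return EpochSet(
            data=self.data[:, idx, :],
            fs_hz=self.fs_hz,
            times=self.times.copy(),
            trial_order=self.trial_order[idx],
            ch_names=list(self.ch_names),
            ch_pos=None if self.ch_pos is None else self.ch_pos.copy(),
        )


def save_epochs(epochs: EpochSet, out_dir: str | Path, ground_truth: dict | None = None) -> Path:
    """Write an EpochSet as ``epochs.npz`` + ``trials.tsv`` (+ optional JSON sidecar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out_dir / "epochs.npz",
        data=epochs.data,
        fs_hz=epochs.fs_hz,
        times=epochs.times,
        trial_order=epochs.trial_order,
        ch_names=np.array(epochs.ch_names),
        ch_pos=np.zeros((0, 3)) if epochs.ch_pos is None else epochs.ch_pos,
    )
    with open(out_dir / "trials.tsv", "w") as fh:
        fh.write("trial_order\n")
        for t in epochs.trial_order:
            fh.write(f"{int(t)}\n")
    if ground_truth is not None:
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(ground_truth, fh, indent=1, default=_jsonify)
    return out_dir


def load_epochs(in_dir: str | Path) -> EpochSet:
    """Load an EpochSet written by :func:`save_epochs`."""
    in_dir = Path(in_dir)
    with np.load(in_dir / "epochs.npz", allow_pickle=False) as z:
        ch_pos = z["ch_pos"]
        return EpochSet(
            data=z["data"],
            fs_hz=float(z["fs_hz"]),
            times=z["times"],
            trial_order=z["trial_order"],
            ch_names=[str(c) for c in z["ch_names"]],
            ch_pos=None if ch_pos.size == 0 else ch_pos,
        )


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
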