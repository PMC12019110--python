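"""Multi-trial region-of-interest time series: container, preprocessing, text I/O.

The container holds a ``(trial, time, node)`` array of BOLD-like signals.
Preprocessing follows the standard resting-state convention: per-series
z-scoring followed by a zero-phase Butterworth band-pass filter (default
band 0.008-0.08 Hz at the scanner's sampling interval).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal


@dataclasses.dataclass
class RoiTimeSeriesSet:
    """Multi-trial, multi-node time-series container.

    Parameters
    ----------
    values : ndarray of shape (n_trials, n_time, n_nodes)
        Signal values; dimensionless after z-scoring.
    node_labels : list of str
        One label per node (column).
    sampling_interval : float
        Seconds per frame (TR).
    preprocessed : bool
        True once :func:`preprocess_timeseries` has been applied.
    """

    values: np.ndarray
    node_labels: list[str]
    sampling_interval: float
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"values must be (trial, time, node), got shape {self.values.shape}"
            )
        if self.values.shape[2] != len(self.node_labels):
            raise ValueError(
                f"{self.values.shape[2]} columns but {len(self.node_labels)} labels"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("time series contain non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[2]

    def node_index(self, label: str) -> int:
        return self.node_labels.index(label)

    def series(self, label: str) -> np.ndarray:
        """All trials of one node, shape (n_trials, n_time)."""
        return self.values[:, :, self.node_index(label)]


def zscore(ts: RoiTimeSeriesSet) -> RoiTimeSeriesSet:
    """Z-score every (trial, node) series independently.

    Raises if any series is constant, naming the offending trial and node.
    """
    v = ts.values
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    bad = np.argwhere(sd[:, 0, :] == 0.0)
    if bad.size:
        t, n = bad[0]
        raise ValueError(
            f"constant series: trial {t}, node {ts.node_labels[n]!r} has zero variance"
        )
    return dataclasses.replace(ts, values=(v - mean) / sd)


def bandpass_sos(
    low_hz: float, high_hz: float, order: int, sampling_interval: float
) -> np.ndarray:
    """Second-order-sections Butterworth band-pass design with validation."""
    nyquist = 0.5 / sampling_interval
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist:.6g} Hz)"
        )
    return signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / sampling_interval,
        output="sos",
    )


def preprocess_timeseries(
    raw: RoiTimeSeriesSet,
    low_hz: float = 0.008,
    high_hz: float = 0.08,
    filter_order: int = 2,
) -> RoiTimeSeriesSet:
    """Z-score each series, then apply a zero-phase Butterworth band-pass.

    Zero-phase filtering (forward-backward, ``sosfiltfilt``) avoids phase
    distortion that would bias lagged regression estimates.
    """
    zs = zscore(raw)
    sos = bandpass_sos(low_hz, high_hz, filter_order, raw.sampling_interval)
    filtered = signal.sosfiltfilt(sos, zs.values, axis=1)
    return dataclasses.replace(zs, values=np.ascontiguousarray(filtered), preprocessed=True)


# ---------------------------------------------------------------------------
# delimited-text I/O: frames as rows, nodes as columns, header of node labels
# ---------------------------------------------------------------------------

def write_timeseries(
    ts: RoiTimeSeriesSet, path: str | Path, trial_column: str = "trial", sep: str = "\t"
) -> None:
    """Write all trials to one delimited file with a trial-ID column."""
    frames = []
    for t in range(ts.n_trials):
        df = pd.DataFrame(ts.values[t], columns=ts.node_labels)
        df.insert(0, trial_column, t)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_timeseries(
    paths: Sequence[str | Path] | str | Path,
    sampling_interval: float,
    trial_column: str = "trial",
    sep: str = "\t",
    preprocessed: bool = False,
) -> RoiTimeSeriesSet:
    """Read trials either from one file with a trial-ID column or one file per trial."""
    if isinstance(paths, (str, Path)):
        df = pd.read_csv(paths, sep=sep, float_precision="round_trip")
        if trial_column in df.columns:
            labels = [c for c in df.columns if c != trial_column]
            trials = [g[labels].to_numpy(float) for _, g in df.groupby(trial_column, sort=True)]
        else:
            labels = list(df.columns)
            trials = [df.to_numpy(float)]
    else:
        dfs = [pd.read_csv(p, sep=sep, float_precision="round_trip") for p in paths]
        labels = list(dfs[0].columns)
        for i, d in enumerate(dfs[1:], 1):
            if list(d.columns) != labels:
                raise ValueError(f"trial file {i} has mismatched node labels")
        trials = [d.to_numpy(float) for d in dfs]
    lengths = {t.shape[0] for t in trials}
    if len(lengths) != 1:
        raise ValueError(f"trials have unequal lengths: {sorted(lengths)}")
    return RoiTimeSeriesSet(
        values=np.stack(trials), node_labels=[str(c) for c in labels],
        sampling_interval=sampling_interval, preprocessed=preprocessed,
    )
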