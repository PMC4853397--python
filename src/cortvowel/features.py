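"""EEG preprocessing (45 Hz low-pass, epoching) and classifier features.

Classifier features are 8-sample bin means over the 1.0-2.0 s post-onset
window: at 256 Hz that window holds 256 samples, so every channel (sensor or
reconstructed vertex) contributes exactly 32 time-point features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import InvalidConfigurationError, InvalidInputError
from .simulate import EpochedEEG

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Trials x features with per-feature names 'channel:bin'."""

    X: np.ndarray
    names: list[str]
    labels: np.ndarray
    channel_kind: str = "sensor"   # or "vertex"

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def lowpass_filter(data: np.ndarray, fs: float, cutoff: float = 45.0,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis."""
    sos = signal.butter(order, cutoff, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def preprocess_eeg(
    data,
    fs: float = 256.0,
    onsets=None,
    labels=None,
    sensor_names=None,
    cutoff: float = 45.0,
    pre_onset_s: float = 1.0,
    post_onset_s: float = 3.0,
) -> EpochedEEG:
    """Low-pass filter at 45 Hz and cut [-1, 3] s epochs around onsets.

    ``data`` is either continuous (sensors x samples, with ``onsets`` sample
    indices and per-onset ``labels``) or an `EpochedEEG`, in which case only
    the filter is applied. Epochs exceeding the data bounds are skipped with a
    logged warning.
    """
    if fs != 256.0:
        warnings.warn(f"sampling rate {fs} differs from the 256 Hz design",
                      RuntimeWarning, stacklevel=2)
    if isinstance(data, EpochedEEG):
        out = lowpass_filter(data.data, data.fs, cutoff)
        return EpochedEEG(out, data.labels.copy(), data.fs, data.onset_index,
                          data.sensor_names)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise InvalidInputError("continuous data must be sensors x samples")
    if onsets is None or labels is None:
        raise InvalidInputError("continuous data requires onsets and labels")
    filtered = lowpass_filter(data, fs, cutoff)
    pre = int(round(pre_onset_s * fs))
    post = int(round(post_onset_s * fs))
    epochs, kept = [], []
    skipped = 0
    for onset, lab in zip(onsets, labels):
        s0, s1 = onset - pre, onset + post
        if s0 < 0 or s1 > data.shape[1]:
            skipped += 1
            continue
        epochs.append(filtered[:, s0:s1])
        kept.append(lab)
    if skipped:
        logger.warning("skipped %d epochs exceeding data bounds", skipped)
    if not epochs:
        raise InvalidInputError("no epochs within data bounds")
    return EpochedEEG(np.stack(epochs), np.asarray(kept), fs, pre, sensor_names)


def extract_features(
    data,
    labels=None,
    fs: float = 256.0,
    onset_index: int | None = None,
    window=(1.0, 2.0),
    bin_size: int = 8,
    channel_names=None,
    channel_kind: str = "sensor",
    sliding: bool = False,
) -> FeatureMatrix:
    """Bin-mean features over the classification window.

    ``data`` is an `EpochedEEG` or a (trials, channels, samples) array of
    reconstructed currents (then ``onset_index`` is relative to the array's
    first sample). The window is reduced per channel to non-overlapping
    ``bin_size``-sample means; with ``sliding=True`` a non-decimating moving
    average is taken instead (same feature count via stride ``bin_size``).
    """
    if isinstance(data, EpochedEEG):
        labels = data.labels if labels is None else labels
        fs = data.fs
        onset_index = data.onset_index
        channel_names = channel_names or data.sensor_names
        arr = data.data
    else:
        arr = np.asarray(data, dtype=float)
        if onset_index is None:
            raise InvalidInputError("array input requires onset_index")
    if arr.ndim != 3:
        raise InvalidInputError("expected trials x channels x samples")
    s0 = onset_index + int(round(window[0] * fs))
    s1 = onset_index + int(round(window[1] * fs))
    if s0 < 0 or s1 > arr.shape[2]:
        raise InvalidConfigurationError("feature window not covered by the data")
    n_win = s1 - s0
    if n_win % bin_size:
        raise InvalidConfigurationError(
            f"window length {n_win} not divisible by bin size {bin_size}"
        )
    seg = arr[:, :, s0:s1]
    n_trials, n_chan, _ = seg.shape
    n_bins = n_win // bin_size
    if sliding:
        kern = np.ones(bin_size) / bin_size
        sm = signal.convolve(
            seg, kern[None, None, :], mode="full")[:, :, bin_size - 1:n_win]
        feats = sm[:, :, ::bin_size][:, :, :n_bins]
    else:
        feats = seg.reshape(n_trials, n_chan, n_bins, bin_size).mean(axis=3)
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_chan)]
    names = [f"{ch}:{b}" for ch in channel_names for b in range(n_bins)]
    X = feats.reshape(n_trials, n_chan * n_bins)
    labels = np.asarray(labels) if labels is not None else np.array([""] * n_trials)
    return FeatureMatrix(X=X, names=names, labels=labels, channel_kind=channel_kind)


class FeatureScaler:
    """Standardize features with training-set statistics (zero mean, unit SD)."""

    def __init__(self):
        self.mean_ = None
        self.std_ = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        self.std_ = np.where(std > 0, std, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.std_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
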