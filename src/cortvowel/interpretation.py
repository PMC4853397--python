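"""Classifier-weight interpretation and seed-based correlation connectivity.

Weight maps normalize each cross-validation fold's classifier weights by the
fold's maximum absolute weight, then average the 32 time-bin values per
channel, giving per-channel contributions in [0, 1] that are comparable across
folds. Channels that are both frequently selected (unpruned) across folds and
carry high mean weight are the FSHV channels; their task-conditioned mean time
courses seed the Pearson-correlation connectivity maps thresholded at |CC| > 0.6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError
from .smlr import SMLRResults

logger = logging.getLogger(__name__)


@dataclass
class WeightMap:
    """Per-fold, per-class, per-channel normalized weight summaries."""

    norm_weight: np.ndarray     # (n_folds, n_classes, n_channels), in [0, 1]
    selected: np.ndarray        # bool, same shape: channel had unpruned weight
    channel_names: list[str]
    classes: np.ndarray

    @property
    def n_folds(self) -> int:
        return self.norm_weight.shape[0]

    def mean_weight(self, class_idx: int | None = None) -> np.ndarray:
        """Across-fold mean channel weight; max over classes when class_idx is None."""
        m = self.norm_weight.mean(axis=0)      # (classes, channels)
        return m.max(axis=0) if class_idx is None else m[class_idx]

    def selection_count(self, class_idx: int | None = None) -> np.ndarray:
        s = self.selected.any(axis=1) if class_idx is None else self.selected[:, class_idx]
        return s.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        mean = self.norm_weight.mean(axis=0)
        for ci, cls in enumerate(self.classes):
            for ch, name in enumerate(self.channel_names):
                rows.append(
                    {"class": cls, "channel": name,
                     "mean_weight": mean[ci, ch],
                     "selection_count": int(self.selected[:, ci, ch].sum())}
                )
        return pd.DataFrame(rows)


@dataclass
class ConnectivityMap:
    """Pearson correlations between channel mean time courses, with seed edges."""

    cc: np.ndarray
    channel_names: list[str]
    seeds: list[int]
    threshold: float
    edges: list = field(default_factory=list)   # (seed, channel, sign)
    zero_variance: np.ndarray | None = None

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"node_i": self.channel_names[i], "node_j": self.channel_names[j],
                 "cc": self.cc[i, j]}
                for i, j, _ in self.edges
            ]
        )


def weight_maps(models: list[SMLRResults], channel_names: list[str],
                n_bins: int = 32) -> WeightMap:
    """Fold-normalized mean absolute weights per channel.

    Each fold's feature weights (bias excluded) are divided by the fold's
    maximum absolute weight; the ``n_bins`` time-bin values per channel are
    then averaged (of absolute values, so negative weights contribute
    comparably). A fold whose weights are all zero yields an all-zero map and
    is flagged with a log message.
    """
    if not models:
        raise InvalidInputError("no models given")
    n_channels = len(channel_names)
    classes = models[0].classes
    n_classes = classes.size
    norm = np.zeros((len(models), n_classes, n_channels))
    selected = np.zeros((len(models), n_classes, n_channels), dtype=bool)
    for f, m in enumerate(models):
        Wf = m.weights[:, :-1]
        if Wf.shape != (n_classes, n_channels * n_bins):
            raise InvalidInputError(
                f"fold {f}: expected {n_channels}x{n_bins} features per class, "
                f"got {Wf.shape[1]}"
            )
        wmax = np.abs(Wf).max()
        if wmax == 0:
            logger.warning("fold %d has all-zero weights; map left at zero", f)
            continue
        Wn = np.abs(Wf) / wmax
        norm[f] = Wn.reshape(n_classes, n_channels, n_bins).mean(axis=2)
        selected[f] = m.active_mask[:, :-1].reshape(
            n_classes, n_channels, n_bins
        ).any(axis=2)
    return WeightMap(norm, selected, list(channel_names), classes)


def select_fshv(weight_map: WeightMap, min_freq: float = 0.8,
                top_quantile: float = 0.1, class_idx: int | None = None) -> list[int]:
    """Frequently selected channels with high mean weight.

    Channels selected in at least ``min_freq`` of folds AND whose mean
    normalized weight lies in the top ``top_quantile`` of all channels. May be
    empty (returned as such with a log note).
    """
    if not (0 < min_freq <= 1 and 0 < top_quantile <= 1):
        raise InvalidInputError("fractions must be in (0, 1]")
    freq = weight_map.selection_count(class_idx) / weight_map.n_folds
    mean_w = weight_map.mean_weight(class_idx)
    cutoff = np.quantile(mean_w, 1 - top_quantile)
    out = [
        int(ch)
        for ch in np.flatnonzero((freq >= min_freq) & (mean_w >= cutoff))
        if mean_w[ch] > 0
    ]
    if not out:
        logger.info("no channel met the FSHV criteria")
    return out


def roi_aggregate(weight_map: WeightMap, roi_labels, all_rois=None) -> pd.DataFrame:
    """Mean channel weight per ROI (one row per ROI; empty ROIs get NaN)."""
    roi_labels = np.asarray(roi_labels)
    if roi_labels.size != len(weight_map.channel_names):
        raise InvalidInputError("every channel needs a ROI label")
    if any(lab is None or lab == "" for lab in roi_labels.tolist()):
        raise InvalidInputError("unlabeled channel")
    mean_w = weight_map.mean_weight()
    if all_rois is None:
        _, first = np.unique(roi_labels, return_index=True)
        all_rois = roi_labels[np.sort(first)]
    rows = []
    for roi in all_rois:
        members = np.flatnonzero(roi_labels == roi)
        rows.append(
            {"roi": roi,
             "mean_weight": float(mean_w[members].mean()) if members.size else np.nan,
             "n_channels": int(members.size)}
        )
    return pd.DataFrame(rows)


def connectivity_map(
    currents: np.ndarray,
    labels,
    task: str,
    seeds,
    channel_names: list[str] | None = None,
    threshold: float = 0.6,
) -> ConnectivityMap:
    """All-pair Pearson correlations of task-conditioned mean time courses.

    ``currents`` is (trials, channels, samples). The signal per channel is the
    across-trial mean time course over the trials of ``task``; edges connect
    each seed to channels with |CC| above the threshold. Channels with zero
    variance get CC = 0 (flagged), not NaN.
    """
    currents = np.asarray(currents, dtype=float)
    labels = np.asarray(labels)
    if currents.ndim != 3:
        raise InvalidInputError("currents must be trials x channels x samples")
    if currents.shape[2] < 3:
        raise InvalidInputError("need >= 3 time samples")
    sel = labels == task
    if not sel.any():
        raise InvalidInputError(f"no trials with task {task!r}")
    sig = currents[sel].mean(axis=0)           # (channels, samples)
    n_chan = sig.shape[0]
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_chan)]
    sd = sig.std(axis=1)
    zero_var = sd == 0
    centered = sig - sig.mean(axis=1, keepdims=True)
    denom = np.where(zero_var, 1.0, sd) * np.sqrt(sig.shape[1])
    normed = centered / denom[:, None]
    cc = normed @ normed.T
    cc[zero_var, :] = 0.0
    cc[:, zero_var] = 0.0
    np.fill_diagonal(cc, np.where(zero_var, 0.0, 1.0))
    cc = np.clip(cc, -1.0, 1.0)
    edges = []
    for s in seeds:
        for j in range(n_chan):
            if j != s and abs(cc[s, j]) > threshold:
                edges.append((int(s), int(j), int(np.sign(cc[s, j]))))
    return ConnectivityMap(cc, list(channel_names), list(seeds), threshold,
                           edges, zero_variance=zero_var)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided p from t = r sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidInputError("need equal-length 1-D vectors with >= 3 values")
    if x.std() == 0 or y.std() == 0:
        raise InvalidInputError("zero variance input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    n = x.size
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * float(stats.t.sf(abs(t), n - 2))
    return r, p
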