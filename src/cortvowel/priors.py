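"""fMRI priors: thresholded t-maps, contrast merging, group/LOO-group variants.

An *area* prior is the vertex subset whose currents will be estimated; an
*activity* prior assigns each area vertex a normalized value in (0, 1] that
scales its prior current variance. Both come from one-sided thresholding of a
t-contrast map at an uncorrected p-value, and the two direction-specific
contrasts (/a/ > /i/ and /i/ > /a/) are merged by union/maximum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InvalidConfigurationError, InvalidInputError
from .glm import TMap

#: Named prior conditions and their uncorrected thresholds (area, activity).
CONDITION_THRESHOLDS = {
    "Unc0001": (0.001, 0.001),
    "Unc0005": (0.005, 0.005),
    "Unc001": (0.01, 0.01),
    "Unc005": (0.05, 0.05),
    "Unc01": (0.1, 0.1),
    "Group": (0.01, 0.01),
    "LOOgroup": (0.01, 0.01),
    "RandLOOgroup": (0.01, 0.01),
}


@dataclass
class PriorSet:
    """Area + activity prior for one named condition.

    ``activity`` is aligned with ``area`` (one value per area vertex), lies in
    [0, 1] and attains 1 when the area is non-empty. ``RandLOOgroup`` carries
    the LOOgroup prior unchanged; the label randomization happens during
    classifier training, not here.
    """

    condition: str
    area: np.ndarray              # sorted vertex ids
    activity: np.ndarray          # values on area vertices
    p_area: float
    p_activity: float
    n_vertices: int               # size of the vertex space the ids index into

    def __post_init__(self):
        self.area = np.asarray(self.area, dtype=int)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.area.size != self.activity.size:
            raise InvalidInputError("area and activity must align")
        if self.area.size and not (
            self.activity.min() >= 0 and abs(self.activity.max() - 1) < 1e-9
        ):
            raise InvalidInputError("activity must lie in [0,1] with max 1")

    @property
    def n_area(self) -> int:
        return self.area.size

    def activity_full(self) -> np.ndarray:
        """Activity expanded to the full vertex space (zeros off-area)."""
        full = np.zeros(self.n_vertices)
        full[self.area] = self.activity
        return full

    def to_json(self) -> str:
        return json.dumps(
            {
                "condition": self.condition,
                "p_area": self.p_area,
                "p_activity": self.p_activity,
                "n_vertices": self.n_vertices,
                "area": self.area.tolist(),
                "activity": self.activity.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PriorSet":
        d = json.loads(text)
        return cls(d["condition"], np.array(d["area"]), np.array(d["activity"]),
                   d["p_area"], d["p_activity"], d["n_vertices"])


def threshold_tmap(tmap: TMap, p_uncorrected: float) -> tuple[np.ndarray, np.ndarray]:
    """Keep vertices with t above the upper-tail Student-t critical value.

    Returns (vertex ids, activity) with activity t_v / max kept t, so the
    normalization is scale invariant. An empty result is a warning, not an
    error; downstream stages must handle it.
    """
    if not 0 < p_uncorrected < 1:
        raise InvalidConfigurationError(f"p must be in (0,1), got {p_uncorrected}")
    crit = stats.t.ppf(1 - p_uncorrected, tmap.df)
    keep = np.flatnonzero(tmap.t > crit)
    if keep.size == 0:
        warnings.warn(
            f"no vertex exceeds t({tmap.df}) critical value {crit:.3f} at "
            f"p={p_uncorrected}; empty prior",
            RuntimeWarning,
            stacklevel=2,
        )
        return keep, np.array([])
    activity = tmap.t[keep] / tmap.t[keep].max()
    return keep, activity


def prior_from_tmap(tmap: TMap, p: float, condition: str, n_vertices: int) -> PriorSet:
    area, act = threshold_tmap(tmap, p)
    return PriorSet(condition, area, act, p, p, n_vertices)


def merge_contrast_priors(prior_a_gt_i: PriorSet, prior_i_gt_a: PriorSet) -> PriorSet:
    """Union of the two direction-specific areas; per-vertex max activity, remaxed."""
    a, b = prior_a_gt_i, prior_i_gt_a
    if a.n_vertices != b.n_vertices:
        raise InvalidInputError("priors live in different vertex spaces")
    if (a.p_area, a.p_activity) != (b.p_area, b.p_activity):
        raise InvalidInputError("priors were thresholded at different p-values")
    full = np.maximum(a.activity_full(), b.activity_full())
    area = np.flatnonzero(full > 0)
    activity = full[area]
    if area.size:
        activity = activity / activity.max()
    return PriorSet(a.condition, area, activity, a.p_area, a.p_activity, a.n_vertices)


def make_group_priors(
    subject_effect_maps: np.ndarray,
    mode: str = "Group",
    held_out: int | None = None,
    p: float = 0.01,
) -> PriorSet:
    """One-sample t across subjects' contrast effects, thresholded as a prior.

    ``subject_effect_maps`` is (n_subjects, n_vertices). ``LOOgroup`` excludes
    the held-out subject before the t-test. Vertices with zero across-subject
    variance are excluded with a warning.
    """
    maps = np.asarray(subject_effect_maps, dtype=float)
    if maps.ndim != 2:
        raise InvalidInputError("subject_effect_maps must be 2-D (subjects x vertices)")
    if mode not in ("Group", "LOOgroup"):
        raise InvalidConfigurationError(f"unknown group prior mode {mode!r}")
    if mode == "LOOgroup":
        if held_out is None:
            raise InvalidConfigurationError("LOOgroup requires a held-out subject id")
        maps = np.delete(maps, held_out, axis=0)
    n = maps.shape[0]
    if n < 2:
        raise InvalidConfigurationError(f"need >= 2 subjects after exclusion, got {n}")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} vertices with zero across-subject variance "
            "excluded from the group t-map",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, -np.inf, mean / (sd / np.sqrt(n)))
    tmap = TMap(contrast=f"group_{mode}", t=t, df=n - 1)
    area, act = threshold_tmap(tmap, p)
    return PriorSet(mode, area, act, p, p, maps.shape[1])
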