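"""Seeded synthetic experiments: source space, lead field, EEG epochs, BOLD runs.

The generator produces data with the statistical structure the downstream
analysis assumes: a cortical source space of radial dipoles on a sphere, an
analytic homogeneous-medium lead field, class-dependent oscillatory current
bursts on small active vertex sets riding on AR(1) background activity, and
event-related BOLD series whose task effects mirror the class-dependent
sources. Three tasks are simulated throughout: covert /a/, covert /i/ and a
no-imagery control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateGeometryError,
    InvalidConfigurationError,
    InvalidInputError,
)
from .layout import sensor_positions

TASKS = ("A", "I", "CTRL")

#: The 30 anatomical regions used for weight aggregation: left/right
#: superior/middle/inferior frontal gyri, primary motor, premotor, primary
#: somatosensory, superior/inferior parietal lobules, primary auditory,
#: superior/middle/inferior temporal gyri, cingulate, hippocampus, occipital.
ROI_NAMES_30: list[str] = [
    f"{hemi}-{roi}"
    for roi in (
        "SFG", "MFG", "IFG", "M1", "PM", "S1", "SPL", "IPL",
        "Aud", "STG", "MTG", "ITG", "CG", "Hip", "OcG",
    )
    for hemi in ("L", "R")
]


@dataclass
class SourceModel:
    """Cortical source space: dipole positions/orientations, ROI labels, lead field."""

    vertex_positions: np.ndarray      # (n_vertices, 3), radius <= 0.9
    vertex_orientations: np.ndarray   # (n_vertices, 3), unit norm
    roi_labels: np.ndarray            # (n_vertices,) strings, <= 30 distinct
    lead_field: np.ndarray | None = None  # (n_sensors, n_vertices), avg-referenced
    sensor_names: list[str] | None = None

    @property
    def n_vertices(self) -> int:
        return self.vertex_positions.shape[0]


@dataclass
class GroundTruth:
    """True generative state of a synthetic experiment.

    ``active_sets`` maps each task label to the vertex indices carrying its
    class waveform (empty for the control task). ``fmri_betas`` maps each task
    to per-vertex BOLD effect sizes. ``snr`` is the sensor-level
    signal-to-noise power ratio requested for the EEG simulation.
    """

    active_sets: dict[str, np.ndarray]
    fmri_betas: dict[str, np.ndarray]
    snr: float = 5.0
    source_amplitude: float = 1.0
    waveform_freqs: dict[str, float] = field(
        default_factory=lambda: {"A": 10.0, "I": 20.0}
    )

    def __post_init__(self):
        self.active_sets = {
            k: np.asarray(v, dtype=int) for k, v in self.active_sets.items()
        }
        self.active_sets.setdefault("CTRL", np.array([], dtype=int))
        if self.active_sets["CTRL"].size:
            raise InvalidConfigurationError("control task must have an empty active set")
        if not self.snr > 0:
            raise InvalidConfigurationError(f"snr must be positive, got {self.snr}")


@dataclass
class EpochedEEG:
    """Epoched sensor data: trials x sensors x samples with task labels."""

    data: np.ndarray          # (n_trials, n_sensors, n_samples)
    labels: np.ndarray        # (n_trials,) in TASKS
    fs: float = 256.0
    onset_index: int = 256    # stimulus onset sample (1 s pre-onset)
    sensor_names: list[str] | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return (np.arange(self.n_samples) - self.onset_index) / self.fs


@dataclass
class BoldSeries:
    """Per-vertex BOLD volumes from an event-related design."""

    data: np.ndarray                      # (n_volumes, n_vertices)
    tr: float = 3.0
    events: list | None = None            # (task, onset_s, duration_s) tuples
    n_runs: int = 3
    run_index: np.ndarray | None = None   # (n_volumes,) run of each volume

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]


@dataclass
class ExperimentDesign:
    """EEG epoch design: 50 trials per task, 4-s epochs at 256 Hz."""

    n_trials_per_task: int = 50
    fs: float = 256.0
    pre_onset_s: float = 1.0
    post_onset_s: float = 3.0
    burst_center_s: float = 1.5
    burst_sigma_s: float = 0.15
    background_ar: float = 0.95
    background_std: float = 1.0


@dataclass
class FmriDesign:
    """Event-related BOLD design: 3 runs x 10 trials/task, TR = 3 s."""

    n_runs: int = 3
    trials_per_task_per_run: int = 10
    tr: float = 3.0
    pre_task_s: float = 1.0
    task_s: float = 3.0
    rest_options_s: tuple = (4.0, 6.0, 10.0)
    tail_s: float = 12.0
    noise_std: float = 1.0


def build_source_space(n_vertices: int, n_rois: int = 30, seed: int = 0) -> SourceModel:
    """Quasi-uniform radial dipoles on a sphere of radius 0.8, labelled by ROI.

    Vertices are placed on a Fibonacci lattice with a small seeded angular
    jitter; orientations are radial (outward). ROI labels partition the vertex
    index range contiguously into ``n_rois`` non-empty blocks.
    """
    if n_rois < 1 or n_vertices < n_rois:
        raise InvalidConfigurationError(
            f"need n_vertices >= n_rois >= 1, got {n_vertices}, {n_rois}"
        )
    if n_rois > len(ROI_NAMES_30):
        raise InvalidConfigurationError(f"at most {len(ROI_NAMES_30)} ROIs supported")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_vertices)
    golden = (1 + math.sqrt(5)) / 2
    z = 1 - 2 * (idx + 0.5) / n_vertices
    theta = 2 * math.pi * idx / golden
    # small jitter so distinct seeds give distinct (still quasi-uniform) spaces
    theta = theta + rng.normal(scale=0.01, size=n_vertices)
    z = np.clip(z + rng.normal(scale=0.005, size=n_vertices), -1.0, 1.0)
    r_xy = np.sqrt(1 - z**2)
    unit = np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    positions = 0.8 * unit
    roi_of = np.minimum(idx * n_rois // n_vertices, n_rois - 1)
    labels = np.array([ROI_NAMES_30[r] for r in roi_of])
    return SourceModel(positions, unit.copy(), labels)


def compute_lead_field(
    source: SourceModel,
    sensor_pos: np.ndarray | None = None,
    sensor_names: list[str] | None = None,
    min_distance: float = 0.05,
) -> np.ndarray:
    """Infinite-homogeneous-medium dipole potentials, average-referenced.

    phi(r_s) = q . (r_s - r_v) / (4 pi ||r_s - r_v||^3) for a unit dipole
    moment along the vertex orientation q; the across-sensor mean is then
    subtracted from every column (average reference). The result is stored on
    the source model and returned.
    """
    if sensor_pos is None:
        sensor_names, sensor_pos = sensor_positions()
    sensor_pos = np.asarray(sensor_pos, dtype=float)
    diff = sensor_pos[:, None, :] - source.vertex_positions[None, :, :]  # (s, v, 3)
    dist = np.linalg.norm(diff, axis=2)
    if dist.min() <= min_distance:
        raise DegenerateGeometryError(
            f"sensor-vertex distance {dist.min():.4g} <= {min_distance}"
        )
    num = np.einsum("svk,vk->sv", diff, source.vertex_orientations)
    G = num / (4 * math.pi * dist**3)
    G = G - G.mean(axis=0, keepdims=True)
    source.lead_field = G
    source.sensor_names = sensor_names
    return G


def _class_waveform(times: np.ndarray, freq: float, center: float, sigma: float,
                    amplitude: float) -> np.ndarray:
    """Gaussian-enveloped sinusoidal burst centred at ``center`` s post-onset."""
    env = np.exp(-0.5 * ((times - center) / sigma) ** 2)
    return amplitude * env * np.sin(2 * math.pi * freq * (times - center))


def _balanced_labels(n_per_task: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.repeat(TASKS, n_per_task)
    return labels[rng.permutation(labels.size)]


def simulate_experiment(
    source: SourceModel,
    truth: GroundTruth,
    design: ExperimentDesign | None = None,
    seed: int = 0,
) -> tuple[EpochedEEG, np.ndarray]:
    """Simulate epoched EEG and return it with the true cortical currents.

    Per-trial currents are the task's burst waveform on its active vertex set
    plus AR(1) background activity on all vertices; sensor data are
    ``lead_field @ currents`` plus white sensor noise scaled so that the
    signal-to-noise power ratio over the burst window (1.0-2.0 s post-onset)
    equals ``truth.snr``. Labels are pseudo-randomly ordered and balanced.
    """
    if design is None:
        design = ExperimentDesign()
    if source.lead_field is None:
        raise InvalidInputError("source model has no lead field; call compute_lead_field")
    for task, vs in truth.active_sets.items():
        if vs.size and (vs.min() < 0 or vs.max() >= source.n_vertices):
            raise InvalidInputError(f"active set for {task} outside vertex range")
    rng = np.random.default_rng(seed)
    fs = design.fs
    n_samples = int(round((design.pre_onset_s + design.post_onset_s) * fs))
    onset_index = int(round(design.pre_onset_s * fs))
    times = (np.arange(n_samples) - onset_index) / fs
    labels = _balanced_labels(design.n_trials_per_task, rng)
    n_trials = labels.size
    G = source.lead_field
    n_vertices = source.n_vertices

    currents = np.zeros((n_trials, n_vertices, n_samples))
    # AR(1) background on all vertices, all trials
    if design.background_std > 0:
        innov_std = design.background_std * math.sqrt(1 - design.background_ar**2)
        e = rng.normal(scale=innov_std, size=(n_trials, n_vertices, n_samples))
        e[..., 0] = rng.normal(scale=design.background_std, size=(n_trials, n_vertices))
        bg = np.empty_like(e)
        bg[..., 0] = e[..., 0]
        for s in range(1, n_samples):
            bg[..., s] = design.background_ar * bg[..., s - 1] + e[..., s]
        currents += bg
    for i, lab in enumerate(labels):
        vs = truth.active_sets.get(lab, np.array([], dtype=int))
        if vs.size:
            wf = _class_waveform(
                times, truth.waveform_freqs[lab], design.burst_center_s,
                design.burst_sigma_s, truth.source_amplitude,
            )
            currents[i, vs, :] += wf

    sensors = np.einsum("sv,tvn->tsn", G, currents)
    burst = (times >= 1.0) & (times < 2.0)
    signal_power = float(np.mean(sensors[:, :, burst] ** 2))
    if np.isfinite(truth.snr):
        noise_std = math.sqrt(signal_power / truth.snr) if signal_power > 0 else 0.0
        sensors = sensors + rng.normal(scale=noise_std, size=sensors.shape)
    epochs = EpochedEEG(
        data=sensors, labels=labels, fs=fs, onset_index=onset_index,
        sensor_names=source.sensor_names,
    )
    return epochs, currents


def hrf_double_gamma(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response (peak 6 s, undershoot 16 s, 1:6)."""
    from scipy import stats

    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, a=peak + 1, scale=1.0) - stats.gamma.pdf(
        t, a=undershoot + 1, scale=1.0
    ) / ratio
    h[t < 0] = 0.0
    return h


def _fmri_schedule(design: FmriDesign, rng: np.random.Generator):
    """Event schedule for one run: tasks and rests permuted over trial triples."""
    events = []
    t = 0.0
    n_triples = design.trials_per_task_per_run
    for _ in range(n_triples):
        task_order = [TASKS[j] for j in rng.permutation(3)]
        rests = np.array(design.rest_options_s)[rng.permutation(3)]
        for task, rest in zip(task_order, rests):
            onset = t + design.pre_task_s
            events.append((task, onset, design.task_s))
            t = onset + design.task_s + rest
    return events, t


def simulate_fmri_series(
    source: SourceModel,
    truth: GroundTruth,
    design: FmriDesign | None = None,
    seed: int = 0,
) -> BoldSeries:
    """Per-vertex BOLD series: HRF-convolved task boxcars weighted by betas + noise.

    Each run follows the event-related schedule pre-task 1 s / task 3 s /
    rest in {4, 6, 10} s pseudo-randomly permuted over consecutive trial
    triples, with 10 trials per task per run and 3 runs.
    """
    if design is None:
        design = FmriDesign()
    for task in TASKS:
        if task not in truth.fmri_betas:
            raise InvalidConfigurationError(f"fmri_betas missing task {task}")
        if np.asarray(truth.fmri_betas[task]).shape != (source.n_vertices,):
            raise InvalidConfigurationError(
                f"fmri_betas[{task}] must have one value per vertex"
            )
    rng = np.random.default_rng(seed)
    dt = 0.1
    run_data, all_events, run_idx = [], [], []
    run_offset = 0.0
    for run in range(design.n_runs):
        events, t_end = _fmri_schedule(design, rng)
        total_s = t_end + design.tail_s
        n_vol = int(total_s // design.tr)
        grid = np.arange(0, total_s + dt, dt)
        hrf = hrf_double_gamma(np.arange(0, 32 + dt, dt))
        vol_times = np.arange(n_vol) * design.tr
        regs = {}
        for task in TASKS:
            box = np.zeros_like(grid)
            for ev_task, onset, dur in events:
                if ev_task == task:
                    box[(grid >= onset) & (grid < onset + dur)] = 1.0
            conv = np.convolve(box, hrf)[: grid.size] * dt
            regs[task] = np.interp(vol_times, grid, conv)
        X = np.column_stack([regs[t] for t in TASKS])
        betas = np.column_stack([np.asarray(truth.fmri_betas[t], float) for t in TASKS])
        y = X @ betas.T  # (n_vol, n_vertices)
        if design.noise_std > 0:
            y = y + rng.normal(scale=design.noise_std, size=y.shape)
        run_data.append(y)
        all_events.extend(
            (task, onset + run_offset, dur) for task, onset, dur in events
        )
        run_idx.append(np.full(n_vol, run))
        run_offset += n_vol * design.tr
    return BoldSeries(
        data=np.vstack(run_data), tr=design.tr, events=all_events,
        n_runs=design.n_runs, run_index=np.concatenate(run_idx),
    )


def default_ground_truth(
    source: SourceModel,
    n_active: int = 2,
    snr: float = 5.0,
    beta_scale: float = 3.0,
    overlap: bool = False,
    seed: int = 0,
) -> GroundTruth:
    """Convenience constructor: focal disjoint (or overlapping) active sets.

    The /a/ and /i/ active sets get positive BOLD effects of ``beta_scale`` in
    their own contrast direction so the GLM t-maps point the priors at the
    true sources. Active vertices are drawn from the sensor-covered upper
    cortex (z > 0.1): the montage has no electrodes below the head, and the
    speech-related areas this emulates all lie under it.
    """
    rng = np.random.default_rng(seed)
    n = source.n_vertices
    covered = np.flatnonzero(source.vertex_positions[:, 2] > 0.1 * 0.8)
    if covered.size < 2 * n_active:
        covered = np.arange(n)
    if overlap:
        pick = rng.choice(covered, size=n_active, replace=False)
        sets = {"A": pick, "I": pick.copy()}
    else:
        pick = rng.choice(covered, size=2 * n_active, replace=False)
        sets = {"A": pick[:n_active], "I": pick[n_active:]}
    betas = {t: np.zeros(n) for t in TASKS}
    betas["A"][sets["A"]] = beta_scale
    betas["I"][sets["I"]] = beta_scale
    return GroundTruth(active_sets=sets, fmri_betas=betas, snr=snr)
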