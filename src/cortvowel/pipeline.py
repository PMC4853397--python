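"""End-to-end orchestration: config, run directory, HDF5 bundle round trips.

`run_pipeline` executes simulate -> glm -> priors -> invert -> features ->
decode -> evaluate -> interpret on a synthetic experiment and writes the
reports (CV accuracies, confusion ratios, permutation p, weight/ROI tables,
connectivity edges) plus a stage-timing log into the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import evaluation, features, glm, interpretation, inverse, priors, simulate
from .exceptions import BundleError, InvalidConfigurationError

logger = logging.getLogger(__name__)

BUNDLE_VERSION = 1


@dataclass
class CVConfig:
    n_repeats: int = 1
    n_groups: int = 10
    filter_scope: str = "outer"
    kfold_k: int = 10
    kfold_repeats: int = 5
    smlr_max_iter: int = 30


@dataclass
class RunConfig:
    """Validated, serializable configuration of a full pipeline run."""

    seed: int = 0
    n_vertices: int = 60
    n_rois: int = 30
    n_sensors: int = 32
    n_trials_per_task: int = 20
    n_active: int = 2
    snr: float = 5.0
    beta_scale: float = 3.0
    condition: str = "Unc001"
    p_threshold: float = 0.01
    m0_grid: tuple = (10.0, 100.0, 1000.0)
    gamma0_grid: tuple = (1.0, 10.0, 100.0)
    window_range: tuple = (0.5, 2.5)
    window_s: float = 0.5
    shift_s: float = 0.25
    reduction_ratio: float = 1.0
    n_permutations: int = 0
    cv: CVConfig = field(default_factory=CVConfig)
    out_dir: str = "cortvowel_run"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigurationError(
                f"unknown config keys: {sorted(unknown)}"
            )
        if "cv" in d and isinstance(d["cv"], dict):
            cv_known = {f.name for f in dataclasses.fields(CVConfig)}
            cv_unknown = set(d["cv"]) - cv_known
            if cv_unknown:
                raise InvalidConfigurationError(
                    f"unknown cv config keys: {sorted(cv_unknown)}"
                )
            d["cv"] = CVConfig(**d["cv"])
        for key in ("m0_grid", "gamma0_grid", "window_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InvalidConfigurationError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["m0_grid"] = list(self.m0_grid)
        d["gamma0_grid"] = list(self.gamma0_grid)
        d["window_range"] = list(self.window_range)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def grid(self) -> list[inverse.HyperParams]:
        return [
            inverse.HyperParams(m0, g0)
            for m0 in self.m0_grid
            for g0 in self.gamma0_grid
        ]


@dataclass
class Dataset:
    """One synthetic experiment: source space, truth, EEG, currents, BOLD."""

    source: simulate.SourceModel
    truth: simulate.GroundTruth
    epochs: simulate.EpochedEEG
    currents_true: np.ndarray
    bold: simulate.BoldSeries
    seed: int = 0
    config_hash: str = ""


def make_dataset(config: RunConfig) -> Dataset:
    """Simulate the full experiment described by the config (seeded)."""
    seed = config.seed
    source = simulate.build_source_space(config.n_vertices, config.n_rois, seed)
    simulate.compute_lead_field(source)
    truth = simulate.default_ground_truth(
        source, n_active=config.n_active, snr=config.snr,
        beta_scale=config.beta_scale, seed=seed + 1,
    )
    design = simulate.ExperimentDesign(n_trials_per_task=config.n_trials_per_task)
    epochs, currents = simulate.simulate_experiment(source, truth, design, seed + 2)
    epochs = features.preprocess_eeg(epochs)
    bold = simulate.simulate_fmri_series(source, truth, seed=seed + 3)
    return Dataset(source, truth, epochs, currents, bold, seed=seed,
                   config_hash=config.hash())


def priors_from_dataset(ds: Dataset, config: RunConfig) -> priors.PriorSet:
    """First-level GLM on the BOLD series, both contrasts thresholded and merged."""
    design = glm.design_from_bold(ds.bold)
    tmaps = glm.fit_glm_tmaps(ds.bold, design)
    pa = priors.prior_from_tmap(tmaps["a_gt_i"], config.p_threshold,
                                config.condition, ds.source.n_vertices)
    pi = priors.prior_from_tmap(tmaps["i_gt_a"], config.p_threshold,
                                config.condition, ds.source.n_vertices)
    return priors.merge_contrast_priors(pa, pi)


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute every stage and write reports; returns the in-memory results."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        dt = time.perf_counter() - t0
        log_lines.append(f"{name}: {dt:.2f}s (seed {config.seed})")
        logger.info("stage %s done in %.2fs", name, dt)
        return result

    ds = stage("simulate", lambda: make_dataset(config))
    prior = stage("glm+priors", lambda: priors_from_dataset(ds, config))
    windows = inverse.WindowSpec(config.window_range, config.window_s, config.shift_s)
    reduced = inverse.reduce_dipoles(ds.source, config.reduction_ratio, config.seed)
    pipe = evaluation.DecodingPipeline(
        ds.epochs, ds.source, prior, reduced_ids=reduced, windows=windows,
    )
    smlr_cfg = {"max_iter": config.cv.smlr_max_iter}
    current_report = stage(
        "decode-currents",
        lambda: evaluation.nested_cv(
            pipe, config.grid(), n_groups=config.cv.n_groups,
            n_repeats=config.cv.n_repeats, seed=config.seed,
            filter_scope=config.cv.filter_scope, smlr_config=smlr_cfg,
        ),
    )
    sensor_feats = features.extract_features(ds.epochs)
    sensor_report = stage(
        "decode-sensors",
        lambda: evaluation.repeated_kfold(
            sensor_feats, k=config.cv.kfold_k, repeats=config.cv.kfold_repeats,
            seed=config.seed, smlr_config=smlr_cfg,
        ),
    )
    perm = None
    if config.n_permutations > 0:
        best = current_report.selected[0]
        feats = pipe.current_features(best, np.arange(ds.epochs.n_trials))
        perm = stage(
            "permutation",
            lambda: evaluation.decoding_permutation_test(
                feats, n_perm=config.n_permutations, seed=config.seed,
                observed=current_report.mean,
            ),
        )

    def interpret():
        hyper = current_report.selected[0]
        model = inverse.HierarchicalCurrentModel(
            ds.epochs, ds.source, prior, hyper, windows=windows,
            reduced_ids=reduced,
        )
        res = model.fit()
        currents = res.reconstruct(t_range=config.window_range)
        ch_names = [f"v{v}" for v in res.vertices]
        wmap = interpretation.weight_maps(current_report.models, ch_names)
        fshv = interpretation.select_fshv(wmap)
        roi_table = interpretation.roi_aggregate(
            wmap, ds.source.roi_labels[res.vertices]
        )
        conn = interpretation.connectivity_map(
            currents, ds.epochs.labels, "A", fshv, channel_names=ch_names
        )
        return wmap, fshv, roi_table, conn

    wmap, fshv, roi_table, conn = stage("interpret", interpret)

    report = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "current_accuracy_mean": current_report.mean,
        "current_accuracy_se": current_report.se,
        "sensor_accuracy_mean": sensor_report.mean,
        "sensor_accuracy_se": sensor_report.se,
        "selected_hyperparams": [
            [h.m0, h.gamma0] for h in current_report.selected
        ],
        "confusion_currents": current_report.confusion.tolist(),
        "confusion_sensors": sensor_report.confusion.tolist(),
        "permutation_p": perm.p_value if perm else None,
        "fshv_channels": fshv,
        "n_prior_vertices": int(prior.n_area),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    roi_table.to_csv(out / "roi_weights.csv", index=False)
    wmap.to_frame().to_csv(out / "weight_map.csv", index=False)
    conn.edge_frame().to_csv(out / "connectivity_edges.csv", index=False)
    np.savetxt(out / "current_fold_accuracies.csv",
               current_report.accuracies, delimiter=",", header="accuracy_pct")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "dataset": ds, "prior": prior, "current_report": current_report,
        "sensor_report": sensor_report, "permutation": perm,
        "weight_map": wmap, "fshv": fshv, "roi_table": roi_table,
        "connectivity": conn, "report": report, "out_dir": out,
    }


# ---------------------------------------------------------------- HDF5 bundle


def save_bundle(path, ds: Dataset) -> None:
    """Write a dataset bundle (groups /eeg, /currents_true, /bold, /source_model, /truth)."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = BUNDLE_VERSION
        f.attrs["seed"] = ds.seed
        f.attrs["config_hash"] = ds.config_hash
        g = f.create_group("eeg")
        g.create_dataset("data", data=ds.epochs.data)
        g.create_dataset("labels", data=np.array(ds.epochs.labels, dtype="S"))
        g.attrs["fs"] = ds.epochs.fs
        g.attrs["onset_index"] = ds.epochs.onset_index
        g.create_dataset(
            "sensor_names",
            data=np.array(ds.epochs.sensor_names or [], dtype="S"),
        )
        f.create_dataset("currents_true", data=ds.currents_true)
        g = f.create_group("bold")
        g.create_dataset("data", data=ds.bold.data)
        g.attrs["tr"] = ds.bold.tr
        g.attrs["n_runs"] = ds.bold.n_runs
        g.create_dataset("run_index", data=ds.bold.run_index)
        g.create_dataset(
            "event_tasks", data=np.array([e[0] for e in ds.bold.events], dtype="S")
        )
        g.create_dataset("event_onsets", data=[e[1] for e in ds.bold.events])
        g.create_dataset("event_durations", data=[e[2] for e in ds.bold.events])
        g = f.create_group("source_model")
        g.create_dataset("vertex_positions", data=ds.source.vertex_positions)
        g.create_dataset("vertex_orientations", data=ds.source.vertex_orientations)
        g.create_dataset("roi_labels", data=np.array(ds.source.roi_labels, dtype="S"))
        g.create_dataset("lead_field", data=ds.source.lead_field)
        g.create_dataset(
            "sensor_names", data=np.array(ds.source.sensor_names or [], dtype="S")
        )
        g = f.create_group("truth")
        for task, vs in ds.truth.active_sets.items():
            g.create_dataset(f"active_{task}", data=vs)
        for task, b in ds.truth.fmri_betas.items():
            g.create_dataset(f"beta_{task}", data=b)
        g.attrs["snr"] = ds.truth.snr
        g.attrs["source_amplitude"] = ds.truth.source_amplitude


def load_bundle(path) -> Dataset:
    """Read a bundle back; arrays round-trip bitwise."""
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("version", -1))
            if version != BUNDLE_VERSION:
                raise BundleError(
                    f"bundle version {version} incompatible with {BUNDLE_VERSION}"
                )
            eeg = f["eeg"]
            epochs = simulate.EpochedEEG(
                data=eeg["data"][()],
                labels=eeg["labels"][()].astype(str),
                fs=float(eeg.attrs["fs"]),
                onset_index=int(eeg.attrs["onset_index"]),
                sensor_names=[s.decode() for s in eeg["sensor_names"][()]] or None,
            )
            currents = f["currents_true"][()]
            b = f["bold"]
            bold = simulate.BoldSeries(
                data=b["data"][()], tr=float(b.attrs["tr"]),
                events=list(
                    zip(
                        b["event_tasks"][()].astype(str),
                        b["event_onsets"][()],
                        b["event_durations"][()],
                    )
                ),
                n_runs=int(b.attrs["n_runs"]),
                run_index=b["run_index"][()],
            )
            s = f["source_model"]
            source = simulate.SourceModel(
                vertex_positions=s["vertex_positions"][()],
                vertex_orientations=s["vertex_orientations"][()],
                roi_labels=s["roi_labels"][()].astype(str),
                lead_field=s["lead_field"][()],
                sensor_names=[n.decode() for n in s["sensor_names"][()]] or None,
            )
            t = f["truth"]
            active = {
                k.split("_", 1)[1]: t[k][()] for k in t if k.startswith("active_")
            }
            betas = {
                k.split("_", 1)[1]: t[k][()] for k in t if k.startswith("beta_")
            }
            truth = simulate.GroundTruth(
                active_sets=active, fmri_betas=betas,
                snr=float(t.attrs["snr"]),
                source_amplitude=float(t.attrs["source_amplitude"]),
            )
            return Dataset(
                source, truth, epochs, currents, bold,
                seed=int(f.attrs["seed"]),
                config_hash=str(f.attrs["config_hash"]),
            )
    except BundleError:
        raise
    except (OSError, KeyError) as exc:
        raise BundleError(f"cannot read bundle {path}: {exc}") from exc
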