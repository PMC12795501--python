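"""Readers, writers, configuration and the end-to-end pipelines.

Formats: RDMs as square or vectorized CSV and as JSON; trial tables as
tab-separated text with a mandatory header; epoch sets as HDF5; beta
volumes and statistic maps as NIfTI.  ``run_pipeline`` executes the two
synthetic end-to-end analyses (behavioral-model pipeline and neural
RSA/decoding pipeline) from a validated configuration with explicit
seeds, and writes a machine-readable provenance report.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .rsa import RDM, n_pairs, pair_indices
from .decoding import EpochSet


TRIAL_COLUMNS = ["participant_id", "reference", "intruder", "correct", "rt"]


# ---------------------------------------------------------------------------
# RDMs
# ---------------------------------------------------------------------------


def write_rdm(rdm: RDM, path, form: str = "square") -> None:
    """Write an RDM as CSV ("square" or "vector" form) or JSON."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {"labels": rdm.labels, "values": rdm.values.tolist(), "metric": rdm.metric}
        path.write_text(json.dumps(payload, indent=2))
        return
    if form == "square":
        df = pd.DataFrame(rdm.to_square(), index=rdm.labels, columns=rdm.labels)
        df.to_csv(path, float_format="%.17g")
    elif form == "vector":
        pairs = pair_indices(rdm.n_conditions)
        df = pd.DataFrame(
            {
                "label_a": [rdm.labels[i] for i, _ in pairs],
                "label_b": [rdm.labels[j] for _, j in pairs],
                "dissimilarity": rdm.values,
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError("form must be 'square' or 'vector'")


def read_rdm(path, metric: str | None = None, atol: float = 1e-9) -> RDM:
    """Read an RDM from square CSV, vectorized CSV, or JSON.

    Square input asymmetric beyond ``atol`` is an error; within
    tolerance it is symmetrized.  NaN entries are rejected.
    """
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return RDM(
            labels=payload["labels"],
            values=np.asarray(payload["values"], dtype=float),
            metric=metric or payload.get("metric", "unknown"),
        )
    df = pd.read_csv(path)
    if list(df.columns[:3]) == ["label_a", "label_b", "dissimilarity"]:
        labels = list(dict.fromkeys(list(df["label_a"]) + list(df["label_b"])))
        n = len(labels)
        if len(df) != n_pairs(n):
            raise ValueError(f"vectorized RDM needs {n_pairs(n)} rows for {n} labels")
        sq = np.zeros((n, n))
        for a, b, v in zip(df["label_a"], df["label_b"], df["dissimilarity"]):
            i, j = labels.index(a), labels.index(b)
            sq[i, j] = sq[j, i] = v
        if np.isnan(sq).any():
            raise ValueError("NaN dissimilarities not allowed")
        return RDM.from_square(labels, sq, metric=metric or "unknown")
    df = df.set_index(df.columns[0])
    mat = df.to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("NaN dissimilarities not allowed")
    if not np.allclose(mat, mat.T, atol=atol):
        raise ValueError(f"square RDM asymmetric beyond {atol}")
    return RDM.from_square(list(df.index), 0.5 * (mat + mat.T), metric=metric or "unknown")


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------


def write_trials(trials: pd.DataFrame, path) -> None:
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"missing trial columns: {sorted(missing)}")
    trials[TRIAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table must have a header with columns {TRIAL_COLUMNS}")
    return df


# ---------------------------------------------------------------------------
# epochs (HDF5)
# ---------------------------------------------------------------------------


def write_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("times", data=epochs.times)
        f.attrs["sampling_rate"] = epochs.sampling_rate
        g = f.create_group("metadata")
        for col in epochs.metadata.columns:
            vals = epochs.metadata[col]
            if vals.dtype == object:
                g.create_dataset(
                    col, data=np.array([("" if v is None else str(v)) for v in vals], dtype="S")
                )
            else:
                g.create_dataset(col, data=vals.to_numpy(dtype=float))


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        sfreq = float(f.attrs["sampling_rate"])
        meta = {}
        for col in f["metadata"]:
            arr = f["metadata"][col][()]
            if arr.dtype.kind == "S":
                meta[col] = [v.decode() for v in arr]
            else:
                meta[col] = arr
    df = pd.DataFrame(meta)
    for col in ("run", "block", "within_block_pos"):
        df[col] = df[col].astype(int)
    df["is_oddball"] = df["is_oddball"].astype(bool)
    return EpochSet(data=data, times=times, metadata=df, sampling_rate=sfreq)


# ---------------------------------------------------------------------------
# volumes (NIfTI)
# ---------------------------------------------------------------------------


def write_volume(volume: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


def read_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "stages",
    "bottom_side_length",
    "tolerance",
    "n_participants",
    "n_channels",
    "n_runs",
    "snr",
    "sampling_rate",
    "n_permutations",
    "cluster_forming_alpha",
    "n_subjects",
    "grid",
    "radius_voxels",
    "smooth_fwhm_mm",
}


@dataclass
class PipelineConfig:
    """Validated configuration for ``run_pipeline``; unknown keys rejected."""

    seed: int
    out_dir: str
    stages: list[str] = field(default_factory=lambda: ["behavior", "neural"])
    bottom_side_length: float = 1.0
    tolerance: float = 0.125
    n_participants: int = 50
    n_channels: int = 16
    n_runs: int = 8
    snr: float = 0.5
    sampling_rate: float = 125.0
    n_permutations: int = 1024
    cluster_forming_alpha: float = 0.05
    n_subjects: int = 6
    grid: tuple = (16, 16, 16)
    radius_voxels: float = 3.0
    smooth_fwhm_mm: float = 0.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d or "out_dir" not in d:
            raise ValueError("config requires explicit 'seed' and 'out_dir'")
        d = dict(d)
        if "grid" in d:
            d["grid"] = tuple(d["grid"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured synthetic pipelines and write a provenance report.

    Stage "behavior": simulate search trials from the feature-model RDM,
    estimate the empirical RDM, regress it on the feature and a control
    geometry.  Stage "neural": simulate epochs with the two planted
    geometries, run temporal RSA with cluster stats and the oddball
    decoding analysis.  Outputs are deterministic given the seed.
    """
    from . import behavior as behav
    from . import features, stimuli, synth
    from .decoding import (
        DecodeConfig,
        drop_block_initial,
        epoch_condition_patterns,
        sliding_average,
        time_resolved_oddball_decode,
    )
    from .rsa import crossnobis_time_series, whitened_rdm_similarity

    from . import __version__ as pkg_version

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": pkg_version,
        "python": platform.python_version(),
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        "stages": {},
    }
    rng = np.random.SeedSequence(config.seed)
    stage_seeds = {s: int(c.generate_state(1)[0] % 2**31) for s, c in
                   zip(config.stages, rng.spawn(len(config.stages)))}
    report["stage_seeds"] = stage_seeds

    shapes = stimuli.make_reference_shapes(config.bottom_side_length)
    feat_rdm = features.feature_rdm(shapes, tolerance=config.tolerance)
    write_rdm(feat_rdm, out / "feature_rdm.csv")

    for stage in config.stages:
        seed = stage_seeds[stage]
        try:
            if stage == "behavior":
                trials = synth.simulate_behavior(
                    feat_rdm, n_participants=config.n_participants, rng_seed=seed
                )
                write_trials(trials, out / "trials.tsv")
                emp = behav.empirical_rdm(trials)
                write_rdm(emp.as_rdm(), out / "behavior_rdm.csv")
                control = RDM(
                    labels=feat_rdm.labels,
                    values=np.random.default_rng(seed + 1).permutation(feat_rdm.values),
                    metric="shuffled-control",
                )
                reg = behav.rdm_regression(
                    emp.as_rdm(), [feat_rdm.zscored(), control.zscored()],
                    model_names=["features", "control"],
                )
                report["stages"]["behavior"] = {
                    "coefficients": dict(zip(reg.model_names, reg.coefficients.tolist())),
                    "r_squared": reg.r_squared,
                    "outputs": ["trials.tsv", "behavior_rdm.csv"],
                }
            elif stage == "neural":
                labels = feat_rdm.labels
                geom_a = synth.random_geometry_rdm(labels, rng_seed=seed + 17)
                regularity = {
                    name: float(features.regularity_score(features.feature_vector(q, config.tolerance)))
                    for name, q in shapes.items()
                }
                spec = synth.SimulationSpec(
                    rdm_early=geom_a,
                    rdm_late=feat_rdm,
                    regularity=regularity,
                    snr=config.snr,
                    n_channels=config.n_channels,
                    sampling_rate=config.sampling_rate,
                )
                epochs = synth.simulate_epochs(spec, n_runs=config.n_runs, rng_seed=seed)
                write_epochs(epochs, out / "epochs.h5")
                labs, pats = epoch_condition_patterns(epochs)
                series = crossnobis_time_series(pats, labs)
                sims = []
                for model in (geom_a.subset(labs).zscored(), feat_rdm.subset(labs).zscored()):
                    sims.append(
                        [
                            whitened_rdm_similarity(
                                RDM(labels=labs, values=series[:, t], metric="crossnobis"), model
                            )
                            for t in range(series.shape[1])
                        ]
                    )
                np.savetxt(out / "rsa_similarity.csv", np.array(sims).T, delimiter=",",
                           header="early_model,late_model", comments="")
                dec = time_resolved_oddball_decode(
                    drop_block_initial(epochs), DecodeConfig()
                )
                dec_s = sliding_average(dec, 100.0, epochs.sampling_rate)
                np.savetxt(out / "decoding_auc.csv", dec_s.T, delimiter=",",
                           header=",".join(sorted(labs)), comments="")
                report["stages"]["neural"] = {
                    "n_epochs": int(epochs.n_epochs),
                    "peak_auc": float(np.nanmax(dec_s)),
                    "outputs": ["epochs.h5", "rsa_similarity.csv", "decoding_auc.csv"],
                }
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            report["stages"][stage] = {"error": str(exc)}
            (out / "provenance.json").write_text(json.dumps(report, indent=2))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    checksums = {
        p.name: _checksum(p) for p in sorted(out.iterdir()) if p.name != "provenance.json"
    }
    report["checksums"] = checksums
    report["parameter_hash"] = hashlib.sha256(
        json.dumps(report["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "provenance.json").write_text(json.dumps(report, indent=2))
    return report
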