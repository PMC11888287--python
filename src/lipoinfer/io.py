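"""Subject-table I/O, run configuration, and the staged pipeline driver."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, make_cohort
from .features import assemble
from .gp import QuasiPeriodicGP
from .grids import T_ALL, grid_for_model
from .ode import Params2D, Params3D, SubjectRecord
from .optimize import FREE_NAMES_2D, FREE_NAMES_3D, FitResult, fit_cohort
from .sampling import (
    CurvePool,
    LabeledDataset,
    fit_lognormal,
    generate_dataset,
    parameter_table,
)
from .train import ScenarioSpec, evaluate, infer_from_fit_curves, train

log = logging.getLogger("lipoinfer")

SUBJECT_COLUMNS = ["subject", "time", "glucose", "ffa", "insulin"]


def read_subjects(path) -> list[SubjectRecord]:
    """Read a long-format subject table (columns subject,time,glucose,ffa,insulin).

    Validates that each subject's time grid equals the 28 protocol times
    exactly; basal values are the t = 0 entries.
    """
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table missing columns {missing}")
    if df[SUBJECT_COLUMNS[1:]].isna().any().any():
        raise ValueError("subject table contains missing values")
    records = []
    for sid, grp in df.groupby("subject", sort=True):
        grp = grp.sort_values("time")
        t = grp["time"].to_numpy(dtype=float)
        if 0.0 not in t:
            raise ValueError(f"subject {sid}: missing t = 0 row; cannot "
                             "extract basal values")
        if t.shape != T_ALL.shape or not np.allclose(t, T_ALL):
            raise ValueError(f"subject {sid}: time grid does not match the "
                             "28 protocol sampling times")
        if (grp[["glucose", "ffa", "insulin"]].to_numpy() <= 0).any():
            raise ValueError(f"subject {sid}: non-positive concentration")
        records.append(SubjectRecord(G=grp["glucose"].to_numpy(float),
                                     F=grp["ffa"].to_numpy(float),
                                     I=grp["insulin"].to_numpy(float),
                                     subject_id=int(sid)))
    return records


def write_subjects(records, path):
    rows = []
    for r in records:
        for k, t in enumerate(T_ALL):
            rows.append({"subject": r.subject_id, "time": t, "glucose": r.G[k],
                         "ffa": r.F[k], "insulin": r.I[k]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fits(fits, path):
    pd.DataFrame([fr.as_row() for fr in fits]).to_csv(path, index=False)


def read_fits(path, model_id) -> list[FitResult]:
    df = pd.read_csv(path)
    names = FREE_NAMES_3D if model_id == "3d" else FREE_NAMES_2D
    cls = Params3D if model_id == "3d" else Params2D
    out = []
    for _, row in df.iterrows():
        p = cls(**{n: float(row[n]) for n in names})
        out.append(FitResult(params=p, loss=float(row["loss"]), n_iter=0,
                             converged=bool(row["converged"]),
                             subject_id=int(row["subject"])))
    return out


@dataclass
class RunConfig:
    """Every knob of the staged pipeline; serializes losslessly to YAML."""

    model_id: str = "2d"
    seed: int = 0
    out_dir: str = "runs/default"
    exclude: list = field(default_factory=list)
    n_subjects: int = 25
    noise_sd: float = 0.03
    pool_size: int = 4000
    n_dataset: int = 2000
    gpr_max_iter: int = 300
    feature: str = "recip_time"
    activation: str = "scaled_tanh"
    epochs: int = 100
    batch_size: int = 256
    max_lr: float = 1e-3
    n_train: int = 100000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls().__dict__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig):
    """Cohort -> fits -> GP pools -> dataset -> train -> evaluate.

    Stage outputs are cached in ``out_dir`` keyed by the config hash (so a
    rerun with an unchanged config reuses every artifact byte-identically,
    and changing any upstream knob, including the seed, renames and thereby
    invalidates all downstream caches).  Returns (summary, model, dataset,
    fits, records).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    summary = {"config_hash": h, "stages": []}

    def stage(name, ext, build, save, load):
        path = out / f"{name}-{h}{ext}"
        cached = path.exists()
        obj = load(path) if cached else build()
        if not cached:
            save(obj, path)
        log.info("stage=%s seed=%d config_hash=%s cached=%s", name,
                 config.seed, h, cached)
        summary["stages"].append({"stage": name, "cached": cached,
                                  "path": str(path)})
        return obj

    spec = CohortSpec(model_id=config.model_id, n_subjects=config.n_subjects,
                      noise_sd=config.noise_sd, seed=config.seed)
    records = stage("cohort", ".csv", lambda: make_cohort(spec)[0],
                    write_subjects, read_subjects)

    fits = stage("fits", ".csv",
                 lambda: fit_cohort(records, config.model_id,
                                    exclude=config.exclude, seed=config.seed),
                 write_fits, lambda p: read_fits(p, config.model_id))

    grid = grid_for_model(config.model_id)
    mask = np.isin(T_ALL, grid)

    def build_pools():
        gp_ins = QuasiPeriodicGP(max_iter=config.gpr_max_iter,
                                 seed=config.seed).fit(
            np.stack([r.I[mask] for r in records]), t=grid)
        curves = {"insulin": gp_ins.sample(config.pool_size, seed=config.seed + 1)}
        if config.model_id == "2d":
            gp_glu = QuasiPeriodicGP(max_iter=config.gpr_max_iter,
                                     seed=config.seed).fit(
                np.stack([r.G for r in records]), t=grid)
            curves["glucose"] = gp_glu.sample(config.pool_size, seed=config.seed + 2)
        return curves

    def save_pools(curves, path):
        import h5py
        with h5py.File(path, "w") as f:
            for k, v in curves.items():
                f[k] = v

    def load_pools(path):
        import h5py
        with h5py.File(path, "r") as f:
            return {k: f[k][:] for k in f}

    curves = stage("pool", ".h5", build_pools, save_pools, load_pools)
    pool = CurvePool(curves["insulin"])
    glucose_pool = CurvePool(curves["glucose"]) if "glucose" in curves else None

    table = parameter_table(fits, subjects=records)
    dist = fit_lognormal(table, exclude=config.exclude)

    dataset = stage(
        "dataset", ".h5",
        lambda: generate_dataset(dist, pool, config.n_dataset, config.model_id,
                                 seed=config.seed, glucose_pool=glucose_pool),
        lambda d, p: d.save(p), LabeledDataset.load)

    scen = ScenarioSpec(config.model_id, config.feature, config.activation,
                        n_train=config.n_train, batch_size=config.batch_size,
                        max_lr=config.max_lr, epochs=config.epochs,
                        seed=config.seed)
    from .train import CNNParameterRegressor
    model = stage("model", ".npz", lambda: train(scen, dataset),
                  lambda m, p: m.save(p), CNNParameterRegressor.load)

    test = dataset.subset("test")
    rep_test = evaluate(model, assemble(test, config.feature).data, test.params)
    rep_fit = infer_from_fit_curves(model, fits, records)
    summary["test_report"] = rep_test.to_dict()
    summary["fit_curves_report"] = rep_fit.to_dict()
    log.info("stage=evaluate seed=%d config_hash=%s mean_r2=%.3f",
             config.seed, h, rep_fit.mean_r2)
    summary["stages"].append({"stage": "evaluate", "cached": False, "path": ""})
    (out / f"summary-{h}.json").write_text(json.dumps(summary, indent=2))
    return summary, model, dataset, fits, records
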