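"""Physiological parameter sampling and simulated-dataset generation.

The per-subject fits define, for every parameter, a physiological range
(componentwise min/max over included subjects) and, jointly, a multivariate
log-normal distribution capturing the correlations among parameters.
Candidate parameter sets are drawn from that log-normal, rejected if any
component leaves its range, paired with a fresh simulated insulin (and, for
the two-state model, glucose) curve, integrated, and kept only if the
trajectory is admissible: strictly non-negative concentrations and the
expected post-bolus shape (glucose decaying toward basal, FFA with a single
dip).  Accepted parameter-trajectory pairs form the labelled training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .grids import grid_for_model
from .ode import (
    PARAM_NAMES_2D,
    PARAM_NAMES_3D,
    Trajectory,
    integrate_batch_2d,
    integrate_batch_3d,
)

__all__ = [
    "build_ranges", "fit_lognormal", "LogNormalParameterModel",
    "admissible", "CurvePool", "generate_dataset", "LabeledDataset",
    "parameter_table",
]


def parameter_table(fits, subjects=None) -> pd.DataFrame:
    """Stack per-subject FitResults into a parameter DataFrame.

    For three-state fits the subject's measured values at t = 22 are appended
    as G22/F22 columns so that initial conditions are sampled jointly with
    the parameters.
    """
    rows = []
    for fr in fits:
        row = {k: v for k, v in fr.as_row().items() if k not in ("loss", "converged")}
        rows.append(row)
    df = pd.DataFrame(rows).set_index("subject")
    if subjects is not None and "SG" in df.columns:
        by_id = {s.subject_id: s for s in subjects}
        df["G22"] = [by_id[i].G[12] for i in df.index]  # t_all[12] = 22
        df["F22"] = [by_id[i].F[12] for i in df.index]
    return df


def build_ranges(params: pd.DataFrame, exclude=()) -> dict:
    """Componentwise [min, max] over included subjects."""
    kept = params.drop(index=[i for i in exclude if i in params.index])
    if len(kept) < 2:
        raise ValueError("need at least 2 included subjects to define ranges")
    return {c: (float(kept[c].min()), float(kept[c].max())) for c in kept.columns}


class LogNormalParameterModel(BaseEstimator):
    """Multivariate log-normal over the physiological parameter box.

    ``fit`` takes the table of per-subject fitted parameters (all positive);
    ``sample`` draws from the log-normal and rejects any vector with a
    component outside its fitted [min, max] range.

    Attributes
    ----------
    names_ : ordered parameter names.
    log_mean_, log_cov_ : sample mean/covariance of the elementwise logs.
    ranges_ : per-parameter (min, max) from the fits.
    """

    def __init__(self, min_acceptance: float = 1e-4):
        self.min_acceptance = min_acceptance

    def fit(self, params: pd.DataFrame, exclude=()):
        kept = params.drop(index=[i for i in exclude if i in params.index])
        vals = kept.to_numpy(dtype=float)
        if np.any(vals <= 0):
            bad = kept.columns[np.argmax((vals <= 0).any(axis=0))]
            raise ValueError(f"non-positive fitted value in column {bad!r}; cannot take logs")
        logs = np.log(vals)
        self.names_ = list(kept.columns)
        self.log_mean_ = logs.mean(axis=0)
        self.log_cov_ = np.cov(logs, rowvar=False)
        self.ranges_ = build_ranges(kept)
        return self

    def sample(self, n: int, seed: int = 0) -> np.ndarray:
        """Draw ``n`` in-range parameter vectors (columns in ``names_`` order)."""
        rng = np.random.default_rng(seed)
        lo = np.array([self.ranges_[c][0] for c in self.names_])
        hi = np.array([self.ranges_[c][1] for c in self.names_])
        out, n_drawn, n_kept = [], 0, 0
        while n_kept < n:
            chunk = max(1024, 2 * (n - n_kept))
            draws = np.exp(rng.multivariate_normal(
                self.log_mean_, self.log_cov_, size=chunk, method="eigh"))
            ok = np.all((draws >= lo) & (draws <= hi), axis=1)
            n_drawn += chunk
            kept = draws[ok]
            n_kept += len(kept)
            out.append(kept)
            if n_drawn >= 4096 and n_kept / n_drawn < self.min_acceptance:
                raise RuntimeError(
                    f"log-normal acceptance rate {n_kept / n_drawn:.2e} below "
                    f"{self.min_acceptance}: ranges and covariance are inconsistent")
        self.last_acceptance_ = n_kept / n_drawn
        return np.concatenate(out)[:n]

    def to_dict(self) -> dict:
        return {"names": self.names_, "log_mean": self.log_mean_.tolist(),
                "log_cov": self.log_cov_.tolist(),
                "ranges": {k: list(v) for k, v in self.ranges_.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "LogNormalParameterModel":
        m = cls()
        m.names_ = list(d["names"])
        m.log_mean_ = np.asarray(d["log_mean"], dtype=float)
        m.log_cov_ = np.asarray(d["log_cov"], dtype=float)
        m.ranges_ = {k: tuple(v) for k, v in d["ranges"].items()}
        return m


def fit_lognormal(params: pd.DataFrame, exclude=()) -> LogNormalParameterModel:
    return LogNormalParameterModel().fit(params, exclude=exclude)


# ---------------------------------------------------------------------------
# Admissibility filter
# ---------------------------------------------------------------------------

#: Default shape tolerances: glucose decay is enforced until G is within
#: ``g_basal_band`` of basal; FFA may wiggle by ``f_tol`` (relative) on either
#: side of its single minimum.
DEFAULT_RULES = {"g_basal_band": 0.05, "f_tol": 0.02, "g_tol": 0.0}


def _shape_flags(states: np.ndarray, Gb, model_id: str, rules) -> np.ndarray:
    """Vectorized admissibility codes for a (n, T, S) state batch.

    0 accept, 1 negative_G, 2 negative_F, 3 shape_G, 4 shape_F.
    """
    flags = np.zeros(states.shape[0], dtype=int)
    bad = ~np.all(np.isfinite(states), axis=(1, 2))
    if model_id == "3d":
        G, F = states[:, :, 0], states[:, :, 1]
    else:
        G, F = None, states[:, :, 0]

    if G is not None:
        neg = (G < 0).any(axis=1) | bad
        flags[(flags == 0) & neg] = 1
    neg_f = (F < 0).any(axis=1) | bad
    flags[(flags == 0) & neg_f] = 2

    if G is not None:
        # non-increasing until within the basal band
        above = G[:, :-1] > (1.0 + rules["g_basal_band"]) * np.asarray(Gb)[:, None]
        rising = np.diff(G, axis=1) > rules["g_tol"] * np.maximum(G[:, :-1], 1e-12)
        flags[(flags == 0) & (above & rising).any(axis=1)] = 3

    # single dip: no rise > f_tol before the minimum, no drop > f_tol after
    k = np.argmin(F, axis=1)
    idx = np.arange(F.shape[1] - 1)[None, :]
    d = np.diff(F, axis=1)
    tol = rules["f_tol"] * np.maximum(F[:, :-1], 1e-12)
    before = (idx < k[:, None]) & (d > tol)
    after = (idx >= k[:, None]) & (d < -tol)
    flags[(flags == 0) & (before | after).any(axis=1)] = 4
    return flags


_REASONS = {0: "ok", 1: "negative_G", 2: "negative_F", 3: "shape_G", 4: "shape_F"}


def admissible(traj: Trajectory, Gb: float | None = None, rules=None):
    """Accept/reject one integrated trajectory; returns (bool, reason)."""
    rules = {**DEFAULT_RULES, **(rules or {})}
    if not traj.ok:
        return False, "integration_failure"
    states = traj.states[None]
    Gb_arr = np.array([Gb if Gb is not None else traj.states[-1, 0]])
    flag = _shape_flags(states, Gb_arr, traj.model_id, rules)[0]
    return flag == 0, _REASONS[flag]


# ---------------------------------------------------------------------------
# Curve pools and dataset generation
# ---------------------------------------------------------------------------

class CurvePool:
    """Pool of simulated input curves with used-id bookkeeping."""

    def __init__(self, curves: np.ndarray):
        self.curves = np.asarray(curves, dtype=float)
        self.used = np.zeros(len(self.curves), dtype=bool)

    @property
    def n_unused(self) -> int:
        return int((~self.used).sum())

    def draw_unused(self, n: int, rng) -> np.ndarray:
        """Draw ``n`` distinct unused curve ids (not yet marked used)."""
        avail = np.flatnonzero(~self.used)
        if len(avail) < n:
            raise RuntimeError(
                f"curve pool exhausted ({len(avail)} unused, {n} needed); "
                "generate a larger pool")
        return rng.choice(avail, size=n, replace=False)

    def mark_used(self, ids):
        self.used[np.asarray(ids)] = True


@dataclass
class LabeledDataset:
    """Admissible parameter-trajectory pairs with their input curves."""

    model_id: str
    param_names: list
    params: np.ndarray        # (N, P)
    traj: np.ndarray          # (N, T, S)
    insulin: np.ndarray       # (N, T)
    insulin_id: np.ndarray    # (N,)
    split: np.ndarray         # (N,) in {"train","val","test"}
    glucose: np.ndarray | None = None   # (N, T), 2D model only
    acceptance_rate: float = float("nan")

    def __len__(self):
        return len(self.params)

    def subset(self, tag: str) -> "LabeledDataset":
        m = self.split == tag
        return LabeledDataset(
            self.model_id, self.param_names, self.params[m], self.traj[m],
            self.insulin[m], self.insulin_id[m], self.split[m],
            None if self.glucose is None else self.glucose[m],
            self.acceptance_rate)

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.attrs["model_id"] = self.model_id
            f.attrs["param_names"] = ",".join(self.param_names)
            f.attrs["acceptance_rate"] = self.acceptance_rate
            f["params"] = self.params
            f["traj"] = self.traj
            f["insulin"] = self.insulin
            f["insulin_id"] = self.insulin_id
            f["split"] = np.array([s.encode() for s in self.split])
            if self.glucose is not None:
                f["glucose"] = self.glucose

    @classmethod
    def load(cls, path) -> "LabeledDataset":
        with h5py.File(path, "r") as f:
            return cls(
                model_id=f.attrs["model_id"],
                param_names=f.attrs["param_names"].split(","),
                params=f["params"][:], traj=f["traj"][:],
                insulin=f["insulin"][:], insulin_id=f["insulin_id"][:],
                split=np.array([s.decode() for s in f["split"][:]]),
                glucose=f["glucose"][:] if "glucose" in f else None,
                acceptance_rate=float(f.attrs["acceptance_rate"]),
            )


def _split_tags(n: int, seed: int, fractions=(0.90, 0.08, 0.02)) -> np.ndarray:
    """Deterministic train/val/test tags from a hash of (row index, seed)."""
    idx = np.arange(n, dtype=np.uint64)
    h = (idx * np.uint64(2654435761) + np.uint64(seed) * np.uint64(0x9E3779B9)) \
        % np.uint64(2 ** 32)
    u = h.astype(float) / 2 ** 32
    tags = np.where(u < fractions[0], "train",
                    np.where(u < fractions[0] + fractions[1], "val", "test"))
    return tags.astype(object)


def generate_dataset(
    dist: LogNormalParameterModel,
    pool: CurvePool,
    n_target: int,
    model_id: str,
    seed: int = 0,
    glucose_pool: CurvePool | None = None,
    rules=None,
    fractions=(0.90, 0.08, 0.02),
    apply_filter: bool = True,
    dt_max: float = 0.1,
) -> LabeledDataset:
    """Sample, integrate and filter until ``n_target`` admissible rows.

    Each accepted row consumes one unused insulin curve (and one glucose
    curve for the two-state model); curves paired with rejected parameter
    sets return to the pool.
    """
    rules = {**DEFAULT_RULES, **(rules or {})}
    rng = np.random.default_rng(seed)
    grid = grid_for_model(model_id)
    names = PARAM_NAMES_3D if model_id == "3d" else PARAM_NAMES_2D
    order = [dist.names_.index(c) for c in names]

    acc_p, acc_traj, acc_ins, acc_ids, acc_glu = [], [], [], [], []
    n_accepted, n_attempted, draw_seed = 0, 0, seed
    while n_accepted < n_target:
        avail = pool.n_unused if glucose_pool is None else min(
            pool.n_unused, glucose_pool.n_unused)
        if avail < n_target - n_accepted:
            raise RuntimeError(
                f"curve pool exhausted ({avail} unused, "
                f"{n_target - n_accepted} still needed); generate a larger pool")
        m = min(max(1024, 2 * (n_target - n_accepted)), 65536, avail)
        draw_seed += 1
        cand = dist.sample(m, seed=draw_seed)[:, order]
        ins_ids = pool.draw_unused(m, rng)
        ins = pool.curves[ins_ids]
        if model_id == "3d":
            states = integrate_batch_3d(cand, ins, grid, dt_max=dt_max)
            Gb = cand[:, names.index("Gb")]
        else:
            if glucose_pool is None:
                raise ValueError("two-state generation needs a glucose_pool")
            glu_ids = glucose_pool.draw_unused(m, rng)
            glu = glucose_pool.curves[glu_ids]
            states = integrate_batch_2d(cand, glu, ins, grid, dt_max=dt_max)
            Gb = None
        needed = n_target - n_accepted
        if apply_filter:
            flags = _shape_flags(states, Gb, model_id, rules)
            ok = np.flatnonzero(flags == 0)
            keep = ok[:needed]
            # count only candidates examined up to the last accepted one
            n_attempted += m if len(ok) <= needed else int(keep[-1]) + 1
        else:
            keep = np.arange(min(m, needed))
            n_attempted += len(keep)
        acc_p.append(cand[keep])
        acc_traj.append(states[keep])
        acc_ins.append(ins[keep])
        acc_ids.append(ins_ids[keep])
        pool.mark_used(ins_ids[keep])
        if model_id == "2d":
            acc_glu.append(glu[keep])
            glucose_pool.mark_used(glu_ids[keep])
        n_accepted += len(keep)

    if n_target == 0:
        empty_t = np.empty((0, len(grid)))
        return LabeledDataset(model_id, list(names), np.empty((0, len(names))),
                              np.empty((0, len(grid), 3 if model_id == "3d" else 2)),
                              empty_t, np.empty(0, dtype=int),
                              np.empty(0, dtype=object),
                              empty_t if model_id == "2d" else None, 1.0)

    return LabeledDataset(
        model_id=model_id, param_names=list(names),
        params=np.concatenate(acc_p), traj=np.concatenate(acc_traj),
        insulin=np.concatenate(acc_ins), insulin_id=np.concatenate(acc_ids),
        split=_split_tags(n_accepted, seed, fractions),
        glucose=np.concatenate(acc_glu) if model_id == "2d" else None,
        acceptance_rate=n_accepted / n_attempted,
    )
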