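"""Network input layouts built from (t, G, I, F) series.

The network sees a stack of rows arranged in fixed pairs, so that a (2, 2)
convolution kernel with row stride 2 straddles exactly one engineered pair
at a time and can form finite-difference-like combinations (e.g. dG/dt from
the (t, G) pair).  Four layouts are supported:

``none`` / ``concat`` : the 12 base rows
    (t, G), (t, I), (t, F), (G, I), (I, F), (G, F)
``recip_time`` : base + 6 rows  (t, 1/G), (t, 1/I), (t, 1/F)
``mutual_recip`` : base + 12 rows
    (t, 1/G), (t, 1/I), (t, 1/F), (1/G, 1/I), (1/I, 1/F), (1/G, 1/F)

``none`` and ``concat`` share the same tensor; they differ only inside the
network (the concat variant feeds a first convolution whose output is
concatenated back onto the input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import T_ALL, T_POST20

__all__ = ["LAYOUTS", "n_rows", "build_rows", "assemble", "FeatureTensor",
           "FeatureStandardizer"]

LAYOUTS = ("none", "concat", "recip_time", "mutual_recip")

_N_ROWS = {"none": 12, "concat": 12, "recip_time": 18, "mutual_recip": 24}


def n_rows(layout: str) -> int:
    if layout not in _N_ROWS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")
    return _N_ROWS[layout]


def build_rows(t, G, I, F, layout: str = "none") -> np.ndarray:
    """Stack one sample's series into the layout's row block.

    Accepts 1-D series of equal length, or batches with a leading N axis for
    G/I/F (t is shared); returns (rows, T) or (N, rows, T).
    """
    n_rows(layout)
    t = np.asarray(t, dtype=float)
    G, I, F = (np.asarray(a, dtype=float) for a in (G, I, F))
    batched = G.ndim == 2
    if not batched:
        G, I, F = G[None], I[None], F[None]
    tb = np.broadcast_to(t, G.shape)
    rows = [tb, G, tb, I, tb, F, G, I, I, F, G, F]
    if layout in ("recip_time", "mutual_recip"):
        if np.any(G <= 0) or np.any(I <= 0) or np.any(F <= 0):
            raise ValueError("reciprocal layouts need strictly positive G, I, F")
        rG, rI, rF = 1.0 / G, 1.0 / I, 1.0 / F
        rows += [tb, rG, tb, rI, tb, rF]
        if layout == "mutual_recip":
            rows += [rG, rI, rI, rF, rG, rF]
    out = np.stack(rows, axis=1)
    return out if batched else out[0]


# spec of where each row comes from, used by tests as a literal oracle table
ROW_SOURCES = {
    "none": ["t", "G", "t", "I", "t", "F", "G", "I", "I", "F", "G", "F"],
    "recip_time": ["t", "G", "t", "I", "t", "F", "G", "I", "I", "F", "G", "F",
                   "t", "1/G", "t", "1/I", "t", "1/F"],
    "mutual_recip": ["t", "G", "t", "I", "t", "F", "G", "I", "I", "F", "G", "F",
                     "t", "1/G", "t", "1/I", "t", "1/F",
                     "1/G", "1/I", "1/I", "1/F", "1/G", "1/F"],
}
ROW_SOURCES["concat"] = ROW_SOURCES["none"]


@dataclass
class FeatureTensor:
    data: np.ndarray  # (N, rows, times)
    layout: str
    model_id: str

    def __post_init__(self):
        expected_rows = n_rows(self.layout)
        expected_t = 16 if self.model_id == "3d" else 28
        if self.data.ndim != 3 or self.data.shape[1:] != (expected_rows, expected_t):
            raise ValueError(
                f"layout {self.layout!r} / model {self.model_id!r} expects "
                f"(N, {expected_rows}, {expected_t}), got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("feature tensor contains non-finite entries")


def assemble(dataset, layout: str, model_id: str | None = None) -> FeatureTensor:
    """Build the input tensor for every row of a LabeledDataset.

    Three-state rows use the post-bolus grid with G and F taken from the
    stored trajectory and I from the paired insulin curve; two-state rows use
    the full grid with G and I input curves and F from the trajectory.
    """
    model_id = model_id or dataset.model_id
    if model_id == "3d":
        t = T_POST20
        G, F = dataset.traj[:, :, 0], dataset.traj[:, :, 1]
        I = dataset.insulin
    else:
        t = T_ALL
        G, I = dataset.glucose, dataset.insulin
        F = dataset.traj[:, :, 0]
    data = build_rows(t, G, I, F, layout)
    return FeatureTensor(data=data, layout=layout, model_id=model_id)


class FeatureStandardizer:
    """Per-row standardization (mean 0, sd 1 over the training set and time).

    The statistics are one scalar pair per feature row (pooling the N and
    time axes), so constant rows such as the raw time vector keep their
    within-row shape while all rows land on comparable scales.
    """

    def fit(self, data: np.ndarray) -> "FeatureStandardizer":
        self.mean_ = data.mean(axis=(0, 2))
        self.sd_ = np.maximum(data.std(axis=(0, 2)), 1e-12)
        return self

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (data - self.mean_[None, :, None]) / self.sd_[None, :, None]

    def fit_transform(self, data: np.ndarray) -> np.ndarray:
        return self.fit(data).transform(data)

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "sd": self.sd_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureStandardizer":
        s = cls()
        s.mean_ = np.asarray(d["mean"], dtype=float)
        s.sd_ = np.asarray(d["sd"], dtype=float)
        return s
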