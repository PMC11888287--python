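"""Gaussian-process simulation of physiological input curves.

Network training needs many more insulin (and, for the two-state model,
glucose) time courses than a cohort provides.  The cohort series are
normalized per time point (each sampling time to mean 0, sd 1 across
subjects, n-1 denominator), a zero-mean GP with a radial quasi-periodic
kernel is fitted to the normalized curves by stochastically ascending the
marginal log likelihood one random subject at a time, and fresh curves are
drawn from the fitted process and denormalized back to concentration units.

The kernel is a product of a squared-exponential envelope and a periodic
factor:

    k(t1, t2) = s^2 exp(-(t1-t2)^2 / (2 l^2)) exp(-2 sin^2(pi |t1-t2| / p) / lp^2)

isolated behind one function so the form can be swapped.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["normalize_per_timepoint", "denormalize", "kernel_rqp",
           "marginal_log_likelihood", "QuasiPeriodicGP"]

_HYPER_NAMES = ("output_scale", "length_scale", "period", "periodic_length", "noise")


def normalize_per_timepoint(cohort: np.ndarray):
    """Standardize each time point across subjects.

    cohort : (n_subjects, n_times). Returns (normalized, mean, sd); sd uses
    the n-1 denominator.  Raises if any time point is degenerate.
    """
    cohort = np.asarray(cohort, dtype=float)
    if cohort.ndim != 2 or cohort.shape[0] < 2:
        raise ValueError("need a (n_subjects >= 2, n_times) matrix")
    mean = cohort.mean(axis=0)
    sd = cohort.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero standard deviation at time index {bad[0]}: "
                         "identical values across subjects")
    return (cohort - mean) / sd, mean, sd


def denormalize(normalized: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return np.asarray(normalized) * sd + mean


def kernel_rqp(t1, t2, hyper: dict) -> np.ndarray:
    """Radial quasi-periodic covariance between time arrays ``t1`` and ``t2``."""
    for name in _HYPER_NAMES[:-1]:
        if hyper[name] <= 0:
            raise ValueError(f"kernel hyperparameter {name} must be > 0")
    d = np.subtract.outer(np.atleast_1d(t1), np.atleast_1d(t2))
    s2 = hyper["output_scale"] ** 2
    radial = np.exp(-d ** 2 / (2 * hyper["length_scale"] ** 2))
    periodic = np.exp(-2 * np.sin(np.pi * np.abs(d) / hyper["period"]) ** 2
                      / hyper["periodic_length"] ** 2)
    return s2 * radial * periodic


def _gram(t, hyper, jitter=1e-10):
    K = kernel_rqp(t, t, hyper)
    K[np.diag_indices_from(K)] += hyper.get("noise", 0.0) ** 2 + jitter
    return K


def _chol(K):
    """Cholesky with escalating jitter (1e-10 -> 1e-6)."""
    for jit in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(K + jit * np.eye(len(K)))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("kernel matrix not positive definite even with jitter")


def marginal_log_likelihood(y: np.ndarray, t: np.ndarray, hyper: dict) -> float:
    """Zero-mean GP marginal log likelihood of one curve ``y`` on grid ``t``."""
    y = np.asarray(y, dtype=float)
    L = _chol(_gram(t, hyper))
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, y))
    return float(-0.5 * y @ alpha - np.log(np.diag(L)).sum()
                 - 0.5 * len(y) * np.log(2 * np.pi))


class QuasiPeriodicGP(BaseEstimator):
    """GP curve simulator with per-time-point normalization.

    Parameters
    ----------
    threshold : stop the stochastic fit once the cohort-averaged marginal log
        likelihood exceeds this; ``None`` means -0.5 per data point.
    step : gradient-ascent step on log-hyperparameters.
    max_iter : iteration cap for the stochastic loop.

    Attributes
    ----------
    hyper_ : fitted kernel hyperparameters.
    mean_, sd_ : per-time-point normalization statistics.
    train_t_ : training grid.
    mll_ : cohort-averaged marginal log likelihood at the stop.
    """

    def __init__(self, threshold=None, step=1e-2, max_iter=20000, seed=0):
        self.threshold = threshold
        self.step = step
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X, t=None):
        """Fit to a (n_subjects, n_times) cohort matrix on grid ``t``."""
        X = np.asarray(X, dtype=float)
        if t is None:
            raise ValueError("the training grid t is required")
        t = np.asarray(t, dtype=float)
        Z, self.mean_, self.sd_ = normalize_per_timepoint(X)
        self.train_t_ = t
        n = len(t)
        threshold = -0.5 * n if self.threshold is None else self.threshold

        rng = np.random.default_rng(self.seed)
        log_h = np.log([1.0, 30.0, 90.0, 1.0, 0.3])  # scale, l, period, lp, noise

        def cohort_mll(lh):
            hyper = dict(zip(_HYPER_NAMES, np.exp(lh)))
            return np.mean([marginal_log_likelihood(z, t, hyper) for z in Z])

        self.n_iter_ = 0
        for it in range(self.max_iter):
            self.n_iter_ = it + 1
            if cohort_mll(log_h) > threshold:
                break
            i = rng.integers(len(Z))
            # one ascent step on subject i's MLL, finite-difference gradient
            # in log-hyperparameter space
            def mll_i(lh):
                return marginal_log_likelihood(Z[i], t, dict(zip(_HYPER_NAMES, np.exp(lh))))
            g = np.empty_like(log_h)
            f0 = mll_i(log_h)
            eps = 1e-5
            for k in range(len(log_h)):
                lh = log_h.copy()
                lh[k] += eps
                g[k] = (mll_i(lh) - f0) / eps
            gnorm = np.linalg.norm(g)
            if gnorm > 1e3:  # guard against near-singular spikes
                g = g / gnorm * 1e3
            log_h = log_h + self.step * g

        self.hyper_ = dict(zip(_HYPER_NAMES, np.exp(log_h)))
        self.mll_ = cohort_mll(log_h)
        return self

    def _posterior_cov(self):
        return _gram(self.train_t_, self.hyper_)

    def sample(self, n: int, seed: int = 0, floor: float = 0.1) -> np.ndarray:
        """Draw ``n`` denormalized curves on the training grid.

        Concentrations must be positive; draws are clipped at ``floor``.
        """
        if n <= 0:
            raise ValueError("n must be >= 1")
        if not hasattr(self, "hyper_"):
            raise RuntimeError("sample() requires a fitted model")
        rng = np.random.default_rng(seed)
        L = _chol(self._posterior_cov())
        z = rng.standard_normal((n, len(self.train_t_)))
        curves = denormalize(z @ L.T, self.mean_, self.sd_)
        return np.maximum(curves, floor)

    def to_dict(self) -> dict:
        return {
            "hyper": self.hyper_,
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "train_t": self.train_t_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuasiPeriodicGP":
        m = cls()
        m.hyper_ = dict(d["hyper"])
        m.mean_ = np.asarray(d["mean"], dtype=float)
        m.sd_ = np.asarray(d["sd"], dtype=float)
        m.train_t_ = np.asarray(d["train_t"], dtype=float)
        m.mll_ = None
        return m
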