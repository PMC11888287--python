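"""Per-subject parameter estimation by Nelder-Mead.

The objective is the mean relative error between model and measured
trajectories: for the three-state model the post-bolus glucose and FFA errors
(equally weighted averages); for the two-state model the FFA error alone over
the full grid, since measured glucose and insulin enter as inputs.  The
simplex never sees negative parameters: every candidate vector is mapped
through a componentwise absolute value before evaluation, so the search is
effectively over the positive orthant without explicit bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .grids import T_ALL, T_POST20
from .ode import (
    PARAM_NAMES_2D,
    Params2D,
    Params3D,
    SubjectRecord,
    integrate,
    make_fast_integrator_2d,
    make_fast_integrator_3d,
)

#: Loss returned when integration blows up, large enough for the simplex to retreat.
FAILED_LOSS = 1e6

#: Free parameters optimized per model (3D: X22 is optimized alongside; G22/F22
#: are pinned to the subject's measurements and are not free).
FREE_NAMES_3D = ["SG", "SI", "CX", "X2", "CF", "L2", "Gb", "Fb", "X22"]
FREE_NAMES_2D = list(PARAM_NAMES_2D)


@dataclass
class FitResult:
    params: object  # Params3D | Params2D
    loss: float
    n_iter: int
    converged: bool
    subject_id: int = 0

    def as_row(self) -> dict:
        row = {"subject": self.subject_id}
        row.update({f: getattr(self.params, f) for f in _free_names(self.params)})
        row["loss"] = self.loss
        row["converged"] = self.converged
        return row


def _free_names(p) -> list[str]:
    return FREE_NAMES_3D if isinstance(p, Params3D) else FREE_NAMES_2D


_FAST_CACHE: dict = {}


def _fast_runner(subject: SubjectRecord, model_id: str):
    """Per-subject cached fixed-step integrator (stage inputs precomputed)."""
    key = (id(subject), model_id)
    if key not in _FAST_CACHE:
        if len(_FAST_CACHE) > 256:
            _FAST_CACHE.clear()
        if model_id == "3d":
            mask = T_ALL > 20
            ins = subject.insulin_signal()
            _FAST_CACHE[key] = make_fast_integrator_3d(ins, subject.Ib, T_POST20)
        else:
            _FAST_CACHE[key] = make_fast_integrator_2d(
                subject.glucose_signal(), subject.insulin_signal(),
                subject.Ib, T_ALL)
    return _FAST_CACHE[key]


def loss_3d(p: Params3D, subject: SubjectRecord, fast: bool = True) -> float:
    """Equal-weight average of the post-bolus mean relative G and F errors."""
    mask = T_ALL > 20
    if fast:
        with np.errstate(all="ignore"):
            states = _fast_runner(subject, "3d")(p, subject.G[mask][0],
                                                 subject.F[mask][0])
        if not np.all(np.isfinite(states)):
            return FAILED_LOSS
        Gm, Fm = states[:, 0], states[:, 1]
    else:
        traj = integrate(
            "3d", p,
            {"insulin": subject.insulin_signal(), "Ib": subject.Ib},
            grid=T_POST20,
            initial_conditions=(subject.G[mask][0], subject.F[mask][0]),
        )
        if not traj.ok:
            return FAILED_LOSS
        Gm, Fm = traj.G, traj.F
    eG = np.mean(np.abs(Gm - subject.G[mask]) / subject.G[mask])
    eF = np.mean(np.abs(Fm - subject.F[mask]) / subject.F[mask])
    return float(0.5 * (eG + eF))


def loss_2d(p: Params2D, subject: SubjectRecord, fast: bool = True) -> float:
    """Mean relative FFA error over the full grid."""
    if fast:
        with np.errstate(all="ignore"):
            states = _fast_runner(subject, "2d")(p)
        if not np.all(np.isfinite(states)):
            return FAILED_LOSS
        Fm = states[:, 0]
    else:
        traj = integrate(
            "2d", p,
            {"insulin": subject.insulin_signal(),
             "glucose": subject.glucose_signal(),
             "Ib": subject.Ib},
            grid=T_ALL,
        )
        if not traj.ok:
            return FAILED_LOSS
        Fm = traj.F
    return float(np.mean(np.abs(Fm - subject.F) / subject.F))


def _loss_vector(x: np.ndarray, model_id: str, subject: SubjectRecord) -> float:
    x = np.abs(x)
    try:
        if model_id == "3d":
            p = Params3D(**dict(zip(FREE_NAMES_3D, x)))
            return loss_3d(p, subject)
        p = Params2D(**dict(zip(FREE_NAMES_2D, x)))
        return loss_2d(p, subject)
    except (ValueError, FloatingPointError):
        return FAILED_LOSS


#: Broad positive boxes for log-uniform multi-start initialization.
INIT_BOX_3D = {
    "SG": (1e-3, 0.2), "SI": (1e-6, 1e-3), "CX": (1e-3, 0.5),
    "X2": (1.0, 100.0), "CF": (1e-3, 0.5), "L2": (0.5, 100.0),
    "Gb": (60.0, 200.0), "Fb": (100.0, 1000.0), "X22": (1e-3, 10.0),
}
INIT_BOX_2D = {
    "SGF": (1e-5, 1e-2), "SFb": (0.5, 100.0), "PXalpha": (1e-7, 1e-3),
    "PX": (1e-3, 1.0), "Fb": (100.0, 1000.0),
}


def _random_init(model_id: str, rng: np.random.Generator) -> np.ndarray:
    box = INIT_BOX_3D if model_id == "3d" else INIT_BOX_2D
    lo = np.log([b[0] for b in box.values()])
    hi = np.log([b[1] for b in box.values()])
    return np.exp(rng.uniform(lo, hi))


def fit_subject(
    subject: SubjectRecord,
    model_id: str,
    init=None,
    seed: int = 0,
    n_starts: int = 5,
    max_iter: int = 5000,
    tol: float = 1e-8,
    n_restarts: int = 3,
) -> FitResult:
    """Estimate one subject's parameters by restarted Nelder-Mead.

    If ``init`` is given it is the single starting point; otherwise
    ``n_starts`` log-uniform draws from a broad plausible box are tried and
    the best kept.  Each start is polished by up to ``n_restarts`` fresh
    simplices from the incumbent; convergence requires both simplex size and
    function-value spread below ``tol``.
    """
    rng = np.random.default_rng(seed)
    if init is not None:
        starts = [np.asarray(init, dtype=float)]
    else:
        starts = [_random_init(model_id, rng) for _ in range(n_starts)]

    best_x, best_loss, best_nit, converged = None, np.inf, 0, False
    for x0 in starts:
        x, nit = x0, 0
        prev = _loss_vector(x0, model_id, subject)
        for _ in range(1 + n_restarts):
            res = minimize(
                _loss_vector, x, args=(model_id, subject), method="Nelder-Mead",
                options={"maxiter": max_iter, "xatol": tol, "fatol": tol,
                         "adaptive": True},
            )
            nit += res.nit
            x = np.abs(res.x)
            if prev - res.fun < 1e-10:  # restart no longer helps
                break
            prev = res.fun
        loss = _loss_vector(x, model_id, subject)
        if loss < best_loss:
            best_x, best_loss, best_nit = x, loss, nit
            converged = bool(res.success) or loss < prev + 1e-12

    names = FREE_NAMES_3D if model_id == "3d" else FREE_NAMES_2D
    cls = Params3D if model_id == "3d" else Params2D
    params = cls(**dict(zip(names, np.abs(best_x))))
    return FitResult(params=params, loss=best_loss, n_iter=best_nit,
                     converged=converged, subject_id=subject.subject_id)


def fit_cohort(subjects, model_id: str, exclude=(), seed: int = 0, **kwargs):
    """Fit every subject not in ``exclude``; returns a list of FitResult."""
    out = []
    for s in subjects:
        if s.subject_id in exclude:
            continue
        out.append(fit_subject(s, model_id, seed=seed + s.subject_id, **kwargs))
    return out
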