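"""Lipolysis ODE models with time-dependent interpolated inputs.

Two minimal models of insulin action on plasma glucose (G), free fatty acids
(F) and a latent remote-insulin compartment (X):

Three-state model (integrated on the post-bolus grid, from t = 22):

    dG/dt = -SG (G - Gb) - SI X G
    dF/dt = -CF (F - Fb) - L2 X^2 / (X2^2 + X^2)
    dX/dt = CX (max(I(t) - Ib, 0) - X)

Two-state FFA model (integrated on the full grid from t = 0), with measured
glucose and insulin as inputs:

    dF/dt = -SGF G(t) F + SFb - Fb X
    dX/dt = PXalpha (I(t) - Ib) - PX X

Basal values Gb and Fb are treated as model parameters.  I(t) (and G(t) for
the two-state model) are piecewise-linear interpolants of sampled series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy.integrate import solve_ivp

from .grids import T_ALL, T_POST20

__all__ = [
    "Params3D",
    "Params2D",
    "InputSignal",
    "SubjectRecord",
    "Trajectory",
    "rhs_3d",
    "rhs_2d",
    "integrate",
    "integrate_batch_2d",
    "integrate_batch_3d",
    "PARAM_NAMES_3D",
    "PARAM_NAMES_2D",
]

#: Column order used everywhere a 3D-model parameter vector is flattened.
#: G22/F22 ride along as sampled initial conditions for simulated rows.
PARAM_NAMES_3D = ["SG", "SI", "CX", "X2", "CF", "L2", "Gb", "Fb", "X22", "G22", "F22"]

#: Column order for the two-state model (Fb is a parameter; X starts at 0).
PARAM_NAMES_2D = ["SGF", "SFb", "PXalpha", "PX", "Fb"]


@dataclass(frozen=True)
class Params3D:
    """Parameters of the three-state model. All non-negative; X2 > 0."""

    SG: float
    SI: float
    CX: float
    X2: float
    CF: float
    L2: float
    Gb: float
    Fb: float
    X22: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"Params3D.{f.name} must be finite and >= 0, got {v}")
        if self.X2 <= 0:
            raise ValueError("Params3D.X2 must be > 0 (appears squared in a denominator)")

    def as_array(self) -> np.ndarray:
        return np.array([self.SG, self.SI, self.CX, self.X2, self.CF, self.L2,
                         self.Gb, self.Fb, self.X22])


@dataclass(frozen=True)
class Params2D:
    """Parameters of the two-state FFA model. All non-negative."""

    SGF: float
    SFb: float
    PXalpha: float
    PX: float
    Fb: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"Params2D.{f.name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.SGF, self.SFb, self.PXalpha, self.PX, self.Fb])


class InputSignal:
    """Piecewise-linear interpolant of a sampled concentration series.

    Queries outside the sampled span clamp to the endpoint values (adaptive
    solvers may probe slightly past the final time).
    """

    def __init__(self, times, values):
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("signal values must be finite")
        self.times = t
        self.values = v

    def __call__(self, t):
        return np.interp(t, self.times, self.values)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's measured (t, G, F, I) series on the full 28-point grid."""

    G: np.ndarray
    F: np.ndarray
    I: np.ndarray
    subject_id: int = 0

    def __post_init__(self):
        for name in ("G", "F", "I"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (28,):
                raise ValueError(f"{name} series must have length 28, got {arr.shape}")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} series must be finite and positive")
            object.__setattr__(self, name, arr)

    @property
    def t(self) -> np.ndarray:
        return T_ALL

    @property
    def Gb(self) -> float:
        return float(self.G[0])

    @property
    def Fb(self) -> float:
        return float(self.F[0])

    @property
    def Ib(self) -> float:
        return float(self.I[0])

    def insulin_signal(self) -> InputSignal:
        return InputSignal(T_ALL, self.I)

    def glucose_signal(self) -> InputSignal:
        return InputSignal(T_ALL, self.G)


@dataclass
class Trajectory:
    """Model state series on a fixed grid. ``ok`` is False on solver failure."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), n_states); columns (G,F,X) or (F,X)
    model_id: str
    ok: bool = True

    @property
    def G(self) -> np.ndarray:
        if self.model_id != "3d":
            raise AttributeError("two-state trajectories carry no glucose state")
        return self.states[:, 0]

    @property
    def F(self) -> np.ndarray:
        return self.states[:, 0 if self.model_id == "2d" else 1]

    @property
    def X(self) -> np.ndarray:
        return self.states[:, -1]


def rhs_3d(state, t, p: Params3D, insulin: InputSignal, Ib: float):
    """Right-hand side of the three-state model at time ``t`` (minutes)."""
    G, F, X = state
    I_t = insulin(t)
    dG = -p.SG * (G - p.Gb) - p.SI * X * G
    dF = -p.CF * (F - p.Fb) - p.L2 * X * X / (p.X2 * p.X2 + X * X)
    dX = p.CX * (max(I_t - Ib, 0.0) - X)
    return (dG, dF, dX)


def rhs_2d(state, t, p: Params2D, glucose: InputSignal, insulin: InputSignal, Ib: float):
    """Right-hand side of the two-state FFA model at time ``t``."""
    F, X = state
    dF = -p.SGF * glucose(t) * F + p.SFb - p.Fb * X
    dX = p.PXalpha * (insulin(t) - Ib) - p.PX * X
    return (dF, dX)


def integrate(
    model_id: str,
    p,
    signals: dict,
    grid=None,
    initial_conditions=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate a model with an adaptive Runge-Kutta solver, sampled at grid times.

    Parameters
    ----------
    model_id : ``"3d"`` or ``"2d"``.
    p : Params3D or Params2D.
    signals : dict with ``"insulin"`` (both models) and ``"glucose"`` (2D)
        InputSignal entries; optional ``"Ib"`` overrides the basal insulin,
        which otherwise defaults to the insulin signal's first value.
    grid : output times; defaults to the model's own grid.
    initial_conditions : ``(G22, F22)`` for the 3D model (X starts at p.X22);
        ignored for the 2D model, which starts at (Fb, 0).
    """
    insulin = signals["insulin"]
    Ib = float(signals.get("Ib", insulin.values[0]))
    if model_id == "3d":
        if grid is None:
            grid = T_POST20
        if initial_conditions is None:
            raise ValueError("3D integration needs (G22, F22) initial conditions")
        G22, F22 = initial_conditions
        y0 = [float(G22), float(F22), p.X22]
        fun = lambda t, y: rhs_3d(y, t, p, insulin, Ib)
    elif model_id == "2d":
        if grid is None:
            grid = T_ALL
        glucose = signals["glucose"]
        y0 = [p.Fb, 0.0]
        fun = lambda t, y: rhs_2d(y, t, p, glucose, insulin, Ib)
    else:
        raise ValueError(f"unknown model_id {model_id!r}")

    grid = np.asarray(grid, dtype=float)
    # The input signals are piecewise linear with kinks at the sampling
    # times, so the solution is integrated segment by segment between grid
    # points; the right-hand side is smooth inside every segment.
    states = np.full((len(grid), len(y0)), np.nan)
    states[0] = y0
    y, ok = list(y0), True
    for k in range(len(grid) - 1):
        sol = solve_ivp(fun, (grid[k], grid[k + 1]), y, method="RK45",
                        rtol=rtol, atol=atol)
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            ok = False
            break
        y = sol.y[:, -1]
        states[k + 1] = y
    return Trajectory(t=grid, states=states, model_id=model_id, ok=ok)


# ---------------------------------------------------------------------------
# Fast scalar RK4 integrators for repeated single-trajectory evaluation.
#
# Nelder-Mead fitting evaluates thousands of candidate parameter vectors on
# one fixed subject; input-signal values at every RK4 stage time are
# precomputed once, leaving a tight float loop per evaluation.  Step size
# 0.25 min keeps the truncation error orders of magnitude below fitting
# noise (validated against the adaptive solver in tests).
# ---------------------------------------------------------------------------

try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard speed dependency
    def _njit(*a, **k):
        if a and callable(a[0]):
            return a[0]
        return lambda f: f


def _stage_arrays(signal_fns, grid, dt_max):
    """Precompute per-sub-step (h, is-output-point, inputs at t, t+h/2, t+h)."""
    hs, lasts, stages = [], [], [[] for _ in signal_fns]
    for k in range(len(grid) - 1):
        n_sub = max(1, int(np.ceil((grid[k + 1] - grid[k]) / dt_max)))
        h = (grid[k + 1] - grid[k]) / n_sub
        for j in range(n_sub):
            t = grid[k] + j * h
            hs.append(h)
            lasts.append(j == n_sub - 1)
            for s, fn in enumerate(signal_fns):
                stages[s].append([float(fn(ti)) for ti in (t, t + h / 2, t + h)])
    return (np.asarray(hs), np.asarray(lasts, dtype=np.bool_),
            [np.asarray(s) for s in stages])


@_njit(cache=True)
def _rk4_2d_core(hs, lasts, Gs, Is, Ib, SGF, SFb, PXa, PX, Fbp, out):
    F, X = Fbp, 0.0
    out[0, 0], out[0, 1] = F, X
    i = 1
    for n in range(hs.shape[0]):
        h = hs[n]
        G0, Gm, G1 = Gs[n, 0], Gs[n, 1], Gs[n, 2]
        I0, Im, I1 = Is[n, 0], Is[n, 1], Is[n, 2]
        f1F = -SGF * G0 * F + SFb - Fbp * X
        f1X = PXa * (I0 - Ib) - PX * X
        Fa, Xa = F + 0.5 * h * f1F, X + 0.5 * h * f1X
        f2F = -SGF * Gm * Fa + SFb - Fbp * Xa
        f2X = PXa * (Im - Ib) - PX * Xa
        Fc, Xc = F + 0.5 * h * f2F, X + 0.5 * h * f2X
        f3F = -SGF * Gm * Fc + SFb - Fbp * Xc
        f3X = PXa * (Im - Ib) - PX * Xc
        Fd, Xd = F + h * f3F, X + h * f3X
        f4F = -SGF * G1 * Fd + SFb - Fbp * Xd
        f4X = PXa * (I1 - Ib) - PX * Xd
        F += h / 6 * (f1F + 2 * f2F + 2 * f3F + f4F)
        X += h / 6 * (f1X + 2 * f2X + 2 * f3X + f4X)
        if lasts[n]:
            out[i, 0], out[i, 1] = F, X
            i += 1


@_njit(cache=True)
def _rk4_3d_core(hs, lasts, Is, Ib, SG, SI, CX, X2, CF, L2, Gb, Fb,
                 G22, F22, X22, out):
    G, F, X = G22, F22, X22
    X2sq = X2 * X2
    out[0, 0], out[0, 1], out[0, 2] = G, F, X
    i = 1
    for n in range(hs.shape[0]):
        h = hs[n]
        I0, Im, I1 = Is[n, 0], Is[n, 1], Is[n, 2]
        d0 = I0 - Ib if I0 > Ib else 0.0
        dm = Im - Ib if Im > Ib else 0.0
        d1 = I1 - Ib if I1 > Ib else 0.0
        k1G = -SG * (G - Gb) - SI * X * G
        k1F = -CF * (F - Fb) - L2 * X * X / (X2sq + X * X)
        k1X = CX * (d0 - X)
        Ga, Fa, Xa = G + 0.5 * h * k1G, F + 0.5 * h * k1F, X + 0.5 * h * k1X
        k2G = -SG * (Ga - Gb) - SI * Xa * Ga
        k2F = -CF * (Fa - Fb) - L2 * Xa * Xa / (X2sq + Xa * Xa)
        k2X = CX * (dm - Xa)
        Gc, Fc, Xc = G + 0.5 * h * k2G, F + 0.5 * h * k2F, X + 0.5 * h * k2X
        k3G = -SG * (Gc - Gb) - SI * Xc * Gc
        k3F = -CF * (Fc - Fb) - L2 * Xc * Xc / (X2sq + Xc * Xc)
        k3X = CX * (dm - Xc)
        Gd, Fd, Xd = G + h * k3G, F + h * k3F, X + h * k3X
        k4G = -SG * (Gd - Gb) - SI * Xd * Gd
        k4F = -CF * (Fd - Fb) - L2 * Xd * Xd / (X2sq + Xd * Xd)
        k4X = CX * (d1 - Xd)
        G += h / 6 * (k1G + 2 * k2G + 2 * k3G + k4G)
        F += h / 6 * (k1F + 2 * k2F + 2 * k3F + k4F)
        X += h / 6 * (k1X + 2 * k2X + 2 * k3X + k4X)
        if lasts[n]:
            out[i, 0], out[i, 1], out[i, 2] = G, F, X
            i += 1


def make_fast_integrator_2d(glucose: InputSignal, insulin: InputSignal,
                            Ib: float, grid=None, dt_max: float = 0.25):
    """Return f(Params2D) -> (len(grid), 2) states, RK4 at fixed step."""
    if grid is None:
        grid = T_ALL
    grid = np.asarray(grid, dtype=float)
    hs, lasts, (Gs, Is) = _stage_arrays((glucose, insulin), grid, dt_max)
    n_out = len(grid)

    def run(p: Params2D) -> np.ndarray:
        out = np.empty((n_out, 2))
        _rk4_2d_core(hs, lasts, Gs, Is, float(Ib),
                     p.SGF, p.SFb, p.PXalpha, p.PX, p.Fb, out)
        return out

    return run


def make_fast_integrator_3d(insulin: InputSignal, Ib: float, grid=None,
                            dt_max: float = 0.25):
    """Return f(Params3D, G22, F22) -> (len(grid), 3) states."""
    if grid is None:
        grid = T_POST20
    grid = np.asarray(grid, dtype=float)
    hs, lasts, (Is,) = _stage_arrays((insulin,), grid, dt_max)
    n_out = len(grid)

    def run(p: Params3D, G22: float, F22: float) -> np.ndarray:
        out = np.empty((n_out, 3))
        _rk4_3d_core(hs, lasts, Is, float(Ib), p.SG, p.SI, p.CX, p.X2,
                     p.CF, p.L2, p.Gb, p.Fb, float(G22), float(F22),
                     p.X22, out)
        return out

    return run


# ---------------------------------------------------------------------------
# Vectorized fixed-step RK4 batch integrators.
#
# Dataset generation integrates 10^4..10^6 parameter sets; a classic RK4 on a
# refined mesh, vectorized across the whole batch, is orders of magnitude
# faster than per-row adaptive calls and is validated against `integrate`
# (and against dt-refinement) in the tests.
# ---------------------------------------------------------------------------

def _batch_interp_factory(grid, curves):
    """Per-row piecewise-linear interpolation of (n, len(grid)) curves,
    sharing one time grid; clamped outside the span."""
    grid = np.asarray(grid, dtype=float)
    curves = np.asarray(curves, dtype=float)
    slopes = np.diff(curves, axis=1) / np.diff(grid)

    def interp(t: float):
        k = int(np.clip(np.searchsorted(grid, t, side="right") - 1, 0, len(grid) - 2))
        dt = np.clip(t - grid[k], 0.0, grid[k + 1] - grid[k])
        return curves[:, k] + slopes[:, k] * dt

    return interp


def _rk4_mesh(grid, dt_max):
    """Sub-steps covering each grid interval with step <= dt_max."""
    pieces = []
    for k in range(len(grid) - 1):
        n_sub = max(1, int(np.ceil((grid[k + 1] - grid[k]) / dt_max)))
        h = (grid[k + 1] - grid[k]) / n_sub
        pieces.append((grid[k], h, n_sub))
    return pieces


def _rk4_batch(f, y0, grid, dt_max):
    grid = np.asarray(grid, dtype=float)
    y = [np.asarray(c, dtype=float).copy() for c in y0]
    out = np.empty((len(grid), len(y0), len(y[0])))
    out[0] = y
    for i, (t0, h, n_sub) in enumerate(_rk4_mesh(grid, dt_max)):
        for j in range(n_sub):
            t = t0 + j * h
            k1 = f(t, y)
            k2 = f(t + h / 2, [yi + h / 2 * ki for yi, ki in zip(y, k1)])
            k3 = f(t + h / 2, [yi + h / 2 * ki for yi, ki in zip(y, k2)])
            k4 = f(t + h, [yi + h * ki for yi, ki in zip(y, k3)])
            y = [yi + h / 6 * (k1i + 2 * k2i + 2 * k3i + k4i)
                 for yi, k1i, k2i, k3i, k4i in zip(y, k1, k2, k3, k4)]
        out[i + 1] = y
    return out  # (n_times, n_states, n_rows)


def integrate_batch_2d(params, glucose_curves, insulin_curves, grid=None,
                       dt_max: float = 0.25) -> np.ndarray:
    """Integrate the two-state model for a batch of parameter rows.

    params : (n, 5) array in PARAM_NAMES_2D order; glucose/insulin curves are
    (n, len(grid)) on the shared grid.  Returns (n, len(grid), 2) states (F, X).
    """
    if grid is None:
        grid = T_ALL
    params = np.atleast_2d(np.asarray(params, dtype=float))
    SGF, SFb, PXa, PX, Fb = params.T
    G = _batch_interp_factory(grid, glucose_curves)
    I = _batch_interp_factory(grid, insulin_curves)
    Ib = np.asarray(insulin_curves, dtype=float)[:, 0]

    def f(t, y):
        F, X = y
        return [-SGF * G(t) * F + SFb - Fb * X, PXa * (I(t) - Ib) - PX * X]

    out = _rk4_batch(f, [Fb, np.zeros_like(Fb)], grid, dt_max)
    return np.moveaxis(out, 2, 0)  # (n, n_times, 2)


def integrate_batch_3d(params, insulin_curves, grid=None,
                       dt_max: float = 0.25) -> np.ndarray:
    """Integrate the three-state model for a batch of parameter rows.

    params : (n, 11) array in PARAM_NAMES_3D order (G22/F22 initial conditions
    included as columns); insulin curves are (n, len(grid)) on the post-bolus
    grid.  Returns (n, len(grid), 3) states (G, F, X).
    """
    if grid is None:
        grid = T_POST20
    params = np.atleast_2d(np.asarray(params, dtype=float))
    SG, SI, CX, X2, CF, L2, Gb, Fb, X22, G22, F22 = params.T
    I = _batch_interp_factory(grid, insulin_curves)
    Ib = np.asarray(insulin_curves, dtype=float)[:, 0]

    def f(t, y):
        G, F, X = y
        return [
            -SG * (G - Gb) - SI * X * G,
            -CF * (F - Fb) - L2 * X * X / (X2 * X2 + X * X),
            CX * (np.maximum(I(t) - Ib, 0.0) - X),
        ]

    out = _rk4_batch(f, [G22, F22, X22], grid, dt_max)
    return np.moveaxis(out, 2, 0)
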