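"""Synthetic FSIGT-like cohort generation.

Stands in for a clinical cohort so that subject fitting, GP simulation and
fit-curve inference run end-to-end without external data.  Each subject gets

* an insulin series: basal before the 20-minute bolus, then a gamma-shaped
  transient peaking a few minutes after the bolus and decaying toward basal;
* a glucose series: basal at t = 0, a fast rise to a post-injection peak and
  slow biphasic-looking decay back toward basal (for the two-state model this
  is an input; for the three-state model it seeds the pre-bolus portion and
  the model supplies t >= 22);
* FFA from integrating the chosen model under hidden true parameters;
* multiplicative log-normal measurement noise on all channels (relative
  assay error on positive concentrations), default 3%.

Hidden true parameters are returned alongside the records for recovery
experiments.  Records failing the admissibility shape rules are redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import T_ALL, T_POST20
from .ode import (
    PARAM_NAMES_2D,
    PARAM_NAMES_3D,
    InputSignal,
    Params2D,
    Params3D,
    SubjectRecord,
    integrate,
)
from .sampling import admissible

__all__ = ["CohortSpec", "make_insulin", "make_glucose", "make_cohort"]


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Log-normal medians/log-sds define the hidden parameter distribution;
    concentration units are mg/dL (glucose), umol/L (FFA), uU/mL (insulin),
    rates in 1/min.
    """

    model_id: str = "2d"
    n_subjects: int = 25
    noise_sd: float = 0.03          # relative measurement noise, all channels
    seed: int = 0
    # insulin archetype
    insulin_basal: tuple = (8.0, 0.25)      # (median, log-sd)
    insulin_peak: tuple = (80.0, 0.35)      # bolus peak height above basal
    insulin_tau: tuple = (4.0, 0.2)         # minutes to peak after the bolus
    # glucose archetype
    glucose_basal: tuple = (92.0, 0.08)
    glucose_peak: tuple = (190.0, 0.2)      # rise above basal
    glucose_decay: tuple = (0.022, 0.25)    # 1/min
    # hidden parameter medians / log-sds
    params_2d: dict = field(default_factory=lambda: {
        "SGF": (3.2e-4, 0.30), "PXalpha": (3.0e-5, 0.35),
        "PX": (0.055, 0.30), "Fb": (480.0, 0.20),
        # SFb is tied to basal balance: SFb = u * SGF * Gb * Fb
        "balance": (0.92, 0.06),
    })
    params_3d: dict = field(default_factory=lambda: {
        "SG": (0.016, 0.25), "SI": (6.0e-5, 0.35), "CX": (0.055, 0.30),
        "X2": (25.0, 0.30), "CF": (0.045, 0.25), "L2": (14.0, 0.35),
        "X22": (0.5, 0.40),
    })

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _lognormal(rng, median, log_sd):
    return float(median * np.exp(log_sd * rng.standard_normal()))


def make_insulin(spec: CohortSpec, rng) -> np.ndarray:
    """One subject's insulin series on the full grid: basal, then a bolus
    transient peaking in (20, 30] and decaying toward basal."""
    Ib = _lognormal(rng, *spec.insulin_basal)
    H = _lognormal(rng, *spec.insulin_peak)
    tau = float(np.clip(_lognormal(rng, *spec.insulin_tau), 1.0, 9.5))
    s = np.maximum(T_ALL - 20.0, 0.0) / tau
    return Ib + H * s * np.exp(1.0 - s)


def make_glucose(spec: CohortSpec, rng, Gb=None) -> np.ndarray:
    """Glucose archetype: basal at t = 0, sharp post-injection rise, slow decay."""
    if Gb is None:
        Gb = _lognormal(rng, *spec.glucose_basal)
    P = _lognormal(rng, *spec.glucose_peak)
    kd = _lognormal(rng, *spec.glucose_decay)
    kr = 1.2  # fast distribution phase, 1/min
    shape = np.exp(-kd * T_ALL) - np.exp(-kr * T_ALL)
    return Gb + P * shape / shape.max()


def _draw_params_2d(spec, rng, Gb):
    d = spec.params_2d
    SGF = _lognormal(rng, *d["SGF"])
    PXa = _lognormal(rng, *d["PXalpha"])
    PX = _lognormal(rng, *d["PX"])
    Fb = _lognormal(rng, *d["Fb"])
    u = _lognormal(rng, *d["balance"])
    SFb = u * SGF * Gb * Fb
    return Params2D(SGF=SGF, SFb=SFb, PXalpha=PXa, PX=PX, Fb=Fb)


def _draw_params_3d(spec, rng, Gb, Fb):
    d = spec.params_3d
    return Params3D(
        SG=_lognormal(rng, *d["SG"]), SI=_lognormal(rng, *d["SI"]),
        CX=_lognormal(rng, *d["CX"]), X2=_lognormal(rng, *d["X2"]),
        CF=_lognormal(rng, *d["CF"]), L2=_lognormal(rng, *d["L2"]),
        Gb=Gb, Fb=Fb, X22=_lognormal(rng, *d["X22"]))


def _noise(rng, x, sd):
    if sd == 0:
        return x.copy()
    return x * np.exp(sd * rng.standard_normal(x.shape) - 0.5 * sd * sd)


def make_cohort(spec: CohortSpec, max_attempts: int = 100):
    """Generate the cohort; returns (records, truth table).

    Truth rows align one-to-one with the records (index = subject id,
    starting at 1).
    """
    rng = np.random.default_rng(spec.seed)
    records, truth_rows = [], []
    for sid in range(1, spec.n_subjects + 1):
        for attempt in range(max_attempts):
            I = make_insulin(spec, rng)
            Ib = I[0]
            insulin = InputSignal(T_ALL, I)
            if spec.model_id == "2d":
                G = make_glucose(spec, rng)
                p = _draw_params_2d(spec, rng, Gb=G[0])
                traj = integrate("2d", p, {"insulin": insulin,
                                           "glucose": InputSignal(T_ALL, G),
                                           "Ib": Ib})
                F = traj.F
                ok, _ = admissible(traj)
                truth = {n: getattr(p, n) for n in PARAM_NAMES_2D}
            else:
                G_arch = make_glucose(spec, rng)
                Gb = G_arch[0]
                Fb = _lognormal(rng, *spec.params_2d["Fb"])
                p = _draw_params_3d(spec, rng, Gb, Fb)
                mask = T_ALL > 20
                F22 = Fb * _lognormal(rng, 1.02, 0.03)
                traj = integrate("3d", p, {"insulin": insulin, "Ib": Ib},
                                 grid=T_POST20,
                                 initial_conditions=(G_arch[mask][0], F22))
                G = G_arch.copy()
                G[mask] = traj.G
                F = np.empty_like(G)
                F[~mask] = np.linspace(Fb, F22, (~mask).sum())
                F[mask] = traj.F
                ok, _ = admissible(traj, Gb=p.Gb)
                truth = {n: getattr(p, n) for n in PARAM_NAMES_3D
                         if n not in ("G22", "F22")}
                truth["G22"] = G_arch[mask][0]
                truth["F22"] = F22
            if not (ok and traj.ok and np.all(F > 0) and np.all(G > 0)):
                continue
            Gn, Fn, In = (_noise(rng, x, spec.noise_sd) for x in (G, F, I))
            try:
                rec = SubjectRecord(G=Gn, F=Fn, I=In, subject_id=sid)
            except ValueError:
                continue
            records.append(rec)
            truth_rows.append({"subject": sid, **truth})
            break
        else:
            raise RuntimeError(
                f"subject {sid}: no admissible record in {max_attempts} attempts")
    truth = pd.DataFrame(truth_rows).set_index("subject")
    return records, truth
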