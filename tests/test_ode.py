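"""ODE model definitions, interpolated inputs, and integration accuracy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipoinfer import (
    InputSignal,
    Params2D,
    Params3D,
    T_ALL,
    T_POST20,
    integrate,
    integrate_batch_2d,
    integrate_batch_3d,
    rhs_2d,
    rhs_3d,
)
from lipoinfer.ode import make_fast_integrator_2d, make_fast_integrator_3d


def _const_signal(grid, value):
    return InputSignal(grid, np.full(len(grid), value))


class TestGrids:
    def test_protocol_grid(self):
        assert T_ALL[0] == 0 and len(T_ALL) == 28
        assert np.all(np.diff(T_ALL) > 0)
        assert len(T_POST20) == 16 and T_POST20[0] == 22 and T_POST20[-1] == 180


class TestInputSignal:
    def test_exact_at_samples_and_clamped_outside(self):
        sig = InputSignal([0.0, 1.0, 3.0], [2.0, 5.0, 4.0])
        assert sig(1.0) == 5.0
        assert sig(2.0) == pytest.approx(4.5)
        assert sig(-10.0) == 2.0 and sig(99.0) == 4.0

    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError):
            InputSignal([0.0, 2.0, 1.0], [1.0, 1.0, 1.0])


class TestRhs:
    def test_basal_equilibrium_3d(self):
        p = Params3D(SG=0.02, SI=1e-4, CX=0.05, X2=20, CF=0.04, L2=10,
                     Gb=90, Fb=500, X22=0)
        ins = _const_signal(T_POST20, 8.0)
        d = rhs_3d((90.0, 500.0, 0.0), 30.0, p, ins, Ib=8.0)
        assert np.allclose(d, 0.0)

    def test_decoupled_linear_limit_3d(self):
        # X = 0 and insulin at basal: dG/dt reduces to -SG (G - Gb)
        p = Params3D(SG=0.03, SI=5e-4, CX=0.1, X2=10, CF=0.04, L2=10,
                     Gb=90, Fb=500, X22=0)
        ins = _const_signal(T_POST20, 8.0)
        dG, dF, dX = rhs_3d((200.0, 500.0, 0.0), 50.0, p, ins, Ib=8.0)
        assert dG == pytest.approx(-0.03 * (200 - 90))
        assert dX == 0.0 and dF == 0.0

    @pytest.mark.parametrize("model_id", ["3d", "2d"])
    def test_term_by_term_oracle(self, model_id):
        """Each derivative equals an independent term-by-term re-derivation
        at 100 random states/parameters."""
        rng = np.random.default_rng(0)
        ins = InputSignal(T_ALL, 8 + 50 * rng.random(28))
        glu = InputSignal(T_ALL, 80 + 200 * rng.random(28))
        for _ in range(100):
            t = float(rng.uniform(0, 180))
            if model_id == "3d":
                p = Params3D(*np.abs(rng.normal(size=9)) + 0.01)
                G, F, X = rng.uniform(1, 500, 3)
                got = rhs_3d((G, F, X), t, p, ins, Ib=8.0)
                I_t = np.interp(t, T_ALL, ins.values)
                exp = (-p.SG * (G - p.Gb) - p.SI * X * G,
                       -p.CF * (F - p.Fb) - p.L2 * (X ** 2) / (p.X2 ** 2 + X ** 2),
                       p.CX * (max(I_t - 8.0, 0.0) - X))
            else:
                p = Params2D(*np.abs(rng.normal(size=5)) + 0.01)
                F, X = rng.uniform(0.1, 500, 2)
                got = rhs_2d((F, X), t, p, glu, ins, Ib=8.0)
                G_t = np.interp(t, T_ALL, glu.values)
                I_t = np.interp(t, T_ALL, ins.values)
                exp = (-p.SGF * G_t * F + p.SFb - p.Fb * X,
                       p.PXalpha * (I_t - 8.0) - p.PX * X)
            assert np.allclose(got, exp, rtol=1e-12)

    def test_x2_zero_rejected_at_construction(self):
        with pytest.raises(ValueError):
            Params3D(SG=0.02, SI=1e-4, CX=0.05, X2=0.0, CF=0.04, L2=10,
                     Gb=90, Fb=500)


class TestIntegrate:
    def test_3d_closed_form_exponential(self):
        """With insulin pinned at basal and no remote insulin, glucose relaxes
        exponentially toward basal."""
        p = Params3D(SG=0.02, SI=3e-4, CX=0.05, X2=20, CF=0.04, L2=10,
                     Gb=90, Fb=500, X22=0)
        ins = _const_signal(T_POST20, 8.0)
        tr = integrate("3d", p, {"insulin": ins, "Ib": 8.0},
                       initial_conditions=(250.0, 520.0))
        exact = 90 + (250 - 90) * np.exp(-0.02 * (T_POST20 - 22))
        assert np.max(np.abs(tr.G - exact) / exact) < 1e-6

    def test_2d_closed_form_relaxation(self):
        """Basal insulin and constant glucose: F relaxes to SFb/(SGF Gc)."""
        p = Params2D(SGF=3e-4, SFb=10.0, PXalpha=2e-5, PX=0.05, Fb=500)
        Gc = 120.0
        tr = integrate("2d", p, {"insulin": _const_signal(T_ALL, 8.0),
                                 "glucose": _const_signal(T_ALL, Gc),
                                 "Ib": 8.0})
        k = p.SGF * Gc
        exact = p.SFb / k + (p.Fb - p.SFb / k) * np.exp(-k * T_ALL)
        assert np.max(np.abs(tr.F - exact) / exact) < 1e-6

    def test_tolerance_halving_invariance(self, cohort_2d):
        records, truth = cohort_2d
        s = records[0]
        p = Params2D(**truth.loc[1].to_dict())
        sig = {"insulin": s.insulin_signal(), "glucose": s.glucose_signal(),
               "Ib": s.Ib}
        a = integrate("2d", p, sig)
        b = integrate("2d", p, sig, rtol=5e-9, atol=5e-11)
        assert np.max(np.abs(a.F - b.F) / np.abs(b.F)) < 1e-6

    def test_remote_insulin_never_negative(self, dist_3d):
        """The positive-part clamp on insulin excursions keeps X >= 0 for
        non-negative initial X on 1000 random parameter sets."""
        rng = np.random.default_rng(3)
        params = dist_3d.sample(1000, seed=4)
        ins = 8 + 40 * rng.random((1000, 16))
        states = integrate_batch_3d(params[:, [dist_3d.names_.index(c) for c in
                                    ("SG", "SI", "CX", "X2", "CF", "L2", "Gb",
                                     "Fb", "X22", "G22", "F22")]], ins)
        assert states[:, :, 2].min() >= 0.0


class TestBatchAndFastIntegrators:
    """The batch RK4 and the per-subject fast path must agree with the
    adaptive reference solution."""

    def test_batch_2d_matches_adaptive(self, cohort_2d):
        records, truth = cohort_2d
        s = records[2]
        p = Params2D(**truth.loc[3].to_dict())
        ref = integrate("2d", p, {"insulin": s.insulin_signal(),
                                  "glucose": s.glucose_signal(), "Ib": s.Ib})
        got = integrate_batch_2d(p.as_array()[None], s.G[None], s.I[None],
                                 dt_max=0.1)
        assert np.max(np.abs(got[0, :, 0] - ref.F) / np.abs(ref.F)) < 1e-6

    def test_fast_integrator_matches_adaptive(self, cohort_2d):
        records, truth = cohort_2d
        s = records[4]
        p = Params2D(**truth.loc[5].to_dict())
        run = make_fast_integrator_2d(s.glucose_signal(), s.insulin_signal(),
                                      s.Ib, dt_max=0.1)
        ref = integrate("2d", p, {"insulin": s.insulin_signal(),
                                  "glucose": s.glucose_signal(), "Ib": s.Ib})
        assert np.max(np.abs(run(p)[:, 0] - ref.F) / np.abs(ref.F)) < 1e-6

    def test_fast_integrator_3d_matches_adaptive(self, cohort_3d):
        records, truth = cohort_3d
        s = records[0]
        row = truth.loc[1]
        p = Params3D(**{k: row[k] for k in ("SG", "SI", "CX", "X2", "CF",
                                            "L2", "Gb", "Fb", "X22")})
        run = make_fast_integrator_3d(s.insulin_signal(), s.Ib, dt_max=0.05)
        ref = integrate("3d", p, {"insulin": s.insulin_signal(), "Ib": s.Ib},
                        initial_conditions=(row["G22"], row["F22"]))
        got = run(p, row["G22"], row["F22"])
        for c in range(2):  # concentration channels
            assert np.max(np.abs(got[:, c] - ref.states[:, c])
                          / np.abs(ref.states[:, c])) < 1e-6


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(0.005, 0.1), st.floats(1e-5, 1e-3), st.floats(100, 300))
def test_basal_fixed_point_property(SG, SI, G22):
    """From exactly basal initial state with basal insulin, the 3D state is
    constant over the whole grid."""
    p = Params3D(SG=SG, SI=SI, CX=0.05, X2=20, CF=0.04, L2=10,
                 Gb=G22, Fb=400, X22=0)
    ins = _const_signal(T_POST20, 10.0)
    tr = integrate("3d", p, {"insulin": ins, "Ib": 10.0},
                   initial_conditions=(G22, 400.0))
    assert np.max(np.abs(tr.states - tr.states[0])) < 1e-9
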