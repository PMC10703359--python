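"""Reaction-diffusion lattice, Euler scheme, initiation rule, calibration."""

import numpy as np
import pytest
from scipy.sparse import diags

from polywhorl.errors import (CalibrationError, GeometryError,
                              NumericalInstabilityError)
from polywhorl.metrics import detect_rings, internode_lengths
from polywhorl.simulator import (SimParams, SimState, calibrate_params,
                                 euler_step, initial_state, laplacian_cylinder,
                                 run_simulation, stability_bound, try_initiate)

SMALL = dict(W=36, L=40, max_steps=6000, max_tentacles=4,
             init_warmup=1500, init_interval=500)


class TestLaplacian:
    def test_constant_field_is_zero(self):
        f = np.full((8, 10), 3.7)
        np.testing.assert_allclose(laplacian_cylinder(f), 0.0, atol=1e-12)

    def test_unit_spike_stencil(self):
        f = np.zeros((9, 9))
        f[4, 4] = 1.0
        lap = laplacian_cylinder(f)
        assert lap[4, 4] == -4
        assert lap[3, 4] == lap[5, 4] == lap[4, 3] == lap[4, 5] == 1
        assert np.count_nonzero(lap) == 5

    def test_flux_conservation(self, rng):
        f = rng.uniform(0, 10, (15, 12))
        assert abs(laplacian_cylinder(f).sum()) < 1e-9

    def test_periodic_wrap_and_neumann_edges(self):
        f = np.zeros((5, 6))
        f[2, 0] = 1.0
        lap = laplacian_cylinder(f)
        assert lap[2, 5] == 1.0  # wraps circumferentially
        f2 = np.zeros((5, 6))
        f2[0, 3] = 1.0
        lap2 = laplacian_cylinder(f2)
        assert lap2[0, 3] == -3.0  # mirrored ghost row at the oral end

    def test_too_small_geometry(self):
        with pytest.raises(GeometryError):
            laplacian_cylinder(np.zeros((2, 10)))


class TestEulerStep:
    def test_pure_decay_tracks_closed_form(self):
        k = 0.3
        errs = []
        for frac in (0.8, 0.2, 0.05):
            p = SimParams(D_a=0, D_b=0, D_c=0, k_a=k, k_b=k, k_c=k,
                          s_a=0, s_b=0, s_c=0, W=6, L=6, noise_amp=0,
                          dt_fraction=frac)
            state = SimState(a=np.full((6, 6), 2.0), b=np.zeros((6, 6)),
                             c=np.zeros((6, 6)))
            t_target = 5.0
            n = int(round(t_target / p.effective_dt))
            for _ in range(n):
                euler_step(state, p)
            exact = 2.0 * np.exp(-k * n * p.effective_dt)
            discrete = 2.0 * (1 - k * p.effective_dt) ** n
            np.testing.assert_allclose(state.a, discrete, rtol=1e-10)
            errs.append(abs(state.a[0, 0] - exact))
        assert errs[0] > errs[1] > errs[2]  # converges to e^(-kt) as dt -> 0

    def test_source_only_first_step(self):
        p = SimParams(D_a=0, D_b=0, D_c=0, k_a=1e-9, k_b=1e-9, k_c=1e-9,
                      s_a=2.0, s_b=0, s_c=0, W=6, L=8, mouth_rows=2,
                      noise_amp=0)
        state = SimState(a=np.zeros((8, 6)), b=np.zeros((8, 6)), c=np.zeros((8, 6)))
        euler_step(state, p)
        dt = p.effective_dt
        np.testing.assert_allclose(state.a[:2], 2.0 * dt)
        np.testing.assert_allclose(state.a[2:], 0.0)

    def test_mass_balance_per_step(self, rng):
        p = SimParams(W=12, L=14, noise_amp=1e-3, seed=7)
        state = initial_state(p)
        state.tentacles = [(7, 3, 0)]
        mouth = np.zeros((14, 12), bool)
        mouth[:2] = True
        dt = p.effective_dt
        for _ in range(50):
            masses = {n: getattr(state, n).sum() for n in "abc"}
            euler_step(state, p)
            for name, k, s, n_src in (("a", p.k_a, p.s_a, mouth.sum()),
                                      ("b", p.k_b, p.s_b, mouth.sum()),
                                      ("c", p.k_c, p.s_c, 1)):
                expected = masses[name] + dt * (s * n_src - k * masses[name])
                got = getattr(state, name).sum()
                assert got == pytest.approx(expected, rel=1e-9)

    def test_nonfinite_field_raises_named_error(self):
        p = SimParams(W=6, L=6, noise_amp=0)
        state = SimState(a=np.zeros((6, 6)), b=np.zeros((6, 6)), c=np.zeros((6, 6)))
        state.b[3, 3] = np.nan
        with pytest.raises(NumericalInstabilityError, match="'b'"):
            euler_step(state, p)

    def test_steady_state_matches_1d_bvp_oracle(self):
        """Axial steady profile of the mouth-sourced activator against an
        independent direct linear solve of the same 1D two-point problem."""
        D, k, s = 1.0, 0.1, 1.0
        L, W = 40, 8
        p = SimParams(D_a=D, D_b=D, D_c=D, k_a=k, k_b=k, k_c=k,
                      s_a=s, s_b=0, s_c=0, W=W, L=L, noise_amp=0,
                      max_steps=0)
        state = SimState(a=np.zeros((L, W)), b=np.zeros((L, W)), c=np.zeros((L, W)))
        for _ in range(4000):
            euler_step(state, p)
        profile = state.a.mean(axis=1)
        # oracle: (k I - D A) x = src with Neumann tridiagonal A
        main = np.full(L, -2.0)
        main[0] = main[-1] = -1.0
        A = diags([np.ones(L - 1), main, np.ones(L - 1)], [-1, 0, 1]).toarray()
        src = np.zeros(L)
        src[:2] = s
        oracle = np.linalg.solve(k * np.eye(L) - D * A, src)
        np.testing.assert_allclose(profile, oracle, rtol=0.02)
        # decay length scale ~ sqrt(D/k)
        ell = np.sqrt(D / k)
        mid = profile[10:30]
        ratio = mid[1:] / mid[:-1]
        assert np.allclose(np.log(ratio), -1.0 / ell, atol=0.05)


class TestStability:
    def test_bound_formula(self):
        p = SimParams()
        assert stability_bound(p) == pytest.approx(1.0 / (4 * 3.0 + 12.0))

    def test_unstable_dt_override_rejected(self):
        with pytest.raises(NumericalInstabilityError):
            SimParams(dt=1.0)

    def test_default_dt_under_bound(self):
        p = SimParams()
        assert p.effective_dt <= stability_bound(p)


class TestTryInitiate:
    def _state(self, p, a=0.0, b=0.0, c=0.0):
        shape = (p.L, p.W)
        return SimState(a=np.full(shape, a), b=np.full(shape, b),
                        c=np.full(shape, c))

    def test_no_cell_above_activator_threshold(self):
        p = SimParams(W=6, L=8)
        state = self._state(p, a=p.T_a * 0.5)
        assert try_initiate(state, p) is None
        assert state.tentacles == []

    def test_single_eligible_cell_selected(self):
        p = SimParams(W=6, L=8)
        state = self._state(p, a=0.0)
        state.a[5, 2] = p.T_a * 2
        assert try_initiate(state, p) == (5, 2)

    def test_mouth_rows_and_existing_tentacles_excluded(self):
        p = SimParams(W=6, L=8, mouth_rows=2)
        state = self._state(p, a=0.0)
        state.a[0, 1] = p.T_a * 10   # mouth: excluded
        state.a[4, 4] = p.T_a * 5
        state.tentacles = [(4, 4, 0)]
        state.a[6, 1] = p.T_a * 2
        assert try_initiate(state, p) == (6, 1)

    def test_tie_breaks_lexicographically(self):
        p = SimParams(W=6, L=8)
        state = self._state(p, a=0.0)
        state.a[5, 4] = p.T_a * 2
        state.a[3, 5] = p.T_a * 2
        assert try_initiate(state, p) == (3, 5)

    def test_inhibitor_gates(self):
        p = SimParams(W=6, L=8)
        state = self._state(p, a=p.T_a * 2)
        state.b[:] = p.T_i * 2
        assert try_initiate(state, p) is None
        state.b[:] = 0.0
        state.c[:] = p.T_ti * 2
        assert try_initiate(state, p) is None


class TestRunSimulation:
    def test_no_sources_no_tentacles(self):
        p = SimParams(s_a=0, s_b=0, s_c=0, noise_amp=1e-4, **SMALL)
        state, arr = run_simulation(p)
        assert state.tentacles == [] and arr is None

    def test_sequential_oral_first(self, simulated_runs):
        state, arr = simulated_runs[(72, 1)]
        steps = [s for _, _, s in state.tentacles]
        assert steps == sorted(steps) and len(set(steps)) == len(steps)
        rows = [r for r, _, _ in state.tentacles]
        assert rows[0] < 40  # oral half of the 80-row lattice
        part = detect_rings(internode_lengths(arr))
        mean_rows = [np.mean([arr.h[i] for i in ring]) for ring in part.rings]
        assert all(b > a for a, b in zip(mean_rows, mean_rows[1:]))

    def test_fields_stay_nonnegative(self, simulated_runs):
        state, _ = simulated_runs[(54, 1)]
        for name in "abc":
            assert getattr(state, name).min() >= 0.0

    def test_tentacles_are_body_cells(self, simulated_runs):
        p = SimParams(W=90)
        state, _ = simulated_runs[(90, 2)]
        cells = [(r, c) for r, c, _ in state.tentacles]
        assert len(set(cells)) == len(cells)
        assert all(r >= p.mouth_rows for r, _ in cells)

    def test_rotating_noise_rotates_pattern(self):
        p = SimParams(noise_amp=2e-4, seed=9, **SMALL)
        rng = np.random.default_rng(p.seed)
        shape = (p.L, p.W)
        noise = tuple(rng.uniform(0, p.noise_amp, shape) for _ in range(3))
        shift = 11
        rolled = tuple(np.roll(f, shift, axis=1) for f in noise)
        _, arr1 = run_simulation(p, initial_noise=noise)
        _, arr2 = run_simulation(p, initial_noise=rolled)
        cells1 = sorted((t.h, (t.theta + shift * 360.0 / p.W) % 360.0)
                        for t in arr1.tentacles)
        cells2 = sorted((t.h, t.theta) for t in arr2.tentacles)
        for (h1, t1), (h2, t2) in zip(cells1, cells2):
            assert h1 == h2
            assert t1 == pytest.approx(t2, abs=1e-9)

    def test_deterministic_given_seed(self):
        p = SimParams(seed=5, **SMALL)
        _, a1 = run_simulation(p)
        _, a2 = run_simulation(p)
        assert [(t.h, t.theta) for t in a1.tentacles] == \
               [(t.h, t.theta) for t in a2.tentacles]


class TestCalibration:
    BASE = SimParams(L=40, max_steps=8000, max_tentacles=6,
                     init_warmup=1500, init_interval=500)

    def test_degenerate_range_returns_known_good_set(self):
        good_ell = np.sqrt(self.BASE.D_c / self.BASE.k_c)
        params = calibrate_params(
            ell_values=[good_ell], tti_values=[self.BASE.T_ti],
            base=self.BASE, seeds=(1,), min_successes=1,
        )
        assert params.T_ti == self.BASE.T_ti
        assert params.k_c == pytest.approx(self.BASE.k_c)

    def test_unbounded_inhibitor_threshold_fails(self):
        with pytest.raises(CalibrationError) as excinfo:
            calibrate_params(
                ell_values=[np.sqrt(self.BASE.D_c / self.BASE.k_c)],
                tti_values=[1e6],  # never blocks: no lateral spacing
                base=self.BASE, seeds=(1,), min_successes=1,
            )
        assert excinfo.value.best_candidate is not None
        assert excinfo.value.report
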