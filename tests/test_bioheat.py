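"""Pennes solver: equilibria, closed-form oracles, conservation, coupling."""

import numpy as np
import pytest

from mwasim.bioheat import (
    CouplingPolicy,
    PennesSolver,
    ProbeObserver,
    SnapshotObserver,
    ThermalProblem,
    ThermalState,
    probe_trace,
    run_coupled,
)
from mwasim.constants import BODY_TEMPERATURE_K
from mwasim.grids import LabelGrid, Tissue
from mwasim.phantom import AntennaTemplate, build_phantom, phantom_for_patient

TB = BODY_TEMPERATURE_K


def uniform_liver(shape=(8, 8, 8), spacing=1.0):
    return LabelGrid(np.full(shape, Tissue.LIVER, np.int16), (spacing,) * 3)


class TestStep:
    def test_equilibrium_without_sources(self, materials):
        problem = ThermalProblem(grid=uniform_liver(), materials=materials,
                                 include_metabolic=False, dt=0.5, duration=5.0,
                                 constant_properties=True)
        state = PennesSolver(problem).run()
        assert np.abs(state.temperature - TB).max() < 1e-9

    def test_uniform_heating_reaches_perfusion_limited_steady_state(self, materials):
        # spatially uniform: conduction vanishes, leaving the scalar balance
        # rho*C dT/dt = rho_b C_b omega_b (Tb - T) + Qmet; the steady excess
        # is Qmet / (rho_b C_b omega_b) with the 37 degC perfusion rate
        problem = ThermalProblem(grid=uniform_liver(), materials=materials,
                                 dt=50.0, duration=10000.0, constant_properties=True)
        state = PennesSolver(problem).run()
        expected = 33800.0 / (1060.0 * 3600.0 * 0.001127)
        excess = state.temperature.max() - TB
        assert np.ptp(state.temperature) < 1e-6  # uniform up to solver tolerance
        assert excess == pytest.approx(expected, rel=1e-3)

    def test_uniform_heating_exponential_rate(self, materials):
        # transient follows (1 - exp(-t/tau)) with tau = rho*C/(rho_b C_b omega_b)
        problem = ThermalProblem(grid=uniform_liver(), materials=materials,
                                 dt=2.0, duration=888.0, constant_properties=True)
        state = PennesSolver(problem).run()
        rho_c = 1079.0 * 3540.0
        lam = 1060.0 * 3600.0 * 0.001127 / rho_c
        expected = 33800.0 / (1060.0 * 3600.0 * 0.001127) * (1 - np.exp(-lam * 888.0))
        assert state.temperature.max() - TB == pytest.approx(expected, rel=0.01)

    def test_slab_conduction_matches_fourier_series(self, materials):
        # 1-D slab with fixed ends: the fundamental sine mode decays as
        # exp(-alpha (pi/L)^2 t); compare at t = 60 s on a 0.5 mm grid
        n = 41
        h = 0.5
        grid = LabelGrid(np.full((n, 1, 1), Tissue.LIVER, np.int16), (h, h, h))
        x = grid.axis_centers(0)
        length = x[-1] - x[0]  # distance between the two fixed voxel centres
        mode = np.sin(np.pi * (x - x[0]) / length)[:, None, None]
        fixed = np.zeros(grid.shape, bool)
        fixed[0], fixed[-1] = True, True

        problem = ThermalProblem(grid=grid, materials=materials, dt=0.5, duration=60.0,
                                 fixed_mask=fixed, fixed_values=TB,
                                 include_metabolic=False, constant_properties=True)
        solver = PennesSolver(problem)
        state = ThermalState(TB + 5.0 * mode)
        # disable perfusion to isolate conduction
        solver._static_maps = (solver._static_maps[0], solver._static_maps[1],
                               np.zeros(grid.shape), solver._static_maps[3])
        for _ in range(120):
            state = solver.step(state, 0.5)
        k = 0.535005
        alpha = k / (1079.0 * 3540.0)
        decay = np.exp(-alpha * (np.pi / (length * 1e-3)) ** 2 * 60.0)
        expected = TB + 5.0 * mode * decay
        interior = slice(1, -1)
        err = np.abs(state.temperature[interior] - expected[interior]).max()
        assert err / (5.0 * decay) < 0.01

    def test_energy_conservation_each_step(self, materials):
        # insulated domain: dE = (sources - perfusion sink) * dt exactly
        grid = uniform_liver((10, 10, 10), 1.0)
        q = np.zeros(grid.shape)
        q[4:6, 4:6, 4:6] = 5e6  # localised heating, W/m^3
        problem = ThermalProblem(grid=grid, materials=materials, q_ext=q,
                                 dt=0.5, duration=0.0)
        solver = PennesSolver(problem)
        state = solver.initial_state()
        for _ in range(20):
            state = solver.step(state, 0.5)
            # backward Euler is a discrete identity here; anything beyond
            # linear-solver tolerance would indicate an assembly defect
            assert solver.last_audit["residual_rel"] < 1e-4

    def test_discrete_maximum_principle(self, materials):
        grid = uniform_liver((10, 10, 10), 1.0)
        q = np.zeros(grid.shape)
        q[5, 5, 5] = 2e7
        problem = ThermalProblem(grid=grid, materials=materials, q_ext=q,
                                 dt=0.5, duration=30.0)
        state = PennesSolver(problem).run()
        assert state.temperature.min() >= TB - 1e-6
        assert state.temperature.max() > TB + 1.0

    def test_invalid_dt_rejected(self, materials):
        with pytest.raises(ValueError):
            ThermalProblem(grid=uniform_liver(), materials=materials, dt=-1.0)


class TestManufactured:
    """Grid convergence of the spatial discretisation on a steady solution."""

    @staticmethod
    def _steady_error(n, materials):
        h = 16.0 / n
        grid = LabelGrid(np.full((n, n, n), Tissue.LIVER, np.int16), (h, h, h))
        lx = n * h * 1e-3
        axes = [grid.axis_centers(a) * 1e-3 for a in range(3)]
        xx = axes[0][:, None, None]
        yy = axes[1][None, :, None]
        zz = axes[2][None, None, :]
        s = np.pi / lx
        t_m = TB + 20.0 * np.sin(s * xx) * np.sin(s * yy) * np.sin(s * zz)

        k = 0.535005
        sink = 1060.0 * 3600.0 * 0.001127
        q = k * 3 * s**2 * (t_m - TB) + sink * (t_m - TB)

        boundary = np.zeros(grid.shape, bool)
        for a in range(3):
            np.moveaxis(boundary, a, 0)[0] = True
            np.moveaxis(boundary, a, 0)[-1] = True
        problem = ThermalProblem(grid=grid, materials=materials, q_ext=q,
                                 fixed_mask=boundary, fixed_values=t_m,
                                 include_metabolic=False, constant_properties=True,
                                 dt=1e9, duration=0.0)
        solver = PennesSolver(problem)
        state = ThermalState(np.full(grid.shape, TB))
        state = solver.step(state, 1e9)  # one huge implicit step = steady solve
        err = state.temperature[~boundary] - t_m[~boundary]
        return float(np.sqrt(np.mean(err**2)))

    def test_second_order_in_space(self, materials):
        e1 = self._steady_error(16, materials)
        e2 = self._steady_error(32, materials)
        assert np.log2(e1 / e2) >= 1.5

    def test_first_order_in_dt(self, materials):
        # uniform problem: exact exponential relaxation toward steady state
        def error(dt):
            problem = ThermalProblem(grid=uniform_liver((4, 4, 4)), materials=materials,
                                     dt=dt, duration=200.0, constant_properties=True)
            state = PennesSolver(problem).run()
            rho_c = 1079.0 * 3540.0
            sink = 1060.0 * 3600.0 * 0.001127
            exact = TB + 33800.0 / sink * (1 - np.exp(-sink / rho_c * 200.0))
            return abs(state.temperature.max() - exact)

        order = np.log2(error(20.0) / error(10.0))
        assert 0.7 <= order <= 1.3


class TestCoupledRun:
    def test_static_properties_make_em_resolve_a_fixed_point(self, materials):
        spec = phantom_for_patient(1, spacing=4.0)
        grid = build_phantom(spec)
        result = run_coupled(grid, materials, AntennaTemplate(), spec.entry_point,
                             spec.tip_point, power_w=30.0, duration=20.0, dt=1.0,
                             policy=CouplingPolicy(resolve_interval_s=5.0),
                             temperature_dependent=False)
        # with frozen dielectric maps, only the initial EM solve happens and
        # the source stays constant
        assert result.state.em_solve_count == 1
        absorbed = [a for (_, _, a) in result.em_history]
        assert len(set(absorbed)) == 1

    def test_energy_gain_bounded_by_delivered_plus_metabolic(self, patient1_run):
        run = patient1_run
        grid = run.grid
        t_final = run.result.state.temperature
        k, rho_c, perf, qmet = run.result.problem.materials.thermal_maps(
            grid.labels, 37.0)
        vol = grid.voxel_volume_mm3 * 1e-9
        gain = float(np.sum(rho_c * (t_final - TB)) * vol)
        metabolic = float(qmet.sum() * vol) * 600.0
        assert gain <= run.result.delivered_energy_J + metabolic

    def test_tumor_exceeds_lethal_threshold_during_ablation(self, patient1_run):
        peak_c = patient1_run.result.state.peak_temperature - 273.15
        tumor = patient1_run.grid.labels == Tissue.TUMOR
        assert peak_c[tumor].max() > 50.0

    def test_minimum_temperature_never_below_baseline(self, patient1_run):
        assert patient1_run.result.state.temperature.min() >= TB - 1e-6

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            CouplingPolicy(resolve_interval_s=0.0)


class TestProbes:
    def test_probe_trace_starts_at_initial_temperature(self, patient1_run):
        snaps = patient1_run.snapshots.snapshots
        times, values = probe_trace(snaps, patient1_run.grid,
                                    patient1_run.spec.tumor_center)
        assert times[0] == 0.0
        assert values[0] == pytest.approx(TB, abs=1e-9)

    def test_on_axis_heating_trace_monotone(self, materials):
        grid = uniform_liver((8, 8, 8), 2.0)
        q = np.zeros(grid.shape)
        q[3:5, 3:5, 3:5] = 1e6
        problem = ThermalProblem(grid=grid, materials=materials, q_ext=q,
                                 dt=1.0, duration=20.0, constant_properties=True)
        obs = ProbeObserver(grid, [(8.0, 8.0, 8.0)])
        PennesSolver(problem).run(observers=[obs])
        _, trace = obs.trace(0)
        assert np.all(np.diff(trace) > -1e-9)

    def test_out_of_domain_probe_rejected(self, materials):
        grid = uniform_liver((8, 8, 8), 2.0)
        with pytest.raises(ValueError, match="outside"):
            ProbeObserver(grid, [(100.0, 8.0, 8.0)])
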