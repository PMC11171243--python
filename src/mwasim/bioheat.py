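"""Pennes bioheat solver on 3-D voxel grids, with EM coupling.

The tissue temperature obeys the Pennes equation

.. math::

    \\rho C \\,\\partial_t T = \\nabla\\cdot(k \\nabla T)
    + \\rho_b C_b \\omega_b (T_b - T) + Q_{met} + Q_{ext},

with insulated (zero-flux) outer boundaries.  Time stepping is implicit
backward Euler with the temperature-dependent coefficients ``k(T)`` and
``omega_b(T)`` lagged at the previous step (single Picard iteration), which
is unconditionally stable and first-order accurate in ``dt``.  The linear
system is a symmetric positive-definite 7-point stencil solved matrix-free
with Jacobi-preconditioned conjugate gradients.

Two-way electromagnetic coupling (:func:`run_coupled`) re-solves the
axisymmetric antenna problem whenever the schedule or the accumulated
change in electrical conductivity demands it, and refreshes the volumetric
heat source ``Q_ext``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import LinearOperator, cg

from .constants import BODY_TEMPERATURE_K, celsius
from .em import EMProblem, EMSolution, build_em_problem, revolve_to_3d, solve_em
from .grids import LabelGrid
from .materials import MaterialModel
from .phantom import AntennaTemplate

__all__ = [
    "ThermalProblem",
    "ThermalState",
    "PennesSolver",
    "CouplingPolicy",
    "CoupledResult",
    "run_coupled",
    "probe_trace",
]


@dataclass
class ThermalProblem:
    """Definition of one bioheat run on a voxel grid (temperatures in K)."""

    grid: LabelGrid
    materials: MaterialModel
    q_ext: np.ndarray | None = None  # W/m^3
    initial_temperature: float = BODY_TEMPERATURE_K
    dt: float = 0.5
    duration: float = 600.0
    fixed_mask: np.ndarray | None = None
    fixed_values: np.ndarray | None = None
    constant_properties: bool = False
    include_metabolic: bool = True

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.q_ext is None:
            self.q_ext = np.zeros(self.grid.shape)
        self.q_ext = np.asarray(self.q_ext, dtype=float)
        if self.q_ext.shape != self.grid.shape:
            raise ValueError("q_ext must live on the thermal grid")
        if np.any(self.q_ext < 0):
            raise ValueError("q_ext must be non-negative")
        self.materials.validate_labels(self.grid.labels)


@dataclass
class ThermalState:
    """Temperature field (K), elapsed time and running peak temperature."""

    temperature: np.ndarray
    time: float = 0.0
    peak_temperature: np.ndarray | None = None
    em_solve_count: int = 0

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        if not np.all(np.isfinite(self.temperature)):
            raise ValueError("temperature field must be finite")
        if self.peak_temperature is None:
            self.peak_temperature = self.temperature.copy()


class PennesSolver:
    """Backward-Euler integrator for one :class:`ThermalProblem`."""

    def __init__(self, problem: ThermalProblem):
        self.problem = problem
        self.h_m = tuple(s * 1e-3 for s in problem.grid.spacing)
        self.blood = problem.materials.blood
        self._static_maps = None
        if problem.constant_properties:
            t0_c = celsius(problem.initial_temperature)
            self._static_maps = problem.materials.thermal_maps(problem.grid.labels, t0_c)
        self.last_audit: dict = {}

    def initial_state(self) -> ThermalState:
        t0 = np.full(self.problem.grid.shape, self.problem.initial_temperature)
        if self.problem.fixed_mask is not None:
            t0[self.problem.fixed_mask] = self.problem.fixed_values[self.problem.fixed_mask] \
                if isinstance(self.problem.fixed_values, np.ndarray) else self.problem.fixed_values
        return ThermalState(t0)

    # -- single implicit step --------------------------------------------

    def _maps(self, t_kelvin: np.ndarray):
        if self._static_maps is not None:
            return self._static_maps
        return self.problem.materials.thermal_maps(self.problem.grid.labels, celsius(t_kelvin))

    def step(self, state: ThermalState, dt: float | None = None) -> ThermalState:
        """Advance one backward-Euler step with lagged coefficients."""
        p = self.problem
        dt = p.dt if dt is None else float(dt)
        if dt <= 0:
            raise ValueError("dt must be positive")
        t_old = state.temperature
        k, rho_c, perf, qmet = self._maps(t_old)
        if not p.include_metabolic:
            qmet = np.zeros_like(qmet)
        sink = self.blood.blood_density * self.blood.blood_specific_heat * perf

        diag_t = rho_c / dt + sink
        rhs = rho_c / dt * t_old + sink * self.blood.blood_temperature + qmet + p.q_ext

        # face conductances per unit volume, W/(m^3 K), stored axis-first
        g_faces = []
        for axis in range(3):
            k_lo = np.moveaxis(k, axis, 0)[:-1]
            k_hi = np.moveaxis(k, axis, 0)[1:]
            g_faces.append(2.0 * k_lo * k_hi / np.maximum(k_lo + k_hi, 1e-300)
                           / self.h_m[axis] ** 2)

        diag_full = diag_t.copy()
        for axis, g in enumerate(g_faces):
            dm = np.moveaxis(diag_full, axis, 0)
            dm[:-1] += g
            dm[1:] += g

        fixed = p.fixed_mask
        shape = t_old.shape

        def apply_full(t3):
            out = diag_t * t3
            for axis, g in enumerate(g_faces):
                tm = np.moveaxis(t3, axis, 0)
                om = np.moveaxis(out, axis, 0)
                d = g * (tm[:-1] - tm[1:])
                om[:-1] += d
                om[1:] -= d
            return out

        if fixed is None:
            n = t_old.size

            def mv(x):
                return apply_full(x.reshape(shape)).ravel()

            b = rhs.ravel()
            minv = (1.0 / diag_full).ravel()
            x0 = t_old.ravel()
        else:
            free = ~fixed
            n = int(free.sum())
            fixed_field = np.zeros(shape)
            fixed_field[fixed] = p.fixed_values[fixed] if isinstance(p.fixed_values, np.ndarray) \
                else p.fixed_values

            def mv(x):
                t3 = fixed_field * 0.0
                t3[free] = x
                return apply_full(t3)[free]

            b = (rhs - apply_full(fixed_field))[free]
            minv = 1.0 / diag_full[free]
            x0 = t_old[free]

        op = LinearOperator((n, n), matvec=mv)
        pre = LinearOperator((n, n), matvec=lambda x: minv * x)
        x, info = cg(op, b, x0=x0, rtol=1e-9, atol=0.0, maxiter=1000, M=pre)
        if info != 0:
            raise RuntimeError(f"bioheat CG failed to converge (info={info}, t={state.time})")

        t_new = np.empty(shape)
        if fixed is None:
            t_new[:] = x.reshape(shape)
        else:
            t_new[~fixed] = x
            t_new[fixed] = fixed_field[fixed]

        self.last_audit = self._audit(t_old, t_new, rho_c, sink, qmet, dt,
                                      has_fixed=fixed is not None)
        return ThermalState(
            temperature=t_new,
            time=state.time + dt,
            peak_temperature=np.maximum(state.peak_temperature, t_new),
            em_solve_count=state.em_solve_count,
        )

    def _audit(self, t_old, t_new, rho_c, sink, qmet, dt, has_fixed):
        """Discrete energy balance of the step (exact for insulated runs)."""
        vol = self.problem.grid.voxel_volume_mm3 * 1e-9  # m^3
        d_energy = float(np.sum(rho_c * (t_new - t_old)) * vol)
        source = float(np.sum(qmet + self.problem.q_ext) * vol * dt)
        perf_sink = float(np.sum(sink * (self.blood.blood_temperature - t_new)) * vol * dt)
        residual = d_energy - source - perf_sink
        scale = max(abs(d_energy), abs(source), 1e-12)
        return {
            "energy_change_J": d_energy,
            "source_J": source,
            "perfusion_J": perf_sink,
            "residual_J": residual if not has_fixed else float("nan"),
            "residual_rel": abs(residual) / scale if not has_fixed else float("nan"),
        }

    # -- plain (uncoupled) run -------------------------------------------

    def run(self, observers=(), state: ThermalState | None = None) -> ThermalState:
        state = state or self.initial_state()
        for obs in observers:
            obs.start(self.problem, state)
        n_steps = int(round(self.problem.duration / self.problem.dt))
        for _ in range(n_steps):
            state = self.step(state)
            for obs in observers:
                obs.after_step(state)
        return state


# ---------------------------------------------------------------------------
# EM-thermal coupling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingPolicy:
    """When to re-solve the EM problem during a thermal run.

    Re-solve when the elapsed time since the last solve reaches
    ``resolve_interval_s``, or earlier when the maximum pointwise relative
    change of electrical conductivity exceeds ``sigma_rel_threshold`` (but
    never more often than ``min_resolve_interval_s``).
    """

    resolve_interval_s: float = 10.0
    sigma_rel_threshold: float = 0.02
    min_resolve_interval_s: float = 2.0

    def __post_init__(self):
        if self.resolve_interval_s <= 0:
            raise ValueError("resolve interval must be positive")


@dataclass
class CoupledResult:
    state: ThermalState
    problem: ThermalProblem
    em_problem: EMProblem
    em_solution: EMSolution
    em_history: list = field(default_factory=list)  # (time, |S|, absorbed W)
    delivered_energy_J: float = 0.0


def run_coupled(phantom: LabelGrid, materials: MaterialModel, template: AntennaTemplate,
                entry_point, tip_point, power_w: float, duration: float,
                dt: float = 0.5, policy: CouplingPolicy = CouplingPolicy(),
                observers=(), temperature_dependent: bool = True,
                initial_temperature: float = BODY_TEMPERATURE_K,
                em_kwargs: dict | None = None) -> CoupledResult:
    """Alternate Pennes stepping with axisymmetric EM re-solves.

    The EM problem is built once (grid, labels, antenna) and only its
    dielectric maps are refreshed from the evolving temperature field; the
    heat source is revolved back onto the voxel grid after each solve.
    With ``temperature_dependent=False`` the dielectric maps are frozen at
    the initial temperature, making the EM problem a fixed point.
    """
    em_kwargs = em_kwargs or {}
    em_problem = build_em_problem(phantom, entry_point, tip_point, template, materials,
                                  power_w, temperature_c=celsius(initial_temperature),
                                  **em_kwargs)
    # voxel index of every EM cell (to sample the temperature field)
    g2 = em_problem.grid
    entry = np.asarray(entry_point, float)
    tip = np.asarray(tip_point, float)
    axis = (entry - tip) / np.linalg.norm(entry - tip)
    azim = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    azim = azim - (azim @ axis) * axis
    azim /= np.linalg.norm(azim)
    pts = (tip[None, None, :] + g2.z_centers[None, :, None] * axis[None, None, :]
           + g2.r_centers[:, None, None] * azim[None, None, :])
    em_idx = tuple(
        np.clip(np.floor((pts[..., a] - phantom.origin[a]) / phantom.spacing[a]).astype(int),
                0, phantom.shape[a] - 1)
        for a in range(3)
    )

    def refresh_em(t_field_k):
        t_em = celsius(t_field_k[em_idx]) if temperature_dependent \
            else np.full(em_problem.labels.shape, celsius(initial_temperature))
        eps, sigma, _ = materials.em_maps(em_problem.labels, t_em)
        em_problem.eps_r = eps
        em_problem.sigma = sigma
        sol = solve_em(em_problem)
        q3d = revolve_to_3d(sol.q_ext, g2, entry_point, tip_point, phantom)
        # power actually deposited inside the thermal domain (the rest is
        # absorbed in the EM far field outside the voxel grid)
        sol.power_audit["deposited_w"] = float(q3d.sum()) * phantom.voxel_volume_mm3 * 1e-9
        return sol, q3d

    problem = ThermalProblem(grid=phantom, materials=materials,
                             initial_temperature=initial_temperature,
                             dt=dt, duration=duration)
    solver = PennesSolver(problem)
    state = solver.initial_state()

    sol, q3d = refresh_em(state.temperature)
    problem.q_ext = q3d
    state.em_solve_count = 1
    sigma_ref = em_problem.sigma.copy()
    t_last_solve = 0.0
    result = CoupledResult(state=state, problem=problem, em_problem=em_problem,
                           em_solution=sol,
                           em_history=[(0.0, abs(sol.s11), sol.power_audit["absorbed_w"])])

    for obs in observers:
        obs.start(problem, state)

    n_steps = int(round(duration / dt))
    for _ in range(n_steps):
        state = solver.step(state, dt)
        result.delivered_energy_J += sol.power_audit["deposited_w"] * dt
        if temperature_dependent:
            since = state.time - t_last_solve
            need = since >= policy.resolve_interval_s - 1e-9
            if not need and since >= policy.min_resolve_interval_s - 1e-9:
                t_em = celsius(state.temperature[em_idx])
                _, sigma_now, _ = materials.em_maps(em_problem.labels, t_em)
                with np.errstate(divide="ignore", invalid="ignore"):
                    rel = np.abs(sigma_now - sigma_ref) / np.where(sigma_ref > 0, sigma_ref, np.inf)
                need = bool(np.nanmax(rel) > policy.sigma_rel_threshold)
            if need:
                sol, q3d = refresh_em(state.temperature)
                problem.q_ext = q3d
                sigma_ref = em_problem.sigma.copy()
                t_last_solve = state.time
                state.em_solve_count += 1
                result.em_history.append((state.time, abs(sol.s11),
                                          sol.power_audit["absorbed_w"]))
        for obs in observers:
            obs.after_step(state)

    result.state = state
    result.em_solution = sol
    return result


# ---------------------------------------------------------------------------
# probing
# ---------------------------------------------------------------------------

class SnapshotObserver:
    """Store temperature (and peak) fields at requested times."""

    def __init__(self, times):
        self.times = sorted(float(t) for t in times)
        self.snapshots: list[tuple[float, np.ndarray, np.ndarray]] = []
        self._next = 0

    def start(self, problem, state):
        while self._next < len(self.times) and self.times[self._next] <= state.time + 1e-9:
            self.snapshots.append((state.time, state.temperature.copy(),
                                   state.peak_temperature.copy()))
            self._next += 1

    def after_step(self, state):
        while self._next < len(self.times) and self.times[self._next] <= state.time + 1e-9:
            self.snapshots.append((state.time, state.temperature.copy(),
                                   state.peak_temperature.copy()))
            self._next += 1


class ProbeObserver:
    """Record linearly interpolated temperature traces at fixed points (mm)."""

    def __init__(self, grid: LabelGrid, points):
        self.points = np.atleast_2d(np.asarray(points, dtype=float))
        axes = [grid.axis_centers(a) for a in range(3)]
        for a in range(3):
            lo, hi = axes[a][0], axes[a][-1]
            if np.any(self.points[:, a] < lo) or np.any(self.points[:, a] > hi):
                raise ValueError("probe location outside the interpolation domain")
        self._axes = axes
        self.times: list[float] = []
        self.values: list[np.ndarray] = []

    def _sample(self, field):
        interp = RegularGridInterpolator(self._axes, field, bounds_error=True)
        return interp(self.points)

    def start(self, problem, state):
        self.times.append(state.time)
        self.values.append(self._sample(state.temperature))

    def after_step(self, state):
        self.times.append(state.time)
        self.values.append(self._sample(state.temperature))

    def trace(self, i: int = 0) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times), np.asarray([v[i] for v in self.values])


def probe_trace(snapshots, grid: LabelGrid, point) -> tuple[np.ndarray, np.ndarray]:
    """Temperature-vs-time trace at one point from stored snapshots."""
    axes = [grid.axis_centers(a) for a in range(3)]
    times, values = [], []
    for t, temp, _peak in snapshots:
        interp = RegularGridInterpolator(axes, temp, bounds_error=True)
        times.append(t)
        values.append(float(interp(np.asarray(point, dtype=float)).item()))
    return np.asarray(times), np.asarray(values)
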