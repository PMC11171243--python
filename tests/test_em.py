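"""Electromagnetic solver: TEM port, energy audit, manufactured solutions."""

import dataclasses

import numpy as np
import pytest

from mwasim.em import (
    EMProblem,
    RectilinearGrid2D,
    assemble_system,
    build_em_problem,
    compute_sar,
    revolve_to_3d,
    solve_em,
)
from mwasim.grids import LabelGrid, Tissue
from mwasim.phantom import AntennaTemplate, build_phantom, phantom_for_patient

import scipy.sparse.linalg as spla


def coax_problem(power=65.0, length=40.0, eps_diel=2.03, sigma_diel=0.0,
                 far_end="absorbing"):
    """Pure coaxial line: dielectric annulus between PEC conductors."""
    ri, rd, ro = 0.135, 0.47, 0.595
    r_faces = np.concatenate([np.linspace(0, ri, 3), np.linspace(ri, rd, 9)[1:],
                              np.linspace(rd, ro, 3)[1:]])
    z_faces = np.arange(0.0, length + 1e-9, 0.25)
    g = RectilinearGrid2D(r_faces, z_faces)
    nr, nz = g.shape
    eps = np.full((nr, nz), eps_diel)
    sig = np.full((nr, nz), sigma_diel)
    cond = np.zeros((nr, nz), bool)
    rc = g.r_centers
    cond[(rc < ri) | (rc >= rd), :] = True
    if far_end == "short":
        cond[:, :2] = True
    port = (rc >= ri) & (rc < rd)
    return EMProblem(g, eps, sig, cond, 2.45e9, power, port, eps_diel)


class TestPort:
    def test_matched_coax_injects_requested_power(self):
        # absorbing far end emulates an infinite line: |S| ~ 0, flux = P_in
        sol = solve_em(coax_problem(power=65.0))
        assert abs(sol.s11) < 0.01
        assert sol.power_audit["port_flux_w"] == pytest.approx(65.0, rel=0.005)

    def test_fifty_watt_setting(self):
        sol = solve_em(coax_problem(power=50.0))
        assert sol.power_audit["port_flux_w"] == pytest.approx(50.0, rel=0.005)

    def test_zero_power_gives_zero_field(self):
        sol = solve_em(coax_problem(power=0.0))
        assert np.allclose(np.abs(sol.w), 0.0, atol=1e-12)

    def test_shorted_coax_reflects_everything(self):
        sol = solve_em(coax_problem(far_end="short"))
        assert abs(sol.s11) == pytest.approx(1.0, abs=0.02)

    def test_missing_port_rejected(self):
        with pytest.raises(ValueError, match="port"):
            p = coax_problem()
            EMProblem(p.grid, p.eps_r, p.sigma, p.conductor, p.frequency, p.power_w,
                      np.zeros_like(p.port_cells_r), p.eps_port)


class TestAntennaSolve:
    @pytest.fixture(scope="class")
    def solution(self, materials):
        spec = phantom_for_patient(1, spacing=1.0)
        grid = build_phantom(spec)
        prob = build_em_problem(grid, spec.entry_point, spec.tip_point,
                                AntennaTemplate(), materials, power_w=65.0)
        return spec, grid, prob, solve_em(prob)

    def test_power_audit_closes(self, solution):
        *_, sol = solution
        audit = sol.power_audit
        assert audit["relative_error"] < 0.02
        # passivity
        assert abs(sol.s11) <= 1.0
        assert audit["absorbed_w"] <= 65.0

    def test_sar_nonnegative_and_zero_in_conductors(self, solution):
        *_, prob, sol = solution
        assert np.all(sol.sar >= 0)
        assert np.allclose(sol.q_ext[prob.conductor], 0.0)

    def test_sar_consistency_with_qext(self, solution):
        # Qext = rho * SAR = sigma |E|^2 / 2 is an algebraic identity
        *_, prob, sol = solution
        e_sq = np.abs(sol.e_r) ** 2 + np.abs(sol.e_z) ** 2
        assert np.allclose(sol.sar * prob.density, sol.q_ext, rtol=1e-12)
        assert np.allclose(compute_sar(e_sq, prob.sigma, prob.density) * prob.density,
                           sol.q_ext, rtol=1e-12, atol=1e-9)

    def test_doubling_sigma_doubles_imaginary_permittivity(self, solution):
        *_, prob, _sol = solution
        eps1 = prob.complex_permittivity()
        prob2 = dataclasses.replace(prob, sigma=2.0 * prob.sigma)
        eps2 = prob2.complex_permittivity()
        assert np.allclose(eps2.imag, 2.0 * eps1.imag)
        assert np.allclose(eps2.real, eps1.real)

    def test_absorbed_power_stable_under_refinement(self, materials):
        spec = phantom_for_patient(1, spacing=1.0)
        grid = build_phantom(spec)
        coarse = build_em_problem(grid, spec.entry_point, spec.tip_point,
                                  AntennaTemplate(), materials, 65.0,
                                  fine_h=0.125, max_h=1.0)
        fine = build_em_problem(grid, spec.entry_point, spec.tip_point,
                                AntennaTemplate(), materials, 65.0,
                                fine_h=0.0625, max_h=0.5)
        p1 = solve_em(coarse).power_audit["absorbed_w"]
        p2 = solve_em(fine).power_audit["absorbed_w"]
        assert abs(p2 - p1) / p2 < 0.03

    def test_translation_invariance_of_heat_source(self, materials):
        spec = phantom_for_patient(1, spacing=2.0)
        shift = np.array([2.0, -2.0, -4.0])

        def solve_for(s):
            g = build_phantom(s)
            prob = build_em_problem(g, s.entry_point, s.tip_point,
                                    AntennaTemplate(), materials, 65.0)
            return solve_em(prob).q_ext

        moved = dataclasses.replace(
            spec,
            liver_center=tuple(np.array(spec.liver_center) + shift),
            tumor_center=tuple(np.array(spec.tumor_center) + shift),
            vessels=[dataclasses.replace(v, start=tuple(np.array(v.start) + shift),
                                         end=tuple(np.array(v.end) + shift))
                     for v in spec.vessels],
            entry_point=tuple(np.array(spec.entry_point) + shift),
            tip_point=tuple(np.array(spec.tip_point) + shift),
        )
        q1 = solve_for(spec)
        q2 = solve_for(moved)
        scale = np.abs(q1).max()
        assert np.allclose(q1, q2, atol=2e-2 * scale)

    def test_all_conductor_cavity_without_port_is_singularity_guarded(self):
        prob = coax_problem()
        prob.conductor[:] = True
        with pytest.raises(RuntimeError, match="active unknowns"):
            solve_em(prob)


class TestManufacturedSolution:
    """Grid convergence of the finite-volume operator on an exact solution."""

    @staticmethod
    def _solve(n):
        R, Z = 20.0, 20.0  # mm
        g = RectilinearGrid2D(np.linspace(0, R, n + 1), np.linspace(0, Z, n + 1))
        rc = g.r_centers[:, None] * 1e-3
        zc = g.z_centers[None, :] * 1e-3
        a = np.pi / (2 * R * 1e-3)
        b = np.pi / (Z * 1e-3)
        k0 = 150.0

        # w ~ r^2 near the axis (regular azimuthal field: H_phi ~ r)
        def w_exact(r, z):
            return np.sin(a * r) ** 2 * np.sin(b * z)

        source = np.sin(b * zc) * (
            -2 * a**2 * np.cos(2 * a * rc) / rc + a * np.sin(2 * a * rc) / rc**2
            + (b**2 - k0**2) * np.sin(a * rc) ** 2 / rc
        )

        D = 1.0 / rc * np.ones_like(zc)
        mass = k0**2 / rc * np.ones_like(zc)
        active = np.ones(g.shape, bool)
        rf = g.r_faces * 1e-3
        zf = g.z_faces * 1e-3
        bc = {
            "r0": {"type": "dirichlet", "value": 0.0},
            "rmax": {"type": "dirichlet", "value": w_exact(rf[-1], zc[0])},
            "zmin": {"type": "dirichlet", "value": w_exact(rc[:, 0], zf[0])},
            "zmax": {"type": "dirichlet", "value": w_exact(rc[:, 0], zf[-1])},
        }
        A, rhs, index = assemble_system(g, D, mass, active, bc, source=source)
        w = spla.spsolve(A.tocsc(), rhs).reshape(g.shape)
        err = w.real - w_exact(rc, zc)
        return float(np.sqrt(np.mean(err**2)))

    def test_second_order_convergence(self):
        e1 = self._solve(24)
        e2 = self._solve(48)
        order = np.log2(e1 / e2)
        assert order >= 1.5


class TestRevolve:
    def test_power_preserved_and_azimuth_invariant(self, materials):
        # voxel domain large enough to enclose the whole EM revolution, so
        # the deposited power must equal the axisymmetric absorbed power
        h = 2.0
        big = LabelGrid(np.full((65, 65, 56), Tissue.LIVER, np.int16), (h, h, h))
        tip = (65.0, 65.0, 50.0)
        entry = (65.0, 65.0, 110.0)
        prob = build_em_problem(big, entry, tip, AntennaTemplate(), materials, 65.0)
        sol = solve_em(prob)
        rc_m = prob.grid.r_centers * 1e-3
        vol2d = (2 * np.pi * rc_m[:, None] * (prob.grid.dr * 1e-3)[:, None]
                 * (prob.grid.dz * 1e-3)[None, :])
        total_axi = float((sol.q_ext * vol2d).sum())

        q3d = revolve_to_3d(sol.q_ext, prob.grid, entry, tip, big)
        total = q3d.sum() * big.voxel_volume_mm3 * 1e-9
        assert total == pytest.approx(total_axi, rel=0.01)

        # azimuth invariance: power deposited per azimuthal quadrant about
        # the axis must be equal (individual voxels carry binning jitter)
        x = big.axis_centers(0)[:, None, None] - tip[0]
        y = big.axis_centers(1)[None, :, None] - tip[1]
        pos_x, neg_x = x > 0.5 * h, x < -0.5 * h  # strict: skip the axis planes
        pos_y, neg_y = y > 0.5 * h, y < -0.5 * h
        quads = [pos_x & pos_y, neg_x & pos_y, pos_x & neg_y, neg_x & neg_y]
        sums = [float(q3d[np.broadcast_to(q, big.shape)].sum()) for q in quads]
        assert max(sums) > 0
        assert max(sums) / min(sums) < 1.02

    def test_partial_domain_receives_no_more_than_absorbed(self, materials):
        spec = phantom_for_patient(1, spacing=1.5)
        grid = build_phantom(spec)
        prob = build_em_problem(grid, spec.entry_point, spec.tip_point,
                                AntennaTemplate(), materials, 65.0)
        sol = solve_em(prob)
        q3d = revolve_to_3d(sol.q_ext, prob.grid, spec.entry_point, spec.tip_point, grid)
        total = q3d.sum() * grid.voxel_volume_mm3 * 1e-9
        assert 0 < total <= sol.power_audit["absorbed_w"] * (1 + 1e-9)

    def test_outside_domain_is_zero(self, materials):
        spec = phantom_for_patient(1, spacing=2.0)
        grid = build_phantom(spec)
        prob = build_em_problem(grid, spec.entry_point, spec.tip_point,
                                AntennaTemplate(), materials, 65.0,
                                r_max=15.0, z_min=-15.0, z_max=15.0)
        sol = solve_em(prob)
        q3d = revolve_to_3d(sol.q_ext, prob.grid, spec.entry_point, spec.tip_point, grid)
        centers = [grid.axis_centers(a) for a in range(3)]
        rr = np.sqrt((centers[0][:, None, None] - spec.tip_point[0]) ** 2
                     + (centers[1][None, :, None] - spec.tip_point[1]) ** 2)
        far = np.broadcast_to(rr > 20.0, grid.shape)
        assert np.allclose(q3d[far], 0.0)
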