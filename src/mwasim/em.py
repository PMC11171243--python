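"""Axisymmetric time-harmonic electromagnetic solver for interstitial antennas.

The microwave field of a coaxial slot antenna is rotationally symmetric to a
good approximation, so the vector wave equation

.. math::

    \\nabla \\times (\\tilde\\varepsilon^{-1} \\nabla \\times \\mathbf{H})
    - k_0^2 \\mu_r \\mathbf{H} = 0,
    \\qquad \\tilde\\varepsilon = \\varepsilon_r - j\\sigma/(\\omega\\varepsilon_0),

is reduced to a scalar equation for the azimuthal magnetic field
``u = H_phi(r, z)``.  With ``w = r u`` the operator becomes a standard
anisotropic Helmholtz form,

.. math::

    -\\partial_r\\big(\\tfrac{f}{r}\\,\\partial_r w\\big)
    -\\partial_z\\big(\\tfrac{f}{r}\\,\\partial_z w\\big)
    - \\frac{k_0^2}{r}\\, w = 0, \\qquad f = 1/\\tilde\\varepsilon,

discretised by a conservative finite-volume scheme on a graded rectilinear
``(r, z)`` grid (fine near the antenna, coarse in the far field).  Boundary
conditions: regularity ``w = 0`` on the axis, natural zero tangential-E on
perfect conductors, first-order absorbing (scattering) conditions on the
outer boundaries, and a matched TEM port on the coax inlet that injects a
prescribed time-averaged power and returns the reflection coefficient S.

Electric fields are recovered from ``w`` by differentiation, giving the
specific absorption rate ``SAR = sigma |E|^2 / (2 rho)`` and the volumetric
heat source ``Qext = sigma |E|^2 / 2`` consumed by the bioheat solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import BODY_TEMPERATURE_C, EPSILON_0, ETA_0, MU_0
from .grids import LabelGrid, Tissue
from .materials import MaterialModel
from .phantom import AntennaTemplate

__all__ = [
    "RectilinearGrid2D",
    "EMProblem",
    "EMSolution",
    "antenna_grid",
    "build_em_problem",
    "solve_em",
    "compute_sar",
    "revolve_to_3d",
]

_CAP_THICKNESS_MM = 0.5  # short-circuit cap above the antenna tip


@dataclass
class RectilinearGrid2D:
    """Tensor-product (r, z) grid; faces in mm, cell centres derived."""

    r_faces: np.ndarray
    z_faces: np.ndarray

    def __post_init__(self):
        self.r_faces = np.asarray(self.r_faces, dtype=float)
        self.z_faces = np.asarray(self.z_faces, dtype=float)
        if self.r_faces[0] != 0.0:
            raise ValueError("radial grid must start on the axis r=0")
        if np.any(np.diff(self.r_faces) <= 0) or np.any(np.diff(self.z_faces) <= 0):
            raise ValueError("grid faces must be strictly increasing")

    @property
    def r_centers(self):
        return 0.5 * (self.r_faces[:-1] + self.r_faces[1:])

    @property
    def z_centers(self):
        return 0.5 * (self.z_faces[:-1] + self.z_faces[1:])

    @property
    def dr(self):
        return np.diff(self.r_faces)

    @property
    def dz(self):
        return np.diff(self.z_faces)

    @property
    def shape(self):
        return (len(self.r_faces) - 1, len(self.z_faces) - 1)


def _graded(start: float, stop: float, h0: float, hmax: float, ratio: float = 1.3):
    """Geometrically graded face positions from start toward stop."""
    faces = [start]
    h = h0
    while faces[-1] < stop - 1e-9:
        faces.append(min(faces[-1] + h, stop))
        h = min(h * ratio, hmax)
    if len(faces) > 2 and faces[-1] - faces[-2] < 0.4 * (faces[-2] - faces[-3]):
        del faces[-2]
    return np.asarray(faces)


def antenna_grid(template: AntennaTemplate, r_max: float = 60.0,
                 z_min: float = -45.0, z_max: float = 55.0,
                 fine_h: float = 0.125, max_h: float = 1.0) -> RectilinearGrid2D:
    """Graded grid with faces aligned to the antenna's material interfaces.

    ``z = 0`` is the antenna tip (cap base); the antenna body extends toward
    ``z_max`` where the coax port sits on the boundary.
    """
    t = template
    r_parts = [
        np.linspace(0.0, t.inner_conductor_radius, 3),
        np.linspace(t.inner_conductor_radius, t.dielectric_radius, 9)[1:],
        np.linspace(t.dielectric_radius, t.outer_conductor_radius, 3)[1:],
        np.linspace(t.outer_conductor_radius, t.catheter_radius, 4)[1:],
        _graded(t.catheter_radius, r_max, 0.1, max_h)[1:],
    ]
    r_faces = np.concatenate(r_parts)

    z_fine_lo = -max(2.0, t.tip_length + 1.0)
    z_fine_hi = t.slot_center_from_tip + t.slot_width / 2 + 3.0
    fine = np.arange(z_fine_lo, z_fine_hi + 0.5 * fine_h, fine_h)
    below = _graded(-z_fine_lo, -z_min, fine_h, max_h)[1:]
    above = _graded(z_fine_hi, z_max, fine_h, max_h)[1:]
    z_faces = np.concatenate([-below[::-1], fine, above])
    return RectilinearGrid2D(r_faces, z_faces)


@dataclass
class EMProblem:
    """Discrete axisymmetric EM problem.

    ``eps_r``/``sigma`` are per-cell material maps; ``conductor`` marks cells
    excluded from the unknowns (perfect electric conductors).  The port is
    the set of top-boundary cells spanning the coax dielectric annulus.
    """

    grid: RectilinearGrid2D
    eps_r: np.ndarray
    sigma: np.ndarray
    conductor: np.ndarray
    frequency: float
    power_w: float
    port_cells_r: np.ndarray  # bool over r-cells on the z=zmax boundary
    eps_port: float
    density: np.ndarray | None = None
    labels: np.ndarray | None = None
    mu_r: float = 1.0

    def __post_init__(self):
        shape = self.grid.shape
        for name in ("eps_r", "sigma", "conductor"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != grid {shape}")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not self.port_cells_r.any():
            raise ValueError("problem needs exactly one port (no port cells set)")

    @property
    def omega(self):
        return 2.0 * np.pi * self.frequency

    @property
    def k0(self):
        """Free-space propagation constant (1/m)."""
        return self.omega * np.sqrt(MU_0 * EPSILON_0)

    def complex_permittivity(self):
        return self.eps_r - 1j * self.sigma / (self.omega * EPSILON_0)


@dataclass
class EMSolution:
    """Fields and derived quantities of one harmonic solve."""

    problem: EMProblem
    w: np.ndarray  # r * H_phi, A (complex)
    h_phi: np.ndarray  # A/m
    e_r: np.ndarray  # V/m
    e_z: np.ndarray
    sar: np.ndarray  # W/kg (zero where density unknown)
    q_ext: np.ndarray  # W/m^3
    s11: complex
    power_audit: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_system(grid: RectilinearGrid2D, diffusivity: np.ndarray, mass: np.ndarray,
                    active: np.ndarray, bc: dict, source: np.ndarray | None = None):
    """Finite-volume assembly of ``-div(D grad w) - m w = s`` on (r, z).

    All lengths are converted to metres internally.  ``bc`` maps each side
    (``r0``, ``rmax``, ``zmin``, ``zmax``) to one of::

        {"type": "neumann"}                      # natural zero flux
        {"type": "dirichlet", "value": arr}      # w on the boundary face
        {"type": "robin", "coef": arr, "rhs": arr}
            # outward flux = coef * w - rhs at the boundary cell

    Faces adjacent to inactive (conductor) cells carry zero flux, which in
    the azimuthal-H formulation is exactly the perfect-conductor condition
    (zero tangential E).  Returns ``(A_csc, b, index_map)`` where
    ``index_map`` is -1 for inactive cells.
    """
    nr, nz = grid.shape
    rf = grid.r_faces * 1e-3
    zf = grid.z_faces * 1e-3
    rc = 0.5 * (rf[:-1] + rf[1:])
    zc = 0.5 * (zf[:-1] + zf[1:])
    dr = np.diff(rf)
    dz = np.diff(zf)

    D = np.asarray(diffusivity, dtype=complex)
    active = np.asarray(active, dtype=bool)
    index = -np.ones((nr, nz), dtype=np.int64)
    index[active] = np.arange(int(active.sum()))
    n = int(active.sum())

    diag = np.zeros((nr, nz), dtype=complex)
    b = np.zeros((nr, nz), dtype=complex)
    rows, cols, vals = [], [], []

    def couple(mask, ip, jp, iq, jq, G):
        m = mask & active[ip, jp] & active[iq, jq]
        if not m.any():
            return
        g = G[m]
        p = index[ip, jp][m]
        q = index[iq, jq][m]
        rows.extend([p, q])
        cols.extend([q, p])
        vals.extend([-g, -g])
        np.add.at(diag, (ip[m], jp[m]), g)
        np.add.at(diag, (iq[m], jq[m]), g)

    # interior faces in r
    if nr > 1:
        ii, jj = np.meshgrid(np.arange(nr - 1), np.arange(nz), indexing="ij")
        a_face = dz[None, :][np.zeros_like(ii), jj]
        d_lo = (rf[1:-1][:, None] - rc[:-1][:, None])[ii, np.zeros_like(jj)]
        d_hi = (rc[1:][:, None] - rf[1:-1][:, None])[ii, np.zeros_like(jj)]
        G = a_face / (d_lo / D[:-1, :][ii, jj] + d_hi / D[1:, :][ii, jj])
        couple(np.ones_like(ii, bool), ii, jj, ii + 1, jj, G)

    # interior faces in z
    if nz > 1:
        ii, jj = np.meshgrid(np.arange(nr), np.arange(nz - 1), indexing="ij")
        a_face = dr[:, None][ii, np.zeros_like(jj)]
        d_lo = (zf[1:-1] - zc[:-1])[jj]
        d_hi = (zc[1:] - zf[1:-1])[jj]
        G = a_face / (d_lo / D[ii, jj] + d_hi / D[ii, jj + 1])
        couple(np.ones_like(ii, bool), ii, jj, ii, jj + 1, G)

    # boundary sides: (cell indexer, face area, centre-to-face distance)
    sides = {
        "r0": (np.s_[0, :], dz, rc[0] - rf[0]),
        "rmax": (np.s_[-1, :], dz, rf[-1] - rc[-1]),
        "zmin": (np.s_[:, 0], dr, zc[0] - zf[0]),
        "zmax": (np.s_[:, -1], dr, zf[-1] - zc[-1]),
    }
    for side, spec_bc in bc.items():
        sl, area, dist = sides[side]
        act = active[sl]
        kind = spec_bc["type"]
        if kind == "neumann":
            continue
        if kind == "dirichlet":
            G = area * D[sl] / dist
            value = np.broadcast_to(np.asarray(spec_bc["value"], dtype=complex), act.shape)
            diag[sl] += np.where(act, G, 0.0)
            b[sl] += np.where(act, G * value, 0.0)
        elif kind == "robin":
            coef = np.broadcast_to(np.asarray(spec_bc["coef"], dtype=complex), act.shape)
            g = np.broadcast_to(np.asarray(spec_bc.get("rhs", 0.0), dtype=complex), act.shape)
            diag[sl] += np.where(act, area * coef, 0.0)
            b[sl] += np.where(act, area * g, 0.0)
        else:
            raise ValueError(f"unknown boundary type '{kind}' on side {side}")

    vol = dr[:, None] * dz[None, :]
    diag -= np.asarray(mass, dtype=complex) * vol
    if source is not None:
        b += np.asarray(source, dtype=complex) * vol

    rows.append(index[active])
    cols.append(index[active])
    vals.append(diag[active])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return A, b[active], index


# ---------------------------------------------------------------------------
# problem construction
# ---------------------------------------------------------------------------

def _paint_antenna(grid: RectilinearGrid2D, template: AntennaTemplate, labels: np.ndarray):
    """Overlay antenna structure labels on the (r, z) tissue section."""
    t = template
    rc = grid.r_centers[:, None]
    zc = grid.z_centers[None, :]
    cap_lo, cap_hi = 0.0, _CAP_THICKNESS_MM
    slot_lo = t.slot_center_from_tip - t.slot_width / 2
    slot_hi = t.slot_center_from_tip + t.slot_width / 2

    body = zc >= cap_hi
    labels[(body & (rc < t.inner_conductor_radius))] = Tissue.ANTENNA_INNER_CONDUCTOR
    labels[(body & (rc >= t.inner_conductor_radius) & (rc < t.dielectric_radius))] = Tissue.ANTENNA_DIELECTRIC
    outer = body & (rc >= t.dielectric_radius) & (rc < t.outer_conductor_radius)
    in_slot = (zc >= slot_lo) & (zc <= slot_hi)
    labels[outer & ~in_slot] = Tissue.ANTENNA_OUTER_CONDUCTOR
    labels[outer & in_slot] = Tissue.ANTENNA_SLOT
    cap = (zc >= cap_lo) & (zc < cap_hi) & (rc < t.outer_conductor_radius)
    labels[cap] = Tissue.ANTENNA_INNER_CONDUCTOR
    sheath = (zc >= -t.tip_length) & (rc < t.catheter_radius) & ~body & ~cap
    labels[sheath] = Tissue.CATHETER
    ring = body & (rc >= t.outer_conductor_radius) & (rc < t.catheter_radius)
    labels[ring] = Tissue.CATHETER
    return labels


def build_em_problem(phantom: LabelGrid, entry_point, tip_point, template: AntennaTemplate,
                     materials: MaterialModel, power_w: float,
                     temperature_c: np.ndarray | float = BODY_TEMPERATURE_C,
                     grid: RectilinearGrid2D | None = None,
                     r_max: float = 60.0, z_min: float = -45.0, z_max: float = 55.0,
                     fine_h: float = 0.125, max_h: float = 1.0) -> EMProblem:
    """Build the axisymmetric EM problem for an antenna inside a phantom.

    Tissue cells take the nearest phantom label along the trajectory
    half-plane; antenna structure is painted analytically from the template.
    ``temperature_c`` may be a scalar or a per-cell map on the same (r, z)
    grid (used by the thermal coupling to refresh the dielectric maps).
    """
    if grid is None:
        grid = antenna_grid(template, r_max=r_max, z_min=z_min, z_max=z_max,
                            fine_h=fine_h, max_h=max_h)
    entry = np.asarray(entry_point, dtype=float)
    tip = np.asarray(tip_point, dtype=float)
    axis = entry - tip
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("entry and tip must be distinct")
    axis /= norm
    azim = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    azim = azim - (azim @ axis) * axis
    azim /= np.linalg.norm(azim)

    rc = grid.r_centers
    zc = grid.z_centers
    pts = (tip[None, None, :] + zc[None, :, None] * axis[None, None, :]
           + rc[:, None, None] * azim[None, None, :])
    idx = []
    for ax in range(3):
        i = np.floor((pts[..., ax] - phantom.origin[ax]) / phantom.spacing[ax]).astype(int)
        idx.append(np.clip(i, 0, phantom.shape[ax] - 1))
    labels = phantom.labels[idx[0], idx[1], idx[2]].astype(np.int16)
    # the 3-D grid carries only the shaft label; rebuild internal structure
    labels[labels == Tissue.CATHETER] = Tissue.LIVER if Tissue.LIVER in labels else Tissue.BACKGROUND
    labels = _paint_antenna(grid, template, labels)

    t_map = np.broadcast_to(np.asarray(temperature_c, dtype=float), labels.shape)
    eps, sigma, conductor = materials.em_maps(labels, t_map)
    density = materials.density_map(labels)

    port_r = ((rc >= template.inner_conductor_radius) & (rc < template.dielectric_radius))
    eps_port = materials.lookup(int(Tissue.ANTENNA_DIELECTRIC)).relative_permittivity
    return EMProblem(grid=grid, eps_r=eps, sigma=sigma, conductor=conductor,
                     frequency=template.frequency_hz, power_w=power_w,
                     port_cells_r=port_r, eps_port=eps_port,
                     density=density, labels=labels)


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------

def port_mode_amplitude(problem: EMProblem) -> float:
    """TEM amplitude H0 such that the injected discrete power equals P_in.

    The coax TEM mode has ``H_phi = H0 / r``; its time-averaged power is
    ``pi * eta * H0^2 * ln(b/a)``.  The log integral is evaluated with the
    same midpoint quadrature the port overlap uses, so the injected power
    matches ``power_w`` on any grid.
    """
    g = problem.grid
    eta = ETA_0 / np.sqrt(problem.eps_port)
    pr = problem.port_cells_r
    ln_disc = float(np.sum(g.dr[pr] / g.r_centers[pr]))  # ~ ln(b/a)
    return float(np.sqrt(problem.power_w / (np.pi * eta * ln_disc)))


def solve_em(problem: EMProblem) -> EMSolution:
    """Assemble, apply boundary conditions and solve; derive SAR and audit."""
    g = problem.grid
    nr, nz = g.shape
    k0 = problem.k0
    eps_c = problem.complex_permittivity()
    f = 1.0 / eps_c
    rc_m = g.r_centers * 1e-3
    D = f / rc_m[:, None]
    mass = problem.mu_r * k0**2 / rc_m[:, None] * np.ones((1, nz))
    active = ~problem.conductor

    k_loc = k0 * np.sqrt(eps_c)
    k_port = k0 * np.sqrt(problem.eps_port)
    h0 = port_mode_amplitude(problem)

    # port excitation on the z=zmax boundary (coax dielectric annulus);
    # remaining top cells absorb with the local material wavenumber
    robin_top_coef = D[:, -1] * 1j * k_loc[:, -1]
    robin_top_rhs = np.zeros(nr, dtype=complex)
    pr = problem.port_cells_r
    robin_top_coef[pr] = D[pr, -1] * 1j * k_port
    robin_top_rhs[pr] = D[pr, -1] * 2j * k_port * h0

    bc = {
        "r0": {"type": "dirichlet", "value": 0.0},
        "rmax": {"type": "robin", "coef": D[-1, :] * 1j * k_loc[-1, :], "rhs": 0.0},
        "zmin": {"type": "robin", "coef": D[:, 0] * 1j * k_loc[:, 0], "rhs": 0.0},
        "zmax": {"type": "robin", "coef": robin_top_coef, "rhs": robin_top_rhs},
    }

    A, b, index = assemble_system(g, D, mass, active, bc)
    if A.shape[0] == 0:
        raise RuntimeError("no active unknowns: check conductor map")
    try:
        lu = spla.splu(A)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"singular EM system; check mesh and boundary tags: {exc}") from exc
    x = lu.solve(b)
    if not np.all(np.isfinite(x)):
        raise RuntimeError("EM solve produced non-finite field values")

    w = np.zeros((nr, nz), dtype=complex)
    w[active] = x
    return _postprocess(problem, w, h0, k_port)


def _postprocess(problem: EMProblem, w: np.ndarray, h0: float, k_port: float) -> EMSolution:
    g = problem.grid
    rc_m = g.r_centers * 1e-3
    zc_m = g.z_centers * 1e-3
    eps_c = problem.complex_permittivity()
    f = 1.0 / eps_c
    jwe = 1j * problem.omega * EPSILON_0

    dw_dr = np.gradient(w, rc_m, axis=0)
    dw_dz = np.gradient(w, zc_m, axis=1)
    inv_r = 1.0 / rc_m[:, None]
    e_r = -(f / jwe) * inv_r * dw_dz
    e_z = (f / jwe) * inv_r * dw_dr
    e_r[problem.conductor] = 0.0
    e_z[problem.conductor] = 0.0
    h_phi = w * inv_r
    e_sq = np.abs(e_r) ** 2 + np.abs(e_z) ** 2

    q_ext = 0.5 * problem.sigma * e_sq
    q_ext[problem.conductor] = 0.0
    rho = problem.density if problem.density is not None else np.full(w.shape, np.nan)
    with np.errstate(invalid="ignore"):
        sar = np.where(rho > 0, q_ext / np.where(rho > 0, rho, 1.0), 0.0)

    # reflection coefficient: overlap of (w - w_inc) with the TEM mode at the
    # port-adjacent cell centres, phase-referred to the port face
    pr = problem.port_cells_r
    dz_last = (g.z_faces[-1] - g.z_centers[-1]) * 1e-3
    w_inc = h0 * np.exp(-1j * k_port * dz_last)  # incident at cell centres
    wr = g.dr[pr] / g.r_centers[pr]
    s11 = complex(np.sum((w[pr, -1] - w_inc) * wr) / (w_inc * np.sum(wr)))

    audit = _power_audit(problem, w, e_r, e_z, h_phi, q_ext, s11)
    return EMSolution(problem=problem, w=w, h_phi=h_phi, e_r=e_r, e_z=e_z,
                      sar=sar, q_ext=q_ext, s11=s11, power_audit=audit)


def _power_audit(problem, w, e_r, e_z, h_phi, q_ext, s11):
    g = problem.grid
    rc_m = g.r_centers * 1e-3
    dr_m = g.dr * 1e-3
    dz_m = g.dz * 1e-3
    vol = 2.0 * np.pi * rc_m[:, None] * dr_m[:, None] * dz_m[None, :]
    absorbed = float(np.sum(q_ext * vol))

    s_r = -0.5 * np.real(e_z * np.conj(h_phi))  # radial Poynting
    s_z = 0.5 * np.real(e_r * np.conj(h_phi))  # axial Poynting
    ring_top = 2.0 * np.pi * rc_m * dr_m
    side = 2.0 * np.pi * (g.r_faces[-1] * 1e-3) * dz_m
    outflow = float(np.sum(s_r[-1, :] * side))
    outflow += float(np.sum(-s_z[:, 0] * ring_top))
    pr = problem.port_cells_r
    top_open = ~pr & ~problem.conductor[:, -1]
    outflow += float(np.sum(s_z[top_open, -1] * ring_top[top_open]))
    port_flux = float(np.sum(-s_z[pr, -1] * ring_top[pr]))

    delivered = (1.0 - abs(s11) ** 2) * problem.power_w
    residual = abs(absorbed + outflow - delivered) / max(delivered, 1e-12)
    return {
        "input_power_w": problem.power_w,
        "reflection_coefficient": abs(s11),
        "delivered_w": delivered,
        "absorbed_w": absorbed,
        "boundary_outflow_w": outflow,
        "port_flux_w": port_flux,
        "relative_error": residual,
    }


def compute_sar(e_field_sq: np.ndarray, sigma: np.ndarray, density: np.ndarray) -> np.ndarray:
    """Specific absorption rate ``sigma |E|^2 / (2 rho)`` in W/kg."""
    return 0.5 * sigma * e_field_sq / density


def revolve_to_3d(q_rz: np.ndarray, grid2d: RectilinearGrid2D, entry_point, tip_point,
                  grid3d: LabelGrid, max_arc_mm: float | None = None) -> np.ndarray:
    """Rotate an axisymmetric source about the antenna axis onto a voxel grid.

    Each (r, z) cell's power ``q * 2*pi*r*dr*dz`` is deposited along its
    revolution ring by sampling the ring at arc steps no longer than half a
    voxel and binning the samples into voxels (ring splatting).  This is
    conservative by construction — the voxel field carries exactly the
    axisymmetric power whose rings intersect the 3-D domain — and keeps the
    strongly ``1/r``-peaked near-antenna deposition in the correct voxels
    even on coarse thermal grids.  Voxels outside the (r, z) domain get
    zero; the result is azimuth-invariant up to voxelisation.
    """
    entry = np.asarray(entry_point, dtype=float)
    tip = np.asarray(tip_point, dtype=float)
    axis = entry - tip
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("entry and tip must be distinct (straight trajectory)")
    axis /= norm
    u = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = u - (u @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    h_min = min(grid3d.spacing)
    arc = max_arc_mm if max_arc_mm is not None else 0.5 * h_min

    rc = grid2d.r_centers
    zc = grid2d.z_centers
    dr_m = grid2d.dr * 1e-3
    dz_m = grid2d.dz * 1e-3
    power = q_rz * 2.0 * np.pi * (rc * 1e-3)[:, None] * dr_m[:, None] * dz_m[None, :]  # W
    total = float(power.sum())
    ir, iz = np.nonzero(power > 1e-12 * max(total, 1e-30))
    if ir.size == 0:
        return np.zeros(grid3d.shape)
    r_cell = rc[ir]
    z_cell = zc[iz]
    p_cell = power[ir, iz]

    counts = np.maximum(8, np.ceil(2.0 * np.pi * r_cell / arc).astype(int))
    starts = np.concatenate([[0], np.cumsum(counts)])
    n_pts = int(starts[-1])
    cell_of = np.repeat(np.arange(ir.size), counts)
    frac = (np.arange(n_pts) - starts[cell_of]) / counts[cell_of]
    # deterministic golden-ratio phase per ring: rings whose point count is
    # not a multiple of 4 would otherwise bias their remainder points toward
    # one azimuth systematically
    phase = (np.arange(ir.size) * 0.61803398875) % 1.0
    phi = 2.0 * np.pi * (frac + phase[cell_of])

    rr = r_cell[cell_of]
    pos = (tip[None, :] + z_cell[cell_of][:, None] * axis[None, :]
           + rr[:, None] * (np.cos(phi)[:, None] * u[None, :]
                            + np.sin(phi)[:, None] * v[None, :]))
    weight = p_cell[cell_of] / counts[cell_of]

    idx = np.empty((3, n_pts), dtype=np.int64)
    inside = np.ones(n_pts, dtype=bool)
    for a in range(3):
        i = np.floor((pos[:, a] - grid3d.origin[a]) / grid3d.spacing[a]).astype(np.int64)
        inside &= (i >= 0) & (i < grid3d.shape[a])
        idx[a] = np.clip(i, 0, grid3d.shape[a] - 1)
    deposit = np.zeros(grid3d.shape)
    np.add.at(deposit, (idx[0][inside], idx[1][inside], idx[2][inside]), weight[inside])
    return deposit / (grid3d.voxel_volume_mm3 * 1e-9)  # W/m^3
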