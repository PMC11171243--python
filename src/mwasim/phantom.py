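"""Synthetic liver phantoms for microwave-ablation studies.

Clinical CT segmentations are replaced by a parametric phantom: a liver
ellipsoid, a spherical (or ellipsoidal) tumor, cylindrical blood vessels and a
straight antenna trajectory, all voxelised onto an axis-aligned grid in
millimetres.  :func:`phantom_from_patient_summary` builds phantoms whose tumor
volume, tumor-to-liver-surface distance and tumor-to-vessel distance match a
patient summary (tumor volumes 0.43/0.62/0.88 cm^3, surface distances
0.1/0.2/9.1 mm, vessel distances 12.4/24.4/19.0 mm for the three reference
cases), so the downstream solvers and metrics can be exercised under
realistic geometry without imaging data.

Construction is fully deterministic given the spec: no randomness is
involved unless an explicit jitter seed is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grids import LabelGrid, Tissue

__all__ = [
    "VesselSpec",
    "AntennaTemplate",
    "PhantomSpec",
    "PATIENT_SUMMARIES",
    "build_phantom",
    "phantom_from_patient_summary",
    "axisymmetric_section",
]


@dataclass(frozen=True)
class VesselSpec:
    """Cylindrical vessel segment: endpoints (mm) and radius (mm)."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("vessel radius must be positive")


@dataclass(frozen=True)
class AntennaTemplate:
    """Axisymmetric coaxial slot-antenna geometry (all lengths mm).

    A standard interstitial 2.45 GHz design: nested inner conductor,
    low-loss dielectric, outer conductor with a ring slot near the
    short-circuited tip, all inside a catheter sheath.
    """

    inner_conductor_radius: float = 0.135
    dielectric_radius: float = 0.470
    outer_conductor_radius: float = 0.595
    catheter_radius: float = 0.895
    slot_center_from_tip: float = 5.0
    slot_width: float = 1.0
    tip_length: float = 1.0
    frequency_hz: float = 2.45e9

    def __post_init__(self):
        radii = (self.inner_conductor_radius, self.dielectric_radius,
                 self.outer_conductor_radius, self.catheter_radius)
        if not all(a < b for a, b in zip(radii, radii[1:])):
            raise ValueError("antenna radii must be strictly nested")
        if self.slot_width <= 0 or self.slot_center_from_tip <= self.slot_width / 2:
            raise ValueError("slot must lie within the antenna extent")

    @classmethod
    def from_config(cls, cfg: dict, frequency_hz: float = 2.45e9) -> "AntennaTemplate":
        return cls(
            inner_conductor_radius=cfg["inner_conductor_radius_mm"],
            dielectric_radius=cfg["dielectric_radius_mm"],
            outer_conductor_radius=cfg["outer_conductor_radius_mm"],
            catheter_radius=cfg["catheter_radius_mm"],
            slot_center_from_tip=cfg["slot_center_from_tip_mm"],
            slot_width=cfg["slot_width_mm"],
            tip_length=cfg["tip_length_mm"],
            frequency_hz=frequency_hz,
        )


@dataclass
class PhantomSpec:
    """Parametric phantom: geometry in physical millimetres.

    ``extent`` is the physical domain size; the grid origin is the domain
    corner and voxel centres sit at ``(i + 0.5) * spacing``.
    """

    liver_center: tuple[float, float, float]
    liver_semiaxes: tuple[float, float, float]
    tumor_center: tuple[float, float, float]
    tumor_radii: tuple[float, float, float]
    vessels: list[VesselSpec] = field(default_factory=list)
    entry_point: tuple[float, float, float] = (40.0, 35.0, 90.0)
    tip_point: tuple[float, float, float] = (40.0, 35.0, 60.0)
    spacing: float = 1.0
    extent: tuple[float, float, float] = (80.0, 70.0, 90.0)
    suggested_power_w: float | None = None

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(r <= 0 for r in self.tumor_radii) or any(a <= 0 for a in self.liver_semiaxes):
            raise ValueError("radii and semi-axes must be positive")

    def tumor_volume_cm3(self) -> float:
        a, b, c = self.tumor_radii
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


#: Printed per-patient summaries of the three reference cases (inputs to the
#: phantom builder): tumor volume, distance to the liver surface, distance to
#: the nearest major vessel, applied power; all ablations last 10 min.
PATIENT_SUMMARIES = {
    1: dict(tumor_volume_cm3=0.43, surface_distance_mm=0.1, vessel_distance_mm=12.4, power_w=65.0),
    2: dict(tumor_volume_cm3=0.62, surface_distance_mm=0.2, vessel_distance_mm=24.4, power_w=50.0),
    3: dict(tumor_volume_cm3=0.88, surface_distance_mm=9.1, vessel_distance_mm=19.0, power_w=65.0),
}

#: Default ablation duration for the reference scenarios (s).
DEFAULT_DURATION_S = 600.0


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from an (..., 3) point cloud to segment ab."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=-1)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(points - proj, axis=-1)


def build_phantom(spec: PhantomSpec, template: AntennaTemplate | None = None,
                  paint_antenna: bool = True) -> LabelGrid:
    """Voxelise a phantom spec into a 3-D :class:`LabelGrid`.

    Painting priority (highest wins): antenna shaft > tumor > vessel >
    liver > background.  The antenna is painted as a catheter-radius
    cylinder along the entry->tip segment (at least one voxel wide on
    coarse grids); its internal conductor/dielectric structure only exists
    on the electromagnetic ``(r, z)`` grid, which is built from the
    template directly.
    """
    template = template or AntennaTemplate()
    _check_tumor_inside_liver(spec)
    h = spec.spacing
    shape = tuple(max(1, int(round(e / h))) for e in spec.extent)
    coords = [((np.arange(n) + 0.5) * h) for n in shape]
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]

    labels = np.zeros(shape, dtype=np.int16)

    lc, ls = np.asarray(spec.liver_center), np.asarray(spec.liver_semiaxes)
    liver = (((x - lc[0]) / ls[0]) ** 2 + ((y - lc[1]) / ls[1]) ** 2
             + ((z - lc[2]) / ls[2]) ** 2) <= 1.0
    labels[liver] = Tissue.LIVER

    if spec.vessels:
        pts = np.stack(np.broadcast_arrays(x, y, z), axis=-1)
        for v in spec.vessels:
            d = _segment_distance(pts, np.asarray(v.start, float), np.asarray(v.end, float))
            labels[d <= v.radius] = Tissue.VESSEL

    tc, tr = np.asarray(spec.tumor_center), np.asarray(spec.tumor_radii)
    tumor = (((x - tc[0]) / tr[0]) ** 2 + ((y - tc[1]) / tr[1]) ** 2
             + ((z - tc[2]) / tr[2]) ** 2) <= 1.0
    labels[tumor] = Tissue.TUMOR

    if paint_antenna:
        pts = np.stack(np.broadcast_arrays(x, y, z), axis=-1)
        shaft_r = max(template.catheter_radius, 0.55 * h)
        d = _segment_distance(pts, np.asarray(spec.entry_point, float),
                              np.asarray(spec.tip_point, float))
        labels[d <= shaft_r] = Tissue.CATHETER

    return LabelGrid(labels, (h, h, h), (0.0, 0.0, 0.0))


def _check_tumor_inside_liver(spec: PhantomSpec) -> None:
    """Reject specs whose tumor surface pokes out of the liver ellipsoid."""
    tc = np.asarray(spec.tumor_center)
    tr = np.asarray(spec.tumor_radii)
    lc = np.asarray(spec.liver_center)
    ls = np.asarray(spec.liver_semiaxes)
    # sample the tumor surface densely
    u = np.linspace(0, math.pi, 24)
    v = np.linspace(0, 2 * math.pi, 48)
    uu, vv = np.meshgrid(u, v)
    pts = np.stack([
        tc[0] + tr[0] * np.sin(uu) * np.cos(vv),
        tc[1] + tr[1] * np.sin(uu) * np.sin(vv),
        tc[2] + tr[2] * np.cos(uu),
    ], axis=-1)
    val = (((pts[..., 0] - lc[0]) / ls[0]) ** 2 + ((pts[..., 1] - lc[1]) / ls[1]) ** 2
           + ((pts[..., 2] - lc[2]) / ls[2]) ** 2)
    if np.any(val > 1.0 + 1e-9):
        raise ValueError("tumor extends outside the liver ellipsoid")


def phantom_from_patient_summary(tumor_volume_cm3: float, surface_distance_mm: float,
                                 vessel_distance_mm: float, power_w: float,
                                 spacing: float = 1.0) -> PhantomSpec:
    """Build a phantom spec matching a printed patient summary.

    The tumor is a sphere of the requested volume placed on the vertical
    axis near the superior pole of the liver ellipsoid so its minimum
    distance to the liver surface equals ``surface_distance_mm``; a
    horizontal vessel runs beneath it at the requested clearance; the
    antenna enters vertically from above with its tip at the tumor centre.
    Realized distances are exact in the continuum and match the request to
    within one voxel after rasterisation.
    """
    if tumor_volume_cm3 <= 0:
        raise ValueError("tumor volume must be positive")
    if surface_distance_mm < 0 or vessel_distance_mm < 0:
        raise ValueError("distances must be non-negative")
    extent = (80.0, 70.0, 90.0)
    center = (40.0, 35.0, 45.0)
    semiaxes = (36.0, 30.0, 40.0)
    r_t = (3.0 * tumor_volume_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)

    depth = surface_distance_mm + r_t  # tumor centre depth below the superior pole
    # the pole is the nearest surface point only while the centre stays inside
    # the polar radius of curvature min(a,b)^2/c
    if depth >= min(semiaxes[0], semiaxes[1]) ** 2 / semiaxes[2]:
        raise ValueError("requested surface distance too deep for the liver pole geometry")
    z_t = center[2] + semiaxes[2] - depth
    tumor_center = (center[0], center[1], z_t)

    r_v = 2.0
    offset = r_t + vessel_distance_mm + r_v
    z_vessel = z_t - offset
    if z_vessel - r_v <= center[2] - semiaxes[2]:
        raise ValueError("vessel clearance does not fit inside the liver")
    vessel = VesselSpec(start=(center[0], 8.0, z_vessel), end=(center[0], 62.0, z_vessel),
                        radius=r_v)

    return PhantomSpec(
        liver_center=center,
        liver_semiaxes=semiaxes,
        tumor_center=tumor_center,
        tumor_radii=(r_t, r_t, r_t),
        vessels=[vessel],
        entry_point=(center[0], center[1], extent[2]),
        tip_point=tumor_center,
        spacing=spacing,
        extent=extent,
        suggested_power_w=power_w,
    )


def realized_distances(grid: LabelGrid) -> dict[str, float]:
    """Measure tumor-to-liver-surface and tumor-to-vessel distances (mm).

    Euclidean distance transforms give centre-to-centre voxel distances; a
    half-voxel correction on each side converts them to surface-to-surface
    estimates accurate to about one voxel.
    """
    from scipy import ndimage

    labels = grid.labels
    tumor = labels == Tissue.TUMOR
    if not tumor.any():
        raise ValueError("phantom contains no tumor voxels")
    h = max(grid.spacing)
    inside = np.isin(labels, [Tissue.LIVER, Tissue.TUMOR, Tissue.VESSEL, Tissue.CATHETER])
    d_surface = ndimage.distance_transform_edt(inside, sampling=grid.spacing)
    surface = max(float(d_surface[tumor].min()) - h, 0.0)
    out = {"surface_distance_mm": surface}
    vessel = labels == Tissue.VESSEL
    if vessel.any():
        d_vessel = ndimage.distance_transform_edt(~vessel, sampling=grid.spacing)
        out["vessel_distance_mm"] = max(float(d_vessel[tumor].min()) - h, 0.0)
    return out


def phantom_for_patient(patient: int, spacing: float = 1.0) -> PhantomSpec:
    """Convenience wrapper over :data:`PATIENT_SUMMARIES`."""
    s = PATIENT_SUMMARIES[patient]
    return phantom_from_patient_summary(s["tumor_volume_cm3"], s["surface_distance_mm"],
                                        s["vessel_distance_mm"], s["power_w"], spacing=spacing)


def axisymmetric_section(grid: LabelGrid, entry_point, tip_point,
                         r_max: float = 60.0, z_min: float = -45.0, z_max: float = 55.0,
                         spacing: float = 0.5, azimuth: tuple[float, float, float] | None = None,
                         ) -> LabelGrid:
    """Nearest-label resample of the half-plane containing the antenna axis.

    Returns a 2-D ``(r, z)`` label grid with ``r = 0`` on the axis and ``z``
    measured along the insertion direction with the antenna tip at
    ``z = 0`` (positive toward the entry point).  Sampling clamps to the
    phantom bounds, so tissue continues smoothly past the voxel domain.

    Only straight insertions are supported; ``entry`` and ``tip`` define the
    axis.  ``azimuth`` picks the half-plane (default: the grid +x direction
    projected perpendicular to the axis).
    """
    entry = np.asarray(entry_point, dtype=float)
    tip = np.asarray(tip_point, dtype=float)
    axis = entry - tip
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("entry and tip must be distinct (straight trajectory)")
    axis = axis / norm

    if azimuth is None:
        azimuth = (1.0, 0.0, 0.0) if abs(axis[0]) < 0.9 else (0.0, 1.0, 0.0)
    u = np.asarray(azimuth, dtype=float)
    u = u - (u @ axis) * axis
    un = np.linalg.norm(u)
    if un == 0:
        raise ValueError("azimuth direction is parallel to the trajectory")
    u = u / un

    nr = int(round(r_max / spacing))
    nz = int(round((z_max - z_min) / spacing))
    r = (np.arange(nr) + 0.5) * spacing
    z = z_min + (np.arange(nz) + 0.5) * spacing
    pts = tip[None, None, :] + z[None, :, None] * axis[None, None, :] + r[:, None, None] * u[None, None, :]

    idx = []
    for ax in range(3):
        i = np.floor((pts[..., ax] - grid.origin[ax]) / grid.spacing[ax]).astype(int)
        idx.append(np.clip(i, 0, grid.shape[ax] - 1))
    section = grid.labels[idx[0], idx[1], idx[2]]
    return LabelGrid(section.astype(np.int16), (spacing, spacing), (0.0, z_min))
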