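"""Arrhenius thermal-damage accumulation and ablation-zone reports.

Thermal injury is modelled by first-order kinetics: the damage integral

.. math::

    \\alpha(t) = \\int_0^t A \\exp\\big(-\\Delta E / (R\\, T(\\tau))\\big)\\, d\\tau

accumulates per voxel with tissue-specific parameters, and the necrotic
fraction is ``theta_d = 1 - exp(-alpha)``.  A voxel is counted as ablated
once ``theta_d > 0.98`` (equivalently ``alpha > ln 50``); an alternative
criterion marks voxels whose running-maximum temperature has crossed 50 degC
(irreversible by assumption).  From a binary ablation zone the module
derives tumor-destruction fraction, damaged healthy-liver volume, the
minimal ablative margin (MAM) and the earliest time at which the treatment
endpoint (complete destruction plus a target margin) is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .constants import celsius
from .grids import LabelGrid, Tissue
from .materials import MaterialModel

__all__ = [
    "ALPHA_NECROSIS",
    "DamageField",
    "AblationZone",
    "MarginReport",
    "StoppingReport",
    "accumulate",
    "necrotic_fraction",
    "extract_zone",
    "destruction_and_damage",
    "compute_mam",
    "stopping_time",
    "DamageObserver",
]

#: Damage-integral threshold equivalent to theta_d > 0.98.
ALPHA_NECROSIS = float(-np.log(0.02))

#: Irreversible-injury temperature threshold (degC) for the alternative criterion.
LETHAL_TEMPERATURE_C = 50.0


@dataclass
class DamageField:
    """Accumulated damage integral alpha per voxel (dimensionless)."""

    alpha: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.alpha < 0):
            raise ValueError("damage integral must be non-negative")


@dataclass
class AblationZone:
    """Binary ablation mask with its extraction criterion and time."""

    mask: np.ndarray
    criterion: str  # "arrhenius_098" | "threshold_50C"
    time: float


@dataclass
class MarginReport:
    tumor_destruction_fraction: float
    healthy_liver_damage_cm3: float
    total_nontumor_damage_cm3: float
    mam_mm: float
    mam_target_mm: float = 5.0

    @property
    def mam_achieved(self) -> bool:
        return self.mam_mm >= self.mam_target_mm

    def as_dict(self) -> dict:
        return {
            "tumor_destruction_fraction": self.tumor_destruction_fraction,
            "healthy_liver_damage_cm3": self.healthy_liver_damage_cm3,
            "total_nontumor_damage_cm3": self.total_nontumor_damage_cm3,
            "mam_mm": self.mam_mm,
            "mam_target_mm": self.mam_target_mm,
            "mam_achieved": self.mam_achieved,
        }


def accumulate(damage: DamageField, temperature_k: np.ndarray, dt: float,
               frequency_factor: np.ndarray, activation_energy: np.ndarray,
               gas_constant: float = 8.314, rule: str = "left") -> DamageField:
    """Advance the damage integral over one interval of length ``dt``.

    ``temperature_k`` is either one field (left-rectangle rule) or a pair
    ``(T_start, T_end)`` when ``rule='trapezoid'``.  Temperatures are
    absolute; non-physical values raise.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")

    def rate(tk):
        tk = np.asarray(tk, dtype=float)
        if np.any(tk <= 0):
            raise ValueError("absolute temperature must be positive")
        return frequency_factor * np.exp(-activation_energy / (gas_constant * tk))

    if rule == "left":
        inc = rate(temperature_k) * dt
    elif rule == "trapezoid":
        t0, t1 = temperature_k
        inc = 0.5 * (rate(t0) + rate(t1)) * dt
    else:
        raise ValueError(f"unknown quadrature rule '{rule}'")
    return DamageField(alpha=damage.alpha + inc, time=damage.time + dt)


def necrotic_fraction(alpha: np.ndarray | DamageField) -> np.ndarray:
    """Necrotic tissue fraction ``theta_d = 1 - exp(-alpha)`` in [0, 1)."""
    a = alpha.alpha if isinstance(alpha, DamageField) else np.asarray(alpha, dtype=float)
    return 1.0 - np.exp(-a)


def extract_zone(theta_d: np.ndarray | None, criterion: str = "arrhenius_098",
                 peak_temperature_k: np.ndarray | None = None,
                 time: float = 0.0) -> AblationZone:
    """Binary ablation zone from the necrosis field or the peak temperature."""
    if criterion == "arrhenius_098":
        if theta_d is None:
            raise ValueError("arrhenius criterion needs the necrosis field")
        mask = np.asarray(theta_d) > 0.98
    elif criterion == "threshold_50C":
        if peak_temperature_k is None:
            raise ValueError("temperature criterion needs the peak-temperature field")
        mask = celsius(np.asarray(peak_temperature_k)) >= LETHAL_TEMPERATURE_C
    else:
        raise ValueError(f"unknown zone criterion '{criterion}'")
    return AblationZone(mask=mask, criterion=criterion, time=time)


_ANTENNA_LABELS = (Tissue.ANTENNA_INNER_CONDUCTOR, Tissue.ANTENNA_DIELECTRIC,
                   Tissue.ANTENNA_OUTER_CONDUCTOR, Tissue.ANTENNA_SLOT, Tissue.CATHETER)


def destruction_and_damage(zone: AblationZone | np.ndarray, grid: LabelGrid,
                           mam_target_mm: float = 5.0) -> MarginReport:
    """Tumor destruction fraction, collateral damage volumes and MAM.

    Antenna-material voxels carry no damage kinetics, so the raw zone has a
    hole along the insertion track; for the margin computation the track is
    counted as ablated (the tissue it displaced is destroyed), while damage
    volumes remain label-based and never count antenna voxels.
    """
    mask = zone.mask if isinstance(zone, AblationZone) else np.asarray(zone, dtype=bool)
    labels = grid.labels
    tumor = labels == Tissue.TUMOR
    if not tumor.any():
        raise ValueError("grid contains no tumor voxels")
    vox_cm3 = grid.voxel_volume_mm3 / 1000.0
    frac = float((mask & tumor).sum() / tumor.sum())
    liver_damage = float((mask & (labels == Tissue.LIVER)).sum()) * vox_cm3
    antenna = np.isin(labels, _ANTENNA_LABELS)
    total_damage = float((mask & ~tumor & ~antenna).sum()) * vox_cm3
    mam = compute_mam(tumor, mask | antenna, grid.spacing)
    return MarginReport(frac, liver_damage, total_damage, mam, mam_target_mm)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """6-connectivity surface voxels of a binary mask."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    return mask & ~ndimage.binary_erosion(mask, structure=structure, border_value=0)


def compute_mam(tumor: np.ndarray, zone: np.ndarray, spacing) -> float:
    """Minimal ablative margin (mm), signed.

    Minimum over tumor-surface voxels of the Euclidean distance to the
    ablation-zone surface; negative where the tumor extends outside the
    zone (uncovered tumor), ``-inf`` for an empty zone.
    """
    tumor = np.asarray(tumor, dtype=bool)
    zone = np.asarray(zone, dtype=bool)
    if not tumor.any():
        raise ValueError("tumor mask is empty")
    if not zone.any():
        return float("-inf")
    tumor_surface = _boundary(tumor)
    zone_surface = _boundary(zone)
    d_to_zone_surface = ndimage.distance_transform_edt(~zone_surface, sampling=spacing)
    sign = np.where(zone, 1.0, -1.0)
    signed = (sign * d_to_zone_surface)[tumor_surface]
    return float(signed.min())


@dataclass
class StoppingReport:
    """Earliest time meeting the treatment endpoint, and what stopping saves."""

    stopping_time_s: float | None
    endpoint_met: bool
    damage_at_stop_cm3: float
    damage_at_end_cm3: float
    relative_damage_reduction: float
    reports: list = field(default_factory=list)  # (time, MarginReport)


def stopping_time(zones: list[AblationZone], grid: LabelGrid,
                  margin_target_mm: float = 5.0) -> StoppingReport:
    """Scan a zone time series for the earliest adequate-treatment time.

    The endpoint is complete tumor destruction together with
    ``MAM >= margin_target_mm``; when it is met only at the final time the
    stopping time equals the full duration.  Also reports the healthy-damage
    volume at the stopping time versus the full duration and the relative
    reduction achieved by stopping early.
    """
    if not zones:
        raise ValueError("need at least one ablation zone snapshot")
    zones = sorted(zones, key=lambda z: z.time)
    reports = [(z.time, destruction_and_damage(z, grid, margin_target_mm)) for z in zones]
    t_star = None
    for t, rep in reports:
        if rep.tumor_destruction_fraction >= 1.0 and rep.mam_mm >= margin_target_mm:
            t_star = t
            break
    end_t, end_rep = reports[-1]
    if t_star is None:
        return StoppingReport(None, False, end_rep.healthy_liver_damage_cm3,
                              end_rep.healthy_liver_damage_cm3, 0.0, reports)
    stop_rep = next(rep for t, rep in reports if t == t_star)
    v_stop = stop_rep.healthy_liver_damage_cm3
    v_end = end_rep.healthy_liver_damage_cm3
    reduction = 1.0 - v_stop / v_end if v_end > 0 else 0.0
    return StoppingReport(t_star, True, v_stop, v_end, reduction, reports)


class DamageObserver:
    """Accumulate damage online during a thermal run and snapshot zones.

    Plugs into :meth:`mwasim.bioheat.PennesSolver.run` /
    :func:`mwasim.bioheat.run_coupled`; uses the left-rectangle rule at the
    thermal step, consistent with the lagged-coefficient time integration.
    """

    def __init__(self, grid: LabelGrid, materials: MaterialModel,
                 zone_times=(), criterion: str = "arrhenius_098",
                 gas_constant: float = 8.314):
        self.grid = grid
        self.criterion = criterion
        self.a_map, self.de_map = materials.arrhenius_maps(grid.labels)
        self.gas_constant = gas_constant
        self.damage = DamageField(np.zeros(grid.shape))
        self.zone_times = sorted(float(t) for t in zone_times)
        self.zones: list[AblationZone] = []
        self._next = 0
        self._last_time = 0.0
        self._peak = None

    def start(self, problem, state):
        self._last_time = state.time
        self._peak = state.peak_temperature.copy()
        self._t_prev = state.temperature.copy()
        self._maybe_snapshot(state.time)

    def after_step(self, state):
        dt = state.time - self._last_time
        self.damage = accumulate(self.damage, self._t_prev, dt,
                                 self.a_map, self.de_map, self.gas_constant)
        self._t_prev = state.temperature.copy()
        self._last_time = state.time
        self._peak = state.peak_temperature
        self._maybe_snapshot(state.time)

    def current_zone(self, time: float | None = None) -> AblationZone:
        theta = necrotic_fraction(self.damage)
        return extract_zone(theta, self.criterion, peak_temperature_k=self._peak,
                            time=self._last_time if time is None else time)

    def _maybe_snapshot(self, t):
        while self._next < len(self.zone_times) and self.zone_times[self._next] <= t + 1e-9:
            self.zones.append(self.current_zone(time=self.zone_times[self._next]))
            self._next += 1
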