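"""Tissue material properties for microwave ablation modelling.

Liver and tumor dielectric properties follow sigmoid laws in temperature,

.. math::

    \\varepsilon_r(T) = l_3\\Big(1 - \\frac{1}{1 + e^{l_1 (l_2 - T)}}\\Big) + 1,
    \\qquad
    \\sigma(T) = c_3\\Big(1 - \\frac{1}{1 + e^{c_1 (c_2 - T)}}\\Big),

with ``T`` in degC; both saturate at their low-temperature plateau below
~60 degC and collapse (toward 1 and 0) once tissue desiccates above the
midpoint.  Thermal conductivity and blood perfusion rise linearly with
temperature; blood vessels are a static material compartment.  Thermal damage
kinetics are first-order Arrhenius, parameterised per tissue.

All constants live in ``data/materials.yaml`` (human-editable); this module
only gives them types, validation and a label-indexed lookup
(:class:`MaterialModel`).
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

from .constants import BODY_TEMPERATURE_C, KELVIN_OFFSET, R_GAS
from .grids import Tissue

__all__ = [
    "SigmoidCoefficients",
    "LinearLaw",
    "StaticTissueProperties",
    "BloodAndSourceParameters",
    "ArrheniusParameters",
    "TissueDefinition",
    "EffectiveProperties",
    "MaterialModel",
    "relative_permittivity",
    "electrical_conductivity",
    "thermal_conductivity",
    "blood_perfusion",
    "load_material_config",
]


def _check_finite(t):
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature must be finite")
    return t


@dataclass(frozen=True)
class SigmoidCoefficients:
    """Sigmoid law coefficients: steepness (1/degC), midpoint (degC), amplitude."""

    steepness: float
    midpoint: float
    amplitude: float

    def __post_init__(self):
        if not (self.steepness > 0 and self.amplitude > 0):
            raise ValueError("sigmoid steepness and amplitude must be positive")


@dataclass(frozen=True)
class LinearLaw:
    """Linear temperature law ``slope * T(degC) + intercept``."""

    slope: float
    intercept: float

    def __call__(self, t_celsius):
        return self.slope * _check_finite(t_celsius) + self.intercept


#: Default liver thermal-conductivity law, W/(m*K) as a function of degC.
THERMAL_CONDUCTIVITY_LAW = LinearLaw(0.001265, 0.4882)

#: Default blood-perfusion law, 1/s as a function of degC.
PERFUSION_LAW = LinearLaw(0.000021, 0.00035)


def relative_permittivity(t_celsius, coeffs: SigmoidCoefficients):
    """Temperature-dependent relative permittivity (dimensionless).

    Monotone decreasing; tends to ``amplitude + 1`` for cold tissue and to 1
    once the tissue has fully desiccated.
    """
    t = _check_finite(t_celsius)
    s = 1.0 / (1.0 + np.exp(np.clip(coeffs.steepness * (coeffs.midpoint - t), -700, 700)))
    return coeffs.amplitude * (1.0 - s) + 1.0


def electrical_conductivity(t_celsius, coeffs: SigmoidCoefficients):
    """Temperature-dependent electrical conductivity (S/m); decreasing in T."""
    t = _check_finite(t_celsius)
    s = 1.0 / (1.0 + np.exp(np.clip(coeffs.steepness * (coeffs.midpoint - t), -700, 700)))
    return coeffs.amplitude * (1.0 - s)


def thermal_conductivity(t_celsius, law: LinearLaw = THERMAL_CONDUCTIVITY_LAW):
    """Liver/tumor thermal conductivity W/(m*K) at ``T`` degC."""
    return law(t_celsius)


def blood_perfusion(t_celsius, law: LinearLaw = PERFUSION_LAW):
    """Blood perfusion rate (1/s) at ``T`` degC, clipped at zero."""
    return np.maximum(law(t_celsius), 0.0)


@dataclass(frozen=True)
class StaticTissueProperties:
    electrical_conductivity: float  # S/m
    relative_permittivity: float
    thermal_conductivity: float  # W/(m*K)
    specific_heat: float  # J/(kg*K)
    density: float  # kg/m^3

    def __post_init__(self):
        for name in ("thermal_conductivity", "specific_heat", "density"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.electrical_conductivity < 0 or self.relative_permittivity < 1:
            raise ValueError("need sigma >= 0 and eps_r >= 1")


@dataclass(frozen=True)
class BloodAndSourceParameters:
    """Perfusion-sink and metabolic-source constants of the bioheat equation."""

    blood_density: float = 1060.0  # kg/m^3
    blood_specific_heat: float = 3600.0  # J/(kg*K)
    blood_temperature: float = BODY_TEMPERATURE_C + KELVIN_OFFSET  # K
    perfusion_law: LinearLaw = PERFUSION_LAW
    metabolic_heat: float = 33800.0  # W/m^3

    def __post_init__(self):
        if self.metabolic_heat < 0:
            raise ValueError("metabolic heat must be non-negative")


@dataclass(frozen=True)
class ArrheniusParameters:
    frequency_factor: float  # 1/s
    activation_energy: float  # J/mol
    gas_constant: float = R_GAS

    def __post_init__(self):
        if not (self.frequency_factor > 0 and self.activation_energy > 0):
            raise ValueError("Arrhenius A and dE must be positive")

    def rate(self, t_kelvin):
        """Damage accumulation rate (1/s) at absolute temperature."""
        t = np.asarray(t_kelvin, dtype=float)
        if np.any(t <= 0):
            raise ValueError("absolute temperature must be positive")
        return self.frequency_factor * np.exp(-self.activation_energy / (self.gas_constant * t))


@dataclass
class TissueDefinition:
    """Complete property set for one tissue label."""

    name: str
    static: StaticTissueProperties
    permittivity_sigmoid: SigmoidCoefficients | None = None
    conductivity_sigmoid: SigmoidCoefficients | None = None
    thermal_conductivity_law: LinearLaw | None = None
    perfused: bool = False
    arrhenius: ArrheniusParameters | None = None
    is_conductor: bool = False


@dataclass(frozen=True)
class EffectiveProperties:
    """Property bundle at one temperature, as consumed by the solvers."""

    electrical_conductivity: float
    relative_permittivity: float
    thermal_conductivity: float
    specific_heat: float
    density: float
    perfusion: float
    is_conductor: bool


def load_material_config(path: str | None = None) -> dict:
    """Load the structured material config (shipped default when no path)."""
    if path is None:
        ref = importlib.resources.files("mwasim.data").joinpath("materials.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return _coerce_numbers(yaml.safe_load(text))


def _coerce_numbers(node):
    """YAML 1.1 parses '7.39e39' (signless exponent) as a string; fix that."""
    if isinstance(node, dict):
        return {k: _coerce_numbers(v) for k, v in node.items()}
    if isinstance(node, list):
        return [_coerce_numbers(v) for v in node]
    if isinstance(node, str):
        try:
            return float(node)
        except ValueError:
            return node
    return node


def _sigmoid_from_cfg(cfg: dict | None, amp_key: str) -> SigmoidCoefficients | None:
    if cfg is None:
        return None
    return SigmoidCoefficients(cfg["steepness_per_C"], cfg["midpoint_C"], cfg[amp_key])


class MaterialModel:
    """Label-indexed property lookup over the full tissue/antenna legend.

    ``lookup`` is pure: identical (label, temperature) inputs give identical
    outputs.  Conductor labels have no dielectric properties (they are
    excluded from the electromagnetic unknowns) but do conduct heat.
    """

    def __init__(self, tissues: dict[int, TissueDefinition], blood: BloodAndSourceParameters,
                 frequency_hz: float = 2.45e9):
        self.tissues = dict(tissues)
        self.blood = blood
        self.frequency_hz = float(frequency_hz)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_config(cls, config: dict, profile: str | None = None) -> "MaterialModel":
        cfg = copy.deepcopy(config)
        if profile:
            try:
                override = cfg["profiles"][profile]
            except KeyError as exc:
                raise KeyError(f"unknown material profile '{profile}'") from exc
            for tname, tcfg in override.get("tissues", {}).items():
                cfg["tissues"][tname].update(tcfg)
        bl = cfg["blood"]
        blood = BloodAndSourceParameters(
            blood_density=bl["density_kg_m3"],
            blood_specific_heat=bl["specific_heat_J_kgK"],
            blood_temperature=bl["temperature_C"] + KELVIN_OFFSET,
            perfusion_law=LinearLaw(bl["perfusion_slope_per_sC"], bl["perfusion_intercept_per_s"]),
            metabolic_heat=bl["metabolic_heat_W_m3"],
        )
        name_to_label = {t.name.lower(): int(t) for t in Tissue}
        tissues: dict[int, TissueDefinition] = {}
        for name, tc in cfg["tissues"].items():
            label = name_to_label[name.lower()]
            conductor = bool(tc.get("is_conductor", False))
            perm = _sigmoid_from_cfg(tc.get("permittivity_sigmoid"), "amplitude")
            cond = _sigmoid_from_cfg(tc.get("conductivity_sigmoid"), "amplitude_S_m")
            klaw_cfg = tc.get("thermal_conductivity_law")
            klaw = LinearLaw(klaw_cfg["slope_W_mKC"], klaw_cfg["intercept_W_mK"]) if klaw_cfg else None
            t0 = BODY_TEMPERATURE_C
            sigma0 = (float(electrical_conductivity(t0, cond)) if cond
                      else tc.get("electrical_conductivity_S_m", 0.0))
            eps0 = (float(relative_permittivity(t0, perm)) if perm
                    else tc.get("relative_permittivity", 1.0))
            k0 = klaw(t0) if klaw else tc.get("thermal_conductivity_W_mK")
            arr_cfg = tc.get("arrhenius")
            arr = (ArrheniusParameters(arr_cfg["frequency_factor_per_s"],
                                       arr_cfg["activation_energy_J_mol"]) if arr_cfg else None)
            tissues[label] = TissueDefinition(
                name=name,
                static=StaticTissueProperties(sigma0, max(eps0, 1.0), k0,
                                              tc["specific_heat_J_kgK"], tc["density_kg_m3"]),
                permittivity_sigmoid=perm,
                conductivity_sigmoid=cond,
                thermal_conductivity_law=klaw,
                perfused=bool(tc.get("perfused", False)),
                arrhenius=arr,
                is_conductor=conductor,
            )
        return cls(tissues, blood, cfg.get("frequency_hz", 2.45e9))

    @classmethod
    def default(cls, profile: str | None = None) -> "MaterialModel":
        return cls.from_config(load_material_config(), profile=profile)

    # -- lookup -----------------------------------------------------------

    def _get(self, label: int) -> TissueDefinition:
        try:
            return self.tissues[int(label)]
        except KeyError as exc:
            raise KeyError(f"no material registered for label {int(label)}") from exc

    def lookup(self, label: int, t_celsius: float = BODY_TEMPERATURE_C) -> EffectiveProperties:
        """Effective property bundle for one label at one temperature (degC)."""
        td = self._get(label)
        _check_finite(t_celsius)
        sigma = (float(electrical_conductivity(t_celsius, td.conductivity_sigmoid))
                 if td.conductivity_sigmoid else td.static.electrical_conductivity)
        eps = (float(relative_permittivity(t_celsius, td.permittivity_sigmoid))
               if td.permittivity_sigmoid else td.static.relative_permittivity)
        k = (float(td.thermal_conductivity_law(t_celsius))
             if td.thermal_conductivity_law else td.static.thermal_conductivity)
        perf = float(blood_perfusion(t_celsius, self.blood.perfusion_law)) if td.perfused else 0.0
        return EffectiveProperties(sigma, eps, k, td.static.specific_heat,
                                   td.static.density, perf, td.is_conductor)

    def validate_labels(self, labels: np.ndarray) -> None:
        """Every label present in a grid must resolve to a property set."""
        for label in np.unique(labels):
            self._get(int(label))

    # -- vectorised per-grid maps ----------------------------------------

    def _per_label(self, labels, fn, dtype=float):
        out = np.zeros(labels.shape, dtype=dtype)
        for label in np.unique(labels):
            out[labels == label] = fn(self._get(int(label)))
        return out

    def em_maps(self, labels: np.ndarray, t_celsius: np.ndarray | float):
        """(eps_r, sigma, conductor-mask) arrays at the given temperatures."""
        t = np.broadcast_to(np.asarray(t_celsius, dtype=float), labels.shape)
        eps = np.ones(labels.shape)
        sigma = np.zeros(labels.shape)
        cond = np.zeros(labels.shape, dtype=bool)
        for label in np.unique(labels):
            td = self._get(int(label))
            m = labels == label
            cond[m] = td.is_conductor
            if td.is_conductor:
                continue
            if td.permittivity_sigmoid:
                eps[m] = relative_permittivity(t[m], td.permittivity_sigmoid)
            else:
                eps[m] = td.static.relative_permittivity
            if td.conductivity_sigmoid:
                sigma[m] = electrical_conductivity(t[m], td.conductivity_sigmoid)
            else:
                sigma[m] = td.static.electrical_conductivity
        return eps, sigma, cond

    def thermal_maps(self, labels: np.ndarray, t_celsius: np.ndarray | float):
        """(k, rho*C, perfusion, Qmet) arrays at the given temperatures."""
        t = np.broadcast_to(np.asarray(t_celsius, dtype=float), labels.shape)
        k = np.zeros(labels.shape)
        rho_c = np.zeros(labels.shape)
        perf = np.zeros(labels.shape)
        qmet = np.zeros(labels.shape)
        for label in np.unique(labels):
            td = self._get(int(label))
            m = labels == label
            k[m] = td.thermal_conductivity_law(t[m]) if td.thermal_conductivity_law \
                else td.static.thermal_conductivity
            rho_c[m] = td.static.density * td.static.specific_heat
            if td.perfused:
                perf[m] = blood_perfusion(t[m], self.blood.perfusion_law)
                qmet[m] = self.blood.metabolic_heat
        return k, rho_c, perf, qmet

    def density_map(self, labels: np.ndarray):
        return self._per_label(labels, lambda td: td.static.density)

    def arrhenius_maps(self, labels: np.ndarray):
        """(A, dE) arrays; labels without kinetics accumulate no damage (A=0)."""
        a = np.zeros(labels.shape)
        de = np.ones(labels.shape)
        for label in np.unique(labels):
            td = self._get(int(label))
            if td.arrhenius is not None:
                m = labels == label
                a[m] = td.arrhenius.frequency_factor
                de[m] = td.arrhenius.activation_energy
        return a, de
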