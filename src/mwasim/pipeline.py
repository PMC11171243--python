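"""End-to-end orchestration: phantom -> EM -> bioheat -> damage -> metrics.

A :class:`RunConfig` (a validated, YAML-serialisable document) fully
determines one simulation; :func:`simulate` executes it and writes a
re-loadable :class:`RunReport` plus mask/field artifacts, so every run can
be replayed from its resolved-config snapshot alone.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from . import __version__
from .bioheat import CouplingPolicy, ProbeObserver, run_coupled
from .constants import BODY_TEMPERATURE_K
from .damage import DamageObserver, destruction_and_damage, stopping_time
from .grids import LabelGrid, save_mask, write_vtk_image
from .materials import MaterialModel, load_material_config
from .metrics import MaskPair, VendorZoneSpec, evaluate_pair, vendor_zone
from .phantom import (AntennaTemplate, build_phantom,
                      phantom_for_patient)

__all__ = ["RunConfig", "simulate", "compare", "load_config"]


class CouplingConfig(BaseModel):
    resolve_interval_s: float = 10.0
    sigma_rel_threshold: float = 0.02
    min_resolve_interval_s: float = 2.0

    def policy(self) -> CouplingPolicy:
        return CouplingPolicy(self.resolve_interval_s, self.sigma_rel_threshold,
                              self.min_resolve_interval_s)


class RunConfig(BaseModel):
    """Resolved configuration of one ablation simulation."""

    scenario: str = "patient1"
    patient: int | None = 1
    mask_path: str | None = None
    entry_point: tuple[float, float, float] | None = None
    tip_point: tuple[float, float, float] | None = None
    spacing_mm: float = 2.5
    power_w: float | None = None
    frequency_hz: float = 2.45e9
    duration_s: float = 600.0
    dt_s: float = 0.5
    output_times_s: list[float] = Field(default_factory=lambda: [420.0, 480.0, 570.0, 600.0])
    zone_criterion: str = "arrhenius_098"
    material_profile: str | None = "tumor_kinetics_adjusted"
    material_config_path: str | None = None
    coupling: CouplingConfig = Field(default_factory=CouplingConfig)
    temperature_dependent: bool = True
    margin_target_mm: float = 5.0
    probes: list[tuple[float, float, float]] = Field(default_factory=list)
    write_fields: bool = False
    output_dir: str = "runs/latest"
    seed: int = 0

    @field_validator("duration_s")
    @classmethod
    def _dur(cls, v):
        if v < 0:
            raise ValueError("duration must be non-negative")
        return v

    @field_validator("dt_s", "spacing_mm")
    @classmethod
    def _pos(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @model_validator(mode="after")
    def _cross(self):
        if self.power_w is not None and self.power_w <= 0:
            raise ValueError("power must be positive")
        if any(t < 0 or t > self.duration_s for t in self.output_times_s):
            raise ValueError("output times must lie within [0, duration]")
        if self.mask_path is None and self.patient is None:
            raise ValueError("either a patient scenario or a mask path is required")
        if self.mask_path is not None and (self.entry_point is None or self.tip_point is None):
            raise ValueError("mask input needs explicit entry and tip points")
        return self


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return RunConfig.model_validate(doc)
    except ValidationError as exc:
        lines = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()]
        raise ValueError("invalid run config:\n  " + "\n  ".join(lines)) from exc


def _prepare(config: RunConfig):
    mat_cfg = load_material_config(config.material_config_path)
    materials = MaterialModel.from_config(mat_cfg, profile=config.material_profile)
    template = AntennaTemplate.from_config(mat_cfg["antenna"], frequency_hz=config.frequency_hz)
    if config.mask_path is not None:
        grid = LabelGrid.load(config.mask_path)
        entry, tip = config.entry_point, config.tip_point
        power = config.power_w or 65.0
        spec = None
    else:
        spec = phantom_for_patient(config.patient, spacing=config.spacing_mm)
        grid = build_phantom(spec, template)
        entry, tip = spec.entry_point, spec.tip_point
        power = config.power_w or spec.suggested_power_w
    return materials, template, grid, entry, tip, power


def simulate(config: RunConfig) -> dict:
    """Run one scenario end to end; returns (and writes) the run report."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_wall = time.time()

    materials, template, grid, entry, tip, power = _prepare(config)

    observers = []
    damage_obs = DamageObserver(grid, materials,
                                zone_times=sorted(set(config.output_times_s) | {config.duration_s}),
                                criterion=config.zone_criterion)
    observers.append(damage_obs)
    probe_obs = None
    if config.probes:
        probe_obs = ProbeObserver(grid, config.probes)
        observers.append(probe_obs)

    result = run_coupled(grid, materials, template, entry, tip, power,
                         duration=config.duration_s, dt=config.dt_s,
                         policy=config.coupling.policy(), observers=observers,
                         temperature_dependent=config.temperature_dependent,
                         initial_temperature=BODY_TEMPERATURE_K)

    margin_reports = {}
    for zone in damage_obs.zones:
        rep = destruction_and_damage(zone, grid, config.margin_target_mm)
        margin_reports[f"{zone.time:g}"] = rep.as_dict()
        save_mask(zone.mask, grid, str(out_dir / f"zone_{zone.time:g}s.nii.gz"))
    stopping = stopping_time(damage_obs.zones, grid, config.margin_target_mm)

    audit = result.em_solution.power_audit
    report = {
        "software_version": __version__,
        "python": platform.python_version(),
        "config": json.loads(config.model_dump_json()),
        "power_audit": audit,
        "em_solves": result.state.em_solve_count,
        "delivered_energy_J": result.delivered_energy_J,
        "margin_reports": margin_reports,
        "stopping": {
            "stopping_time_s": stopping.stopping_time_s,
            "endpoint_met": stopping.endpoint_met,
            "damage_at_stop_cm3": stopping.damage_at_stop_cm3,
            "damage_at_end_cm3": stopping.damage_at_end_cm3,
            "relative_damage_reduction": stopping.relative_damage_reduction,
        },
        "max_temperature_C": float(result.state.peak_temperature.max() - 273.15),
        "wall_time_s": time.time() - t_wall,
    }

    with open(out_dir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(json.loads(config.model_dump_json()), fh)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    if probe_obs is not None:
        frame = pd.DataFrame(
            np.column_stack([probe_obs.times, np.asarray(probe_obs.values)]),
            columns=["time_s"] + [f"probe{i}_K" for i in range(len(config.probes))],
        )
        frame.to_csv(out_dir / "probes.csv", index=False)
    if config.write_fields:
        write_vtk_image(str(out_dir / "final_fields.vtk"),
                        {"temperature_K": result.state.temperature,
                         "peak_temperature_K": result.state.peak_temperature,
                         "q_ext_W_m3": result.problem.q_ext},
                        grid.spacing, grid.origin)
    return report


def compare(config: RunConfig, reference_mask_path: str,
            vendor: VendorZoneSpec | None = None) -> dict:
    """Score a simulated final zone against a reference mask (plus vendor)."""
    report = simulate(config)
    out_dir = Path(config.output_dir)
    final_zone = LabelGrid.load(str(out_dir / f"zone_{config.duration_s:g}s.nii.gz"))
    try:
        reference = LabelGrid.load(reference_mask_path)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"reference mask not found: {reference_mask_path}") from exc
    if reference.shape != final_zone.shape:
        raise ValueError("reference mask grid does not match the simulation grid")
    pair = MaskPair(reference.labels > 0, final_zone.labels > 0, final_zone.spacing)
    out = {"model": evaluate_pair(pair).as_dict()}
    if vendor is not None:
        materials, template, grid, entry, tip, power = _prepare(config)
        vz = vendor_zone(vendor, grid, entry, tip)
        out["vendor"] = evaluate_pair(
            MaskPair(reference.labels > 0, vz, final_zone.spacing)).as_dict()
    report["comparison"] = out
    with open(out_dir / "comparison.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return report
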