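"""Shared fixtures: material models and one session-scoped coupled run.

The coupled run uses the patient-1-like scenario (65 W, 10 min) on a
2.5 mm voxel phantom under the adjusted tumor-kinetics profile; several
test modules interrogate it (temperatures, damage, margins, audits) so it
is computed once per session.
"""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mwasim.bioheat import SnapshotObserver, run_coupled
from mwasim.damage import DamageObserver
from mwasim.materials import MaterialModel
from mwasim.phantom import AntennaTemplate, build_phantom, phantom_for_patient

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def materials():
    return MaterialModel.default()


@pytest.fixture(scope="session")
def materials_adjusted():
    return MaterialModel.default("tumor_kinetics_adjusted")


@pytest.fixture(scope="session")
def patient1_run(materials_adjusted):
    """Coupled EM/bioheat run of the patient-1-like scenario (600 s, 65 W)."""
    spec = phantom_for_patient(1, spacing=2.5)
    grid = build_phantom(spec)
    template = AntennaTemplate()
    zone_times = list(range(60, 601, 60))
    damage = DamageObserver(grid, materials_adjusted, zone_times=zone_times)
    snapshots = SnapshotObserver(times=[0.0, 300.0, 600.0])
    import time

    t0 = time.time()
    result = run_coupled(grid, materials_adjusted, template, spec.entry_point,
                         spec.tip_point, power_w=65.0, duration=600.0, dt=0.5,
                         observers=[damage, snapshots])
    wall = time.time() - t0
    return SimpleNamespace(spec=spec, grid=grid, template=template, result=result,
                           damage=damage, snapshots=snapshots, wall_time_s=wall)
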