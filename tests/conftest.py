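import numpy as np
import pandas as pd
import pytest

from coherent_staffing.care_system_model import (
    CareSystemConfiguration,
    LAYOUTS,
    NtPRatio,
    NurseRegistry,
    Roster,
    SkillMatrix,
    Unit,
    load_reference_system,
)
from coherent_staffing.synthetic_demand import (
    TransitionMatrix,
    default_transition_matrices,
)


@pytest.fixture(scope="session")
def reference_config():
    return load_reference_system()


@pytest.fixture(scope="session")
def all_configs():
    return {layout: load_reference_system(layout) for layout in LAYOUTS}


@pytest.fixture(scope="session")
def matrices():
    return default_transition_matrices()


def build_config(
    unit_specs,
    roster,
    ntp,
    skill=None,
    registry=None,
):
    """Assemble a small care system for unit tests.

    ``unit_specs``: list of (id, department, beds, group, rank);
    ``roster``/``ntp``: {shift_type: {unit: value}}; ``skill``: square
    0/1 DataFrame-able mapping (defaults to identity).
    """
    units = tuple(
        Unit(id=u, department=dep, beds=b, patient_group=g, specialization_rank=r)
        for (u, dep, b, g, r) in unit_specs
    )
    ids = [u.id for u in units]
    if skill is None:
        Z = pd.DataFrame(np.eye(len(ids), dtype=int), index=ids, columns=ids)
    else:
        Z = pd.DataFrame(skill, index=ids, columns=ids).fillna(0).astype(int)
    Z.index.name = "from"
    return CareSystemConfiguration(
        layout="current",
        units=units,
        roster=Roster(pd.DataFrame(roster).T[ids]),
        ntp=NtPRatio(pd.DataFrame(ntp).T[ids]),
        skill_matrix=SkillMatrix(Z),
        registry=NurseRegistry(registry or {u.id: 10 for u in units}),
    )


@pytest.fixture
def single_unit_config():
    """One 10-bed ward, constant roster of 3, ratio 1:2 everywhere."""
    return build_config(
        [("W1", "Ward", 10, "adult", 1)],
        {s: {"W1": 3} for s in ("day", "evening", "night")},
        {s: {"W1": 2} for s in ("day", "evening", "night")},
    )


def single_unit_matrices(stay: float, unit: str = "W1"):
    P = pd.DataFrame({unit: {unit: stay}, "exit": {unit: 1 - stay}})
    P.index.name = "from"
    return {"adult": TransitionMatrix("adult", P)}
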