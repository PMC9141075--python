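"""Structural description of a multi-unit care system.

Units, daily rosters, nurse-to-patient ratios, qualification (skill)
matrices and the registered-nurse headcounts, together with a bundled
reference system: a 70-bed, two-department perinatology service with
six wards, one of which (the maternity ward O1) is modelled as two
locations — O1n (newborn beds) and O1a (adult beds).

Three strategic layouts of the same system are supported:

``current``
    six independent units; qualification follows specialization rank
    (more specialized nurses may cover less specialized units).
``config1_two_departments``
    the three units of each department are pooled, with a reciprocal
    N3/O1n link between the departments.
``config2_one_department``
    one fully pooled department; every nurse may work everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SHIFT_TYPES",
    "CURRENT",
    "CONFIG1",
    "CONFIG2",
    "LAYOUTS",
    "FLOAT_POOL",
    "NEWBORN",
    "ADULT",
    "Unit",
    "Roster",
    "NtPRatio",
    "SkillMatrix",
    "NurseRegistry",
    "CareSystemConfiguration",
    "canonical_layout",
    "shift_type_of",
    "round_half_up",
    "largest_remainder_apportion",
    "load_reference_system",
    "derive_skill_matrix",
    "nurses_to_train",
]

SHIFT_TYPES: tuple[str, ...] = ("day", "evening", "night")

CURRENT = "current"
CONFIG1 = "config1_two_departments"
CONFIG2 = "config2_one_department"
LAYOUTS: tuple[str, ...] = (CURRENT, CONFIG1, CONFIG2)

_LAYOUT_ALIASES = {
    CURRENT: CURRENT,
    "config1": CONFIG1,
    CONFIG1: CONFIG1,
    "config2": CONFIG2,
    CONFIG2: CONFIG2,
}

#: Label of the optional float-pool row in a skill matrix.
FLOAT_POOL = "pool"

NEWBORN = "newborn"
ADULT = "adult"

TRAINING_COST_PER_NURSE_EUR = 20_000


def canonical_layout(layout: str) -> str:
    """Resolve a layout name or alias to its canonical identifier."""
    try:
        return _LAYOUT_ALIASES[layout]
    except KeyError:
        raise ValueError(
            f"unknown layout {layout!r}; expected one of {LAYOUTS}"
        ) from None


def shift_type_of(shift_index: int, shifts_per_day: int = 3) -> str:
    """Shift type (day/evening/night) of a running shift index."""
    return SHIFT_TYPES[shift_index % shifts_per_day]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def largest_remainder_apportion(
    total: int,
    weights: Sequence[float],
    caps: Sequence[int] | None = None,
) -> np.ndarray:
    """Apportion ``total`` indivisible items proportionally to ``weights``.

    Standard largest-remainder (Hamilton) apportionment: each index gets
    the floor of its quota and the leftover items go to the largest
    fractional remainders, ties broken by index order.  ``caps`` bounds
    the allocation per index.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    alloc = np.zeros(len(w), dtype=int)
    if total == 0:
        return alloc
    if w.sum() <= 0:
        raise ValueError("cannot apportion a positive total over zero weights")
    cap = None if caps is None else np.asarray(caps, dtype=int)
    if cap is not None and cap.sum() < total:
        raise ValueError("caps cannot accommodate the requested total")
    quotas = total * w / w.sum()
    alloc = np.floor(quotas).astype(int)
    if cap is not None:
        alloc = np.minimum(alloc, cap)
    remainders = quotas - alloc
    order = sorted(range(len(w)), key=lambda i: (-remainders[i], i))
    left = total - int(alloc.sum())
    while left > 0:
        progressed = False
        for i in order:
            if left == 0:
                break
            if cap is None or alloc[i] < cap[i]:
                alloc[i] += 1
                left -= 1
                progressed = True
        if not progressed:  # pragma: no cover - guarded by cap check above
            raise ValueError("apportionment could not place all items")
    return alloc


@dataclass(frozen=True)
class Unit:
    """One physical care location.

    ``specialization_rank`` is ordinal within the department, 1 being
    the most specialized.
    """

    id: str
    department: str
    beds: int
    patient_group: str
    specialization_rank: int

    def __post_init__(self) -> None:
        if self.beds <= 0:
            raise ValueError(f"unit {self.id}: beds must be positive")
        if self.patient_group not in (NEWBORN, ADULT):
            raise ValueError(f"unit {self.id}: unknown patient group")


@dataclass
class Roster:
    """Nurses scheduled per shift type and unit (repeats daily)."""

    scheduled: pd.DataFrame  # index: shift types, columns: unit ids

    def __post_init__(self) -> None:
        self.scheduled = self.scheduled.loc[list(SHIFT_TYPES)].astype(int)
        if (self.scheduled.values < 0).any():
            raise ValueError("roster entries must be non-negative")

    @property
    def units(self) -> tuple[str, ...]:
        return tuple(self.scheduled.columns)

    def row(self, shift_type: str) -> pd.Series:
        return self.scheduled.loc[shift_type]

    def total(self, shift_type: str) -> int:
        return int(self.scheduled.loc[shift_type].sum())

    @property
    def grand_total(self) -> int:
        return int(self.scheduled.values.sum())


@dataclass
class NtPRatio:
    """Patients one nurse covers, per shift type and unit."""

    patients_per_nurse: pd.DataFrame  # index: shift types, columns: unit ids

    def __post_init__(self) -> None:
        self.patients_per_nurse = self.patients_per_nurse.loc[
            list(SHIFT_TYPES)
        ].astype(int)
        if (self.patients_per_nurse.values <= 0).any():
            raise ValueError("nurse-to-patient ratios must be positive")

    def row(self, shift_type: str) -> pd.Series:
        return self.patients_per_nurse.loc[shift_type]


@dataclass
class SkillMatrix:
    """Binary qualification map.

    ``Z[j, i] == 1`` iff a nurse registered in location ``j`` may work
    in unit ``i``.  Rows are locations (units plus an optional float
    pool); columns are units only — nurses cannot be reallocated into
    the pool mid-shift.
    """

    Z: pd.DataFrame

    def __post_init__(self) -> None:
        self.Z = self.Z.astype(int)
        self.validate()

    def validate(self) -> None:
        vals = self.Z.values
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("skill matrix entries must be 0/1")
        if FLOAT_POOL in self.Z.columns:
            raise ValueError("skill matrix must not have a float-pool column")
        for u in self.Z.columns:
            if self.Z.loc[u, u] != 1:
                raise ValueError(f"skill matrix diagonal must be 1 (unit {u})")
        if self.has_float_pool and not (self.Z.loc[FLOAT_POOL] == 1).all():
            raise ValueError("float-pool row must be all ones")

    @property
    def units(self) -> tuple[str, ...]:
        return tuple(self.Z.columns)

    @property
    def has_float_pool(self) -> bool:
        return FLOAT_POOL in self.Z.index

    def can_serve(self, j: str, i: str) -> bool:
        return bool(self.Z.loc[j, i])

    def unit_matrix(self) -> "SkillMatrix":
        """Copy without the float-pool row."""
        if not self.has_float_pool:
            return SkillMatrix(self.Z.copy())
        return SkillMatrix(self.Z.drop(index=FLOAT_POOL))

    def with_float_pool(self) -> "SkillMatrix":
        """Copy with an all-ones float-pool row appended."""
        if self.has_float_pool:
            return SkillMatrix(self.Z.copy())
        Z = self.Z.copy()
        Z.loc[FLOAT_POOL] = 1
        return SkillMatrix(Z)

    def dominates(self, other: "SkillMatrix") -> bool:
        """Entrywise ``>=`` on the shared unit rows/columns."""
        a = self.unit_matrix().Z
        b = other.unit_matrix().Z
        return bool((a.loc[b.index, b.columns].values >= b.values).all())

    @classmethod
    def from_csv(cls, path) -> "SkillMatrix":
        Z = pd.read_csv(path, index_col=0)
        Z.index.name = "from"
        return cls(Z)

    def to_csv(self, path) -> None:
        self.Z.to_csv(path)


@dataclass
class NurseRegistry:
    """Registered nurses by unit or qualification group."""

    registered: dict[str, int]

    def __post_init__(self) -> None:
        for group, count in self.registered.items():
            if count < 0:
                raise ValueError(f"registry group {group}: negative headcount")

    @property
    def total(self) -> int:
        return int(sum(self.registered.values()))

    def __getitem__(self, group: str) -> int:
        return self.registered[group]


@dataclass
class CareSystemConfiguration:
    """A complete strategic description of one care-system layout."""

    layout: str
    units: tuple[Unit, ...]
    roster: Roster
    ntp: NtPRatio
    skill_matrix: SkillMatrix
    registry: NurseRegistry
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.layout = canonical_layout(self.layout)
        ids = self.unit_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate unit ids")
        for table, name in (
            (self.roster.scheduled, "roster"),
            (self.ntp.patients_per_nurse, "ntp_ratio"),
        ):
            if tuple(table.columns) != ids:
                raise ValueError(f"{name} columns must match unit order {ids}")
        if self.skill_matrix.units != ids:
            raise ValueError("skill matrix columns must match unit order")

    @property
    def unit_ids(self) -> tuple[str, ...]:
        return tuple(u.id for u in self.units)

    @property
    def beds(self) -> pd.Series:
        return pd.Series(
            {u.id: u.beds for u in self.units}, name="beds"
        ).loc[list(self.unit_ids)]

    @property
    def total_beds(self) -> int:
        return int(self.beds.sum())

    @property
    def departments(self) -> tuple[str, ...]:
        seen: list[str] = []
        for u in self.units:
            if u.department not in seen:
                seen.append(u.department)
        return tuple(seen)

    def unit(self, unit_id: str) -> Unit:
        for u in self.units:
            if u.id == unit_id:
                return u
        raise KeyError(unit_id)

    @property
    def patient_groups(self) -> dict[str, tuple[str, ...]]:
        groups: dict[str, list[str]] = {}
        for u in self.units:
            groups.setdefault(u.patient_group, []).append(u.id)
        return {g: tuple(us) for g, us in groups.items()}

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "layout": self.layout,
            "units": [
                {
                    "id": u.id,
                    "department": u.department,
                    "beds": u.beds,
                    "patient_group": u.patient_group,
                    "specialization_rank": u.specialization_rank,
                }
                for u in self.units
            ],
            "roster": {
                s: {u: int(v) for u, v in self.roster.row(s).items()}
                for s in SHIFT_TYPES
            },
            "ntp_ratio": {
                s: {u: int(v) for u, v in self.ntp.row(s).items()}
                for s in SHIFT_TYPES
            },
            "skill_matrix": {
                str(j): [int(v) for v in self.skill_matrix.Z.loc[j]]
                for j in self.skill_matrix.Z.index
            },
            "registry": dict(self.registry.registered),
            "extras": dict(self.extras),
        }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CareSystemConfiguration":
        units = tuple(Unit(**u) for u in raw["units"])
        ids = [u.id for u in units]
        roster = Roster(pd.DataFrame(raw["roster"]).T[ids])
        ntp = NtPRatio(pd.DataFrame(raw["ntp_ratio"]).T[ids])
        Z = pd.DataFrame.from_dict(
            {j: dict(zip(ids, row)) for j, row in raw["skill_matrix"].items()},
            orient="index",
        )[ids]
        Z.index.name = "from"
        # keep unit order, pool row (if any) last
        order = ids + [j for j in Z.index if j not in ids]
        return cls(
            layout=raw["layout"],
            units=units,
            roster=roster,
            ntp=ntp,
            skill_matrix=SkillMatrix(Z.loc[order]),
            registry=NurseRegistry(dict(raw["registry"])),
            extras=dict(raw.get("extras", {})),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "CareSystemConfiguration":
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            text = Path(source).read_text()
        else:
            text = str(source)
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# bundled reference system
# ---------------------------------------------------------------------------


def _data_file(name: str):
    return resources.files(__package__).joinpath("data").joinpath(name)


def _split_maternity_column(
    table: Mapping[str, Mapping[str, int]],
    units: Sequence[Unit],
    split_id: str = "O1",
    parts: tuple[str, str] = ("O1n", "O1a"),
    proportional: bool = True,
) -> pd.DataFrame:
    """Expand a single ``O1`` roster column into O1n/O1a.

    The reference tables publish one maternity-ward column; the two
    bed groups are separate locations here.  Headcounts are split
    proportionally to beds by largest remainder.
    """
    ids = [u.id for u in units]
    beds = {u.id: u.beds for u in units}
    out: dict[str, dict[str, int]] = {}
    for shift, row in table.items():
        row = dict(row)
        if split_id in row and not set(parts) <= set(row):
            count = int(row.pop(split_id))
            if proportional:
                alloc = largest_remainder_apportion(
                    count, [beds[p] for p in parts]
                )
            else:  # same value for both locations (used for ratios)
                alloc = [count, count]
            for p, v in zip(parts, alloc):
                row[p] = int(v)
        out[shift] = row
    return pd.DataFrame(out).T[ids]


def derive_skill_matrix(layout: str) -> SkillMatrix:
    """Qualification matrix of one of the three strategic layouts."""
    layout = canonical_layout(layout)
    return SkillMatrix.from_csv(_data_file(f"skill_matrix_{layout}.csv"))


def load_reference_system(layout: str = CURRENT) -> CareSystemConfiguration:
    """Load the bundled 70-bed reference system for a given layout.

    The roster, ratios and registry are identical across layouts; only
    the skill matrix changes.
    """
    layout = canonical_layout(layout)
    raw = yaml.safe_load(_data_file("care_system.yaml").read_text())
    units = tuple(Unit(**u) for u in raw["units"])
    roster = Roster(_split_maternity_column(raw["roster"], units))
    ntp = NtPRatio(
        _split_maternity_column(raw["ntp_ratio"], units, proportional=False)
    )
    return CareSystemConfiguration(
        layout=layout,
        units=units,
        roster=roster,
        ntp=ntp,
        skill_matrix=derive_skill_matrix(layout),
        registry=NurseRegistry(dict(raw["registry"])),
        extras=dict(raw.get("training", {})),
    )


_MODEL_ALIASES = {
    "model0": "model0",
    "model 0": "model0",
    0: "model0",
    "model1": "model1",
    "model 1": "model1",
    "model1-current": "model1",
    1: "model1",
    "model2": "model2",
    "model 2": "model2",
    2: "model2",
    "model3": "model3",
    "model 3": "model3",
    3: "model3",
}


def nurses_to_train(
    layout_or_model,
    registry: NurseRegistry | None = None,
    flex_rate: float | None = None,
    config1_obstetrics_trainees: int | None = None,
) -> int:
    """Cross-training headcount a strategy or layout change requires.

    * strategy model 0/1 on the current layout: no training — nurses
      only ever cover less specialized units they already master;
    * strategy model 2/3: the float-pool share of the registered
      headcount (``flex_rate`` of the registry total, rounded);
    * two-department layout: all N2 and N3 nurses plus the small group
      of obstetrics nurses not yet department-wide qualified;
    * one-department layout: everyone.
    """
    if registry is None:
        registry = load_reference_system().registry
    key = layout_or_model
    if isinstance(key, str):
        key = key.strip().lower()
    if key in _MODEL_ALIASES:
        model = _MODEL_ALIASES[key]
        if model in ("model0", "model1"):
            return 0
        if flex_rate is None:
            raise ValueError(f"{model} requires a flex_rate")
        if flex_rate < 0:
            raise ValueError("flex_rate must be non-negative")
        return round_half_up(flex_rate * registry.total)
    layout = canonical_layout(key)
    if layout == CURRENT:
        return 0
    if layout == CONFIG1:
        if config1_obstetrics_trainees is None:
            extras = load_reference_system().extras
            config1_obstetrics_trainees = int(
                extras.get("config1_obstetrics_trainees", 10)
            )
        return registry["N2"] + registry["N3"] + config1_obstetrics_trainees
    return registry.total  # CONFIG2
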