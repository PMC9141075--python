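"""Shift-ahead demand prediction and staffing gaps.

Step 1 of the reallocation process: from the current per-unit census
and the per-group transition matrices, compute the expected census one
shift (8 h) ahead, convert it to required nurses via the shift type's
nurse-to-patient ratio, and compare with the scheduled roster.  All
units are predicted jointly, so inter-unit patient flows are reflected
in every unit's expected demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .care_system_model import NtPRatio

__all__ = [
    "StaffingState",
    "predict_census",
    "predict_census_ahead",
    "required_nurses",
    "staffing_gap",
]


@dataclass
class StaffingState:
    """Availability vs requirement for one shift, all units jointly."""

    shift_index: int
    shift_type: str
    a: pd.Series  # available scheduled nurses per unit
    d: pd.Series  # required nurses per unit

    def __post_init__(self) -> None:
        self.a = self.a.astype(int)
        self.d = self.d.astype(int)
        if list(self.a.index) != list(self.d.index):
            raise ValueError("available and required must share the unit set")
        if (self.a < 0).any() or (self.d < 0).any():
            raise ValueError("nurse counts must be non-negative")

    @property
    def e(self) -> pd.Series:
        """Excess nurses: e = a - d (negative means short)."""
        return self.a - self.d

    def status(self, unit: str) -> str:
        e = int(self.e[unit])
        if e < 0:
            return "short"
        return "enough" if e == 0 else "surplus"


def _validated_rows(matrices, atol: float = 1e-9):
    for tm in matrices.values():
        sums = tm.P.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError(
                f"{tm.group} transition rows must sum to 1 "
                f"(got {sums.round(6).to_dict()})"
            )


def predict_census(
    matrices: Mapping,
    current_census: pd.Series,
    expected_admissions: Mapping[str, float] | pd.Series | None = None,
) -> pd.Series:
    """Expected next-shift census per unit.

    ``expected[j] = sum_i census[i] * P[i, j] + admissions[j]`` per
    patient group, summed onto the full unit set.  Real-valued; rows of
    every transition matrix must sum to 1.
    """
    _validated_rows(matrices)
    expected = pd.Series(0.0, index=current_census.index)
    for tm in matrices.values():
        units = list(tm.units)
        sub = current_census.reindex(units).fillna(0.0).astype(float)
        expected.loc[units] += sub.values @ tm.P[units].values
    if expected_admissions is not None:
        adm = pd.Series(dict(expected_admissions)).reindex(
            current_census.index
        ).fillna(0.0)
        if (adm < 0).any():
            raise ValueError("expected admissions must be non-negative")
        expected = expected + adm
    return expected


def predict_census_ahead(
    matrices: Mapping,
    current_census: pd.Series,
    expected_admissions=None,
    steps: int = 1,
) -> pd.Series:
    """Multi-shift lookahead by repeated one-step prediction.

    Provided for completeness; the planning horizon is one shift by
    default.
    """
    census = current_census.astype(float)
    for _ in range(steps):
        census = predict_census(matrices, census, expected_admissions)
    return census


def required_nurses(
    expected_census: pd.Series, ntp: NtPRatio, shift_type: str
) -> pd.Series:
    """Nurses needed to cover an (expected) census: ceil(census / ratio).

    Fractional nurses cannot be scheduled, so requirements round up;
    zero census needs zero nurses.
    """
    ratios = ntp.row(shift_type)
    census = expected_census.reindex(ratios.index)
    if census.isna().any():
        raise ValueError("census missing units present in the ratio table")
    if (census < 0).any():
        raise ValueError("census must be non-negative")
    # round at 1e-9 so exact divisions survive float noise
    d = np.ceil((census / ratios).round(9)).astype(int)
    return d


def staffing_gap(
    roster_a: pd.Series,
    d: pd.Series,
    shift_index: int = 0,
    shift_type: str = "day",
) -> StaffingState:
    """Bundle availability and requirement; the gap is ``state.e``."""
    return StaffingState(shift_index, shift_type, roster_a, d)
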