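"""Synthetic shift-indexed patient-flow generator.

Demand is modelled per patient group (newborns, adults) as a discrete-time
Markov chain over units with an absorbing exit state, stepped once per 8 h
shift, plus exogenous admissions.  Admissions are Poisson with a gamma
day-level multiplier shared by the three shifts of a day, which makes the
coefficient of variation (CV) of the per-shift total nurse demand tunable
above the pure-Poisson floor.  ``calibrate_dispersion`` searches the
multiplier dispersion that hits a target CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .care_system_model import (
    ADULT,
    NEWBORN,
    SHIFT_TYPES,
    CareSystemConfiguration,
    shift_type_of,
)

__all__ = [
    "EXIT",
    "TransitionMatrix",
    "DemandScenario",
    "DemandTrace",
    "default_transition_matrices",
    "default_arrival_rates",
    "stationary_census",
    "simulate_trace",
    "required_demand_series",
    "demand_cv",
    "calibrate_dispersion",
    "obstetrics_to_neonatology_share",
]

#: Label of the absorbing leave-the-system column.
EXIT = "exit"


@dataclass
class TransitionMatrix:
    """Per-group probability of moving unit -> unit/exit within one shift."""

    group: str
    P: pd.DataFrame  # index: from-units, columns: to-units + EXIT

    def __post_init__(self) -> None:
        self.P = self.P.astype(float)
        if EXIT not in self.P.columns:
            raise ValueError("transition matrix needs an 'exit' column")
        if (self.P.values < 0).any():
            raise ValueError("transition probabilities must be non-negative")

    @property
    def units(self) -> tuple[str, ...]:
        return tuple(c for c in self.P.columns if c != EXIT)

    def validate(self, atol: float = 1e-9) -> None:
        sums = self.P.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=atol):
            bad = sums[~np.isclose(sums, 1.0, atol=atol)]
            raise ValueError(f"rows must sum to 1: {bad.to_dict()}")

    def renormalized(self) -> "TransitionMatrix":
        """Divide every row by its sum so each row is a distribution."""
        P = self.P.div(self.P.sum(axis=1), axis=0)
        return TransitionMatrix(self.group, P)

    def internal(self) -> pd.DataFrame:
        """Within-system block (exit column dropped)."""
        return self.P[list(self.units)]

    @classmethod
    def from_csv(cls, path, group: str, renormalize: bool = False):
        P = pd.read_csv(path, index_col=0)
        tm = cls(group, P)
        return tm.renormalized() if renormalize else tm

    def to_csv(self, path) -> None:
        self.P.to_csv(path)


def _data_file(name: str):
    return resources.files("coherent_staffing").joinpath("data").joinpath(name)


def default_transition_matrices(
    renormalize: bool = True,
) -> dict[str, TransitionMatrix]:
    """Bundled per-group transition matrices.

    Only the newborn maternity-ward (O1n) row carries the case-study figures
    (4% to N1, 4% to N3, 16% exit, 77% stay; the source figures sum to
    1.01 and is renormalized on load).  All other rows are synthetic
    defaults whose stay probabilities imply geometric lengths of stay of
    a plausible order for each level of care.
    """
    with resources.as_file(_data_file("transition_newborn.csv")) as p:
        newborn = TransitionMatrix.from_csv(p, NEWBORN, renormalize)
    with resources.as_file(_data_file("transition_adult.csv")) as p:
        adult = TransitionMatrix.from_csv(p, ADULT, renormalize)
    return {NEWBORN: newborn, ADULT: adult}


def obstetrics_to_neonatology_share(
    matrices: Mapping[str, TransitionMatrix], unit: str = "O1n"
) -> float:
    """Share of departures from the newborn maternity beds that are
    transfers into Neonatology (rather than exits)."""
    row = matrices[NEWBORN].renormalized().P.loc[unit]
    departures = 1.0 - row[unit]
    to_neo = sum(v for u, v in row.items() if u.startswith("N"))
    return float(to_neo / departures)


@dataclass
class DemandScenario:
    """Parameters of one synthetic demand stream."""

    horizon_shifts: int
    arrival_rates: Mapping[str, float]  # mean admissions per shift, per unit
    dispersion: float = 0.0  # variance of the day-level gamma multiplier
    target_cv: float | None = None
    seed: int = 0
    shifts_per_day: int = 3
    initial_census: Mapping[str, int] | None = None
    enforce_capacity: bool = False

    def __post_init__(self) -> None:
        if self.horizon_shifts < 3:
            raise ValueError("horizon must cover at least 3 shifts")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.target_cv is not None and self.target_cv <= 0:
            raise ValueError("target_cv must be positive")


@dataclass
class DemandTrace:
    """Realized patient flows over a horizon of shifts.

    ``census[t]`` is the start-of-shift census of shift ``t`` for
    ``t = 0..T``; the flow arrays cover the transition from shift ``t``
    to ``t + 1`` for ``t = 0..T-1``.
    """

    units: tuple[str, ...]
    census: np.ndarray  # (T+1, n)
    admissions: np.ndarray  # (T, n) accepted admissions
    exits: np.ndarray  # (T, n)
    transfers: np.ndarray  # (T, n, n), diagonal = stays
    refusals: np.ndarray  # (T, n)

    @property
    def horizon(self) -> int:
        return self.admissions.shape[0]

    def census_series(self, t: int) -> pd.Series:
        return pd.Series(self.census[t], index=list(self.units))

    def check_conservation(self) -> None:
        """Census bookkeeping identity at every shift."""
        for t in range(self.horizon):
            inflow = self.transfers[t].sum(axis=0)  # includes stays
            expected = inflow + self.admissions[t]
            if not np.array_equal(expected, self.census[t + 1]):
                raise AssertionError(f"conservation violated at shift {t}")
            outflow = self.transfers[t].sum(axis=1) + self.exits[t]
            if not np.array_equal(outflow, self.census[t]):
                raise AssertionError(f"outflow mismatch at shift {t}")

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-shift, per-unit view; replayable via ``from_frame``."""
        rows = []
        for t in range(self.horizon):
            for i, u in enumerate(self.units):
                rows.append(
                    {
                        "shift": t,
                        "shift_type": shift_type_of(t),
                        "unit": u,
                        "census": int(self.census[t, i]),
                        "census_next": int(self.census[t + 1, i]),
                        "admissions": int(self.admissions[t, i]),
                        "exits": int(self.exits[t, i]),
                        "refusals": int(self.refusals[t, i]),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DemandTrace":
        """Rebuild a census-level trace from the tidy view.

        Per-patient transfer detail is not serialized, so the rebuilt
        trace carries zero transfer matrices; it replays identically
        through the simulator, which consumes censuses only.
        """
        units = tuple(dict.fromkeys(frame["unit"]))
        n = len(units)
        uidx = {u: i for i, u in enumerate(units)}
        T = int(frame["shift"].max()) + 1
        census = np.zeros((T + 1, n), dtype=int)
        admissions = np.zeros((T, n), dtype=int)
        exits = np.zeros((T, n), dtype=int)
        refusals = np.zeros((T, n), dtype=int)
        for _, row in frame.iterrows():
            t, i = int(row["shift"]), uidx[row["unit"]]
            census[t, i] = int(row["census"])
            census[t + 1, i] = int(row["census_next"])
            admissions[t, i] = int(row["admissions"])
            exits[t, i] = int(row["exits"])
            refusals[t, i] = int(row["refusals"])
        return cls(
            units=units,
            census=census,
            admissions=admissions,
            exits=exits,
            transfers=np.zeros((T, n, n), dtype=int),
            refusals=refusals,
        )


def stationary_census(
    matrices: Mapping[str, TransitionMatrix],
    arrival_rates: Mapping[str, float],
) -> pd.Series:
    """Expected long-run census of the Markov chain with immigration.

    Solves ``c = c Q + a`` per patient group, where ``Q`` is the
    within-system transition block and ``a`` the mean admissions.
    """
    out: dict[str, float] = {}
    for tm in matrices.values():
        units = list(tm.units)
        Q = tm.renormalized().internal().values
        a = np.array([float(arrival_rates.get(u, 0.0)) for u in units])
        c = np.linalg.solve(np.eye(len(units)) - Q.T, a)
        out.update(dict(zip(units, c)))
    return pd.Series(out)


#: Default long-run bed occupancy per unit.  The intensive-care end
#: (N1) runs hot but with a slow, predictable census; the maternity
#: ward (O1a, O1n) is the volatile, high-turnover demand stream; the
#: small specialized units keep a modest reserve that the skill-based
#: strategy can redeploy.
DEFAULT_OCCUPANCY: dict[str, float] = {
    "N1": 0.77,
    "N2": 0.65,
    "N3": 0.80,
    "O1n": 0.75,
    "O1a": 0.84,
    "O2": 0.30,
    "O3": 0.50,
}


def default_arrival_rates(
    config: CareSystemConfiguration,
    matrices: Mapping[str, TransitionMatrix] | None = None,
    occupancy: float | Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Mean admissions per shift that hold every unit at ``occupancy``.

    Inverts the stationary-census relation: ``a = c (I - Q)`` with
    ``c = occupancy * beds``.  ``occupancy`` may be a scalar or a
    per-unit mapping; the default mapping keeps specialized units at
    conservative utilization.
    """
    if matrices is None:
        matrices = default_transition_matrices()
    if occupancy is None:
        occupancy = DEFAULT_OCCUPANCY
    beds = config.beds
    rates: dict[str, float] = {}
    for tm in matrices.values():
        units = list(tm.units)
        Q = tm.renormalized().internal().values
        if isinstance(occupancy, Mapping):
            occ = np.array([float(occupancy.get(u, 0.75)) for u in units])
        else:
            occ = float(occupancy)
        c = occ * beds.loc[units].values.astype(float)
        a = c @ (np.eye(len(units)) - Q)
        if (a < -1e-9).any():
            raise ValueError(
                "occupancy target implies negative arrival rates; "
                "adjust the transition matrices or the occupancy"
            )
        rates.update({u: float(max(v, 0.0)) for u, v in zip(units, a)})
    return {u: rates[u] for u in config.unit_ids}


def simulate_trace(
    config: CareSystemConfiguration,
    scenario: DemandScenario,
    matrices: Mapping[str, TransitionMatrix] | None = None,
    rng: np.random.Generator | None = None,
) -> DemandTrace:
    """Sample one patient-flow trace.

    Per shift and unit, each patient independently follows the group's
    transition row (multinomial draw); admissions are Poisson with the
    day-level gamma multiplier.  With ``scenario.enforce_capacity``,
    admissions beyond free beds are refused (logged, never an error).
    Identical ``(config, scenario)`` give bitwise-identical traces.
    """
    if matrices is None:
        matrices = default_transition_matrices()
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    units = list(config.unit_ids)
    n = len(units)
    uidx = {u: i for i, u in enumerate(units)}
    T = scenario.horizon_shifts
    spd = scenario.shifts_per_day

    # per-unit destination distribution mapped onto global indices;
    # exit encoded as destination index n
    probs = np.zeros((n, n + 1))
    for tm in (m.renormalized() for m in matrices.values()):
        for u in tm.units:
            row = tm.P.loc[u]
            for dest, p in row.items():
                j = n if dest == EXIT else uidx[dest]
                probs[uidx[u], j] = p
    row_sums = probs.sum(axis=1)
    if not np.allclose(row_sums[row_sums > 0], 1.0):
        raise ValueError("transition rows must sum to 1")
    missing = [u for u in units if row_sums[uidx[u]] == 0]
    if missing:
        raise ValueError(f"no transition row for units {missing}")

    rates = np.array([float(scenario.arrival_rates.get(u, 0.0)) for u in units])
    beds = config.beds.values

    n_days = T // spd + 1
    if scenario.dispersion > 0:
        shape = 1.0 / scenario.dispersion
        multipliers = rng.gamma(shape, scenario.dispersion, size=n_days)
    else:
        multipliers = np.ones(n_days)

    census = np.zeros((T + 1, n), dtype=int)
    if scenario.initial_census is not None:
        census[0] = [int(scenario.initial_census.get(u, 0)) for u in units]
    else:
        c0 = stationary_census(matrices, scenario.arrival_rates)
        census[0] = np.rint(c0.reindex(units).fillna(0.0).values).astype(int)

    admissions = np.zeros((T, n), dtype=int)
    exits = np.zeros((T, n), dtype=int)
    transfers = np.zeros((T, n, n), dtype=int)
    refusals = np.zeros((T, n), dtype=int)

    for t in range(T):
        for i in range(n):
            c = census[t, i]
            if c == 0:
                continue
            draw = rng.multinomial(c, probs[i])
            transfers[t, i, :] = draw[:n]
            exits[t, i] = draw[n]
        arrived = rng.poisson(rates * multipliers[t // spd])
        after_moves = transfers[t].sum(axis=0)
        if scenario.enforce_capacity:
            free = np.maximum(beds - after_moves, 0)
            accepted = np.minimum(arrived, free)
            refusals[t] = arrived - accepted
        else:
            accepted = arrived
        admissions[t] = accepted
        census[t + 1] = after_moves + accepted

    return DemandTrace(
        units=tuple(units),
        census=census,
        admissions=admissions,
        exits=exits,
        transfers=transfers,
        refusals=refusals,
    )


def required_demand_series(
    trace: DemandTrace, config: CareSystemConfiguration
) -> np.ndarray:
    """Per-shift total required nurses implied by the realized census."""
    from .markov_prediction import required_nurses

    totals = []
    for t in range(1, trace.horizon + 1):
        d = required_nurses(
            trace.census_series(t), config.ntp, shift_type_of(t)
        )
        totals.append(int(d.sum()))
    return np.asarray(totals)


def demand_cv(trace: DemandTrace, config: CareSystemConfiguration) -> float:
    """CV of the per-shift total required-nurse series."""
    series = required_demand_series(trace, config)
    return float(series.std(ddof=1) / series.mean())


def calibrate_dispersion(
    config: CareSystemConfiguration,
    scenario_template: DemandScenario,
    target_cv: float,
    matrices: Mapping[str, TransitionMatrix] | None = None,
    n_shifts: int = 300,
    tol: float = 0.02,
    max_dispersion: float = 64.0,
) -> float:
    """Dispersion whose realized demand CV is within ``tol`` of target.

    Deterministic bisection on a fixed-seed simulation of at least 200
    shifts.  Raises if the target sits below the dispersion-zero
    (pure-Poisson) floor or above what ``max_dispersion`` can reach.
    """
    if matrices is None:
        matrices = default_transition_matrices()
    horizon = max(n_shifts, 200)

    def cv_at(dispersion: float) -> float:
        sc = replace(
            scenario_template,
            horizon_shifts=horizon,
            dispersion=dispersion,
            target_cv=None,
        )
        return demand_cv(simulate_trace(config, sc, matrices), config)

    floor = cv_at(0.0)
    if target_cv < floor - tol:
        raise ValueError(
            f"target CV {target_cv:.3f} is below the feasible floor "
            f"{floor:.3f} at these arrival rates"
        )
    if abs(floor - target_cv) <= tol:
        return 0.0

    lo, hi = 0.0, 0.5
    while cv_at(hi) < target_cv:
        lo, hi = hi, hi * 2
        if hi > max_dispersion:
            raise ValueError(
                f"target CV {target_cv:.3f} unreachable below dispersion "
                f"{max_dispersion}"
            )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        cv = cv_at(mid)
        if abs(cv - target_cv) <= tol / 2:
            return mid
        if cv < target_cv:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    return 0.5 * (lo + hi)
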