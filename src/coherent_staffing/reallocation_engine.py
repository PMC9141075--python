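"""Centralized nurse reallocation for one shift.

Step 2 of the reallocation process: given the staffing gaps of all
units and a qualification matrix, decide simultaneously which surplus
nurses move where.  Four strategies are supported:

* model 0 — no flexibility: nothing moves;
* model 1 — skill-based pairwise reallocation: surplus nurses cover
  shortages wherever the skill matrix permits;
* model 2 — centralized float pool: universally qualified pool nurses
  are deployed to the largest shortages;
* model 3 — float pool first, then skill-based reallocation of what
  remains.

The pairwise rule realizes, one nurse batch at a time, the pairing
``move = min(shortage, surplus)`` wherever the skill matrix permits,
updating residuals after every move so no donor is over-committed.
Receivers are served in decreasing shortage; among qualified donors the
least flexible (fewest other open shortages they could serve) gives
first, which keeps flexible donors available and makes the greedy match
the exhaustive optimum on small systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .care_system_model import (
    CONFIG1,
    CONFIG2,
    CURRENT,
    SHIFT_TYPES,
    CareSystemConfiguration,
    Roster,
    SkillMatrix,
    largest_remainder_apportion,
    round_half_up,
)
from .markov_prediction import StaffingState

__all__ = [
    "ReallocationPlan",
    "FloatPool",
    "FlexRate",
    "pairwise_reallocate",
    "optimal_coverage_residual",
    "flex_rate",
    "build_float_pool",
    "deploy_float",
    "run_model",
    "inherent_pooling_matrix",
    "MODEL_IDS",
]

MODEL_IDS = (0, 1, 2, 3)


@dataclass
class ReallocationPlan:
    """Outcome of one shift's centralized reallocation decision."""

    units: tuple[str, ...]
    moves: dict[tuple[str, str], int] = field(default_factory=dict)
    float_deployed: pd.Series | None = None
    residual_e: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = list(self.units)
        if self.float_deployed is None:
            self.float_deployed = pd.Series(0, index=idx)
        if self.residual_e is None:
            self.residual_e = pd.Series(0, index=idx)
        self.float_deployed = self.float_deployed.astype(int)
        self.residual_e = self.residual_e.astype(int)

    @property
    def total_moved(self) -> int:
        """M: total unit-to-unit reallocated nurses this shift."""
        return int(sum(self.moves.values()))

    def net_delta(self) -> pd.Series:
        """Per-unit nurse change: incoming - outgoing + float."""
        delta = pd.Series(0, index=list(self.units))
        for (j, i), q in self.moves.items():
            delta[j] -= q
            delta[i] += q
        return delta + self.float_deployed

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"from": j, "to": i, "count": q}
            for (j, i), q in sorted(self.moves.items())
        ]
        for u, q in self.float_deployed.items():
            if q:
                rows.append({"from": "pool", "to": u, "count": int(q)})
        return pd.DataFrame(rows, columns=["from", "to", "count"])


def pairwise_reallocate(state: StaffingState, Z: SkillMatrix) -> ReallocationPlan:
    """Skill-constrained pairwise reallocation (strategy model 1)."""
    units = list(state.e.index)
    n = len(units)
    zm = Z.unit_matrix().Z.reindex(index=units, columns=units).fillna(0)
    z = zm.values.astype(int)
    e = state.e.to_numpy(dtype=int, copy=True)
    moves: dict[tuple[str, str], int] = {}
    blocked: set[int] = set()

    while True:
        receivers = [
            i for i in range(n) if e[i] < 0 and i not in blocked
        ]
        if not receivers:
            break
        i = min(receivers, key=lambda i: (e[i], i))
        donors = [j for j in range(n) if j != i and e[j] > 0 and z[j, i]]
        if not donors:
            blocked.add(i)
            continue
        # least flexible qualified donor first: fewest other open
        # shortages it could serve, then largest surplus, then order
        open_short = (e < 0).astype(int)
        j = min(
            donors,
            key=lambda j: (
                int(z[j] @ open_short) - int(z[j, i]),
                -e[j],
                j,
            ),
        )
        q = int(min(-e[i], e[j]))
        key = (units[j], units[i])
        moves[key] = moves.get(key, 0) + q
        e[i] += q
        e[j] -= q

    return ReallocationPlan(
        units=tuple(units),
        moves=moves,
        residual_e=pd.Series(e, index=units),
    )


def optimal_coverage_residual(e: pd.Series, Z: SkillMatrix) -> pd.Series:
    """Residual gaps after a maximum-coverage reallocation.

    Solves the donor -> receiver transportation problem exactly
    (Edmonds-Karp max-flow), so the total shortage left is the minimum
    any feasible move set can achieve under the qualification matrix.
    Used for the real-time netting inside pooled layouts, where nurses
    are assigned to units when demand realizes and no greedy planning
    rule applies.
    """
    units = list(e.index)
    n = len(units)
    zm = Z.unit_matrix().Z.reindex(index=units, columns=units).fillna(0)
    z = zm.values.astype(int)
    ev = e.to_numpy(dtype=int, copy=True)
    donors = [j for j in range(n) if ev[j] > 0]
    receivers = [i for i in range(n) if ev[i] < 0]
    if not donors or not receivers:
        return pd.Series(ev, index=units)

    # node ids: 0 = source, 1..n = units, n + 1 = sink
    size = n + 2
    cap = np.zeros((size, size), dtype=int)
    for j in donors:
        cap[0, j + 1] = ev[j]
    for i in receivers:
        cap[i + 1, n + 1] = -ev[i]
    big = int(ev[ev > 0].sum())
    for j in donors:
        for i in receivers:
            if i != j and z[j, i]:
                cap[j + 1, i + 1] = big

    flow = np.zeros_like(cap)
    while True:  # BFS augmenting path
        parent = np.full(size, -1)
        parent[0] = 0
        queue = [0]
        while queue and parent[size - 1] == -1:
            u = queue.pop(0)
            for v in range(size):
                if parent[v] == -1 and cap[u, v] - flow[u, v] > 0:
                    parent[v] = u
                    queue.append(v)
        if parent[size - 1] == -1:
            break
        path = [size - 1]
        while path[-1] != 0:
            path.append(parent[path[-1]])
        path.reverse()
        bottleneck = min(
            cap[a, b] - flow[a, b] for a, b in zip(path, path[1:])
        )
        for a, b in zip(path, path[1:]):
            flow[a, b] += bottleneck
            flow[b, a] -= bottleneck

    residual = ev.copy()
    for j in donors:
        residual[j] -= flow[0, j + 1]
    for i in receivers:
        residual[i] += flow[i + 1, n + 1]
    return pd.Series(residual, index=units)


@dataclass(frozen=True)
class FlexRate:
    """Share of scheduled nurses reallocated over a shift set."""

    fraction: float

    @property
    def percent(self) -> int:
        """Nearest whole percent, for reporting."""
        return round_half_up(100.0 * self.fraction)


def flex_rate(moved, scheduled) -> FlexRate:
    """r = sum(M_n) / sum of scheduled nurses over the same shifts."""
    M = float(np.sum(moved))
    A = float(np.sum(scheduled))
    if A <= 0:
        raise ValueError("no scheduled nurses; flex rate undefined")
    if M < 0:
        raise ValueError("moved counts must be non-negative")
    return FlexRate(M / A)


@dataclass
class FloatPool:
    """Centrally held, universally qualified nurses per shift type."""

    rate: float
    size: dict[str, int]  # shift type -> pool nurses
    withdrawn: pd.DataFrame  # per shift type and unit

    def size_for(self, shift_type: str) -> int:
        return int(self.size[shift_type])


def build_float_pool(
    roster: Roster, r: float
) -> tuple[FloatPool, Roster]:
    """Carve a float pool of share ``r`` out of a roster.

    Per shift type the pool holds ``round(total * r)`` nurses; the
    per-unit withdrawals follow largest-remainder apportionment on the
    scheduled headcounts so the reduced roster and the pool conserve
    the total exactly.
    """
    if not 0 <= r < 1:
        raise ValueError("flex rate must satisfy 0 <= r < 1")
    sizes: dict[str, int] = {}
    withdrawn_rows: dict[str, pd.Series] = {}
    reduced = roster.scheduled.copy()
    for shift_type in SHIFT_TYPES:
        a = roster.row(shift_type)
        f = round_half_up(float(a.sum()) * r)
        if f > int(a.sum()):
            raise ValueError("pool larger than the scheduled roster")
        w = largest_remainder_apportion(f, a.values, caps=a.values)
        sizes[shift_type] = f
        withdrawn_rows[shift_type] = pd.Series(w, index=a.index)
        reduced.loc[shift_type] = a.values - w
    if (reduced.values < 0).any():
        raise ValueError("flex rate drives a unit's availability negative")
    withdrawn = pd.DataFrame(withdrawn_rows).T.loc[list(SHIFT_TYPES)]
    return FloatPool(rate=r, size=sizes, withdrawn=withdrawn), Roster(reduced)


def deploy_float(
    e: pd.Series, pool_size: int, home: pd.Series | None = None
) -> pd.Series:
    """Send pool nurses to shortages, largest shortage first.

    One nurse at a time to the currently deepest shortage (ties by unit
    order).  Nurses left over once every shortage is covered return to
    the units they were withdrawn from (``home``, largest withdrawal
    first); without a home profile they stay in the pool.
    """
    units = list(e.index)
    residual = e.copy().astype(int)
    deployed = pd.Series(0, index=units)
    left = int(pool_size)
    while left > 0:
        shortages = sorted(
            (i for i in units if residual[i] < 0),
            key=lambda i: (residual[i], units.index(i)),
        )
        if not shortages:
            break
        i = shortages[0]
        deployed[i] += 1
        residual[i] += 1
        left -= 1
    if left > 0 and home is not None:
        returned = pd.Series(0, index=units)
        slots = home.reindex(units).fillna(0).astype(int)
        while left > 0:
            open_units = [u for u in units if returned[u] < slots[u]]
            if not open_units:
                break
            u = max(
                open_units,
                key=lambda x: (slots[x] - returned[x], -units.index(x)),
            )
            returned[u] += 1
            deployed[u] += 1
            left -= 1
    return deployed


def inherent_pooling_matrix(config: CareSystemConfiguration) -> SkillMatrix:
    """Qualification implied by the layout alone, before any strategy.

    In the current layout the six units are independent (identity); in
    the pooled layouts the configuration's skill matrix itself encodes
    the department- or system-wide pooling.
    """
    if config.layout == CURRENT:
        ids = list(config.unit_ids)
        Z = pd.DataFrame(
            np.eye(len(ids), dtype=int), index=ids, columns=ids
        )
        Z.index.name = "from"
        return SkillMatrix(Z)
    return config.skill_matrix.unit_matrix()


def run_model(
    model_id: int,
    state: StaffingState,
    config: CareSystemConfiguration,
    float_pool: FloatPool | None = None,
    shift_type: str | None = None,
) -> ReallocationPlan:
    """Apply one flexibility strategy to one shift's staffing state.

    For models 2 and 3 the caller must pass the pool and build the
    state's availability from the pool-reduced roster.  The layout's
    inherent pooling applies under every model; strategy models 1 and 3
    additionally enable the skill-based matrix.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    if model_id in (2, 3) and float_pool is None:
        raise ValueError(f"model {model_id} requires a float pool")
    units = tuple(state.e.index)
    z_inherent = inherent_pooling_matrix(config)
    z_strategy = config.skill_matrix.unit_matrix()

    deployed = pd.Series(0, index=list(units))
    e = state.e.copy()
    if model_id in (2, 3) and float_pool is not None:
        stype = shift_type or state.shift_type
        home = float_pool.withdrawn.loc[stype]
        deployed = deploy_float(e, float_pool.size_for(stype), home=home)
        e = e + deployed

    Z = z_strategy if model_id in (1, 3) else z_inherent
    inner = pairwise_reallocate(
        StaffingState(
            state.shift_index,
            state.shift_type,
            state.a + deployed,
            state.d,
        ),
        Z,
    )
    return ReallocationPlan(
        units=units,
        moves=inner.moves,
        float_deployed=deployed,
        residual_e=inner.residual_e,
    )
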