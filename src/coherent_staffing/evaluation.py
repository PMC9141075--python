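"""Decision layer: turning scenario results into staffing decisions.

Practical rounding of gap averages, best-strategy selection, decision
regret across demand conditions, training costs, and the sizing of
flexible nurses and flexible beds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .care_system_model import (
    CareSystemConfiguration,
    Roster,
    SHIFT_TYPES,
    largest_remainder_apportion,
    round_half_up,
)

__all__ = [
    "DecisionSummary",
    "round_staffing",
    "select_best_strategy",
    "decision_regret",
    "training_cost",
    "load_reference_flex_distribution",
    "minimum_sufficient_flex_rate",
    "size_flexible_nurses",
    "size_flexible_beds",
    "summarize_decisions",
    "TRAINING_COST_PER_NURSE_EUR",
]

TRAINING_COST_PER_NURSE_EUR = 20_000


def round_staffing(x: float) -> int:
    """Round a gap average to the nearest whole nurse, halves away from 0.

    An average shortfall under half a shift can be absorbed informally,
    so it rounds to zero; beyond that a full extra shift is requested.
    """
    return round_half_up(float(x))


@dataclass
class DecisionSummary:
    """Best-strategy sets, regret and the cost-aware optimum."""

    table: pd.DataFrame
    best_understaffing: tuple[str, ...]
    best_overstaffing: tuple[str, ...]
    regret: dict[str, dict[str, float]] = field(default_factory=dict)
    optimal: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "best_understaffing": list(self.best_understaffing),
            "best_overstaffing": list(self.best_overstaffing),
            "regret": self.regret,
            "optimal": list(self.optimal),
        }


def select_best_strategy(
    results: Mapping[str, tuple[float, float]], tol: float = 1e-9
) -> DecisionSummary:
    """Best responses by average gaps.

    ``results`` maps response id -> (U, O) with U <= 0 <= O.  The best
    understaffing set maximizes U (closest to zero); the best
    overstaffing set minimizes O.  Ties return sets.
    """
    if len(results) < 1:
        raise ValueError("need at least one response")
    u = {r: float(v[0]) for r, v in results.items()}
    o = {r: float(v[1]) for r, v in results.items()}
    best_u = max(u.values())
    best_o = min(o.values())
    b_u = tuple(r for r in results if u[r] >= best_u - tol)
    b_o = tuple(r for r in results if o[r] <= best_o + tol)
    table = pd.DataFrame(
        {
            "response": list(results),
            "U": [u[r] for r in results],
            "O": [o[r] for r in results],
            "U_rounded": [round_staffing(u[r]) for r in results],
            "O_rounded": [round_staffing(o[r]) for r in results],
        }
    )
    return DecisionSummary(
        table=table, best_understaffing=b_u, best_overstaffing=b_o
    )


def decision_regret(
    results_by_condition: Mapping[str, Mapping[str, float]],
    chosen: str,
) -> dict[str, float]:
    """Understaffing regret of a chosen response per demand condition.

    ``regret = U_best - U_chosen`` (both negative scales); zero means
    the chosen response is best under that condition too.
    """
    out: dict[str, float] = {}
    for condition, u_values in results_by_condition.items():
        if chosen not in u_values:
            raise ValueError(
                f"response {chosen!r} not evaluated under {condition!r}"
            )
        out[condition] = float(max(u_values.values()) - u_values[chosen])
    return out


def training_cost(
    nurse_count: int, unit_cost: float = TRAINING_COST_PER_NURSE_EUR
) -> float:
    """Cost of cross-training a number of nurses (EUR)."""
    if nurse_count < 0:
        raise ValueError("nurse count must be non-negative")
    return float(nurse_count) * float(unit_cost)


def load_reference_flex_distribution() -> pd.DataFrame:
    """Bundled empirical flexibility-rate distribution (365 cases)."""
    path = resources.files("coherent_staffing").joinpath(
        "data/flex_rate_distribution.csv"
    )
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def minimum_sufficient_flex_rate(
    distribution: pd.DataFrame, coverage: float = 0.95
) -> int:
    """Smallest tabulated rate whose cumulative share reaches coverage.

    ``distribution`` needs columns ``rate_pct`` and ``frequency``.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    dist = distribution.sort_values("rate_pct")
    total = dist["frequency"].sum()
    if total <= 0:
        raise ValueError("empty distribution")
    cumulative = dist["frequency"].cumsum() / total
    hit = dist.loc[cumulative >= coverage, "rate_pct"]
    if hit.empty:
        raise ValueError("coverage never reached")
    return int(hit.iloc[0])


def size_flexible_nurses(roster: Roster, rate: float) -> dict[str, int]:
    """Flexible nurses per shift type: round(rate * scheduled total)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return {
        s: round_half_up(rate * roster.total(s)) for s in SHIFT_TYPES
    }


def _display_beds(config: CareSystemConfiguration) -> pd.Series:
    """Bed counts with the two maternity-ward locations merged back."""
    beds: dict[str, int] = {}
    for u in config.units:
        key = "O1" if u.id in ("O1n", "O1a") else u.id
        beds[key] = beds.get(key, 0) + u.beds
    return pd.Series(beds)


def _display_ratio(config: CareSystemConfiguration, shift_type: str) -> pd.Series:
    row = config.ntp.row(shift_type)
    out: dict[str, int] = {}
    for u, v in row.items():
        key = "O1" if u in ("O1n", "O1a") else u
        out[key] = int(v)  # both maternity locations share the ratio
    return pd.Series(out)


def size_flexible_beds(
    config: CareSystemConfiguration,
    flexible_nurses: Mapping[str, int],
    allocation_override: Mapping[str, Mapping[str, int]] | None = None,
) -> pd.DataFrame:
    """Flexible beds per shift type and unit.

    Each shift type's flexible nurses are apportioned across units by
    largest remainder on bed shares (wards holding more of the system's
    beds contribute more flexible staff), then converted to beds via
    that shift's nurse-to-patient ratio.  ``allocation_override`` maps a
    shift type to an explicit unit -> nurses allocation, replacing the
    apportionment for that shift type.
    """
    beds = _display_beds(config)
    rows = []
    for shift_type in SHIFT_TYPES:
        f = int(flexible_nurses.get(shift_type, 0))
        if allocation_override and shift_type in allocation_override:
            alloc = pd.Series(
                dict(allocation_override[shift_type]), dtype=int
            ).reindex(beds.index, fill_value=0)
            if int(alloc.sum()) != f:
                raise ValueError(
                    f"override for {shift_type} must place exactly {f} nurses"
                )
        else:
            alloc = pd.Series(
                largest_remainder_apportion(f, beds.values), index=beds.index
            )
        ratio = _display_ratio(config, shift_type)
        for unit in beds.index:
            nurses = int(alloc[unit])
            if nurses == 0:
                continue
            rows.append(
                {
                    "shift_type": shift_type,
                    "unit": unit,
                    "flexible_nurses": nurses,
                    "flexible_beds": nurses * int(ratio[unit]),
                }
            )
    return pd.DataFrame(
        rows, columns=["shift_type", "unit", "flexible_nurses", "flexible_beds"]
    )


def summarize_decisions(
    results_by_condition: Mapping[str, Mapping[str, tuple[float, float]]],
    costs: Mapping[str, float],
    primary_condition: str | None = None,
) -> DecisionSummary:
    """Lexicographic decision: performance first, then cost, then regret.

    The best set is formed on rounded average gaps (understaffing, then
    overstaffing) under the primary demand condition; within it, the
    cheapest responses are optimal.  Regret of every best response is
    reported across all conditions as a robustness check.
    """
    conditions = list(results_by_condition)
    if primary_condition is None:
        primary_condition = conditions[0]
    primary = results_by_condition[primary_condition]

    rounded = {
        r: (round_staffing(uo[0]), round_staffing(uo[1]))
        for r, uo in primary.items()
    }
    best_u = max(v[0] for v in rounded.values())
    tier = [r for r, v in rounded.items() if v[0] == best_u]
    best_o = min(rounded[r][1] for r in tier)
    best = tuple(r for r in tier if rounded[r][1] == best_o)

    min_cost = min(costs[r] for r in best)
    optimal = tuple(r for r in best if costs[r] <= min_cost)

    regret = {
        r: decision_regret(
            {
                c: {rr: uo[0] for rr, uo in results_by_condition[c].items()}
                for c in conditions
                if r in results_by_condition[c]
            },
            r,
        )
        for r in best
    }

    table = pd.DataFrame(
        [
            {
                "condition": c,
                "response": r,
                "U": uo[0],
                "O": uo[1],
                "U_rounded": round_staffing(uo[0]),
                "O_rounded": round_staffing(uo[1]),
                "training_cost_eur": float(costs.get(r, float("nan"))),
            }
            for c in conditions
            for r, uo in results_by_condition[c].items()
        ]
    )
    summary = select_best_strategy(primary)
    return DecisionSummary(
        table=table,
        best_understaffing=summary.best_understaffing,
        best_overstaffing=summary.best_overstaffing,
        regret=regret,
        optimal=optimal,
    )
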