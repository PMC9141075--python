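"""What-if experiments over a horizon of shifts.

Each scenario (response R0-R8 plus the enlarged-pool variants) drives a
synthetic demand trace through the predict -> reallocate pipeline one
shift at a time: the planner predicts next-shift demand from the
current census using expected transitions, the strategy reallocates
against that prediction, and the realized (sampled) demand then scores
the residual under-/overstaffing.  Prediction error is therefore
endogenous.

In the pooled layouts, nurses scheduled to a pooled department are
assigned to its units when demand realizes — pooling is part of the
strategic configuration, not a per-shift decision — so realized gaps
are netted within each pooled block before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .care_system_model import (
    CONFIG1,
    CONFIG2,
    CURRENT,
    CareSystemConfiguration,
    load_reference_system,
    round_half_up,
    shift_type_of,
)
from .markov_prediction import (
    StaffingState,
    predict_census,
    required_nurses,
)
from .reallocation_engine import (
    build_float_pool,
    inherent_pooling_matrix,
    optimal_coverage_residual,
    run_model,
)
from .synthetic_demand import (
    DemandScenario,
    DemandTrace,
    default_transition_matrices,
    simulate_trace,
)

__all__ = [
    "RESPONSES",
    "ScenarioSpec",
    "ScenarioResult",
    "run_scenario",
    "flexibility_rate_series",
]

#: response id -> (layout, strategy model, float-pool rate)
RESPONSES: dict[str, tuple[str, int, float]] = {
    "R0": (CURRENT, 0, 0.0),
    "R1": (CURRENT, 1, 0.0),
    "R2": (CURRENT, 2, 0.07),
    "R2_20": (CURRENT, 2, 0.20),
    "R2_40": (CURRENT, 2, 0.40),
    "R3": (CURRENT, 3, 0.07),
    "R4": (CONFIG1, 0, 0.0),
    "R5": (CONFIG1, 1, 0.0),
    "R6": (CONFIG1, 2, 0.07),
    "R7": (CONFIG1, 3, 0.07),
    "R8": (CONFIG2, 0, 0.0),
}


@dataclass
class ScenarioSpec:
    """One (response, demand condition) experiment."""

    response_id: str
    layout: str
    model_id: int
    float_rate: float
    demand: DemandScenario
    replications: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.seed is None:
            self.seed = self.demand.seed

    @classmethod
    def for_response(
        cls,
        response_id: str,
        demand: DemandScenario,
        replications: int = 1,
        seed: int | None = None,
    ) -> "ScenarioSpec":
        try:
            layout, model_id, rate = RESPONSES[response_id]
        except KeyError:
            raise ValueError(f"unknown response id {response_id!r}") from None
        return cls(
            response_id=response_id,
            layout=layout,
            model_id=model_id,
            float_rate=rate,
            demand=demand,
            replications=replications,
            seed=seed,
        )


@dataclass
class ScenarioResult:
    """Per-shift gap series and summary staffing statistics."""

    response_id: str
    spec: ScenarioSpec
    under: np.ndarray  # (reps, T) sum of negative residuals, <= 0
    over: np.ndarray  # (reps, T) sum of positive residuals, >= 0
    moved: np.ndarray  # (reps, T) unit-to-unit reallocations M_n
    scheduled: np.ndarray  # (T,) scheduled nurses per evaluated shift

    @property
    def horizon(self) -> int:
        return self.under.shape[1]

    @property
    def U(self) -> float:
        """Mean understaffed nurses per shift (negative sign kept)."""
        return float(self.under.mean())

    @property
    def O(self) -> float:
        """Mean overstaffed nurses per shift."""
        return float(self.over.mean())

    @property
    def sd_U(self) -> float:
        return float(self.under.std(ddof=1))

    @property
    def sd_O(self) -> float:
        return float(self.over.std(ddof=1))

    @property
    def rep_under_means(self) -> np.ndarray:
        return self.under.mean(axis=1)

    def per_shift_under(self, rep: int = 0) -> np.ndarray:
        return self.under[rep]

    def summary(self) -> dict:
        return {
            "response": self.response_id,
            "U": self.U,
            "sd_U": self.sd_U,
            "O": self.O,
            "sd_O": self.sd_O,
        }


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(rep)]))


def run_scenario(
    spec: ScenarioSpec,
    config_library: Mapping[str, CareSystemConfiguration] | None = None,
    matrices=None,
    traces: Sequence[DemandTrace] | None = None,
) -> ScenarioResult:
    """Run one response over the scenario's horizon and replications.

    ``traces`` allows injecting pre-generated demand traces (one per
    replication) so several responses can be compared on a common
    realized demand stream; otherwise traces are sampled from the
    spec's seed, one deterministic substream per replication.
    """
    if config_library is None:
        config_library = {spec.layout: load_reference_system(spec.layout)}
    config = config_library[spec.layout]
    if matrices is None:
        matrices = default_transition_matrices()
    demand = spec.demand
    T = demand.horizon_shifts
    if T < 3:
        raise ValueError("horizon must cover at least 3 shifts")
    if traces is not None and len(traces) < spec.replications:
        raise ValueError("need one injected trace per replication")

    use_pool = spec.model_id in (2, 3) and spec.float_rate > 0
    if use_pool:
        pool, planning_roster = build_float_pool(config.roster, spec.float_rate)
    else:
        pool, planning_roster = None, config.roster
    rates = {
        u: float(demand.arrival_rates.get(u, 0.0)) for u in config.unit_ids
    }
    z_inherent = inherent_pooling_matrix(config)
    pooled_layout = config.layout != CURRENT

    under = np.zeros((spec.replications, T))
    over = np.zeros((spec.replications, T))
    moved = np.zeros((spec.replications, T), dtype=int)
    scheduled = np.array(
        [config.roster.total(shift_type_of(t + 1)) for t in range(T)]
    )

    for rep in range(spec.replications):
        if traces is not None:
            trace = traces[rep]
        else:
            trace = simulate_trace(
                config, demand, matrices, rng=_rep_rng(spec.seed, rep)
            )
        if trace.horizon < T:
            raise ValueError("injected trace shorter than the horizon")
        for t in range(T):
            next_type = shift_type_of(t + 1)
            predicted = predict_census(
                matrices, trace.census_series(t), rates
            )
            d_pred = required_nurses(predicted, config.ntp, next_type)
            a = planning_roster.row(next_type)
            plan = run_model(
                spec.model_id,
                StaffingState(t + 1, next_type, a, d_pred),
                config,
                float_pool=pool,
                shift_type=next_type,
            )
            d_act = required_nurses(
                trace.census_series(t + 1), config.ntp, next_type
            )
            a_after = a + plan.net_delta()
            e = (a_after - d_act).astype(int)
            if pooled_layout:
                # real-time assignment within pooled blocks
                e = optimal_coverage_residual(e, z_inherent)
            under[rep, t] = float(e[e < 0].sum())
            over[rep, t] = float(e[e > 0].sum())
            moved[rep, t] = plan.total_moved

    return ScenarioResult(
        response_id=spec.response_id,
        spec=spec,
        under=under,
        over=over,
        moved=moved,
        scheduled=scheduled,
    )


def flexibility_rate_series(
    result: ScenarioResult, per: str = "shift"
) -> pd.DataFrame:
    """Empirical distribution of required flexibility rates.

    ``per='shift'``: one observation per shift, 100 * (nurses
    reallocated in the shift) / (nurses scheduled in the shift).
    ``per='day'``: flows and schedules are summed over each day's three
    shifts first.  Returns rate (rounded percent), frequency and the
    cumulative share, sorted by rate.
    """
    if per not in ("shift", "day"):
        raise ValueError("per must be 'shift' or 'day'")
    rates: list[int] = []
    spd = result.spec.demand.shifts_per_day
    for rep in range(result.moved.shape[0]):
        m = result.moved[rep].astype(float)
        s = result.scheduled.astype(float)
        if per == "day":
            n_days = len(m) // spd
            m = m[: n_days * spd].reshape(n_days, spd).sum(axis=1)
            s = s[: n_days * spd].reshape(n_days, spd).sum(axis=1)
        rates.extend(round_half_up(100.0 * mi / si) for mi, si in zip(m, s))
    counts = pd.Series(rates).value_counts().sort_index()
    table = pd.DataFrame(
        {"rate_pct": counts.index.astype(int), "frequency": counts.values}
    )
    table["cumulative_pct"] = (
        100.0 * table["frequency"].cumsum() / table["frequency"].sum()
    )
    return table.reset_index(drop=True)
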