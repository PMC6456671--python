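"""Constraint-landscape sweeps over (T_TR, T_IN) grids.

For each transport cap the intracellular caps are visited in decreasing
order so that the binary pattern of the previous (looser) cell seeds the
next solve, exploiting the observation that neighboring instances share
most of their active reactions.  Feasibility is monotone in both caps
(raising a cap only relaxes the problem), which both structures the
feasible-region frontier and lets the minimum-cap searches bisect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import build_community
from .model_io import MetabolicModel, classify_reactions
from .optimizer import (
    DolmnProblem,
    DolmnSolution,
    solve_stage1,
    solve_stage2,
    warm_start_from,
)

__all__ = ["LandscapeResult", "sweep", "min_feasible_T_IN", "min_feasible_T_TR"]


@dataclass
class CellResult:
    """One (K, T_TR, T_IN) grid cell; mirrors the per-strain output record
    (sparse_con = T_IN, biomass, flux, int)."""

    K: int
    T_TR: int
    T_IN: int
    status: str
    biomass_per_strain: np.ndarray | None
    stage1: DolmnSolution
    stage2: DolmnSolution | None

    @property
    def sparse_con(self) -> int:
        return self.T_IN

    @property
    def feasible(self) -> bool:
        return self.stage1.feasible

    @property
    def solution(self) -> DolmnSolution:
        """The stage-2 solution when available, else stage 1."""
        return self.stage2 if self.stage2 is not None else self.stage1


@dataclass
class LandscapeResult:
    """All cells of one sweep plus the community column index."""

    K: int
    reaction_ids: list[str]  # community column -> source reaction id
    cells: list[CellResult] = field(default_factory=list)
    community: object = None  # CommunityModel used for every cell

    def cell(self, T_TR: int, T_IN: int) -> CellResult | None:
        for c in self.cells:
            if c.T_TR == T_TR and c.T_IN == T_IN:
                return c
        return None

    def feasible_cells(self) -> list[CellResult]:
        return [c for c in self.cells if c.feasible]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "K": c.K,
                    "T_TR": c.T_TR,
                    "T_IN": c.T_IN,
                    "status": c.status,
                    "biomass": (
                        float(c.solution.biomass_per_strain[0])
                        if c.feasible
                        else np.nan
                    ),
                    "gap": c.stage1.mip_gap if c.feasible else np.nan,
                }
            )
        return pd.DataFrame(rows)


def sweep(
    model: MetabolicModel,
    K: int,
    t_tr_values: list[int],
    t_in_values: list[int],
    mu_min: float = 0.1,
    run_stage2: bool = True,
    mip_gap: float = 1e-6,
    time_limit: float | None = None,
    use_warm_starts: bool = True,
) -> LandscapeResult:
    """Solve every cell of the (T_TR, T_IN) grid for K strains.

    Within each T_TR column, cells are visited in decreasing T_IN, feeding
    each solution forward as a warm-start hint.  Infeasible cells are
    recorded, not raised.  A frontier-monotonicity check warns if a cell is
    infeasible while a dominated cell (both caps <=) was feasible, which
    indicates solver time-limit artifacts.
    """
    if not t_tr_values or not t_in_values:
        raise ValueError("grids must be nonempty")
    if min(t_tr_values) < 0 or min(t_in_values) < 0:
        raise ValueError("cap values must be nonnegative")
    classification = classify_reactions(model)
    comm = build_community(model, classification, K)
    result = LandscapeResult(
        K=K,
        reaction_ids=[ci.reaction_id for ci in comm.column_layout],
        community=comm,
    )
    for t_tr in sorted(set(t_tr_values), reverse=True):
        prev: DolmnSolution | None = None
        for t_in in sorted(set(t_in_values), reverse=True):
            prob = DolmnProblem(
                community=comm,
                T_TR=t_tr,
                T_IN=t_in,
                mu_min=mu_min,
                mip_gap=mip_gap,
                time_limit=time_limit,
            )
            if use_warm_starts and prev is not None and prev.feasible:
                prob = warm_start_from(prev, prob)
            s1 = solve_stage1(prob)
            s2 = None
            if s1.feasible and run_stage2:
                s2 = solve_stage2(prob, s1)
            result.cells.append(
                CellResult(
                    K=K,
                    T_TR=t_tr,
                    T_IN=t_in,
                    status=s1.status,
                    biomass_per_strain=s1.biomass_per_strain,
                    stage1=s1,
                    stage2=s2,
                )
            )
            if s1.feasible:
                prev = s1
    _check_frontier_monotonicity(result)
    return result


def _check_frontier_monotonicity(result: LandscapeResult) -> None:
    feas = {(c.T_TR, c.T_IN) for c in result.cells if c.feasible}
    for c in result.cells:
        if c.feasible:
            continue
        dominated = [
            p for p in feas if p[0] <= c.T_TR and p[1] <= c.T_IN
        ]
        if dominated:
            warnings.warn(
                f"frontier monotonicity violated at (T_TR={c.T_TR}, "
                f"T_IN={c.T_IN}): infeasible although {dominated[0]} was "
                "feasible; likely a solver gap/time-limit artifact",
                RuntimeWarning,
            )


def _bisect_min_cap(lo: int, hi: int, feasible_at) -> int | None:
    """Smallest value in [lo, hi] at which ``feasible_at`` holds, exploiting
    monotone feasibility; None if not even ``hi`` is feasible."""
    if not feasible_at(hi):
        return None
    while lo < hi:
        mid = (lo + hi) // 2
        if feasible_at(mid):
            hi = mid
        else:
            lo = mid + 1
    return hi


def min_feasible_T_IN(
    model: MetabolicModel,
    K: int,
    T_TR: int | None = None,
    mu_min: float = 0.1,
    mip_gap: float = 1e-6,
    time_limit: float | None = None,
) -> int | None:
    """Smallest T_IN with a feasible stage-1 solve at the given T_TR
    (``None`` = transports unconstrained).  Returns None if no T_IN up to
    the full intracellular count is feasible."""
    classification = classify_reactions(model)
    comm = build_community(model, classification, K)
    n_i = len(comm.IN_k[1])
    t_tr = T_TR if T_TR is not None else len(comm.TR_k[1])
    cache: dict[int, bool] = {}

    def feasible_at(t_in: int) -> bool:
        if t_in not in cache:
            prob = DolmnProblem(
                community=comm, T_TR=t_tr, T_IN=t_in, mu_min=mu_min,
                mip_gap=mip_gap, time_limit=time_limit,
            )
            cache[t_in] = solve_stage1(prob).feasible
        return cache[t_in]

    return _bisect_min_cap(0, n_i, feasible_at)


def min_feasible_T_TR(
    model: MetabolicModel,
    K: int,
    T_IN: int | None = None,
    mu_min: float = 0.1,
    mip_gap: float = 1e-6,
    time_limit: float | None = None,
) -> int | None:
    """Smallest T_TR with a feasible stage-1 solve at the given T_IN."""
    classification = classify_reactions(model)
    comm = build_community(model, classification, K)
    n_t = len(comm.TR_k[1])
    t_in = T_IN if T_IN is not None else len(comm.IN_k[1])
    cache: dict[int, bool] = {}

    def feasible_at(t_tr: int) -> bool:
        if t_tr not in cache:
            prob = DolmnProblem(
                community=comm, T_TR=t_tr, T_IN=t_in, mu_min=mu_min,
                mip_gap=mip_gap, time_limit=time_limit,
            )
            cache[t_tr] = solve_stage1(prob).feasible
        return cache[t_tr]

    return _bisect_min_cap(0, n_t, feasible_at)
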