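"""Two-stage optimization for metabolic division of labor.

Stage 1 is a cardinality-constrained MILP: maximize community biomass over
fluxes ``x`` and binary reaction indicators ``t`` subject to steady state
``S_c x = 0``, flux bounds, indicator coupling ``diag(x_lb) t <= x <=
diag(x_ub) t``, equal per-strain growth ``x_biom^1 = ... = x_biom^K >=
mu_min``, and per-strain caps ``sum_{j in TR_k} t_j <= T_TR`` and
``sum_{j in IN_k} t_j <= T_IN``.

Stage 2 fixes ``t`` and the per-strain biomass fluxes to the stage-1 values
and minimizes the l1 norm of all non-exchange fluxes (an LP after splitting
each flux into nonnegative forward/backward parts), stripping redundant flux
such as futile cycles.

Two valid tightenings are applied to the stage-1 MILP before handing it to
the solver; neither changes the feasible flux set or the optimum:

* per-column indicator coefficients are shrunk to flux-variability bounds of
  the LP relaxation (a smaller valid big-M);
* strains are interchangeable, so a symmetry-breaking cut orders strains by
  their number of active reactions.

The backend is the HiGHS family of solvers via :mod:`scipy.optimize`.
"""

from __future__ import annotations

import contextlib
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .community import CommunityModel

__all__ = [
    "DolmnProblem",
    "DolmnSolution",
    "solve_stage1",
    "solve_stage2",
    "warm_start_from",
    "decompose_start",
    "solve_fixed_t",
]

STATUS_OPTIMAL = "optimal"
STATUS_FEASIBLE = "feasible"  # incumbent with nonzero gap
STATUS_INFEASIBLE = "infeasible"
STATUS_TIMEOUT = "timeout"

FLUX_TOL = 1e-6


@dataclass
class DolmnProblem:
    """One (K, T_TR, T_IN) instance.

    ``big_m_cap`` replaces infinite flux bounds before the MILP is built
    (1000 mmol/gDW/h, the COBRA convention).  ``mip_gap`` is the relative
    optimality gap demanded of the solver; ``time_limit`` is in seconds.
    """

    community: CommunityModel
    T_TR: int
    T_IN: int
    mu_min: float = 0.1
    big_m_cap: float = 1000.0
    mip_gap: float = 1e-6
    time_limit: float | None = None
    fva_tighten: bool = True
    symmetry_break: bool = True
    warm_start_t: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.T_TR < 0 or self.T_IN < 0:
            raise ValueError("T_TR and T_IN must be nonnegative")
        if self.mu_min < 0:
            raise ValueError("mu_min must be nonnegative")
        finite = np.isfinite(self.community.x_lb_c) & np.isfinite(self.community.x_ub_c)
        max_abs = 0.0
        if finite.any():
            max_abs = max(
                np.abs(self.community.x_lb_c[finite]).max(),
                np.abs(self.community.x_ub_c[finite]).max(),
            )
        if not np.isfinite(self.big_m_cap) or self.big_m_cap < max_abs:
            raise ValueError(
                f"big_m_cap must be finite and >= max finite |bound| ({max_abs})"
            )

    def capped_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.clip(self.community.x_lb_c, -self.big_m_cap, self.big_m_cap)
        ub = np.clip(self.community.x_ub_c, -self.big_m_cap, self.big_m_cap)
        return lb, ub


@dataclass
class DolmnSolution:
    status: str
    t: np.ndarray | None
    x: np.ndarray | None
    biomass_per_strain: np.ndarray | None
    objective: float | None
    mip_gap: float | None
    stage: int
    K: int
    T_TR: int
    T_IN: int

    @property
    def feasible(self) -> bool:
        return self.status in (STATUS_OPTIMAL, STATUS_FEASIBLE)


@contextlib.contextmanager
def _silence_stdout():
    """HiGHS prints C-level debug lines during MIP solves; mute them."""
    try:
        fd = os.dup(1)
    except OSError:
        yield
        return
    try:
        devnull = os.open(os.devnull, os.O_WRONLY)
        os.dup2(devnull, 1)
        os.close(devnull)
        yield
    finally:
        os.dup2(fd, 1)
        os.close(fd)


def _forced_on_columns(problem: DolmnProblem) -> np.ndarray:
    """Gated columns with strictly positive lower bound (e.g. ATP
    maintenance): the indicator constraint forces t=1, so they consume
    cardinality budget."""
    lb, _ = problem.capped_bounds()
    comm = problem.community
    gated = _gated_columns(comm)
    return gated[lb[gated] > 0]


def _gated_columns(comm: CommunityModel) -> np.ndarray:
    """Columns carrying a binary: all strain columns except biomass.

    Exchange columns are shared and carry no cardinality constraint, so
    their binaries are fixed to 1 and omitted from the MILP; the biomass
    column is exempt from the intracellular count and always on.
    """
    sets = [comm.TR_k[k] for k in range(1, comm.K + 1)]
    sets += [comm.IN_k[k] for k in range(1, comm.K + 1)]
    return np.sort(np.concatenate(sets)) if sets else np.array([], dtype=int)


def _fva_bounds(
    comm: CommunityModel,
    lb: np.ndarray,
    ub: np.ndarray,
    mu_min: float,
    columns: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Min/max of each requested flux over the LP relaxation polytope
    (steady state + bounds + equal growth >= mu_min)."""
    Nc = comm.N_c
    rows = [comm.S_c]
    b = comm.biomass_columns
    d, ri, ci = [], [], []
    for k in range(1, comm.K):
        ri += [k - 1, k - 1]
        ci += [int(b[0]), int(b[k])]
        d += [1.0, -1.0]
    if comm.K > 1:
        rows.append(sp.csr_matrix((d, (ri, ci)), shape=(comm.K - 1, Nc)))
    A = sp.vstack(rows).tocsc()
    rhs = np.zeros(A.shape[0])
    lo = lb.copy()
    lo[b[0]] = max(lo[b[0]], mu_min)
    bnds = np.column_stack([lo, ub])
    out_lb = lb[columns].copy()
    out_ub = ub[columns].copy()
    c = np.zeros(Nc)
    for a, j in enumerate(columns):
        c[j] = -1.0
        r = linprog(c, A_eq=A, b_eq=rhs, bounds=bnds, method="highs")
        if r.status == 0:
            out_ub[a] = min(out_ub[a], -r.fun)
        c[j] = 1.0
        r = linprog(c, A_eq=A, b_eq=rhs, bounds=bnds, method="highs")
        if r.status == 0:
            out_lb[a] = max(out_lb[a], r.fun)
        c[j] = 0.0
    return out_lb, out_ub


def _build_stage1_milp(problem: DolmnProblem):
    comm = problem.community
    Nc = comm.N_c
    lb, ub = problem.capped_bounds()
    gated = _gated_columns(comm)
    ng = len(gated)
    tcol = {int(g): Nc + a for a, g in enumerate(gated)}
    nvar = Nc + ng

    # indicator coefficients: valid per-column big-M, optionally FVA-shrunk
    ind_lb = lb[gated].copy()
    ind_ub = ub[gated].copy()
    if problem.fva_tighten and ng:
        flb, fub = _fva_bounds(comm, lb, ub, problem.mu_min, gated)
        pad = 1e-7
        # keep sign structure: an indicator coefficient of 0 still allows x=0
        ind_lb = np.where(ind_lb < 0, np.minimum(flb - pad, 0.0), ind_lb)
        ind_ub = np.where(ind_ub > 0, np.maximum(fub + pad, 0.0), ind_ub)

    rows, lo, hi = [], [], []
    rows.append(sp.hstack([comm.S_c, sp.csr_matrix((comm.M_c, ng))]))
    lo += [0.0] * comm.M_c
    hi += [0.0] * comm.M_c

    d, ri, ci = [], [], []
    nr = 0
    for a, g in enumerate(gated):
        g = int(g)
        ri += [nr, nr]
        ci += [g, tcol[g]]
        d += [1.0, -float(ind_ub[a])]
        lo.append(-np.inf)
        hi.append(0.0)
        nr += 1
        ri += [nr, nr]
        ci += [g, tcol[g]]
        d += [1.0, -float(ind_lb[a])]
        lo.append(0.0)
        hi.append(np.inf)
        nr += 1
    rows.append(sp.csr_matrix((d, (ri, ci)), shape=(nr, nvar)))

    d, ri, ci = [], [], []
    nr = 0
    for k in range(1, comm.K + 1):
        for cols, cap in ((comm.TR_k[k], problem.T_TR), (comm.IN_k[k], problem.T_IN)):
            for g in cols:
                ri.append(nr)
                ci.append(tcol[int(g)])
                d.append(1.0)
            lo.append(-np.inf)
            hi.append(float(cap))
            nr += 1
    rows.append(sp.csr_matrix((d, (ri, ci)), shape=(nr, nvar)))

    b = comm.biomass_columns
    d, ri, ci = [], [], []
    nr = 0
    for k in range(1, comm.K):
        ri += [nr, nr]
        ci += [int(b[0]), int(b[k])]
        d += [1.0, -1.0]
        lo.append(0.0)
        hi.append(0.0)
        nr += 1
    ri.append(nr)
    ci.append(int(b[0]))
    d.append(1.0)
    lo.append(problem.mu_min)
    hi.append(np.inf)
    nr += 1
    rows.append(sp.csr_matrix((d, (ri, ci)), shape=(nr, nvar)))

    if problem.symmetry_break and comm.K > 1:
        # strains are interchangeable: order them by active-reaction count
        d, ri, ci = [], [], []
        nr = 0
        for k in range(1, comm.K):
            for g in np.concatenate([comm.TR_k[k], comm.IN_k[k]]):
                ri.append(nr)
                ci.append(tcol[int(g)])
                d.append(1.0)
            for g in np.concatenate([comm.TR_k[k + 1], comm.IN_k[k + 1]]):
                ri.append(nr)
                ci.append(tcol[int(g)])
                d.append(-1.0)
            lo.append(0.0)
            hi.append(np.inf)
            nr += 1
        rows.append(sp.csr_matrix((d, (ri, ci)), shape=(nr, nvar)))

    A = sp.vstack(rows)
    cobj = np.zeros(nvar)
    cobj[b] = -1.0  # maximize summed biomass
    lov = np.concatenate([lb, np.zeros(ng)])
    hiv = np.concatenate([ub, np.ones(ng)])
    integrality = np.concatenate([np.zeros(Nc), np.ones(ng)])
    return A, np.array(lo), np.array(hi), cobj, lov, hiv, integrality, gated


def _assemble_t(comm: CommunityModel, gated: np.ndarray, t_gated: np.ndarray) -> np.ndarray:
    t = np.ones(comm.N_c)
    t[gated] = np.round(t_gated)
    return t


def solve_stage1(problem: DolmnProblem) -> DolmnSolution:
    """Solve the stage-1 MILP; infeasibility is a result, not an error."""
    comm = problem.community
    A, lo, hi, cobj, lov, hiv, integ, gated = _build_stage1_milp(problem)
    options: dict = {"mip_rel_gap": problem.mip_gap}
    if problem.time_limit is not None:
        options["time_limit"] = float(problem.time_limit)

    incumbent = None
    if problem.warm_start_t is not None:
        # scipy's MILP interface takes no MIP start; evaluate the hinted t by
        # LP so a known-feasible incumbent exists if the solver times out.
        incumbent = solve_fixed_t(
            comm,
            problem.warm_start_t,
            mu_min=problem.mu_min,
            big_m_cap=problem.big_m_cap,
            T_TR=problem.T_TR,
            T_IN=problem.T_IN,
        )

    with _silence_stdout():
        res = milp(
            cobj,
            constraints=LinearConstraint(A, lo, hi),
            bounds=Bounds(lov, hiv),
            integrality=integ,
            options=options,
        )

    K = comm.K
    if res.status == 0:
        status = STATUS_OPTIMAL
    elif res.status == 2:
        return DolmnSolution(
            STATUS_INFEASIBLE, None, None, None, None, None, 1, K,
            problem.T_TR, problem.T_IN,
        )
    elif res.x is not None:
        status = STATUS_FEASIBLE
    else:
        if incumbent is not None and incumbent.feasible:
            return replace(incumbent, status=STATUS_FEASIBLE, mip_gap=np.inf)
        return DolmnSolution(
            STATUS_TIMEOUT, None, None, None, None, None, 1, K,
            problem.T_TR, problem.T_IN,
        )

    t = _assemble_t(comm, gated, res.x[comm.N_c :])
    # polish: re-solve the LP at the integer solution's t, removing MILP
    # feasibility slack so stage 2 can pin biomass exactly
    polish = solve_fixed_t(
        comm, t, mu_min=problem.mu_min, big_m_cap=problem.big_m_cap
    )
    if polish.feasible:
        x = polish.x
        objective = polish.objective
    else:  # numerically degenerate incumbent; fall back to raw MILP fluxes
        x = res.x[: comm.N_c]
        objective = float(-res.fun)
    x = np.where((t < 0.5) & (np.abs(x) <= FLUX_TOL), 0.0, x)
    sol = DolmnSolution(
        status=status,
        t=t,
        x=x,
        biomass_per_strain=x[comm.biomass_columns],
        objective=objective,
        mip_gap=float(getattr(res, "mip_gap", 0.0) or 0.0),
        stage=1,
        K=K,
        T_TR=problem.T_TR,
        T_IN=problem.T_IN,
    )
    if incumbent is not None and incumbent.feasible and sol.objective is not None:
        if incumbent.objective > sol.objective + FLUX_TOL and status != STATUS_OPTIMAL:
            return replace(incumbent, status=STATUS_FEASIBLE, mip_gap=sol.mip_gap)
    return sol


def solve_fixed_t(
    community: CommunityModel,
    t: np.ndarray,
    mu_min: float = 0.1,
    big_m_cap: float = 1000.0,
    T_TR: int | None = None,
    T_IN: int | None = None,
) -> DolmnSolution:
    """Maximize community biomass with the binary pattern ``t`` frozen.

    Used by the warm-start path and by the brute-force oracle.  If caps are
    given and ``t`` violates them, the result is infeasible by fiat (a hint
    that breaks the caps cannot be an incumbent).
    """
    t = np.asarray(t, dtype=float)
    comm = community
    if T_TR is not None or T_IN is not None:
        for k in range(1, comm.K + 1):
            if T_TR is not None and t[comm.TR_k[k]].sum() > T_TR + 0.5:
                return DolmnSolution(
                    STATUS_INFEASIBLE, None, None, None, None, None, 1, comm.K,
                    T_TR or 0, T_IN or 0,
                )
            if T_IN is not None and t[comm.IN_k[k]].sum() > T_IN + 0.5:
                return DolmnSolution(
                    STATUS_INFEASIBLE, None, None, None, None, None, 1, comm.K,
                    T_TR or 0, T_IN or 0,
                )
    lb = np.clip(comm.x_lb_c, -big_m_cap, big_m_cap)
    ub = np.clip(comm.x_ub_c, -big_m_cap, big_m_cap)
    off = t < 0.5
    lb = np.where(off, 0.0, lb)
    ub = np.where(off, 0.0, ub)
    if np.any(lb > ub):  # a forced-on reaction (lb>0) switched off
        return DolmnSolution(
            STATUS_INFEASIBLE, None, None, None, None, None, 1, comm.K,
            T_TR or 0, T_IN or 0,
        )
    rows = [comm.S_c]
    b = comm.biomass_columns
    d, ri, ci = [], [], []
    for k in range(1, comm.K):
        ri += [k - 1, k - 1]
        ci += [int(b[0]), int(b[k])]
        d += [1.0, -1.0]
    if comm.K > 1:
        rows.append(sp.csr_matrix((d, (ri, ci)), shape=(comm.K - 1, comm.N_c)))
    A = sp.vstack(rows).tocsc()
    lb[b[0]] = max(lb[b[0]], mu_min)
    if lb[b[0]] > ub[b[0]]:
        return DolmnSolution(
            STATUS_INFEASIBLE, None, None, None, None, None, 1, comm.K,
            T_TR or 0, T_IN or 0,
        )
    cobj = np.zeros(comm.N_c)
    cobj[b] = -1.0
    res = linprog(
        cobj, A_eq=A, b_eq=np.zeros(A.shape[0]),
        bounds=np.column_stack([lb, ub]), method="highs",
    )
    if res.status != 0:
        return DolmnSolution(
            STATUS_INFEASIBLE, None, None, None, None, None, 1, comm.K,
            T_TR or 0, T_IN or 0,
        )
    x = res.x
    return DolmnSolution(
        status=STATUS_OPTIMAL,
        t=np.round(t),
        x=x,
        biomass_per_strain=x[b],
        objective=float(-res.fun),
        mip_gap=0.0,
        stage=1,
        K=comm.K,
        T_TR=T_TR if T_TR is not None else -1,
        T_IN=T_IN if T_IN is not None else -1,
    )


def solve_stage2(problem: DolmnProblem, stage1: DolmnSolution) -> DolmnSolution:
    """Minimize the l1 norm of non-exchange fluxes at fixed t and biomass."""
    if not stage1.feasible:
        raise ValueError("stage-2 requires a feasible stage-1 solution")
    comm = problem.community
    Nc = comm.N_c
    t = stage1.t
    lb, ub = problem.capped_bounds()
    off = t < 0.5
    lb = np.where(off, 0.0, lb)
    ub = np.where(off, 0.0, ub)
    # biomass pinned to the stage-1 values
    for k, bcol in enumerate(comm.biomass_columns):
        v = float(stage1.biomass_per_strain[k])
        lb[bcol] = v
        ub[bcol] = v

    nonexch = np.array(
        [i for i, ci in enumerate(comm.column_layout) if ci.role != "exchange"],
        dtype=int,
    )
    ns = len(nonexch)
    nvar = Nc + ns
    rows_eq = sp.hstack([comm.S_c, sp.csr_matrix((comm.M_c, ns))])
    d, ri, ci = [], [], []
    nr = 0
    for a, j in enumerate(nonexch):
        ri += [nr, nr]
        ci += [int(j), Nc + a]
        d += [1.0, -1.0]
        nr += 1
        ri += [nr, nr]
        ci += [int(j), Nc + a]
        d += [-1.0, -1.0]
        nr += 1
    A_ub = sp.csr_matrix((d, (ri, ci)), shape=(nr, nvar))
    cobj = np.zeros(nvar)
    cobj[Nc:] = 1.0
    s_hi = np.maximum(np.abs(lb[nonexch]), np.abs(ub[nonexch]))
    bounds = np.column_stack(
        [
            np.concatenate([lb, np.zeros(ns)]),
            np.concatenate([ub, s_hi]),
        ]
    )
    res = linprog(
        cobj,
        A_ub=A_ub,
        b_ub=np.zeros(nr),
        A_eq=rows_eq,
        b_eq=np.zeros(comm.M_c),
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        warnings.warn(
            "stage-2 LP unexpectedly infeasible; returning stage-1 fluxes",
            RuntimeWarning,
        )
        return replace(stage1, stage=2)
    x = res.x[:Nc]
    return DolmnSolution(
        status=STATUS_OPTIMAL,
        t=t,
        x=x,
        biomass_per_strain=x[comm.biomass_columns],
        objective=float(res.fun),  # l1 norm of non-exchange fluxes
        mip_gap=0.0,
        stage=2,
        K=comm.K,
        T_TR=problem.T_TR,
        T_IN=problem.T_IN,
    )


def warm_start_from(neighbor: DolmnSolution, problem: DolmnProblem) -> DolmnProblem:
    """Carry a neighboring cell's binary pattern into ``problem`` as a MIP
    start hint; the feasible set and optimum are untouched."""
    if neighbor.t is None:
        return problem
    return replace(problem, warm_start_t=np.array(neighbor.t))


def decompose_start(k_minus_1: DolmnSolution, problem: DolmnProblem) -> DolmnProblem:
    """Build a K-strain start from a (K-1)-strain solution by duplicating the
    first strain's block into the new slot (caps are per strain, so the copy
    always respects them)."""
    comm = problem.community
    K = comm.K
    if k_minus_1.t is None:
        return problem
    n_strain = len(comm.columns_of_strain(1))
    n_e = comm.n_exchange
    expected = n_e + (K - 1) * n_strain
    if len(k_minus_1.t) != expected:
        raise ValueError(
            f"K-1 solution has {len(k_minus_1.t)} columns, expected {expected} "
            f"for the same source model with {K - 1} strains"
        )
    t = np.ones(comm.N_c)
    t[n_e : n_e + (K - 1) * n_strain] = k_minus_1.t[n_e:]
    t[n_e + (K - 1) * n_strain :] = k_minus_1.t[n_e : n_e + n_strain]
    return replace(problem, warm_start_t=t)
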