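"""Self-contained test networks and an exact enumeration oracle.

Everything here is generated in memory so the package is fully testable
without downloading any model repository content.

The toy network has three metabolites (X, Y, Z) in extracellular and
intracellular form.  Only X is supplied by the medium; Y and Z can be moved
between cells and the shared environment by reversible transports.  Biomass
consumes one unit each of intracellular X, Y and Z, and two irreversible
conversions X->Y and Y->Z complete the chain.  A single strain therefore
needs both conversions (two intracellular reactions besides biomass), while
two strains can split them and survive on one conversion each by exchanging
Y and Z — provided all three transports are allowed.

Stoichiometric coefficients are set to +/-1: connectivity alone determines
every feasibility outcome of interest, so unit coefficients are the fixture
convention.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.sparse as sp

from .community import CommunityModel
from .model_io import MetabolicModel
from .optimizer import DolmnSolution, solve_fixed_t

__all__ = ["make_toy_model", "make_random_network", "brute_force_oracle"]


def _model_from_dicts(
    mets: list[str],
    compartments: dict[str, str],
    reactions: list[tuple[str, dict[str, float], float, float]],
    biomass: str,
) -> MetabolicModel:
    midx = {m: i for i, m in enumerate(mets)}
    rows, cols, vals = [], [], []
    lb, ub = [], []
    rxn_ids = []
    for j, (rid, stoich, lo, hi) in enumerate(reactions):
        rxn_ids.append(rid)
        lb.append(lo)
        ub.append(hi)
        for m, v in stoich.items():
            rows.append(midx[m])
            cols.append(j)
            vals.append(float(v))
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(mets), len(reactions)))
    c = np.zeros(len(reactions))
    c[rxn_ids.index(biomass)] = 1.0
    return MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=rxn_ids,
        S=S,
        x_lb=np.array(lb, float),
        x_ub=np.array(ub, float),
        c=c,
        biomass_reaction=biomass,
        compartments=compartments,
    )


def make_toy_model(uptake_limit: float = 10.0) -> MetabolicModel:
    """The six-metabolite, nine-reaction toy network (see module docstring)."""
    mets = ["X_e", "Y_e", "Z_e", "X_c", "Y_c", "Z_c"]
    comp = {m: ("e" if m.endswith("_e") else "c") for m in mets}
    big = 1000.0
    reactions = [
        ("EX_X", {"X_e": -1.0}, -uptake_limit, big),  # medium supplies X
        ("EX_Y", {"Y_e": -1.0}, 0.0, big),  # Y/Z may only leave the system
        ("EX_Z", {"Z_e": -1.0}, 0.0, big),
        ("TX", {"X_e": -1.0, "X_c": 1.0}, -big, big),
        ("TY", {"Y_e": -1.0, "Y_c": 1.0}, -big, big),
        ("TZ", {"Z_e": -1.0, "Z_c": 1.0}, -big, big),
        ("R1", {"X_c": -1.0, "Y_c": 1.0}, 0.0, big),  # X -> Y
        ("R2", {"Y_c": -1.0, "Z_c": 1.0}, 0.0, big),  # Y -> Z
        ("BIOMASS", {"X_c": -1.0, "Y_c": -1.0, "Z_c": -1.0}, 0.0, big),
    ]
    return _model_from_dicts(mets, comp, reactions, "BIOMASS")


def make_random_network(
    seed: int,
    n_intracellular: int = 5,
    n_extracellular: int = 2,
    density: float = 0.3,
    reversibility_fraction: float = 0.3,
) -> MetabolicModel:
    """A seeded random network with a feasible biomass route by construction.

    The skeleton is deterministic: extracellular metabolite 0 is the sole
    medium nutrient, a transport brings it inside, an irreversible conversion
    chain runs through every intracellular metabolite, and biomass consumes
    the end of the chain.  ``density`` then adds that fraction of all ordered
    intracellular pairs as extra conversion reactions, each reversible with
    probability ``reversibility_fraction``.  Identical seeds give identical
    models.
    """
    if n_intracellular < 1 or n_extracellular < 1:
        raise ValueError("need at least one intracellular and one extracellular metabolite")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    big = 1000.0
    ext = [f"ex{i}_e" for i in range(n_extracellular)]
    intr = [f"m{i}_c" for i in range(n_intracellular)]
    mets = ext + intr
    comp = {m: "e" for m in ext} | {m: "c" for m in intr}

    reactions: list[tuple[str, dict[str, float], float, float]] = []
    for i, m in enumerate(ext):
        lo = -10.0 if i == 0 else 0.0
        reactions.append((f"EX_{i}", {m: -1.0}, lo, big))
    for i, m in enumerate(ext):
        target = intr[i % n_intracellular]
        reactions.append((f"T_{i}", {m: -1.0, target: 1.0}, -big, big))
    for i in range(n_intracellular - 1):
        reactions.append(
            (f"CHAIN_{i}", {intr[i]: -1.0, intr[i + 1]: 1.0}, 0.0, big)
        )
    pairs = [
        (a, b)
        for a in range(n_intracellular)
        for b in range(n_intracellular)
        if a != b and not (b == a + 1)  # chain pairs already present
    ]
    n_extra = int(round(density * len(pairs)))
    chosen = rng.permutation(len(pairs))[:n_extra]
    for idx in sorted(chosen):
        a, b = pairs[idx]
        rev = rng.random() < reversibility_fraction
        reactions.append(
            (f"R_{a}_{b}", {intr[a]: -1.0, intr[b]: 1.0}, -big if rev else 0.0, big)
        )
    reactions.append(("BIOMASS", {intr[-1]: -1.0}, 0.0, big))
    return _model_from_dicts(mets, comp, reactions, "BIOMASS")


def brute_force_oracle(
    community: CommunityModel,
    T_TR: int,
    T_IN: int,
    mu_min: float = 0.1,
    big_m_cap: float = 1000.0,
    max_gated: int = 20,
) -> tuple[float, np.ndarray | None]:
    """Exact stage-1 optimum by exhaustive enumeration plus LP.

    Activating a reaction never shrinks the feasible set, so only maximal
    binary patterns under the caps need evaluating: for each strain, every
    subset of transports of size min(T_TR, N_t) crossed with every subset of
    non-biomass intracellular reactions of size min(T_IN, N_i - 1).  Each
    pattern is scored by the biomass-maximizing LP.

    Returns ``(objective, t)``; ``(-inf, None)`` when nothing is feasible.
    Refuses communities with more than ``max_gated`` gated columns.
    """
    comm = community
    n_gated = sum(len(comm.TR_k[k]) + len(comm.IN_k[k]) for k in range(1, comm.K + 1))
    if n_gated > max_gated:
        raise ValueError(
            f"{n_gated} gated columns exceed the enumeration cap ({max_gated})"
        )

    per_strain: list[list[tuple[tuple[int, ...], tuple[int, ...]]]] = []
    for k in range(1, comm.K + 1):
        tr = [int(i) for i in comm.TR_k[k]]
        inn = [int(i) for i in comm.IN_k[k]]
        tr_subsets = list(itertools.combinations(tr, min(T_TR, len(tr))))
        in_subsets = list(itertools.combinations(inn, min(T_IN, len(inn))))
        per_strain.append([(a, b) for a in tr_subsets for b in in_subsets])

    best_obj = -math.inf
    best_t = None
    for combo in itertools.product(*per_strain):
        t = np.zeros(comm.N_c)
        t[: comm.n_exchange] = 1.0
        t[comm.biomass_columns] = 1.0
        for tr_set, in_set in combo:
            t[list(tr_set)] = 1.0
            t[list(in_set)] = 1.0
        sol = solve_fixed_t(comm, t, mu_min=mu_min, big_m_cap=big_m_cap)
        if sol.feasible and sol.objective > best_obj:
            best_obj = sol.objective
            best_t = sol.t
    return best_obj, best_t
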