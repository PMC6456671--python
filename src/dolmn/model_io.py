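"""Reading metabolic models and classifying their reactions.

Models follow COBRA conventions: a stoichiometric matrix ``S`` (metabolites x
reactions, reactants negative), per-reaction flux bounds in mmol/gDW/h, an
objective vector singling out the biomass pseudo-reaction, and compartment
tags on metabolite identifiers.  SBML (Level 3 + FBC) and BiGG-style JSON are
parsed through cobrapy; a canonical internal JSON dialect is used for test
fixtures and round-trips.

Reactions fall into three classes determined purely by the sparsity pattern
of ``S`` and the compartment tags:

* **exchange** reactions touch only extracellular metabolites (they move mass
  across the system boundary),
* **transport** reactions touch at least one extracellular and one
  intracellular metabolite,
* **intracellular** reactions touch only intracellular metabolites.

This classification drives the block structure of the community
stoichiometric matrix (see :mod:`dolmn.community`).
"""

from __future__ import annotations

import gzip
import json
import os
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "MetabolicModel",
    "ReactionClassification",
    "load_model",
    "load_ecoli_core",
    "classify_reactions",
    "write_model_json",
    "read_model_json",
    "fba",
]


class ModelParseError(ValueError):
    """Raised when a model file cannot be interpreted."""


class ModelConfigurationError(ValueError):
    """Raised when a parsed model lacks required structure (e.g. no biomass)."""


class ClassificationError(ValueError):
    """Raised when a metabolite's compartment cannot be determined."""


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model.

    Attributes
    ----------
    metabolite_ids : list of str
        Identifiers carrying compartment tags (``glc__D_e``, ``pyr_c`` ...).
    reaction_ids : list of str
        Reaction identifiers.
    S : scipy.sparse.csc_matrix
        Stoichiometric matrix, shape ``(m, n)``; negative entries are
        reactants, positive are products.
    x_lb, x_ub : ndarray
        Flux bounds (mmol/gDW/h); infinities are retained as sentinels.
    c : ndarray
        Objective weights; nonzero on the biomass reaction in loaded models.
    biomass_reaction : str
        Identifier of the growth pseudo-reaction (flux in 1/h).
    compartments : dict
        Metabolite id -> compartment tag (``"e"``, ``"c"`` ...).
    subsystems : dict
        Reaction id -> pathway/subsystem annotation (may be empty).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_matrix
    x_lb: np.ndarray
    x_ub: np.ndarray
    c: np.ndarray
    biomass_reaction: str
    compartments: dict[str, str] = field(default_factory=dict)
    subsystems: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = sp.csc_matrix(self.S)
        self.x_lb = np.asarray(self.x_lb, dtype=float)
        self.x_ub = np.asarray(self.x_ub, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        m, n = self.S.shape
        if m != len(self.metabolite_ids) or n != len(self.reaction_ids):
            raise ModelConfigurationError(
                f"S has shape {self.S.shape}, expected "
                f"({len(self.metabolite_ids)}, {len(self.reaction_ids)})"
            )
        if self.x_lb.shape != (n,) or self.x_ub.shape != (n,) or self.c.shape != (n,):
            raise ModelConfigurationError("bounds/objective length mismatch with reactions")
        if np.any(self.x_lb > self.x_ub):
            bad = self.reaction_ids[int(np.argmax(self.x_lb > self.x_ub))]
            raise ModelConfigurationError(f"x_lb > x_ub for reaction {bad!r}")
        if self.biomass_reaction not in self.reaction_ids:
            raise ModelConfigurationError(
                f"biomass reaction {self.biomass_reaction!r} not in model"
            )

    @property
    def m(self) -> int:
        return self.S.shape[0]

    @property
    def n(self) -> int:
        return self.S.shape[1]

    @property
    def biomass_index(self) -> int:
        return self.reaction_ids.index(self.biomass_reaction)

    def reaction_index(self, rxn_id: str) -> int:
        return self.reaction_ids.index(rxn_id)

    def metabolite_index(self, met_id: str) -> int:
        return self.metabolite_ids.index(met_id)


@dataclass
class ReactionClassification:
    """Partition of reactions and metabolites by compartment topology."""

    exchange_ids: list[str]
    transport_ids: list[str]
    intracellular_ids: list[str]
    extracellular_metabolites: list[str]
    intracellular_metabolites: list[str]

    @property
    def n_e(self) -> int:
        return len(self.exchange_ids)

    @property
    def n_t(self) -> int:
        return len(self.transport_ids)

    @property
    def n_i(self) -> int:
        return len(self.intracellular_ids)

    @property
    def m_e(self) -> int:
        return len(self.extracellular_metabolites)

    @property
    def m_i(self) -> int:
        return len(self.intracellular_metabolites)


_SUFFIX_RE = re.compile(r"(?:_([a-zA-Z0-9]+)|\[([a-zA-Z0-9]+)\])$")


def _compartment_of(met_id: str, annotated: dict[str, str]) -> str | None:
    tag = annotated.get(met_id)
    if tag:
        return tag
    m = _SUFFIX_RE.search(met_id)
    if m:
        return m.group(1) or m.group(2)
    return None


def classify_reactions(
    model: MetabolicModel, extracellular_tag: str = "e"
) -> ReactionClassification:
    """Partition reactions into exchange / transport / intracellular.

    Compartments come from the model's annotations when present, else from
    the identifier suffix convention (``_e`` or ``[e]``).  Any compartment
    other than the extracellular tag counts as intracellular, so periplasmic
    species in multi-compartment models fold into the intracellular class.

    Raises
    ------
    ClassificationError
        If a metabolite carries no recognizable compartment tag.
    """
    is_ext = np.zeros(model.m, dtype=bool)
    unknown = []
    for i, met in enumerate(model.metabolite_ids):
        tag = _compartment_of(met, model.compartments)
        if tag is None:
            unknown.append(met)
        else:
            is_ext[i] = tag == extracellular_tag
    if unknown:
        raise ClassificationError(
            f"no compartment tag recognizable for metabolites: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )

    S = model.S.tocsc()
    exchange, transport, intracellular = [], [], []
    for j, rxn in enumerate(model.reaction_ids):
        rows = S.indices[S.indptr[j] : S.indptr[j + 1]]
        touches_e = bool(is_ext[rows].any())
        touches_i = bool((~is_ext[rows]).any())
        if touches_e and touches_i:
            transport.append(rxn)
        elif touches_e:
            exchange.append(rxn)
        else:
            intracellular.append(rxn)

    mets = np.array(model.metabolite_ids, dtype=object)
    return ReactionClassification(
        exchange_ids=exchange,
        transport_ids=transport,
        intracellular_ids=intracellular,
        extracellular_metabolites=list(mets[is_ext]),
        intracellular_metabolites=list(mets[~is_ext]),
    )


def _from_cobra(cm) -> MetabolicModel:
    import cobra.util.array

    biomass = [r.id for r in cm.reactions if r.objective_coefficient]
    if len(biomass) != 1:
        raise ModelConfigurationError(
            f"expected exactly one objective (biomass) reaction, found {len(biomass)}"
        )
    # Strip boundary pseudo-metabolites so exchange columns are single-row.
    boundary_mets = [m for m in cm.metabolites if getattr(m, "boundary_condition", False)]
    if boundary_mets:
        cm = cm.copy()
        cm.remove_metabolites(boundary_mets)
    S = sp.csc_matrix(cobra.util.array.create_stoichiometric_matrix(cm, array_type="lil"))
    return MetabolicModel(
        metabolite_ids=[m.id for m in cm.metabolites],
        reaction_ids=[r.id for r in cm.reactions],
        S=S,
        x_lb=np.array([r.lower_bound for r in cm.reactions], dtype=float),
        x_ub=np.array([r.upper_bound for r in cm.reactions], dtype=float),
        c=np.array([r.objective_coefficient for r in cm.reactions], dtype=float),
        biomass_reaction=biomass[0],
        compartments={m.id: m.compartment for m in cm.metabolites if m.compartment},
        subsystems={r.id: (r.subsystem or "") for r in cm.reactions},
    )


def load_model(path: str, format: str | None = None) -> MetabolicModel:
    """Load a model from SBML (L3+FBC), BiGG JSON, or the internal JSON.

    ``format`` is one of ``"sbml"``, ``"bigg-json"``, ``"internal-json"``;
    when omitted it is guessed from the file extension (``.xml``/``.sbml`` ->
    SBML, ``.json`` -> BiGG JSON unless the file carries the internal marker).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        base = path[:-3] if path.endswith(".gz") else path
        if base.endswith((".xml", ".sbml")):
            format = "sbml"
        elif base.endswith(".json"):
            opener = gzip.open if path.endswith(".gz") else open
            with opener(path, "rt") as fh:
                head = json.load(fh)
            format = "internal-json" if head.get("format") == "dolmn-model" else "bigg-json"
        else:
            raise ModelParseError(f"cannot guess model format from {path!r}")

    if format == "internal-json":
        return read_model_json(path)

    import cobra.io

    try:
        if format == "sbml":
            cm = cobra.io.read_sbml_model(path)
        elif format == "bigg-json":
            cm = cobra.io.load_json_model(path)
        else:
            raise ModelParseError(f"unknown format {format!r}")
    except ModelParseError:
        raise
    except Exception as exc:  # cobra raises a zoo of exception types
        raise ModelParseError(f"failed to parse {path!r}: {exc}") from exc
    return _from_cobra(cm)


def load_ecoli_core() -> MetabolicModel:
    """Load the E. coli core carbon metabolism network (BiGG ``e_coli_core``).

    Reads the copy of the network shipped inside the installed cobrapy
    distribution, so no download is needed.  Default bounds encode aerobic
    minimal glucose medium (glucose uptake at 10 mmol/gDW/h).
    """
    import cobra

    path = os.path.join(os.path.dirname(cobra.__file__), "data", "textbook.xml.gz")
    return load_model(path, format="sbml")


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (for SBML/JSON export)."""
    import cobra

    cm = cobra.Model("dolmn_model")
    mets = {}
    for mid in model.metabolite_ids:
        met = cobra.Metabolite(mid, compartment=model.compartments.get(mid))
        mets[mid] = met
    cm.add_metabolites(list(mets.values()))
    S = model.S.tocsc()
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        r = cobra.Reaction(rid)
        r.lower_bound = float(model.x_lb[j])
        r.upper_bound = float(model.x_ub[j])
        r.subsystem = model.subsystems.get(rid, "")
        rxns.append(r)
    cm.add_reactions(rxns)
    for j, rid in enumerate(model.reaction_ids):
        col = S[:, j]
        cm.reactions.get_by_id(rid).add_metabolites(
            {mets[model.metabolite_ids[i]]: float(v)
             for i, v in zip(col.indices, col.data)}
        )
    cm.objective = cm.reactions.get_by_id(model.biomass_reaction)
    return cm


def write_model_sbml(model: MetabolicModel, path: str) -> None:
    """Write SBML L3+FBC via cobrapy."""
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), path)


def write_model_json(model: MetabolicModel, path: str) -> None:
    """Write the canonical internal JSON (exact round-trip of S and bounds)."""
    coo = model.S.tocoo()
    payload = {
        "format": "dolmn-model",
        "metabolites": model.metabolite_ids,
        "reactions": model.reaction_ids,
        "stoichiometry": [
            [int(i), int(j), float(v)] for i, j, v in zip(coo.row, coo.col, coo.data)
        ],
        "x_lb": [None if np.isneginf(v) else float(v) for v in model.x_lb],
        "x_ub": [None if np.isposinf(v) else float(v) for v in model.x_ub],
        "c": model.c.tolist(),
        "biomass_reaction": model.biomass_reaction,
        "compartments": model.compartments,
        "subsystems": model.subsystems,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_model_json(path: str) -> MetabolicModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "dolmn-model":
        raise ModelParseError(f"{path!r} is not an internal model file")
    mets = payload["metabolites"]
    rxns = payload["reactions"]
    ijv = payload["stoichiometry"]
    for i, j, _ in ijv:
        if not (0 <= i < len(mets)) or not (0 <= j < len(rxns)):
            raise ModelParseError(f"stoichiometry entry ({i},{j}) out of range in {path!r}")
    rows = [e[0] for e in ijv]
    cols = [e[1] for e in ijv]
    vals = [e[2] for e in ijv]
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(mets), len(rxns)))
    lb = np.array([-np.inf if v is None else v for v in payload["x_lb"]], dtype=float)
    ub = np.array([np.inf if v is None else v for v in payload["x_ub"]], dtype=float)
    return MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=rxns,
        S=S,
        x_lb=lb,
        x_ub=ub,
        c=np.asarray(payload["c"], dtype=float),
        biomass_reaction=payload["biomass_reaction"],
        compartments=payload.get("compartments", {}),
        subsystems=payload.get("subsystems", {}),
    )


def fba(model: MetabolicModel, big_m_cap: float = 1000.0):
    """Plain flux balance analysis: maximize c'x s.t. Sx = 0, lb <= x <= ub.

    Returns ``(Z_opt, x)``; ``(None, None)`` if infeasible.  Infinite bounds
    are capped at ``big_m_cap`` to keep the LP bounded.
    """
    from scipy.optimize import linprog

    lb = np.clip(model.x_lb, -big_m_cap, big_m_cap)
    ub = np.clip(model.x_ub, -big_m_cap, big_m_cap)
    res = linprog(
        -model.c,
        A_eq=model.S,
        b_eq=np.zeros(model.m),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status != 0:
        return None, None
    return -res.fun, res.x
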