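"""Community stoichiometric matrix assembly.

A K-strain community shares one extracellular compartment: the universal
matrix is split into blocks ``S^e`` (exchange), ``S^t1`` (extracellular rows
of transports), ``S^t2`` (intracellular rows of transports) and ``S^i``
(intracellular reactions), and the strain block ``[S^t2, S^i]`` is replicated
K times along the diagonal:

    S_c = [ S^e  S^t1 0    S^t1 0    ...
            0    S^t2 S^i  0    0    ...
            0    0    0    S^t2 S^i  ... ]

giving ``M_c = M_e + K*M_i`` rows and ``N_c = N_e + K*(N_t + N_i)`` columns.
Column order is fixed as [exchange | strain-1 transport | strain-1
intracellular | ... | strain-K transport | strain-K intracellular]; all
downstream indexing relies on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .model_io import MetabolicModel, ReactionClassification, classify_reactions

__all__ = ["CommunityModel", "ColumnInfo", "build_community", "strain_view"]

ROLE_EXCHANGE = "exchange"
ROLE_TRANSPORT = "transport"
ROLE_INTRACELLULAR = "intracellular"


@dataclass(frozen=True)
class ColumnInfo:
    """Provenance of one community column."""

    role: str  # exchange | transport | intracellular
    strain: int  # 0 for shared exchange columns, else 1..K
    reaction_id: str  # source reaction in the universal model


@dataclass
class CommunityModel:
    """K replicated strains over a shared extracellular environment.

    ``TR_k[k]`` / ``IN_k[k]`` (keys 1..K) are the community column indices
    subject to the transport / intracellular cardinality caps; the biomass
    column is exempt from the intracellular count, so ``len(IN_k[k]) ==
    N_i - 1``.  ``medium`` lists extracellular metabolites whose exchange
    reaction admits uptake (lower bound < 0).
    """

    S_c: sp.csc_matrix
    K: int
    column_layout: list[ColumnInfo]
    row_ids: list[str]
    extracellular_rows: np.ndarray
    TR_k: dict[int, np.ndarray]
    IN_k: dict[int, np.ndarray]
    biomass_columns: np.ndarray  # one per strain, ordered k=1..K
    x_lb_c: np.ndarray
    x_ub_c: np.ndarray
    medium: set[str]
    source_model: MetabolicModel = field(repr=False)
    classification: ReactionClassification = field(repr=False)

    @property
    def M_c(self) -> int:
        return self.S_c.shape[0]

    @property
    def N_c(self) -> int:
        return self.S_c.shape[1]

    @property
    def n_exchange(self) -> int:
        return self.classification.n_e

    def columns_of_strain(self, k: int) -> np.ndarray:
        """All transport + intracellular column indices of strain k."""
        return np.array(
            [i for i, ci in enumerate(self.column_layout) if ci.strain == k], dtype=int
        )

    def transport_columns(self, k: int) -> np.ndarray:
        return np.array(
            [
                i
                for i, ci in enumerate(self.column_layout)
                if ci.strain == k and ci.role == ROLE_TRANSPORT
            ],
            dtype=int,
        )

    def intracellular_columns(self, k: int) -> np.ndarray:
        return np.array(
            [
                i
                for i, ci in enumerate(self.column_layout)
                if ci.strain == k and ci.role == ROLE_INTRACELLULAR
            ],
            dtype=int,
        )

    def S_t1(self, k: int) -> sp.csc_matrix:
        """Extracellular rows of strain k's transport columns (Eq-5 block)."""
        return self.S_c[self.extracellular_rows][:, self.transport_columns(k)]


def build_community(
    model: MetabolicModel,
    classification: ReactionClassification | None = None,
    K: int = 1,
) -> CommunityModel:
    """Assemble the community matrix for ``K`` strains of one source model."""
    if K <= 0:
        raise ValueError(f"K must be a positive integer, got {K}")
    if classification is None:
        classification = classify_reactions(model)

    ridx = {r: j for j, r in enumerate(model.reaction_ids)}
    midx = {m: i for i, m in enumerate(model.metabolite_ids)}
    ex_cols = np.array([ridx[r] for r in classification.exchange_ids], dtype=int)
    tr_cols = np.array([ridx[r] for r in classification.transport_ids], dtype=int)
    in_cols = np.array([ridx[r] for r in classification.intracellular_ids], dtype=int)
    ext_rows = np.array(
        [midx[m] for m in classification.extracellular_metabolites], dtype=int
    )
    int_rows = np.array(
        [midx[m] for m in classification.intracellular_metabolites], dtype=int
    )
    Me, Mi = len(ext_rows), len(int_rows)
    Ne, Nt, Ni = len(ex_cols), len(tr_cols), len(in_cols)

    S = model.S.tocsc()
    S_e = S[ext_rows][:, ex_cols]
    S_t1 = S[ext_rows][:, tr_cols]
    S_t2 = S[int_rows][:, tr_cols]
    S_i = S[int_rows][:, in_cols]

    top = [S_e] + [sp.hstack([S_t1, sp.csr_matrix((Me, Ni))])] * K
    blocks = [sp.hstack(top)]
    strain_block = sp.hstack([S_t2, S_i])
    for k in range(K):
        row = [sp.csr_matrix((Mi, Ne))]
        for k2 in range(K):
            row.append(strain_block if k2 == k else sp.csr_matrix((Mi, Nt + Ni)))
        blocks.append(sp.hstack(row))
    S_c = sp.vstack(blocks).tocsc()

    layout: list[ColumnInfo] = [
        ColumnInfo(ROLE_EXCHANGE, 0, model.reaction_ids[j]) for j in ex_cols
    ]
    strain_src = np.concatenate([tr_cols, in_cols]) if Nt + Ni else np.array([], dtype=int)
    for k in range(1, K + 1):
        layout += [ColumnInfo(ROLE_TRANSPORT, k, model.reaction_ids[j]) for j in tr_cols]
        layout += [
            ColumnInfo(ROLE_INTRACELLULAR, k, model.reaction_ids[j]) for j in in_cols
        ]

    x_lb_c = np.concatenate([model.x_lb[ex_cols]] + [model.x_lb[strain_src]] * K)
    x_ub_c = np.concatenate([model.x_ub[ex_cols]] + [model.x_ub[strain_src]] * K)

    row_ids = list(np.array(model.metabolite_ids, dtype=object)[ext_rows])
    for k in range(1, K + 1):
        row_ids += [
            f"{model.metabolite_ids[i]}__strain{k}" for i in int_rows
        ]

    biomass = model.biomass_reaction
    TR_k: dict[int, np.ndarray] = {}
    IN_k: dict[int, np.ndarray] = {}
    biomass_columns = []
    for k in range(1, K + 1):
        off = Ne + (k - 1) * (Nt + Ni)
        TR_k[k] = np.arange(off, off + Nt)
        strain_in = np.arange(off + Nt, off + Nt + Ni)
        keep = np.array(
            [layout[i].reaction_id != biomass for i in strain_in], dtype=bool
        )
        IN_k[k] = strain_in[keep]
        bcol = strain_in[~keep]
        if bcol.size != 1:
            raise ValueError(
                "biomass reaction must be intracellular; "
                f"found {bcol.size} biomass columns for strain {k}"
            )
        biomass_columns.append(int(bcol[0]))

    ex_met_of_col = {}
    for a, j in enumerate(ex_cols):
        rows = S[:, j].nonzero()[0]
        ex_met_of_col[a] = [model.metabolite_ids[i] for i in rows]
    medium = {
        m
        for a in range(Ne)
        if model.x_lb[ex_cols[a]] < 0
        for m in ex_met_of_col[a]
    }

    return CommunityModel(
        S_c=S_c,
        K=K,
        column_layout=layout,
        row_ids=row_ids,
        extracellular_rows=np.arange(Me),
        TR_k=TR_k,
        IN_k=IN_k,
        biomass_columns=np.array(biomass_columns, dtype=int),
        x_lb_c=x_lb_c,
        x_ub_c=x_ub_c,
        medium=medium,
        source_model=model,
        classification=classification,
    )


def strain_view(community: CommunityModel, t: np.ndarray, k: int) -> MetabolicModel:
    """Strain k's subnetwork: shared exchange columns plus its own columns
    with ``t_j = 1`` (columns with ``t_j = 0`` are removed)."""
    t = np.asarray(t)
    if t.shape != (community.N_c,):
        raise ValueError(f"t must have length {community.N_c}, got {t.shape}")
    if not 1 <= k <= community.K:
        raise ValueError(f"strain index {k} out of range 1..{community.K}")

    keep = [
        i
        for i, ci in enumerate(community.column_layout)
        if ci.strain == 0 or (ci.strain == k and t[i] >= 0.5)
    ]
    keep = np.array(keep, dtype=int)
    Me = len(community.extracellular_rows)
    Mi_rows = np.arange(Me + (k - 1) * _mi(community), Me + k * _mi(community))
    rows = np.concatenate([community.extracellular_rows, Mi_rows])
    sub = community.S_c[rows][:, keep]
    # drop strain suffix from row ids for a self-contained single-strain model
    row_ids = [community.row_ids[i].replace(f"__strain{k}", "") for i in rows]
    rxn_ids = [community.column_layout[i].reaction_id for i in keep]
    src = community.source_model
    comp = {m: src.compartments.get(m, "") for m in row_ids if m in src.compartments}
    c = np.zeros(len(keep))
    bio = src.biomass_reaction
    if bio in rxn_ids:
        c[rxn_ids.index(bio)] = 1.0
    else:
        raise ValueError(f"strain {k} view lost its biomass column (t=0 on biomass)")
    return MetabolicModel(
        metabolite_ids=row_ids,
        reaction_ids=rxn_ids,
        S=sub.tocsc(),
        x_lb=community.x_lb_c[keep],
        x_ub=community.x_ub_c[keep],
        c=c,
        biomass_reaction=bio,
        compartments=comp,
        subsystems={r: src.subsystems.get(r, "") for r in rxn_ids},
    )


def _mi(community: CommunityModel) -> int:
    return community.classification.m_i
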