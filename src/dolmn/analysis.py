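"""Downstream analysis of solved landscapes.

Per-strain net exchange fluxes come from the transport block: for strain k,
``x_e^k = S^(t1,k) x_t^k``, the extracellular rows of the strain's transport
columns applied to its transport fluxes (positive = net secretion into the
shared environment).  A metabolite is *exchanged* when one strain's net flux
is positive and another's negative, unless it is part of the medium.

Metabolic differentiation between strains is measured two ways: Jaccard
distance on active-reaction sets (network content) and Euclidean distance on
flux vectors (network use).  PCA operates on biomass-normalized intracellular
fluxes, with biomass itself excluded from the features.  Exchange-flux
correlation (Spearman by default, Pearson secondary) across all solutions in
a landscape reveals co-exchanged metabolite groups; the correlation matrix is
ordered by Ward hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import pearsonr, spearmanr

from .community import CommunityModel
from .optimizer import DolmnSolution

__all__ = [
    "ExchangeProfile",
    "net_exchange_flux",
    "identify_exchanged_metabolites",
    "jaccard_distance",
    "euclidean_flux_distance",
    "pca_projection",
    "exchange_correlations",
]

EXCHANGE_FLUX_THRESHOLD = 1e-6  # mmol/gDW/h, solver noise floor


@dataclass
class ExchangeProfile:
    """Per-strain net exchange fluxes and the exchanged-metabolite calls."""

    metabolites: list[str]  # extracellular metabolite ids (row order)
    fluxes: np.ndarray  # shape (K, M_e), positive = secretion
    exchanged: dict[str, tuple[frozenset, frozenset]]  # met -> (producers, consumers)

    @property
    def exchanged_metabolites(self) -> set[str]:
        return set(self.exchanged)


def net_exchange_flux(
    community: CommunityModel, solution: DolmnSolution, k: int
) -> np.ndarray:
    """Strain k's net exchange flux over extracellular metabolites."""
    if not solution.feasible:
        raise ValueError("solution is not feasible")
    if not 1 <= k <= community.K:
        raise ValueError(f"strain index {k} out of range 1..{community.K}")
    x_t = solution.x[community.transport_columns(k)]
    return np.asarray(community.S_t1(k) @ x_t).ravel()


def identify_exchanged_metabolites(
    community: CommunityModel,
    solution: DolmnSolution,
    threshold: float = EXCHANGE_FLUX_THRESHOLD,
) -> ExchangeProfile:
    """Apply the secrete/uptake rule across strains, excluding the medium.

    With a single strain there is no partner, so the exchanged set is empty
    by definition.
    """
    if not solution.feasible:
        raise ValueError("solution is not feasible")
    mets = community.classification.extracellular_metabolites
    fluxes = np.vstack(
        [net_exchange_flux(community, solution, k) for k in range(1, community.K + 1)]
    )
    exchanged: dict[str, tuple[frozenset, frozenset]] = {}
    if community.K >= 2:
        for i, m in enumerate(mets):
            if m in community.medium:
                continue
            producers = frozenset(
                k + 1 for k in range(community.K) if fluxes[k, i] > threshold
            )
            consumers = frozenset(
                k + 1 for k in range(community.K) if fluxes[k, i] < -threshold
            )
            if producers and consumers:
                exchanged[m] = (producers, consumers)
    return ExchangeProfile(metabolites=list(mets), fluxes=fluxes, exchanged=exchanged)


def jaccard_distance(
    t_a: np.ndarray, t_b: np.ndarray, subset: np.ndarray | None = None
) -> float:
    """1 - |A & B| / |A | B| over active indices; 0 when both sets are empty."""
    t_a = np.asarray(t_a) >= 0.5
    t_b = np.asarray(t_b) >= 0.5
    if t_a.shape != t_b.shape:
        raise ValueError("binary vectors must have equal length")
    if subset is not None:
        t_a = t_a[subset]
        t_b = t_b[subset]
    union = np.logical_or(t_a, t_b).sum()
    if union == 0:
        return 0.0
    inter = np.logical_and(t_a, t_b).sum()
    return float(1.0 - inter / union)


def euclidean_flux_distance(
    x_a: np.ndarray, x_b: np.ndarray, subset: np.ndarray | None = None
) -> float:
    """l2 norm of the flux difference, optionally over a reaction subset."""
    x_a = np.asarray(x_a, float)
    x_b = np.asarray(x_b, float)
    if x_a.shape != x_b.shape:
        raise ValueError("flux vectors must have equal length")
    if subset is not None:
        x_a = x_a[subset]
        x_b = x_b[subset]
    return float(np.linalg.norm(x_a - x_b))


def _strain_rows(landscape) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """One row per strain per feasible cell: biomass-normalized intracellular
    fluxes (biomass excluded) and, alongside, normalized net exchange fluxes."""
    comm = landscape.community
    feats = []
    ex_rows = []
    index = []
    bio_idx = {k: int(comm.biomass_columns[k - 1]) for k in range(1, comm.K + 1)}
    for cell in landscape.feasible_cells():
        sol = cell.solution
        for k in range(1, comm.K + 1):
            cols = comm.intracellular_columns(k)
            cols = cols[cols != bio_idx[k]]
            mu = sol.x[bio_idx[k]]
            if abs(mu) < 1e-12:
                continue
            feats.append(sol.x[cols] / mu)
            ex_rows.append(net_exchange_flux(comm, sol, k) / mu)
            index.append((cell.T_TR, cell.T_IN, k))
    idx = pd.MultiIndex.from_tuples(index, names=["T_TR", "T_IN", "strain"])
    return (
        pd.DataFrame(np.vstack(feats) if feats else np.empty((0, 0)), index=idx),
        np.vstack(ex_rows) if ex_rows else np.empty((0, 0)),
        idx,
    )


def pca_projection(landscape, n_components: int | None = None) -> dict:
    """PCA of biomass-normalized intracellular fluxes across a landscape.

    Returns a dict with ``coordinates`` (DataFrame indexed by (T_TR, T_IN,
    strain)), ``explained_variance_ratio`` and ``components``.
    """
    from sklearn.decomposition import PCA

    feats, _, idx = _strain_rows(landscape)
    if feats.shape[0] < 2:
        raise ValueError("PCA needs at least two feasible strain flux vectors")
    X = feats.to_numpy()
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    return {
        "coordinates": pd.DataFrame(
            coords,
            index=idx,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
        ),
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "components": pca.components_,
    }


def exchange_correlations(
    landscape,
    method: str = "spearman",
    threshold: float = EXCHANGE_FLUX_THRESHOLD,
) -> dict:
    """Correlate biomass-normalized net exchange fluxes across solutions.

    Rows are strain-cell observations, columns extracellular metabolites.
    Zero-variance metabolites get NaN rows/columns (undefined, not zero).
    Returns the correlation matrix, the Ward-linkage leaf order over the
    metabolites with defined correlations, and the per-metabolite exchange
    frequency (percentage of feasible multi-strain cells in which the
    metabolite is exchanged).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    comm = landscape.community
    _, ex, idx = _strain_rows(landscape)
    mets = comm.classification.extracellular_metabolites
    if ex.shape[0] < 3:
        raise ValueError("need at least three feasible strain observations")
    df = pd.DataFrame(ex, index=idx, columns=mets)
    corr = df.corr(method=method)  # pandas leaves zero-variance cols as NaN
    defined = [m for m in mets if not corr[m].isna().all()]
    order = None
    if len(defined) >= 2:
        sub = corr.loc[defined, defined].fillna(0.0)
        Z = linkage(sub.to_numpy(), method="ward")
        order = [defined[i] for i in leaves_list(Z)]

    freq = {}
    multi = [c for c in landscape.feasible_cells() if c.K >= 2]
    for m in mets:
        if not multi:
            freq[m] = np.nan
            continue
        n_ex = sum(
            1
            for c in multi
            if m
            in identify_exchanged_metabolites(comm, c.solution, threshold).exchanged
        )
        freq[m] = 100.0 * n_ex / len(multi)

    return {
        "correlation": corr,
        "cluster_order": order,
        "exchange_frequency_percent": pd.Series(freq),
        "observations": df,
    }
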