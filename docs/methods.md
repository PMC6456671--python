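# Methods

## Model and assumptions

`dolmn` operates on constraint-based metabolic models under the standard
steady-state assumption `S x = 0` with flux bounds encoding irreversibility
and medium composition (mmol·gDW⁻¹·h⁻¹; biomass flux read as growth rate in
h⁻¹).  Reactions are classified from the sparsity pattern of `S` and
metabolite compartment tags into exchange (only extracellular metabolites),
transport (both compartment types) and intracellular (only intracellular
metabolites).  Compartments come from model annotations when present,
otherwise from the `_e` / `[e]` identifier suffix convention; compartments
other than the extracellular tag (e.g. periplasm) are folded into the
intracellular class so the three-way scheme is preserved.  Boundary
pseudo-metabolites, when an SBML file declares them, are stripped so that
every exchange column touches exactly one metabolite row.

A K-strain community shares one extracellular compartment.  The community
matrix replicates the `[S^t2, S^i]` block per strain along the diagonal;
column order is fixed as `[exchange | strain-1 transport | strain-1
intracellular | … | strain-K]` and all downstream indexing (stage-2's
"everything after the exchange block", Eq-5 transport slices, strain views)
relies on that layout.  All strains are copies of one source network —
heterogeneous communities are out of scope.

The coexistence requirement is an equal-growth coupling
`x_biom^1 = … = x_biom^K ≥ μ_min`, modeling stable chemostat coexistence.
μ_min defaults to 0.1 h⁻¹.

## Stage 1: cardinality-constrained MILP

Binary indicators gate fluxes through `diag(x_lb) t ≤ x ≤ diag(x_ub) t`; a
single binary gates both directions of a reversible reaction.  Design
choices that the formulation leaves open were resolved as follows:

* **Objective** — the sum of all strain biomass columns.  Under the
  equal-growth equality any positive combination is equivalent; the sum is
  symmetric under strain permutation.
* **Exchange binaries** — exchange columns carry no cardinality constraint,
  so their binaries are fixed to 1 rather than left as solver noise.
* **Biomass exemption** — the biomass pseudo-reaction does not count toward
  `T_IN` (and its binary is fixed to 1; the growth floor forces it on
  anyway).  With this convention the toy network is feasible for one strain
  at exactly `T_IN = 2` — the two conversions — which is the behavior the
  fixture encodes.
* **Forced-on reactions** — intracellular reactions with strictly positive
  lower bound (ATP maintenance in the E. coli models) cannot take `t = 0`
  and therefore consume intracellular budget.
* **Infinite bounds** — capped at `big_m_cap` (default 1000, the COBRA
  convention) before the MILP is built.

Two tightenings are applied that provably do not change the feasible flux
set or the optimum, only solver behavior: (i) each indicator coefficient is
shrunk from the raw bound to the flux-variability range of that column over
the LP relaxation (plus a 1e-7 pad), computed by 2·N_c auxiliary LPs; and
(ii) for K ≥ 2 a symmetry-breaking cut orders strains by their number of
active reactions, removing permutation-equivalent branches.  Tolerances:
relative MIP gap 1e-6 by default (configurable, with a time limit, for
larger instances), solver feasibility at HiGHS defaults, indicator/equality
checks at 1e-6 in all reported invariants.

After the MILP returns, the incumbent's binary pattern is re-solved as a
plain LP ("polish") and those fluxes are reported.  This removes the MILP's
integrality/feasibility slack so that stage 2 can pin the biomass values
exactly, and it makes the reported objective agree with enumeration oracles
to machine precision.

Infeasibility is a result (`status="infeasible"`), never an exception:
landscape sweeps must record the infeasible region.

Alternate optima are real — the binary pattern is generally not unique — so
tests compare objectives and feasibility boundaries, never specific
reaction sets.

## Warm starts and decomposition

SciPy's MILP interface accepts no starting point, so the warm-start hooks
adjust behavior around the solver instead: a neighboring solution's `t` is
evaluated by a fixed-`t` LP, and that incumbent is returned (flagged
`feasible`, gap ∞ or the solver's) if the MILP itself times out without one
or returns something worse.  The `K-1 → K` decomposition start duplicates an
existing strain's block, which always satisfies the per-strain caps.  The
feasible set and the optimum are never altered by either hook.

Time-limited solves report the best incumbent with its gap; on hard
instances (the 2-strain core network near the feasibility boundary) the
incumbent is typically found within a minute while closing the last ~2% of
the dual bound can take far longer, so reported growth rates from
time-limited runs carry the recorded `mip_gap` and are hardware-dependent.

## Stage 2: l1 flux parsimony

With `t` and the per-strain biomass fixed to the stage-1 values, the l1 norm
of all non-exchange fluxes is minimized as an LP (each flux split against an
auxiliary absolute-value variable).  This removes circulating flux in
reversible 2-cycles and other redundancy; it cannot increase the l1 norm and
preserves every stage-1 feasibility invariant.  Degenerate alternate routes
of equal l1 cost may remain and are reported as-is.

## Landscape sweeps

`sweep` visits each transport cap from large to small and, within it, the
intracellular caps in decreasing order, passing each feasible solution
forward as the next cell's warm-start hint.  Feasibility is monotone in both
caps; a violation in recorded results (possible only through solver
time-limit artifacts) triggers a warning rather than silent acceptance.
`min_feasible_T_IN` / `min_feasible_T_TR` bisect over a cap using this
monotonicity.  Grid values are explicit user input; no default grid is
claimed to replicate any published scan, and no interpolation of infeasible
cells is stored.

## Analysis layer

Net exchange flux per strain is `x_e^k = S^(t1,k) x_t^k` (positive =
secretion).  A metabolite is called exchanged when some strain's net flux
exceeds +1e-6 and another's is below −1e-6 — the threshold is the solver
noise floor, configurable — and the metabolite is not supplied by the medium
(operationalized as: its exchange reaction's lower bound is negative in the
loaded model).  Jaccard distance compares active-reaction sets (defined as 0
when both sets are empty); Euclidean distance compares flux vectors;
pathway-restricted variants take subsystem annotations from the model.  PCA
runs on intracellular fluxes normalized by (and excluding) the biomass flux,
one row per strain per feasible cell.  Exchange-flux correlations (Spearman
headline, Pearson secondary) use the same biomass normalization;
zero-variance metabolites are reported as missing, not zero, and the
correlation matrix is ordered by Ward linkage.  Exchange frequency is the
percentage of *feasible multi-strain* cells in which a metabolite is
exchanged (infeasible cells have no exchange state to count).

## Synthetic fixtures

The toy network (6 metabolites, 9 reactions) encodes the minimal
division-of-labor story: medium supplies only X, biomass needs X, Y and Z,
and the conversion chain X→Y→Z can be split between two strains that trade
Y and Z through reversible transports.  Stoichiometric coefficients are ±1;
connectivity alone fixes every feasibility outcome the fixture is used to
check, so unit coefficients are the fixture convention, and toy flux values
are not treated as ground truth.

Random fixtures guarantee feasibility by construction (medium → transport →
conversion chain → biomass) instead of rejection sampling, then add a
density-controlled set of random conversions, each reversible with a given
probability, from a seeded generator.  They emulate network *structure*
(sparsity, reversibility, a single carbon source) but not biological realism
— no cofactor coupling, no maintenance ATP, no realistic stoichiometric
ratios — so passing tests demonstrate algorithmic correctness, not
biological prediction quality.

The brute-force oracle enumerates only cap-maximal binary patterns (adding
a reaction never hurts a maximization), scores each with the fixed-`t` LP,
and refuses instances above ~20 gated columns.

## Problem sizes used in the test suite

The default suite runs the toy grids exhaustively, 20 seeded random
fixtures (≤ 12 gated columns each) against the enumeration oracle, a
single-strain core-network sweep at `T_IN ∈ {24…30}` (each instance proves
optimal in seconds), and one 2-strain core instance at `T_TR=11, T_IN=26`
with a 300-second budget, which returns a near-optimal incumbent with its
gap recorded.  Genome-scale boundary searches live in
`scripts/reproduce_ijr904.py` and are run separately.

## Known limitations

* The MILP backend cannot accept true MIP starts, so warm starts accelerate
  nothing inside the solver; they only guarantee an incumbent.
* Hard symmetric instances (K ≥ 2 near the feasibility boundary) may return
  incumbents with a 1–3% gap within practical budgets; boundary locations
  from `min_feasible_*` at tight caps inherit that sensitivity.
* No thermodynamic (loopless) constraints beyond stage-2 parsimony; no
  bilevel or multi-objective variants; no mixing of different source models
  in one community.
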