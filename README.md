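# dolmn — division of labor in metabolic networks

`dolmn` partitions a constraint-based metabolic network into K strain
subnetworks that must coexist at equal growth rates while each strain is
allowed at most `T_TR` transport reactions and `T_IN` intracellular
reactions.  It is aimed at systems biologists studying how microbial
consortia split metabolic work: when the reaction budgets drop below what a
single organism needs, feasible solutions survive only through cross-feeding,
and the package identifies which metabolites are exchanged and how the
strains differentiate.

## The optimization problem

Given a stoichiometric matrix `S` with flux bounds and a biomass reaction,
the K-strain community matrix `S_c` shares the extracellular compartment and
replicates the transport + intracellular block per strain
(`M_c = M_e + K·M_i`, `N_c = N_e + K·(N_t + N_i)`).  Stage 1 is a MILP over
fluxes `x` and binary reaction indicators `t`:

```
max  Σ_k x_biom^k
s.t. S_c x = 0
     x_lb ≤ x ≤ x_ub
     diag(x_lb) t ≤ x ≤ diag(x_ub) t
     x_biom^1 = … = x_biom^K ≥ μ_min      (default 0.1 / h)
     Σ_{j∈TR_k} t_j ≤ T_TR,  Σ_{j∈IN_k} t_j ≤ T_IN   for every strain k
     t_j ∈ {0,1}
```

Stage 2 fixes `t` and the per-strain biomass fluxes and minimizes the l1
norm of all non-exchange fluxes (an LP), removing futile cycles and other
redundant flux.  Per-strain net exchange fluxes follow from the transport
block, `x_e^k = S^(t1,k) x_t^k`; a metabolite is *exchanged* when one strain
secretes it and another takes it up, unless the medium already supplies it.

Solvers are the open-source HiGHS LP/MILP codes via SciPy.

## Worked example

```python
from dolmn import (make_toy_model, classify_reactions, build_community,
                   DolmnProblem, solve_stage1, solve_stage2,
                   identify_exchanged_metabolites)

toy = make_toy_model()            # X uptake; X->Y; Y->Z; biomass needs X+Y+Z
comm = build_community(toy, classify_reactions(toy), K=2)
prob = DolmnProblem(community=comm, T_TR=3, T_IN=1)
s1 = solve_stage1(prob)
s2 = solve_stage2(prob, s1)
print(s1.status, s1.biomass_per_strain)
print(identify_exchanged_metabolites(comm, s2).exchanged_metabolites)
```

prints

```
optimal [1.66666667 1.66666667]
{'Z_e', 'Y_e'}
```

With only one intracellular conversion allowed per strain (`T_IN=1`), no
single strain can run both `X->Y` and `Y->Z`, so a lone strain is infeasible;
the two strains grow at 1.67/h each by splitting the chain and exchanging
the intermediates Y and Z through the shared environment.  Cutting the
transport budget to `T_TR=2` removes the ability to trade and the 2-strain
community becomes infeasible too.

The same workflow scales to genome-scale content: `load_ecoli_core()` loads
the E. coli core carbon network, and
`dolmn sweep --model M --strains 2 --t-tr 9:25:2 --t-in 20:50:2 --out dir/`
maps a whole feasibility landscape from the command line.

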