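# Methods

## Model and formulation

`symcomm` studies small bacterial communities (the motivating system is the
five-member *Drosophila* gut community of *Acetobacter* and *Lactobacillus*
species) with steady-state constraint-based modelling. Every species is a
stoichiometric network: metabolites, reactions with flux bounds
(mmol·gDW⁻¹·h⁻¹), and a biomass reaction whose flux is the growth rate μ
(h⁻¹). Exchange reactions are single-metabolite boundary reactions with the
usual sign convention (negative flux = uptake); a medium is a map from
boundary metabolite to maximal uptake rate, applied as the exchange lower
bound −(limit).

Communities join K species through a shared lumen compartment. Member
networks are copied verbatim under a `member::` namespace; each member's
boundary exchange `met_e ↔ ∅` is rewired into a species exchange
`member::met_e ↔ met_u`, and a single community exchange `met_u ↔ ∅` per
lumen metabolite connects the lumen to the host-controlled environment.
Species-exchange bounds replicate the member's own exchange bounds and are
abundance-scaled in the LP; community-exchange bounds come only from the
medium and are never abundance-scaled — nutrient supply belongs to the
environment, not to the populations.

The steady state imposes one shared growth rate μ on all members
(coexistence constraint). With abundances X_k ≥ 0 and aggregate fluxes V,
the fixed-μ LP is

    max  Σ_k X_k
    s.t. S·V = 0                         (member + lumen mass balance)
         lb_j·X_k ≤ V_j ≤ ub_j·X_k       (member reactions)
         V[biomass_k] = μ·X_k
         lb_m ≤ V[EX_m] ≤ ub_m           (community exchanges)

and μmax is the largest μ at which max ΣX ≥ 1; any optimum with ΣX ≥ 1
scales down onto ΣX = 1 because the constraint set is positively
homogeneous in (X, V) apart from the fixed community-exchange bounds, which
only relax when scaling down. μmax is located by bisection to an absolute
tolerance of 1e−7 h⁻¹, bracketed by doubling upward from 1 h⁻¹ while the
LP stays feasible.

## The canonical solve chain

Each community × medium cell is solved as:

1. **Max growth** — bisection as above; the solve at μmax fixes ΣX = 1 and
   minimizes Σ|V| plus a lexicographic abundance tie-break (weight 1e−9 per
   member rank), so degenerate abundance splits resolve deterministically.
2. **FVA at 99.99 % of μmax** — every community reaction is minimized and
   maximized subject to the same constraints with ΣX = 1; every solve
   records the member growth-rate vector μ·X (two vectors per reaction).
3. **Medoid floors** — the medoid of the recorded growth-rate vectors (the
   vector minimizing the summed Euclidean distance to all others, ties to
   first occurrence) becomes a per-member lower bound. By default the bound
   applies to the biomass formation rate via the linear constraint
   V[biomass_k] ≥ medoid_k, which is exact at any μ; a switch
   (`mode="abundance"`) bounds X_k instead (medoid divided by the FVA μ).
   The constrained bisection is seeded at the FVA μ, where the medoid
   vector is feasible by construction; if the floors are ever infeasible
   they are relaxed geometrically (×0.99 per iteration, at most 100 times,
   logged) rather than aborting the cell.
4. **L1 flux minimization** — at the fixed μ and X, Σ|V| is minimized by a
   split-variable LP. Biomass fluxes are pinned by the μ·X coupling;
   exchange fluxes stay free so that extraneous exchange flux can also be
   removed. This zeroes futile cycles exactly.

All LPs are solved with HiGHS (through `scipy.optimize.linprog`) at primal
and dual feasibility tolerance 1e−8.

### Numerical choices

- **No-growth probe.** A community counts as non-growing when the LP at
  μ = 1e−6 h⁻¹ cannot reach ΣX = 1. The probe must sit well above the
  1e−8 feasibility tolerance: at smaller μ the biomass flux a "growing"
  solution needs is itself below solver tolerance, and truly auxotrophic,
  unrescued models would register as growing. 1e−6 h⁻¹ is far below any
  biologically meaningful rate at the scales simulated (0.1–30 h⁻¹).
- **Abundance cap.** Raw abundance variables are bounded by 1e6 so the
  max-ΣX LP stays bounded at tiny μ (an abundance ray with biomass-coupling
  residual below solver tolerance is otherwise reported as unbounded). The
  cap never binds a reported solution, which lives on ΣX = 1.
- **Degeneracy.** Identical competitors make the abundance split degenerate;
  the L1 + lexicographic polish picks a unique, reproducible vertex. These
  cells are recognizable in output by exactly reproducible splits rather
  than warnings.
- **Known systematic.** The medoid floors inherit the 99.99 % FVA level, so
  canonical growth rates sit up to ~(1−0.9999)·μ below the unconstrained
  optimum. Interaction deltas therefore carry a drag of order 1e−4·μ, which
  is why a member whose "unchanged" status rests on an exact resource-cap
  equality can classify as slightly decreased. Exact zeros (non-growing
  members) are unaffected. This mirrors the source system, where the zero
  sides of amensal and neutral interactions are structurally non-growing
  members and commensal interactions are never observed.

## Media

Three tiers mirror a host-diet gradient. *Minimal* carries only the primary
C/N/S/P sources — glucose, glycerol, ammonia, sulfate, phosphate (defaults
10, 10, 1000, 1000, 1000 mmol·gDW⁻¹·h⁻¹). *Base* adds the union of pool
auxotrophies at a limiting rate (default 1 mmol·gDW⁻¹·h⁻¹) so every species
grows in isolation. *Rich* multiplies base by an excess factor (default 10)
and opens every transportable metabolite of the pool. Auxotrophies are
detected by a single-metabolite rescue sweep on the minimal medium; species
no single metabolite rescues fall back to a greedy prune from the full
candidate set (deterministic order), which finds combined requirements such
as an amino acid plus a cell-wall precursor. Secretion caps default to
1000 mmol·gDW⁻¹·h⁻¹ unless the medium overrides them.

## Ecology statistics

Growth readout is the biomass formation rate μ·X_k (gDW·h⁻¹); monoculture
X = 1 makes it comparable across community sizes. Pair interactions compare
each member's rate in the full community against its monoculture on the
same medium (not against the pair sub-community) and map the sign pair onto
competitive (−,−), parasitic (+,−), mutualistic (+,+), commensal (+,0),
amensal (−,0), neutral (0,0), with |Δ| ≤ ε = 1e−6 gDW·h⁻¹ counting as
zero. Metabolite roles come from net species-lumen flux with the same ε
(a member on both sides of one metabolite is assigned by net sign): no
producer and one/many consumers gives single-use/co-consumed, any producer
with a distinct consumer gives cross-fed, no consumer and one/many
producers gives single-produced/coproduced. Per-metabolite pattern
frequencies divide each pattern's occurrences by the metabolite's total
occurrences across all communities of a medium and sum to one. Host-available
outputs are metabolites whose community exchange shows net secretion > ε in
at least one community; a metabolite secreted by one member but fully
consumed by another never appears, because the lumen balance closes. A
metabolite present in the medium can still be classified cross-fed; origin
is visible in the medium files, not in the pattern rule.

## Synthetic generator

Toy species follow a fixed template: carbon uptake → precursor conversion →
biomass, with biomass consuming the precursor at 1/yield, ammonia at
0.5 mmol·gDW⁻¹, each auxotrophy metabolite at its stated coefficient, and
producing each secretion at its stated yield (growth-coupled overflow).
Yields use a small grid (0.05–0.25 gDW/mmol) and integer-ish coefficients
so reference optima are exact (e.g. yield 0.1 × uptake 10 → μ = 1
exactly). An optional two-reaction loop plants a futile cycle for the L1
check. The six interaction scenarios are engineered so the named category
follows from a hand-solvable LP (documented in the scenario docstrings);
scenario media place tier limits an order of magnitude apart. The
five-member demo pool echoes the gut-community structure: two prototrophic
producers, an arginine auxotroph, and two lactobacilli of which one
requires both arginine and a cell-wall precursor secreted only by the
other — reproducing the coculture-rescue cascade. Random pools plant
auxotrophy/secretion wiring with a recorded ground truth for
recovery tests.

What the generator does **not** emulate: genome-scale network topology,
substitutable routes through internal metabolism, maintenance ATP,
secondary metabolites, or realistic uptake kinetics. Passing tests
demonstrate the correctness of the formulation, the solver chain and the
classification logic on networks where ground truth is provable — not
predictive accuracy on real genome-scale reconstructions.

## Problem sizes and reports

The shipped experiment solves 31 communities × 3 media (93 cells, roughly
40–90 LPs per cell including FVA) in well under a minute on one core.
Reports are TSVs with floats at 9 decimal places (byte-reproducible
reruns), plus a JSON summary and a provenance manifest (config hash, solver
version, per-cell status). Cells are cached by config hash; reruns skip
completed cells. `scripts/acceptance.py` recomputes the headline numbers
from scratch — enumeration counts, singleton FBA equivalence, scenario
classification accuracy, futile-cycle removal, lumen-balance residuals,
host-available metabolite counts — and writes them as JSON.

## Limitations

- Pair interactions inside larger communities inherit third-party effects
  by design (comparison is always against monoculture).
- The medoid constraint intentionally biases growth rates ~1e−4 below
  optimum (see above); analyses needing exact optima should read the
  unconstrained solution.
- The L1 polish preserves biomass fluxes but not necessarily every exchange
  total of the input solution; exchanged totals are whatever the minimal-
  flux solution realizes at the same μ and X.
- Whether the medoid floor should bind abundance X_k or biomass formation
  rate μ·X_k is genuinely ambiguous in the method's description; both are
  implemented, rate-binding is the default.
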