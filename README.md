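# symcomm

Steady-state community metabolic modelling for small bacterial consortia —
who grows, who feeds whom, and what is left over for the host.

Given a pool of single-species stoichiometric models (SBML L3+FBC or a
plain JSON dialect) and a set of media, `symcomm` assembles every
sub-community (2ⁿ − 1 for a pool of n), solves each one for its maximum
steady-state community growth rate, and derives the ecology of the result:
pairwise interaction signs, metabolite-use patterns, per-taxon metabolite
richness, and the net metabolites a host could harvest. It was built for
gut-microbiome pools of a handful of species (the motivating system is the
five-member *Drosophila* gut community: *Acetobacter fabarum*, *A.
pomorum*, *A. tropicalis*, *Lactobacillus brevis*, *L. plantarum*) but is
agnostic to the organisms.

## The model

All members of a community share one growth rate μ (the coexistence
condition of steady-state community FBA). With member abundances X_k
(ΣX = 1) and aggregate fluxes V, a community is feasible at μ when

    S·V = 0,   lb_j·X_k ≤ V_j ≤ ub_j·X_k,   V[biomass_k] = μ·X_k,

with species exchanges routed through a shared lumen compartment and
medium-fixed bounds on lumen↔environment exchanges. μmax is found by
bisection on LP feasibility (HiGHS, feasibility tolerance 1e−8). The
canonical per-cell solution then applies flux variability analysis at
99.99 % of μmax, floors each member's biomass formation rate at the medoid
of the FVA growth-rate vectors, re-solves, and finishes with an L1 flux
minimization that removes futile cycles. Pairwise interactions classify the
change in biomass formation rate μ·X_k versus monoculture as competitive
(−,−), parasitic (+,−), mutualistic (+,+), commensal (+,0), amensal (−,0)
or neutral (0,0); metabolite traffic through the lumen classifies as
single-use, co-consumed, cross-fed, single-produced or coproduced. See
`docs/methods.md` for the full formulation and the numerical choices.

## Worked example

Solve the built-in five-member demo pool (31 communities × 3 media) and
inspect a cross-feeding rescue:

```python
import symcomm as sc
from symcomm.pipeline import RunConfig, run_experiment, load_solutions

config = RunConfig(out="demo_run", scenario="five_member_demo", seed=1)
run_experiment(config)
sols = load_solutions(config)["minimal"]

mono_af = sols[frozenset({"AF"})]
pair = sols[frozenset({"AF", "AP"})]
print("AF alone on minimal:", mono_af.mu)
print("AF+AP community mu:", round(pair.mu, 6))
print("AF growth in coculture:", round(pair.growth_rates["AF"], 6))
print("arginine cross-fed:",
      round(pair.species_lumen_flux("AP")["arg_u"], 6))
```

prints

```
AF alone on minimal: 0.0
AF+AP community mu: 1.285714
AF growth in coculture: 0.857143
arginine cross-fed: 0.857143
```

The arginine auxotroph AF cannot grow alone on the minimal medium
(μ = 0); cocultured with the prototroph AP the community grows at
μ = 9/7 ≈ 1.29 h⁻¹, AF forms biomass at 6/7 ≈ 0.86 gDW·h⁻¹, and AP's net
arginine secretion into the shared lumen (0.86 mmol·h⁻¹, one unit per unit
of AF biomass) is exactly the flux that rescues it. The run directory contains
`interactions.tsv`, `use_patterns.tsv`, `use_pattern_frequencies.tsv`,
`richness.tsv`, `host_outputs.tsv`, per-reaction `fluxes.tsv` with FVA
ranges, a `summary.json`, and a provenance `manifest.json`.

The same pipeline runs from the shell:

```sh
symcomm synth --scenario mutualism --out pool/
symcomm run --models pool/manifest.json --media pool/media --out results/
symcomm report --run results/
```

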