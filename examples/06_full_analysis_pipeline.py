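"""Run the four-model-family analysis end to end on a synthetic dataset.

Simulates 60 species with a planted positive life-span effect on C22:6n3
(DHA), assembles the trait table (indices + life history + migration
distances), enumerates the analysis plan for a reduced panel, fits every
model, and prints the results table with significance markers.
"""

from phylofa import (MCMCSettings, SimulationConfig, build_plan,
                     forest_summary, run_plan, simulate_dataset, vcv)
from phylofa.pipeline import assemble_trait_table, expected_chance_significant

ds = simulate_dataset(SimulationConfig(
    n_species=60, seed=7, planted_effects={"C22:6n3": 0.8}))
traits = assemble_trait_table(ds.composition, ds.traits)
cov = vcv(ds.tree, normalize=True)

plan = build_plan(
    traits,
    fa_panel=["C16:0", "C22:6n3"],
    families=["body_mass", "life_span"],
    mcmc=MCMCSettings(chains=2, iterations=2000, burn_in=500, thinning=2),
    seed=21,
)
print(f"plan: {len(plan)} models ({len(plan.skipped)} skipped)")

results = run_plan(plan, traits, cov)
cols = ["response", "model_family", "ame_mean", "ci_low", "ci_high",
        "marker", "rhat_max", "n_species"]
print(forest_summary(results)[cols].round(3).to_string(index=False))
print(f"\nexpected significant by chance at 95%: "
      f"{expected_chance_significant(results):.1f} of {len(plan)} models")
print("The planted DHA-life span row carries a '*' with a positive effect. "
      "Because compositions close to 100 mol%, a strong planted DHA effect "
      "propagates: indices that weight DHA heavily (DBI, PI, ACL, PUFA, the "
      "n-3 ratio) inherit a life-span association, and displaced acids like "
      "C16:0 acquire the opposite sign — exactly the coupling the residual-"
      "correlation analysis of example 05 visualises.")
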