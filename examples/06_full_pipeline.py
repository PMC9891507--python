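"""End-to-end pipeline: simulate -> impute -> z-score -> PLS -> per-trait
Bayesian scan -> category-grouped results and odds effects on disk.
"""

from isorisk import run_pipeline

config = {
    "seed": 21,
    "simulation": {
        "n_participants": 1500,
        "trait_specs": [
            {"name": "tobacco", "kind": "ordinal", "category": "lifestyle", "n_levels": 3},
            {"name": "hearing", "kind": "binary", "category": "physical"},
            {"name": "neuroticism", "kind": "ordinal", "category": "mental", "n_levels": 13},
            {"name": "income", "kind": "ordinal", "category": "societal", "n_levels": 5},
        ],
        "true_beta": {"tobacco": 0.18, "hearing": 0.25, "neuroticism": 0.9, "income": -0.4},
        "true_age_beta": 0.2,
        "true_sex_beta": -0.3,
        "missing_rate": 0.05,
    },
    "impute": "hotdeck",
    "sampler": {"chains": 2, "draws": 500, "warmup": 500},
}

artifacts = run_pipeline(config, out_dir="scratch/pipeline_demo")
print(artifacts["results"].round(3).to_string(index=False))
print(f"\nPLS mode correlations: "
      f"{[round(r, 3) for r in artifacts['pls_summary']['mode_correlations']]}")
for eff in artifacts["effects"][:4]:
    print(eff.describe())
print(f"\nwrote results_table.csv, odds_effects.csv, pls_summary.json, "
      f"barplot_data/ and manifest.json under {artifacts['out_dir']}")
print("Rows are traits grouped by category; per target the posterior mean "
      "and 90% HPDI bounds mirror how population studies tabulate these "
      "associations.")
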