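"""Filter an ASV table, choose a rarefaction depth, estimate diversity.

Shows the taxonomic/singleton filter, the depth grid search, repeated
rarefaction with averaging, Hill numbers and the rare/common log-ratio.
"""
from soilrich import SimulationConfig, simulate_study
from soilrich.community import (
    compute_diversity, filter_taxa, grid_search_depth, repeated_rarefaction,
)

study = simulate_study(SimulationConfig(n_sites=30, species_pool_size=400,
                                        read_depth=3000, seed=2))
table, report = filter_taxa(study.asv_table)
print(f"removed {report['archaea']:.1%} archaea, {report['unassigned']:.1%} unassigned, "
      f"{report['singletons']:.1%} singletons")

gs = grid_search_depth(table, depths=[500, 1000, 1500, 2000, 2500])
print(f"grid search selected depth {gs.depth} "
      f"(trade-off of samples kept vs reads per sample)")

avg = repeated_rarefaction(table, gs.depth, reps=50, seed=2)
div = compute_diversity(avg)
print(div[["richness", "hill_1", "hill_2", "n_rare", "n_common", "log_ratio"]]
      .head(5).round(2))
print("hill_1/hill_2 weight abundant taxa more; log_ratio > 0 means rare taxa outnumber common ones")
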