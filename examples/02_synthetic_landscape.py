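"""Generate a synthetic remeasured-inventory landscape and inspect it.

The generator produces paired plot censuses (roughly a decade apart) whose
stand structure follows known power-law size-density frontiers, with
disturbance flags, stratum weights and areal labels — everything the
downstream estimators need, plus the generating truth to validate against.
"""

import foreststab as fs

config = fs.LandscapeConfig(seed=42, n_plots=300)
censuses, truth = fs.generate_landscape(config)

pairs, excluded = fs.filter_change_analysis(censuses)
training, train_excl = fs.filter_frontier_training(censuses)
print(f"censuses: {len(censuses)}  change pairs: {len(pairs)}  "
      f"frontier-training stands: {len(training)}")
reasons = {}
for r in train_excl.values():
    reasons[r] = reasons.get(r, 0) + 1
print(f"training exclusions by reason: {reasons}")

pt = truth.plot_table
print(f"\nfraction of stands above their type's frontier: "
      f"{pt['above_frontier'].mean():.3f} (target {config.exceedance})")
print(f"disturbed plots: fire {pt['fire_flag'].mean():.2%}, "
      f"insect {pt['insect_flag'].mean():.2%}, "
      f"disease {pt['disease_flag'].mean():.2%} of plots per interval")

pop = truth.population_table
print("\nrealised per-species change (truth):")
for sp, sub in pop.groupby("species"):
    pct = 100 * sub["fsi"].mean() / sub["rd_t1"].mean()
    print(f"  species {sp}: mean RD(t1) {sub['rd_t1'].mean():.3f}, "
          f"true %FSI {pct:+.2f} %/yr on {len(sub)} plot populations")
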