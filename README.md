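# stratodyn

Quantitative tools for fossil diversity dynamics and the sedimentary rock
record across the Ediacaran–Cambrian transition (~580–510 Ma), built for
paleobiologists who work with age-calibrated, genus-level range
compilations rather than full occurrence databases.

The package implements, as a tested library with a command-line front end:

* **Monte Carlo age resampling** — each fossil occurrence carries a
  permitted age interval and an uncertainty category 1–4; category-1
  records keep their full range, categories 2–4 receive one uniform draw
  per occurrence, and a taxon's realized range is the envelope of its
  records. Replicate datasets stream from a master seed.
* **Moving-window diversity dynamics** — range-through genus richness and
  Foote per-capita origination/extinction rates
  (`p = ln((N_bt+N_Ft)/N_bt)/Δt`, `q = ln((N_bt+N_bL)/N_bt)/Δt`) on
  100-ka-stepped windows (label 570.5 ⇒ 570.9–570.0 Ma), with
  mean/min/max aggregation across replicates and genus-density
  normalization against rock quantities.
* **Rock-record flux budgeting** — unit volume = area × mean thickness,
  spread uniformly over the unit's age span into 50-ka bins; lithofacies
  percentages of the marine nonevaporitic record; presence/absence
  depositional area and nondeposition fraction; leave-one-region-out
  sensitivity filters.
* **Sampling intensity** — maximum-possible counts of fossiliferous
  surfaces per window, split by age-constraint quality.
* **Correlation suite** — Spearman's ρ (tied ranks, t-approximation
  p-values) on raw and first-differenced window series; 10-point moving
  mean/minimum smoothing and pairing of δ¹³C_carb / δ²³⁸U_carb series.
* **Synthetic data generator** — four-assemblage taxon ranges, regional
  rock stacks with hiatuses, fossiliferous surfaces, and antithetic
  isotope series, all with a ground-truth record for parameter-recovery
  testing.

See `docs/methods.md` for models, conventions, and limitations.

## Worked example

```python
import stratodyn as st
from stratodyn import synthetic_data as sd, pipeline as pl

cfg = sd.SyntheticConfig(master_seed=1)          # default study conditions
occ, truth = sd.generate_occurrences(cfg)        # 332 genera, 4 assemblages
units = sd.generate_rock_record(cfg)             # 24 regions, 50-ka flux atoms
surfaces = sd.generate_surfaces(cfg, occ)
geochem, _ = sd.generate_geochem(cfg)

res = pl.run_pipeline(occ, units, surfaces=surfaces, geochem=geochem,
                      n_replicates=100, master_seed=2)

row = res.correlations.query(
    "predictor == 'sampling_intensity' and subset.str.startswith('pre-BACE')"
).iloc[0]
print(f"pre-BACE richness vs sampling intensity: rho={row.rho:.2f}, n={row.n}")

geo = res.geochem_correlations.query(
    "pairing == 'moving_mean_vs_mean' and mode == 'raw'"
).iloc[0]
print(f"d13C vs d238U (10-pt moving means):      rho={geo.rho:.2f}, n={geo.n}")
```

Output:

```
pre-BACE richness vs sampling intensity: rho=0.52, n=447
d13C vs d238U (10-pt moving means):      rho=-0.66, n=617
```

The first number says that, older than the 535-Ma cutoff, mean
reconstructed genus richness rises and falls with the number of sampled
fossiliferous surfaces — sampling effort, not just rock availability,
shapes the Ediacaran diversity signal. The second shows the built-in
antithetic relationship between the carbon-isotope curve and the uranium
redox proxy being recovered through the smoothing-and-pairing machinery at
roughly the target strength (−0.7).

The same pipeline runs from the shell over tidy TSV/CSV tables:

```sh
stratodyn simulate --config config.yaml --out data/
stratodyn run      --config config.yaml --out results/
```

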