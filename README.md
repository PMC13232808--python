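# nichekit

Ensemble species distribution modelling (SDM) and niche-change analysis for
raster landscapes, with a virtual-species simulator that provides known
ground truth for validating every stage.

## The problem

Projecting how a species' suitable habitat shifts under climate change is a
standard workflow in biogeography: relate presence records to environmental
predictor rasters, combine several statistical learners into an ensemble,
threshold the predicted suitability into a binary range map, and summarize
how that range moves and shrinks under scenario climates. `nichekit`
implements that chain end to end for users who need a reproducible, scriptable
version of the classic presence/pseudo-absence ensemble protocol:

1. **Predictor screening** — aligned GeoTIFF layers are stacked on one grid
   with a shared validity mask; pairwise Pearson screening greedily drops one
   member of every pair with |r| ≥ 0.7.
2. **Occurrence formatting** — records are deduplicated to one per grid cell,
   optionally capped by uniform subsampling (default 500), and complemented by
   1,000 pseudo-absence cells drawn uniformly from the study area.
3. **Ensemble modelling** — six member families (GBM, RF, ANN, MARS, GAM,
   CTA) are evaluated by repeated 70/30 calibration/evaluation splits
   (3 replicates) using Cohen's Kappa, the True Skill Statistic
   TSS = sensitivity + specificity − 1, and the rank-based AUC. Members with
   mean AUC ≥ 0.7 are combined into an AUC-weighted mean (EMwmean),
   a coefficient of variation (EMcv) and confidence-interval bounds (EMci);
   variable importance is permutation based (1 − correlation of EMwmean
   predictions after shuffling one predictor).
4. **Change statistics** — suitability maps are binarized at the
   TSS-maximizing threshold; the Range Change Index
   RCI = (S_colonization − S_extinction) / S_present × 100
   (−100 = complete loss), Schoener's D overlap
   D = 1 − ½ Σ|pᵢ − qᵢ| between normalized maps, median (outlier-robust)
   centroid positions in longitude/latitude/elevation, per-cell species
   richness SR and its change ΔSR, and occurrence frequencies across
   categorical zones.

Because real occurrence archives and full-resolution climate rasters are
rarely redistributable, the `synthetic` module generates spatially
autocorrelated virtual landscapes and virtual species whose true suitability
is a known closed-form response, so the whole pipeline can be tested against
constructed truth (known RCI, known poleward shifts, known driving variable).

## Worked example

```python
import nichekit as nk
from nichekit.synthetic import benchmark_scene, ScenarioDelta, apply_scenario

# strong-signal virtual specialist on a 100x100 landscape with a
# temperature-like (southward-increasing) driving layer
stack, vs = benchmark_scene(seed=3, gradient=1.5)
occ = nk.sample_occurrences(vs, 200, seed=13)
occ = nk.dedupe_to_grid(occ, stack.grid, stack.mask)
pa = nk.sample_pseudo_absences(stack, occ, n=1000, seed=23)
table = nk.build_modeling_table(stack, occ, pa)

ens = nk.build_ensemble(table, tags=("RF", "GBM", "CTA"), seed=33)
print("member AUCs:", {m.learner_tag: round(m.mean_auc, 3) for m in ens.members})
print("TSS-max threshold:", round(ens.threshold, 3))

warming = ScenarioDelta({"env1": 0.6}, "warming")
future = apply_scenario(stack, warming)
base_b = nk.binarize(nk.project(ens, stack), ens.threshold)
fut_b = nk.binarize(nk.project(ens, future), ens.threshold)

summary = nk.range_change(base_b, fut_b)
print(f"RCI: {summary.rci:.1f}  (truth: {nk.truth_change(vs, stack, future, ens.threshold).rci:.1f})")
c0, c1 = nk.centroid(base_b), nk.centroid(fut_b)
print(f"median centroid northing: {c0.median_lat/1000:.1f} km -> {c1.median_lat/1000:.1f} km")
```

Output:

```
member AUCs: {'RF': 0.887, 'GBM': 0.875, 'CTA': 0.858}
TSS-max threshold: 0.152
RCI: 6.0  (truth: 8.1)
median centroid northing: -15.4 km -> -12.1 km
```

All three members clear the AUC ≥ 0.7 gate; the pooled held-out TSS-max
cutoff (0.152) binarizes the maps. Under the +0.6 standardized-unit warming
the estimated range change (+6.0) tracks the constructed truth (+8.1), and the
suitable range's median centroid moves ~3 km poleward, as the built-in
south-north gradient of the driving layer guarantees it must.

## Command line

The `nichekit` console script runs each stage, or the full chain, from one
YAML configuration:

```bash
nichekit simulate --out demo --seed 1          # synthetic worked example
nichekit run --config config.yaml              # screen→fit→project→change→overlap→report
nichekit fit --config config.yaml              # any single stage in isolation
```

Every artifact (metrics, importances, suitability/binary GeoTIFFs, change
summaries, overlap matrices, richness/ΔSR maps) is listed with SHA-256 hashes
in `report/manifest.json`; two runs with the same master seed are
byte-identical.

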