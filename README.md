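# nanocorona

Quantification of nanomaterial protein-corona evolution from two imaging
arms: two-color single-molecule localization microscopy (dSTORM) and
correlative reflectance/fluorescence confocal microscopy.

## The problem

When engineered nanomaterials (here TiO₂ agglomerates with different polymer
coatings) enter serum, they acquire a *protein corona* — an adsorbed layer of
biomolecules that governs their cellular uptake, trafficking and fate.  After
internalization the corona can be lost, degraded, or *exchanged* for
intracellular proteins.  Tracking that evolution requires quantitative image
analysis at two scales:

* **SMLM arm.**  Localization tables (one fluorophore detection per row, nm
  coordinates) from two-color dSTORM, where channel 1 labels the initial
  corona and channel 2 the secondary (exchanged) protein population.  The
  chain is: a density filter (keep localizations with ≥ 15 neighbors within
  200 nm) to suppress diffuse background → per-channel DBSCAN, with the
  `minPts` parameter selected by sweeping 3…100 (values < d + 1 rejected) and
  scoring each labeling with a between/within variance ratio
  (Calinski–Harabasz type, B/(k−1) ÷ W/(n−k) over non-noise points) → an
  alpha-shape concave hull per cluster (Delaunay simplices with circumradius
  ≤ α) giving cluster area/volume, molecular density n/measure and
  equivalent diameter → cross-channel merging of clusters into corona
  objects classified *initial* / *exchanged* / *mixed* by their channel-1
  fraction, plus radial core–shell profiles (core diameter = 2·r₉₀ of the
  core channel).

* **Confocal arm.**  Four-channel images (cell trace, corona fluorophore,
  label-free reflectance, lysosome marker).  The cell interior is segmented
  (Otsu + hole filling), reflectance spots are labelled inside it, corona
  intensity is measured **only on spots** (separating corona from unbound
  label), and lysosomal co-localization (spot∩lysosome area fraction),
  reflectance area and agglomerate equivalent diameter are reported per time
  point.  Time courses are normalized to percent change between subsequent
  points, Δ%ₜ = 100·(vₜ − vₜ₋₁)/vₜ₋₁ with the log transform ln(vₜ/vₜ₋₁),
  and compared with a balanced two-way ANOVA (material × time).

Because no localization or image data accompany the study design, a
first-class synthetic-data module generates ground-truthed scenes for both
arms: lognormal agglomerate sizes per coating preset (354–6676 nm means),
geometric fluorophore blinking over 20 000 frames, Gaussian localization
precision, Poisson background, a 350/600 nm two-channel core–shell geometry,
and confocal scenes whose corona retention, lysosome overlap and spot sizes
follow per-coating presets.

## Worked example

```bash
python examples/smlm_clustering.py
```

```
simulated 2739 localizations in 5 clusters
density filter kept 2534/2739 localizations
ch1: chose min_pts=3, found k=5 clusters, median area 0.0922 um^2, median density 3254 um^-2
ch2: chose min_pts=79, found k=4 clusters, median area 0.0776 um^2, median density 2322 um^-2
```

Five PVP-size agglomerates (354 ± 66 nm) were planted with a 70 % initial-
corona label fraction; the sweep recovers all five channel-1 clusters, and
the alpha-shape areas (~0.08–0.09 µm²) match objects a few hundred nm
across.  The other examples show corona-object classification
(`corona_composition.py` recovers planted initial/exchanged/mixed counts
3/4/3), the 3D core–shell radial profile (`shell_profile.py` estimates a
336.5 nm core against the 337.9 nm closed form), and the confocal time
course (`confocal_timecourse.py` measures cumulative corona decreases of
43.1 / 60.9 / 4.9 / 0.6 % for uncoated / PVP / F127 / AA4040 with lysosomal
co-localization between 42 and 60 %).

A thin CLI wraps the same functions:

```bash
nanocorona simulate-smlm --seed 1 --out scene/
nanocorona cluster --in scene/localizations.csv --eps 200 --out clustered/
nanocorona run --config run.json --seed 1 --out results/
```

## Layout

```
src/nanocorona/
  synth.py      ground-truthed SMLM scene generator (+ coating presets)
  io.py         localization CSV / report TSV dialects
  cluster.py    density filter, DBSCAN, variance-ratio min-points sweep
  geometry.py   alpha shapes, cluster stats, composition, radial profiles
  confocal.py   confocal scenes, segmentation, spot metrics, ANOVA
  pipeline.py   end-to-end orchestration with manifests
  cli.py        command-line interface
docs/methods.md   model and parameter documentation
examples/         one narrative script per capability
```
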