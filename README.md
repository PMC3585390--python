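# isletnet

Functional-connectivity analysis of beta cells in pancreatic islets of
Langerhans, from multicellular calcium-imaging time series.

Beta cells are electrically coupled through gap junctions and synchronize
their cytosolic Ca²⁺ dynamics when stimulated with glucose. Given
fluorescence traces of many ROIs (cells) recorded across a glucose step
protocol — low glucose (LG1), activation (ON), sustained high-glucose
activity (HG), deactivation (OFF), and low glucose again (LG2) — this
package

- conditions the traces (photobleaching correction by a linear + exponential
  baseline fit, F/F₀ normalization, unit rescale) and classifies beta cells
  by their regime-specific response;
- builds **functional networks**: cells *i, j* are connected when the Pearson
  correlation *R*<sub>ij</sub> of their signals over a window exceeds a
  positive threshold *R*<sub>th</sub> (default 0.75), with the significance
  cutoff *R*<sub>crit</sub> = *t*<sub>c</sub>/√(n−2+*t*<sub>c</sub>²) from
  the two-tailed t test at df = n−2;
- characterizes the networks: average degree *k*<sub>avg</sub>, clustering
  coefficient *C*<sub>avg</sub>, global efficiency *E*<sub>glob</sub> (mean
  inverse shortest-path length), a matched G(n, m) random-graph reference
  (*C*<sub>rand</sub>, *E*<sub>rand</sub>), and the small-world-ness
  **S = (C<sub>avg</sub>/C<sub>rand</sub>) / (E<sub>rand</sub>/E<sub>glob</sub>)**;
- fits the pooled cumulative degree distribution *G(k)* with a power law, an
  exponential, and an exponentially truncated power law (broad-scale test);
- relates connectivity to geometry: distance–correlation 2-D histograms,
  distance-binned average correlation, hub link lengths, clustering vs. link
  length;
- tracks network evolution with sliding correlation windows;
- aggregates multi-islet studies: per-regime medians and ranges, Friedman
  ANOVA plus paired Wilcoxon signed-rank tests with Bonferroni correction.

Because raw recordings of this kind are rarely shared, the package includes a
**synthetic-data generator** that emulates islet calcium dynamics — quiescent
baselines, per-cell activation delays, plateau oscillations phase-lagged by a
traveling calcium wave, peripheral non-beta cells oscillating in low glucose,
photobleaching and imaging noise — so the entire pipeline runs and is
validated with no external data.

## Worked example

```python
import isletnet as isl

params = isl.SimParams(n_cells=60, seed=1)         # one synthetic islet
traces, geom = isl.simulate_islet(params)

model = isl.IsletFunctionalConnectivity(traces, geom.cells)  # R_th = 0.75
res = model.fit(seed=0)
print(res.summary())
```

```
Islet functional connectivity
================================================================
cells traced: 60   beta: 54   R_th: 0.75

         r_avg    k_avg   c_avg  e_glob  c_rand  e_rand  clustering_ratio  efficiency_ratio       s  mean_link_length_um  hub_link_length_um
regime
LG1     0.0624   0.5556  0.1111  0.0105  0.0000  0.0143               NaN               NaN     NaN              76.5519             76.5519
ON      0.8924  51.8889  0.9814  0.9895     NaN     NaN               NaN               NaN     NaN              92.8945             90.0121
HG      0.3736  11.5926  0.7110  0.4776  0.2186  0.5994            3.2526            1.2551  2.5915              70.4455             78.9621
OFF     0.9388  53.0000  1.0000  1.0000     NaN     NaN               NaN               NaN     NaN              93.4428             93.1411
LG2     0.0514   0.2963  0.0802  0.0063  0.0000  0.0064               NaN               NaN     NaN              74.9384             74.9384
```

Reading the table: 54 of 60 ROIs classified as beta cells. The driven
transients (ON, OFF) are nearly globally synchronized (*r*<sub>avg</sub> ≈
0.9, near-complete graphs), the high-glucose plateau is intermediate
(*r*<sub>avg</sub> = 0.37) with a sparse, spatially clustered network whose
clustering exceeds the random reference 3.3-fold at comparable integration —
small-world-ness S = 2.59 — while the low-glucose regimes are weakly
correlated with almost empty networks (their ratios are undefined when the
random reference has no triangles, reported as NaN rather than infinities).

Multi-islet studies follow the same pattern:

```python
study = isl.IsletStudy.simulate(n_islets=9, seed=1)
out = study.fit(seed=1)
print(out.summary())          # medians, Friedman/Wilcoxon table, degree fits
out.save("study_output")      # summary.csv, table1.csv, stats.csv, degree_fits.csv
```

A `isletnet` console command wraps the same steps
(`simulate` / `analyze` / `study` / `report`).

## Layout

- `isletnet.simulate` — synthetic geometries and traces, fixture I/O
- `isletnet.preprocess` — bleach correction, F/F₀, unit rescale, classifier
- `isletnet.network` — correlation matrices, significance cutoff, thresholded
  graphs, sliding windows
- `isletnet.graphmetrics` — clustering, efficiency, random reference,
  small-world-ness, degree-distribution fits
- `isletnet.spatial` — distance-resolved analyses
- `isletnet.model` — `IsletFunctionalConnectivity` / `IsletStudy` model
  objects and their results
- `docs/methods.md` — model assumptions, parameter choices, limitations
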