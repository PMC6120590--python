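# oct4lineage

Single-cell lineage analysis of OCT4 inheritance and fate
predetermination in human embryonic stem cells (hESCs).

When hESCs receive a differentiation stimulus (BMP4), each cell either
self-renews (staying OCT4⁺/CDX2⁻) or differentiates (OCT4⁻/CDX2⁺).
Time-lapse tracking of an endogenous OCT4 reporter shows this decision
is largely set *before* the stimulus arrives: OCT4 levels are
heritable from mother to daughter, are asymmetrically partitioned at
division, and predict the eventual fate of a cell's progeny.  This
package implements that analysis as a reusable pipeline for anyone
working with tracked single-cell fluorescence lineages:

* **lineage core** — validated lineage forests from delimited track
  tables (cell id, parent id, frame, time, mean nuclear intensity),
  per-cell summaries, kinship queries (sister / cousin / second
  cousin, division distance);
* **pulse detection** — peaks with prominence ≥ 200 a.f.u. and width
  ≥ 15 min at half-prominence (findpeaks semantics);
* **fate classification** — two-component Gaussian mixture over
  endpoint (OCT4, CDX2) intensities; cells called only at posterior
  `p_diff < 0.01` or `> 0.99`; pro-fate labels back-propagated through
  the lineage (pro-self / pro-differentiated / pro-mixed);
* **fate prediction** — binomial GLM (logit link) on pre-stimulus
  mean OCT4, pulse frequency and cycle duration, with stratified
  5-fold cross-validation, Wald p-values, KS group comparisons and
  decision-surface slices;
* **inheritance analysis** — kinship |ΔOCT4| with a random-pair
  baseline, sister partition ratios (38%/12%/3% of divisions at least
  as extreme as 5:6 / 3:4 / 1:2), DAPI-vs-OCT4 ratio densities,
  protein half-life math (t½ = 7.34 h ⇒ 99.22% maternal at 5 min),
  mother–daughter traces aligned at division with the R² curve
  against the level at +8 h (maternal / inherited / autonomous
  periods), the sister-resampling estimate of the asymmetric-division
  contribution, rank-mixing trajectories and the autocorrelation
  mixing time;
* **synthetic data** — a seeded branching-lineage generator with
  heritable setpoints, 7.34 h turnover, pulses, calibrated partition
  asymmetry and post-stimulus bimodal endpoints, providing ground
  truth for every stage;
* **pipeline/CLI** — `oct4lineage all config.yaml` runs everything and
  writes tables, fit reports, curves and a manifest.

The model at the core of the variance decomposition: each aligned time
point t contributes R²(t) = corr(X(t), X_final)², where X(t) is the
(15-min smoothed) level on the mother branch (t < 0) or daughter
branch (t ≥ 0) and X_final is the daughter level at +8 h.  Maternal
levels explain a flat plateau of the final variance; the curve jumps
within the first hour after division — the inherited period, when
> 95% of the protein is still maternal (100·(1/2)^(t/t½) = 95.4% at
30 min) — and rises to R² = 1 by construction at +8 h.

## Worked example

```python
from oct4lineage.pipeline import run_pipeline, report

out = run_pipeline({"seed": 1, "output_dir": "runs/demo"})
print(report(out))
```

prints

```
OCT4 lineage analysis report
================================
pro-fate fractions: pro_self=0.75, pro_diff=0.16, pro_mixed=0.09
sister fate concordance: 0.959
classifier CV accuracy: 0.932
coefficient p-values: mean_oct4=2.91e-03, pulse_frequency=8.98e-02, cycle_duration=1.23e-01
group KS tests: 2/9 significant
sister-ratio extremity: >= 5:6: 0.400, >= 3:4: 0.113, >= 1:2: 0.029
R2 landmarks: maternal 0.540, +1 h 0.802, final 1.0
mixing time: 1.25 h (9% of a cycle)
maternal fraction: 99.22% at 5 min, 95.39% at 30 min
```

Reading this: the simulated differentiation run produced mostly
pro-self lineages with a small pro-mixed fraction; sisters almost
always chose the same fate; the logistic model predicts pro-fate from
pre-stimulus features well above the class baseline, with mean OCT4
level the most significant predictor and cycle duration not
significant; 40% of simulated divisions were at least as asymmetric as
5:6 (matching the generator's calibration targets of 38/12/3%); and
the variance-explained curve rises from its maternal plateau to 0.80
within one hour of division, reaching identity at the +8 h endpoint.
The same stages run on your own data by pointing the config at track
tables instead of the simulator:

```yaml
# config.yaml
seed: 7
inputs:
  stimulus_track_table: tracks_bmp4.csv     # cell_id,parent_id,frame,time_min,level_afu
  endpoint_table: endpoints.csv             # cell_id,oct4_afu,cdx2_afu
  undisturbed_track_table: tracks_72h.csv
stimulus_time_min: 2520
```

```sh
oct4lineage all config.yaml --out runs/mydata
oct4lineage report runs/mydata
```

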