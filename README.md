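# axotrace

Quantification of **anterograde and retrograde axonal transport in the mouse
retinocollicular projection**, for dual-tracer experiments in glaucoma models:
cholera toxin subunit B (CTB) injected into the eye reports anterograde
transport into the superior colliculus (SC), FluoroGold (FG) injected over the
SC reports retrograde transport back to retinal ganglion cell (RGC) somata,
and ERRβ immunolabel reports structural persistence of the projection. The
unit of analysis is the *projection*: one eye together with its contralateral
colliculus.

The package is aimed at visual-neuroscience labs that image whole-mount
retinas and serial SC sections and need a reproducible, scriptable
quantification chain plus a way to validate it — every stage can be exercised
on synthetic phantoms with seeded ground truth.

## What it computes

**Retina (retrograde).** FG-labeled somata are detected by a robust pipeline
(large-median background correction; Gaussian smoothing; threshold at local
background + *k*·1.4826·MAD; 8-connected labeling; watershed separation of
touching somata; size 15–300 µm², circularity ≥ 0.4 and edge filters),
giving

- density = *N*<sub>cells</sub> / retina area (cells/mm²), and
- **percent area intact** = 100 · (*A* − Σ*A*<sub>dropout</sub>) / *A*, where
  dropout regions are 8-connected groups of 100-µm tiles containing no
  detected centroid, kept when larger than 0.05 mm² — capturing the
  wedge-shaped ("sectorial") label loss characteristic of glaucomatous
  degeneration.

**Colliculus (anterograde / structural).** Per section, a pixel is labeled iff
brighter than mean + *k*·SD of a non-retinorecipient reference region
(*k* = 2 by default). The retinorecipient outline is split into mediolateral
bins; each bin reports its fraction of labeled pixels; stacked sections give
the retinotopic map rendered 0 % (blue) → 100 % (red); and the
whole-structure **percent area fraction intact** is the pooled labeled-pixel
fraction over all sections.

**Statistics.** 3 (label: CTB, FG, ERRβ) × 5 (group: D2G, D3, D9-10, D11-12,
D13) between-subjects factorial ANOVA with Type II sums of squares, protected
Fisher's LSD post-hoc tests, within-projection paired *t*-tests, Pearson
correlation, and unity-line deviation analysis with an exact binomial sign
test.

**Phantoms.** `axotrace.phantoms` renders whole-mount retina montages
(disc mask with radial relieving cuts, Gaussian-profile somata, sectorial
dropout wedges), serial SC stacks (superficial labeled band with mediolateral
deficit spans), and measure-level cohorts — all with ground truth, all
bit-reproducible from a single seed.

## Worked example

```python
from axotrace import phantoms as ph, retina as rq, stats as st

# a retina with a seeded 25% sectorial dropout wedge
spec = ph.RetinaPhantomSpec(dropout_wedges=((120.0, 45.0),), n_cells=1500)
image, truth = ph.generate_retina_phantom(spec, seed=7)
result, cells = rq.analyze_retina(image)

# a five-group cohort patterned on the dual-tracer study design
cohort = ph.generate_cohort(ph.CohortSpec.default_study(), seed=7)
anova = st.factorial_anova(st.cohort_to_long(cohort))
r, p = st.pearson_r(cohort.fg_density, cohort.fg_intact_pct)
u = st.unity_deviation(cohort.fg_intact_pct, cohort.ctb_intact_pct)
```

prints (via the obvious format calls):

```
true intact 75.0%  true density 985/mm^2
detected 1500 cells over 1.52 mm^2 -> 985 cells/mm^2, 79.5% area intact
label x group: F(8, 90) = 29.55, p = 4.47e-22
FG density vs %intact: r = 0.98, p = 4.3e-26
CTB below unity line: 24/33, sign test p = 0.014
```

The detector recovers all 1500 seeded somata exactly; the tile-occupancy
statistic reads the 25 % wedge as 79.5 % intact (tile discretization at the
wedge border accounts for the gap to the geometric 75 %); the seeded
label × group interaction (anterograde collapse preceding retrograde loss)
is detected, and most projections fall below the CTB-vs-FG unity line.

The same stages are available from the shell:

```sh
axotrace simulate study --n-per-group 2 --seed 1 --out study/
axotrace pipeline run --manifest study/manifest.csv --out results/
axotrace quant retina --image r.tif --mask m.tif --pixel-size-um 1.5 --out out/
axotrace quant sc --manifest sections.csv --channel ctb --render --out out/
axotrace stats run --cohort cohort.csv --out out/
```

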