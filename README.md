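# petalvision

Petal spectral phenotyping and insect color-space modelling for
ozone-exposure experiments.

Tropospheric ozone damages more than leaves: in open-top-chamber (OTC)
fumigation studies on the endangered Mediterranean herb *Erodium
paularense*, ozone changed petal reflectance, the anthocyanin content of
petals, and petal size — all traits that pollinators use to find
flowers. `petalvision` packages the quantitative machinery such a study
needs, end to end, for anyone analysing flower reflectance under
environmental treatments:

* **Spectra** — reading, validating, resampling (1 nm), trimming and
  averaging relative-reflectance spectra (white reference = 1),
  plus the 325–600 nm peak-height metric.
* **Pigment index** — the anthocyanin reflectance index
  `ARI = (R800/R550) − (R800/R700)`, scale-invariant and computed on
  point wavelengths.
* **Pollinator vision** — quantum catches `Q = ∫ R(λ) S(λ) I(λ) dλ`
  under a D65 illuminant with von Kries adaptation to a green-foliage
  background (`q = Q/Q_background`), mapped into the bee color hexagon
  (`E = q/(q+1)`), the fly categorical space (quadrants of
  `q_{R7p}−q_{R8p}` vs `q_{R7y}−q_{R8y}`) and the butterfly tetrahedron
  (relative catches of u/s/m/l receptors). Receptor sensitivities come
  from the Govardovskii A1 pigment template, so every λmax is plain
  configuration.
* **Perceptibility** — discrimination rules per guild: quadrant change
  (fly), 0.09 hexagon-unit Euclidean distance (bee), 0.03 on the UV
  relative-catch axis (butterfly), with group-level summaries against a
  control treatment.
* **Statistics** — Bray–Curtis + PERMANOVA (pseudo-F, seeded or exact
  permutation p), one-way ANOVA/ANCOVA, planned single-df contrasts
  (orthogonal-polynomial and mean-based codings), and an ML
  random-intercept model with AIC selection against the fixed-only fit.
* **Exposure** — AOT40 (accumulated excess over 40 nL L⁻¹ in the
  07–15 h window), window/daily means, filtration efficiency, chamber
  microclimate deltas and Magnus-formula VPD.
* **Synthetic data** — a calibrated generator of anthocyanin-type petal
  spectra, petal areas and hourly O₃ series with treatment effects,
  plant-level variation and reproducible seeding, so the entire pipeline
  is testable without instrument files.

## Worked example

Simulate a field-design-sized dataset (three ozone treatments, two
plants each, nine petals per plant), compute pigment indices, and test
the planned "linear increase" contrast on peak height:

```python
import numpy as np
from petalvision.spectra import make_grid, resample
from petalvision.synthetic_data import SimConfig, simulate_dataset
from petalvision.pigment_indices import index_table
from petalvision.stats import contrast_test, named_contrast

sset, meta = simulate_dataset(SimConfig(treatments=("CFA", "NFA", "FU+"), seed=1))
idx = index_table(sset.map(lambda sp: resample(sp, make_grid(325, 1075))))
print(idx.groupby("treatment")[["ari", "peak_height_325_600"]].mean().round(3))

res = contrast_test(idx["peak_height_325_600"].to_numpy(),
                    idx["treatment"].to_numpy(),
                    named_contrast("linear_increase"))
print(f"linear increase in peak height: F(1,{res.df2}) = {res.f:.2f}, p = {res.p:.4f}")
```

prints

```
             ari  peak_height_325_600
treatment
CFA        2.959                0.512
FU+        2.951                0.568
NFA        4.522                0.568
linear increase in peak height: F(1,51) = 169.07, p = 0.0000
```

Reading the output: mean ARI is elevated in NFA only (the configured
non-linear anthocyanin response — CFA and FU+ sit near 2.96, NFA near
4.5), while overall reflectance, and with it the 325–600 nm peak height,
rises with exposure (0.512 → 0.568), which the single-df contrast flags
strongly (F(1,51) = 169, p < 10⁻⁴).

The same analyses run from the shell:

```sh
petalvision simulate --out-dir data --seed 1
petalvision indices --in data/spectra.csv --metadata data/metadata.csv --out ari.csv
petalvision vision --guild bee --in data/spectra.csv --metadata data/metadata.csv --out bee.csv
petalvision perceive --guild bee --in bee.csv --control CFA --out perceptible.csv
petalvision exposure --in data/o3_series.csv
petalvision run --config run.yaml      # full pipeline + manifest
```

## Documentation

`docs/methods.md` describes the models, their assumptions, the default
parameter values (and why), what the synthetic generator does and does
not emulate, and the package's numerical choices.
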