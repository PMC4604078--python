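# dystromorph

Quantitative measurement pipeline for preclinical muscular-dystrophy
studies in the *mdx* (dystrophin-null) mouse model: muscle-fiber
morphometry, immunofluorescence and trichrome quantification, micro-CT
trabecular bone morphometry, qPCR / RNA-Seq expression summarization,
behavioral and force assay metrics, and the statistical decision procedure
that turns group measurements into the p values reported in figures.

It is written for researchers who need the classic semi-automated ImageJ
workflows as reproducible, scriptable, unit-tested code — and for anyone
re-analyzing published dystrophy data who needs to know *exactly* how a
number was produced. Every stage is paired with a seeded synthetic
generator with exact ground truth, so the whole pipeline is verifiable
without access to the original animals or images.

## What it computes

* **Fibers** — from a membrane (collagen-IV) and a nuclei channel: border
  mask (background subtraction → threshold → gap-closing dilation →
  skeleton), per-fiber area and **minimum Feret diameter** (exact rotating
  calipers on the convex hull), centrally nucleated (C/N) classification,
  fiber density, per-class Feret means and histograms.
* **Regions** — thresholded immunopositive-cell counts per mm² with
  field-of-view averaging; IgG-positive and trichrome (blue) area percent;
  revertant-fiber density per mm².
* **Bone** — seeded-region-growing segmentation of μCT volumes; BV/TV,
  Tb.Th and Tb.Sp by maximal-inscribed-sphere local thickness, Tb.N =
  BV/TV / Tb.Th (plate model, per mm).
* **Expression** — geNorm reference-gene stability (M value, iterative
  exclusion), relative expression 2^−ΔΔCt, log z-scoring and Ward
  hierarchical clustering of FPKM matrices.
* **Assays** — novel-object discrimination index
  (100·novel/(novel+familiar)), grip strength (mean of two trials),
  twitch/tetanic force normalized to muscle wet weight (N/g).
* **Stats** — unpaired t, one-way ANOVA + Tukey HSD, Mann–Whitney U
  (W = first-sample rank sum; exact for small tie-free samples),
  Kruskal–Wallis H, Anderson–Darling normality, permutation ANOVA, and the
  decision pipeline that chains them with a recorded decision path and
  {0.05, 0.005, 0.001} star annotations.

## Worked example

Generate a synthetic 100-fiber field with 30 % planted central nucleation,
then measure it:

```python
from dystromorph import fibers, synth

membrane, nuclei, truth = synth.generate_fiber_field(
    100, size_px=(512, 512), pct_central=0.30, seed=42)
cfg = fibers.MorphometryConfig(um_per_px=1.0)
fiber_map, records, summary = fibers.run_morphometry(membrane, nuclei, cfg)
print(f"{summary.n_fibers} fibers, "
      f"{summary.pct_central_nucleated:.1f}% centrally nucleated, "
      f"mean min Feret {summary.mean_min_feret_um:.1f} um")
```

prints

```
100 fibers, 30.0% centrally nucleated, mean min Feret 43.0 um
```

— all 100 tessellated fibers are recovered, the planted 30 % C/N fraction
is classified exactly, and the mean minimum Feret diameter is within the
border width (3 px) of the generator's polygon truth (43.5 µm).

The statistics pipeline on a two-group table:

```python
import numpy as np
from dystromorph import stats

rng = np.random.default_rng(0)
res = stats.decision_pipeline([rng.normal(0, 1, 10), rng.normal(1.5, 1, 10)],
                              stats.DecisionConfig(seed=1))
print(res.statistic_kind, round(res.statistic, 2), round(res.p, 4), res.stars)
```

prints `t -2.53 0.0208 *` — a two-group comparison routes to the unpaired
t test and the p value earns one star under the {0.05, 0.005, 0.001}
scheme.

Each stage is also exposed as a CLI:

```sh
dystromorph simulate fibers --seed 42 --n 100 --out field/
dystromorph fibers --membrane field/membrane.tif --nuclei field/nuclei.tif --out out/
dystromorph bone --volume scan.tif --roi start:100,n:100 --out out/
dystromorph stats --input measurements.csv --seed 1 --out out/
```

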