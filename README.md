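# rgcdegen

Analysis pipeline for functional typing of retinal ganglion cells (RGCs)
during photoreceptor degeneration, with a ground-truth synthetic-cohort
simulator standing in for two-photon recordings.

## The problem

In retinitis pigmentosa models such as the rd10 mouse, rods and then cones
die while the retina's output neurons — the RGCs — survive far longer. The
scientific question is whether that loss of input silences all RGC types
alike or hits some functional types harder. Answering it from population
calcium imaging requires a long chain of quantitative steps, each with its
own conventions and thresholds. This package implements that chain as a
tested, reusable library:

1. **Preprocessing** — Savitzky–Golay detrending (3rd order, 60 s window),
   baseline subtraction, peak normalisation, trigger-aligned snippets.
2. **Responsiveness** — the repeatability quality index
   `QI = Var_t[⟨C⟩_r] / ⟨Var_t[C]⟩_r` on the T×R snippet matrix `C`;
   a cell is responsive if `QI_chirp ≥ 0.35` or `QI_MB ≥ 0.6`.
3. **Direction/orientation selectivity** — SVD tuning curves,
   `DSI = |Σ r_k e^{iθ_k}| / Σ r_k` (doubled angles for OSI), add-one
   permutation tests.
4. **Receptive fields** — spline-basis penalised linear-Gaussian model on
   the clipped calcium gradient,
   `L = (1/T) Σ (ċ − y0 − X S b)² + β|b|₁` with a cubic B-spline tensor
   basis ((10, 12, 9) coefficients on a (32, 20, 15) grid, β = 0.01, Adam,
   lr 0.1), rank-1 SVD split into spatial/temporal components, 2D Gaussian
   fit, 2-SD-ellipse RF size, peak-lag kinetics, quality gates
   (`QI_SVD > 0.5`, `QI_sRF > 0.5`, lag ∈ [0, 0.3] s).
5. **Functional typing** — a nearest-template classifier over 32 groups in
   five super-groups (Off, On–Off, Fast On, Slow On, Uncertain) with a
   confidence score (cells with CS ≥ 0.25 enter type-resolved analyses),
   the On–Off index, and the α-RGC large-soma flag (> 136 µm²).
6. **Cohort statistics** — per-field responsive fractions, relative type
   abundance `log2(f_rd10 / f_wt)` with exact two-tailed binomial tests
   (BH-adjusted, α < 0.01), Mann–Whitney U with rank-biserial effect size
   `rb = 1 − 2U/(n₁n₂)`, Jensen–Shannon divergence between QI
   distributions, Pearson correlation matrices, percent-difference
   summaries.

The synthetic module (`rgcdegen.synthetic_cohort`) simulates recording
fields of 100–120 cells (~60% responsive in wild type) as
linear–nonlinear–calcium encoders with known type, tuning and receptive
field, plus a degeneration schedule that scales responsiveness per
super-group and age. See `docs/methods.md` for the full model description.

## Worked example

```python
from rgcdegen import pipeline

analysis = pipeline.run_cohort_analysis(seed=1, n_fields=8)
print(analysis.responsive_fractions[analysis.responsive_fractions.genotype == "rd10"])
print(" > ".join(analysis.resilience_ranking))
```

prints (seed 1, 8 fields per cohort):

```
  genotype   age      mean        sd  n_fields  n_cells
0     rd10  P180  0.010463  0.010032         8      870
1     rd10   P30  0.427159  0.051002         8      888
2     rd10   P45  0.291122  0.052971         8      879
3     rd10   P90  0.139903  0.029717         8      906
Uncertain > Fast On > Slow On > On-Off > Off
```

The rd10 responsive fraction collapses from ~44% at P30 to under 1% at
P180 while wild-type cohorts stay near 60% (`analysis.responsive_fractions`
holds those rows too), and the measured super-group resilience ranking —
the descending order of mean relative abundance log2(rd10/WT) over
P30–P90 — recovers the order planted in the degeneration schedule:
'Uncertain' cells persist longest, Off cells vanish first.

The same pipeline is scriptable from a shell:

```bash
rgcdegen all --seed 1 --fields 4 --out results/
```

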