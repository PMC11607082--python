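# clonaging

Clonal-tracking analysis of hematopoietic stem cell (HSC) lineage bias and
the onset of immune aging.

Immune aging shows up in peripheral blood as an excess of innate cells
(granulocytes) over adaptive cells (B cells) — a falling **BG ratio**
(population B-cell % ÷ granulocyte %). Individuals of the same
chronological age reach that state at different times. In barcoded
transplantation experiments, each HSC clone carries a heritable DNA
barcode, so its contribution to every blood cell type can be followed for
over a year. `clonaging` implements the quantitative pipeline that turns
such data into an account of *which clones* drive the aging phenotype:

1. **Quantification** — barcode read counts are scaled to population units
   with FACS fractions:
   `abundance_b (%WBC) = (cell type % of WBC) × (donor %) × (GFP %) × reads_b / total reads`
   (for HSCs, `% of all HSCs = donor % × GFP % × reads_b / total reads`).
   Clones exceeding 0.01 %WBC at some time point are tracked.
2. **Lineage bias** — per clone, `Θ = arctan(Gr_norm / B_norm)` on
   abundances normalized by the pre-divergent (9-month) population
   percents, mapped onto a bias axis `[−1, 1]` (+1 myeloid committed,
   −1 lymphoid committed); clones are lymphoid-biased for
   `Θ ∈ [0, π/8]`, myeloid-biased for `Θ ∈ [3π/8, π/2]`, balanced between.
3. **Shift classification** — the pooled absolute bias shifts
   (end − pre-divergent) are modeled by a Gaussian KDE; a Gaussian fitted
   around its highest peak captures lineage-stable clones, and the first
   intersection of the residual with that Gaussian sets the cutoff
   separating **aging** (shift toward myeloid) and **anti-aging** (toward
   lymphoid) clones.
4. **Clonal dynamics** — expansion thresholds from a ranked
   half-of-total-abundance rule, top-clone abundances, persistent /
   exhausted / activated fate labels from presence patterns, change
   counting with a 0.1 %WBC floor, a granulocyte-to-HSC differentiation
   index, and an export for short-time-series clustering.
5. **Aging phenotype** — early vs delayed classification of mice (end BG
   ratio below vs within the cohort's initial range), the four-way
   decomposition of clone-level production changes, and the correlation of
   normalized population changes.
6. **PLSR** — a two-component NIPALS partial least squares regression of
   the end-point BG ratio on five clonal/population predictors, with
   variable-importance-of-projection (VIP) scores.

Because the underlying mouse tables are not public, the package ships a
first-class synthetic-cohort generator (`clonaging.simulate`) that emits
barcode counts, FACS panels, mouse metadata and ground truth with the
statistical structure the analysis assumes — every stage is tested
against it.

## Worked example

```python
from clonaging import (CohortConfig, RunConfig, simulate_cohort, run_pipeline,
                       LineageShiftModel)

counts, panel, mice, truth = simulate_cohort(CohortConfig(seed=1))
report = run_pipeline(RunConfig(seed=1), counts, panel, mice)
print(LineageShiftModel(report.tables["bias_shifts"]).fit().summary())
```

```
Lineage shift classification
============================
clones (included shifts): 1484
KDE bandwidth (Scott):    0.06614
stable Gaussian:          mu=-0.05064 sigma=0.15797 amplitude=4.7612
cutoff |delta bias|:      0.35560
fraction stable:          0.6988
fraction aging:           0.1395
fraction anti-aging:      0.1617
```

About 30% of tracked clones shift their lineage bias beyond the
density-derived cutoff of |Δbias| ≈ 0.36 — the generator's study
conditions place the true shifting fraction at 30%. The PLSR stage of the
same run prints:

```
PLSR of end-point BG ratio
==========================
mice: 18   predictors: 5   components: 2
R^2: 0.9566

predictor             VIP     std. coef
b_clonal_sum_pre      0.621      0.1061
gr_clonal_sum_pre     0.407     -0.2062
bg_ratio_pre          0.111     -0.0466
delta_b_clonal        1.411      0.4481 *
delta_gr_clonal       1.564     -0.5724 *
(* VIP > 1: highly influential)
```

The *changes* in clonal granulocyte and B-cell output dominate (VIP > 1),
while pre-divergent abundance levels carry little influence — the change
in myelopoiesis, not the starting state, determines the end-point BG
ratio.

The same analyses are available from the shell:

```sh
clonaging simulate --out cohort/ --seed 1
clonaging run-all --in cohort/ --out results/
```

which writes per-stage CSV tables plus `summary.json` (machine-readable,
reproducible bit-for-bit for a given seed) and `report.txt`.

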