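# Methods

This note documents the models, thresholds and design choices behind
`clonaging`, and what the synthetic-cohort tests do and do not establish
about real data.

## Units and thresholds

All percentages are stored in percent units (0–100) so the analysis
thresholds can be compared exactly as printed:

| parameter | default | meaning |
|---|---|---|
| `inclusion_threshold_pct_wbc` | 0.01 %WBC | a clone is tracked iff its blood abundance strictly exceeds this at ≥ 1 (time point, blood cell type) |
| `change_floor_pct_wbc` | 0.1 %WBC | per-clone production changes smaller in magnitude are ignored in change counting |
| `b_min` | 0.05 %WBC | B-cell eligibility floor for lineage bias; `gr_min = (initial Gr / initial B) × b_min` per mouse |
| `presence_threshold_pct` | 0.01 %WBC | presence for fate labels (persistent / exhausted / activated) |
| `plsr_components` | 2 | PLSR components (fixed, no cross-validation) |

The tracking filter interprets "at least one time point" per (time point,
blood cell type) pair; HSC abundance never qualifies a clone on its own,
and a removed clone is removed from every compartment so clone identity
sets stay consistent downstream. A pooled-lineage variant is available
(`filter_per_celltype=False`).

## Lineage bias

Normalized abundances divide the clone's %WBC by the population
granulocyte or B-cell percentage at the **pre-divergent** time point for
all time points (a per-time-point variant sits behind
`normalize_at_predivergent=False`). The balance angle uses a two-argument
arctangent, so `B_normalized = 0` yields exactly `π/2` rather than a
division.

The bias statistic is stated to span `[−1, 1]` with +1 myeloid and −1
lymphoid committed, but the raw map `2(θ − π/4)` spans `[−π/2, π/2]`.
The implementation honors the stated semantics with the affine map
`bias = (4/π)θ − 1`; the raw variant is available via
`bias_scale_to_unit=False`. This changes only the scale, not ordering or
category boundaries.

Eligibility uses OR (`gr ≥ gr_min` **or** `b ≥ b_min`), applied to %WBC
abundances with the mouse's initial FACS percents standing in for the
initial cell counts (proportional in a fixed blood draw). A bias shift is
computed when the clone is eligible at both compared time points
(default; `eligibility_both_timepoints=False` relaxes to either).
Ineligible clones are flagged, not dropped.

## Shift classifier

Absolute shifts pooled over all clones and mice (one shared cutoff;
per-group operation is possible by fitting groups separately) are fed to
a Gaussian KDE with Scott's bandwidth (no bandwidth is prescribed by the
procedure; it is configurable). The KDE is **reflected about zero** so no
probability mass leaks to negative |shift| — this keeps the density
normalized on [0, ∞) and the half-normal mode exactly at 0. The grid is
uniform over [0, max shift + 3 bandwidths], 512 points by default.

The lineage-stable Gaussian is fitted by least squares on the window
extending outward from the highest KDE peak while the density is
non-increasing ("around the highest peak" made operational). The cutoff
is the smallest grid value beyond the peak where
`y_changed = max(y0 − y_unchanged, 0)` reaches `y_unchanged`; when the
curves never intersect (the density is essentially pure Gaussian), the
fallback `μ + 3σ` is returned with an explicit flag. A shift exactly at
the cutoff counts as shifting, keeping the stable-Gaussian interpretation
conservative. Positive shifts (toward +1 = myeloid) are *aging* clones,
negative *anti-aging*.

Numerical notes: grid refinement moves the cutoff by less than one coarse
grid step (tested); the cutoff equals an independent brute-force
first-crossing scan exactly on the shared grid.

## Clonal dynamics

The expansion rule reads "half of all the tracked clones" as half of the
summed **abundance** of tracked clones: per mouse, clones are ranked
descending, the minimal prefix with cumulative abundance ≥ half the total
is taken, its lowest member recorded, and the cohort threshold is the
mean of the per-mouse values. Expanded clones strictly exceed the
threshold at the end time point. All rankings break ties by barcode
identifier for determinism.

Fate labels map presence patterns at months 4 / 9 / end: (1,1,1)
persistent, (1,1,0) exhausted, (0,0,1) activated, everything else
"other". The presence floor is not printed anywhere; the tracking floor
(0.01 %WBC) is used and configurable.

The myeloid-differentiation index is the clone's end-point granulocyte
%WBC divided by its end-point HSC abundance — a surrogate ratio chosen
because the quantification underlying the published comparison is built
from exactly these two abundances without a printed formula; clones with
zero HSC abundance are excluded and flagged. The short-time-series export
retains clones whose abundance changes by ≥ 0.01 %WBC between the initial
and some later time point, requires all four time points, and leaves
log-normalization to the downstream clustering tool.

## Aging phenotype

A mouse is *early aging* iff its end-point BG ratio is strictly below the
minimum initial-time-point ratio of the reference cohort; a ratio exactly
at the boundary is *delayed* ("within the range"). The reference cohort
is a parameter so naïve-mouse and transplant analyses can use different
references. The four-way decomposition sums clone deltas sign-partitioned
per lineage (increase/decrease × myeloid/lymphoid) over **all** tracked
clones by default (the 0.1 %WBC floor is available as an option);
"suppressing" categories are the decrease/increase sums compared between
groups, since no further formula is given. Per lineage,
increase-sum + decrease-sum equals the net clonal change exactly.

## PLSR

Classical NIPALS with deflation of both predictor and response blocks,
convergence tolerance 1e-10, ≤ 500 iterations per component. Columns are
centered and scaled to unit variance by default (the VIP convention
assumes it; `scale=False` is available). VIP scores use the standard
weights-and-explained-variance formula; the mean of squared VIPs is 1 by
construction, and VIP > 1 flags influential predictors. The
implementation is cross-checked in tests against an independent SVD-based
PLS (the per-component weight is the dominant left singular vector of
`Xᵀy`) and against scikit-learn, to ≤ 1e-6.

## Synthetic cohort generator

The generator emulates the tabular structure of a barcoded-transplant
study: per-(mouse, time point, cell type) barcode read counts, FACS
panels (cell type % of WBC, donor %, GFP % among donor cells) and mouse
metadata, for time points at 4 (initial), 6 (optional mid), 9
(pre-divergent) and 12/15 (end) months.

Generative model, chosen once as defaults:

- **Sizes** are log-normal (σ = 1), the field-standard heavy-tailed clone
  size distribution; the `expanded` archetype is 4× oversized.
- **Lineage outputs**: granulocyte output ∝ sin θ, B-cell output ∝ cos θ
  of the clone's bias angle. Shifting archetypes change θ while holding
  the B output flat, so aging clones raise and anti-aging clones *reduce*
  granulocyte output — encoding the observed mechanism so
  differentiation-index tests have signal.
- **Archetype mixes**: 9 early + 9 delayed mice, 100 clones each; true
  shifting fraction 0.30 in both groups (aging/anti-aging 0.22/0.08 in
  early, 0.03/0.27 in delayed mice), stable clones jitter their bias with
  sd 0.06, shifting clones move |Δbias| ~ U(0.4, 0.9). Exhausted clones
  (4%) vanish at the end time point, activated clones (5%) appear there.
- **Group coupling**: early mice scale their B-cell end outputs down in
  proportion to their own granulocyte gain (their normalized population
  changes anticorrelate); delayed mice get a small ratio-neutral common
  drift. Both couplings can be disabled, restoring exact B-flatness of
  the anti-aging archetype.
- **Noise**: multinomial sequencing at 50,000 reads per (mouse, time
  point, cell type) and truncated multiplicative FACS noise (relative sd
  0.02). `exact_counts=True` substitutes the analytic infinite-depth
  expectation.

Conservation holds by construction: per (mouse, time point, cell type)
the noiseless FACS percent is derived from the ground-truth clone sums,
so abundances sum exactly to
`celltype % × donor % × GFP % / 10⁴`. Enforcing this requires a
per-lineage rescaling that maps the drawn θ through a fixed monotone
distortion `θ′ = arctan((α/β) tan θ)`; the ground truth records the
implied θ′, which the pipeline recovers to ≤ 1e-9 in the noiseless,
exact-count limit. Shift directions and category memberships are
preserved by monotonicity.

A mouse's ground-truth group is the classification rule applied to its
*noiseless* ratios, not its archetype mix: the mix drives the phenotype
without defining it, so occasionally a delayed-mix mouse is genuinely
early. In the group-recovery test, "≥ 2 noise SD from the threshold"
accounts for noise in both the end ratio and the min-of-initial
threshold (sd = √2 × FACS noise × value each), and the check is verified
to be non-vacuous (~270 of 360 mice unambiguous over 20 seeds).

### What the generator does not emulate

Real barcode libraries have unequal representation, PCR amplification
bias and barcode collisions; real FACS gating errors are not
multiplicative Gaussians; clone trajectories between time points are not
piecewise-constant; T cells and platelets are absent by design. Passing
tests therefore demonstrate that the pipeline's statistics recover the
structure they are defined on — not that the biological conclusions would
survive instrument-specific artifacts absent from this model.

## Problem sizes

Default test problem sizes: 18 mice × 100 clones × 4 time points
(≈ 15k count rows) per cohort; the classifier-recovery mixture uses 2,000
clones; calibration and recovery checks run 10–20 seeded cohorts. These
sizes give stable statistics for every estimator while keeping the whole
suite fast on a single core.
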