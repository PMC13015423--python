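# Methods

This note documents the models and numerical conventions behind each stage of
the pipeline, the synthetic study conditions, and the design choices made
where a convention had to be fixed.

## MMEJ Deletion Footprint

Deletion length is the net allele-length difference (reference minus
alternate). VCF records are split per alternate allele before comparison;
complex substitutions with a longer reference count as deletions of the net
difference; insertions and balanced substitutions are excluded. In MAF
dialect, `Tumor_Seq_Allele2 = "-"` means the whole reference allele is
deleted. The frameshift flag comes from `Variant_Classification`
(`Frame_Shift_Del` / `In_Frame_Del`) when present, else from length mod 3.

Bins are closed intervals: [1,5], [6,13], [14,20], [21,50] bp. Deletions
longer than 50 bp are counted for QC (`overflow_gt50`) but excluded from all
bins and therefore from the MDF; 50 bp is the upper end of the scar spectrum
the statistic targets, and longer events are more often complex structural
variants. The raw MDF is the 6–13 plus 14–20 bp count.

Standardization choices:

* **Sample (n−1) standard deviation** for the z-score — the conventional
  default for the small cohorts this statistic is applied to. A
  zero-variance cohort yields all-zero z-scores with a warning; a
  single-tumor cohort is an error.
* **Positive shift = z − min(z)** — an affine, display-oriented transform.
  Every downstream correlation or rank statistic is identical on raw,
  z-scored or shifted values (asserted by tests).
* **Quartiles** from linear-interpolation empirical quantiles of z at
  0.25/0.5/0.75, with ties assigned to the lower quartile; `mdf_high` means
  strictly above the cohort median.
* The standardization cohort is whatever set of tumors one invocation
  receives; pooling cohorts is the caller's choice via the manifest.

Microhomology sequence context is deliberately *not* inspected: the
footprint is purely size-based.

## Coupling statistics

All tests are two-sided. Mann-Whitney uses exact enumeration when both
groups have n ≤ 8 and no ties, otherwise the tie-corrected normal
approximation without continuity correction (so identical samples give
p = 1 exactly). Contingency tables use Pearson chi-square without
continuity correction, df = (r−1)(c−1), and reject zero margins.

TMB adjustment regresses log10(neoantigens+1) on log10(TMB+1) by ordinary
least squares (normal equations) and correlates the residuals with MDF —
the log10(x+1) scale matches how both burdens are conventionally displayed
and stabilizes the right-skewed counts. Pearson is the default for the
MDF-neoantigen coupling; Spearman is exposed for general monotone
association. No multiple-testing correction is applied by default; pairwise
subgroup contrasts can opt into Benjamini-Hochberg.

## Spatial immune synapse

The proximity statistic is the fraction of CD8⁺ T cells whose nearest
APC-like macrophage (macrophage with HLA-DRA > 0 *and* CD74 > 0, strict
inequalities on log1p values) lies within the radius. Conventions:

* The radius is **inclusive** (≤ 20 μm), applied identically to the
  proximity fraction and the proximal/distal stratification.
* Distances are double-precision Euclidean in μm; neighbor queries use a
  KD-tree whose inclusion set is asserted (in tests) to equal the
  brute-force all-pairs computation exactly.
* The permutation null redraws the APC-like subset uniformly among all
  macrophages, preserving the APC count and every cell position. The
  empirical p is the literal proportion of permuted fractions ≥ observed
  (ties count); it can be exactly 0, and an optional (k+1)/(n+1) estimator
  is strictly positive for users who want the conservative version.
* Stratified expression comparisons use **all** macrophages (not only
  APC-like), two-sided Mann-Whitney per gene, and report the rank-biserial
  effect size 2U/(n₁n₂) − 1.
* Each sample is analyzed independently; nothing is pooled across samples.
* Degenerate cases: no CD8 cells → the fraction is undefined (error); no
  APC-like macrophages → fraction 0 with a warning (the test itself requires
  ≥ 1); all macrophages APC-like → p = 1 with a warning.

## Trajectory binning

The "neoantigen gradient" is implemented as tumor-level ordering: cells are
sorted by (tumor burden ascending, tumor id, stable input order) and split
into 30 contiguous bins of near-equal size (the first `n mod 30` bins get
one extra cell). This is the central interpretive decision of the module —
a per-cell latent ordering such as diffusion pseudotime would also fit the
idea, so the ordering step is isolated in `order_and_bin` and alternative
assignments can be passed directly to `summarize_bins`. Equal cell count
(not equal burden width) was chosen so every bin summary rests on the same
sample size.

Entropy is Shannon entropy in bits, computed as −Σ p·log2 p with
0·log 0 = 0; using log2 directly makes the value exact on dyadic
compositions (e.g. a uniform 4-type bin is exactly 2 bits). Module scores
z-score each present gene across all cells jointly (sample sd; zero-variance
genes contribute 0) and average over the genes present; absent genes are
dropped with a warning and an empty intersection is an error.

## Outcomes

Kaplan-Meier estimation and the log-rank test are delegated to lifelines
(events precede censorings at tied times). RMST is the area under the KM
step function on [0, τ], integrated here so the truncation contract is
explicit: if follow-up ends with a censoring before τ, the last KM value is
carried flat to τ with a warning (the common convention of reference RMST
implementations). The variance is the Greenwood-type plug-in
Σ Aᵢ² dᵢ/(nᵢ(nᵢ−dᵢ)) over event times tᵢ ≤ τ, with Aᵢ the residual area
from tᵢ to τ; between-group differences get normal 95% CIs. Median splits
assign ties to the lower stratum. Differences are reported unadjusted.

## Synthetic study conditions

The generators encode the data structure the analysis assumes, with
defaults chosen once as the reference conditions:

* **Variant catalogs** — 60 tumors, half HRD; deletions per tumor
  Poisson(40); each deletion drawn from the 6–20 bp regime (discrete
  uniform) with probability 0.6 (HRD) or 0.05 (HRP), else from the 1–5 bp
  regime (discrete uniform). The two discrete uniforms are the simplest
  shapes consistent with the bin structure. Neoantigen burden is
  Poisson(0.5 × scar-derived frameshift count + 5): the coupling runs
  through MMEJ-regime frameshift deletions specifically, reflecting the
  model that the repair scar — not total mutation count — is the frameshift
  neoantigen source; the baseline of 5 keeps HR-proficient tumors at a
  realistic nonzero burden. Missense count is Poisson(60), and
  TMB = (missense + deletions)/30 Mb (a fixed nominal exome footprint),
  giving TMB ≈ 3.3/Mb, typical of pancreatic cancer. An optional
  gamma-Poisson dispersion parameter adds overdispersion to the neoantigen
  draw.
* **Spatial samples** — a 500 × 500 μm window, 300 macrophages (30%
  APC-like), 150 CD8 cells; geometry is strictly 2D (sections are planar).
  Attracted CD8 cells are Gaussian displacements (σ = 5 μm) from a random
  APC-like macrophage, clipped to the window; attraction 0 is the exact
  null. Expression is generated directly on the log1p scale; non-APC
  macrophages always have at least one antigen-presentation gene at 0, so
  the ground-truth flag coincides with the expression rule when no
  proximity effect is applied.
* **Immune census** — cell-type composition interpolates linearly from
  (70% macrophage, 8/8/5/5/4% T/NK/B/Treg) to (10% macrophage, diverse) as
  burden rank rises; gradient strength scales the interpolation. Per-tumor
  MDF is an increasing linear function of burden plus Gaussian noise.
* **Survival** — exponential event times (rate ln2/median) with independent
  exponential censoring; the closed form RMST (1−e^{−λτ})/λ provides the
  estimator's oracle.

What the generators do *not* emulate: sequence context (no microhomology
sequences), read-level noise or variant-calling artifacts, 3D tissue
architecture, realistic single-cell count distributions (expression is
Gaussian around type-specific means on the log1p scale), and cohort-level
overdispersion of deletion counts across tumors of the same class (counts
are conditionally Poisson). Passing tests therefore demonstrate the
correctness and calibration of the statistics under these idealized
conditions, not the biological effect sizes of any real cohort: in
particular, within-class MDF-neoantigen correlations are bounded near
r ≈ 0.4 by the Poisson noise at the default coupling, well below the
strongest correlations reported on real HRD tumors, where deletion burden
varies far more between patients.

## Problem sizes

Calibration and power checks use 100–200 simulated samples with 500
permutations each; RMST accuracy uses 500 cohorts of n = 200 (the
acceptance script uses 200); coupling recovery uses 100 seeds of 60-tumor
cohorts. These sizes keep Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* The MDF is size-only; true microhomology-mediated events cannot be
  distinguished from other short deletions of the same length.
* The permutation test conditions on the observed APC count; it does not
  model uncertainty in the APC definition itself.
* The trajectory is a tumor-level ordering: within-tumor heterogeneity in
  neoantigen exposure is invisible to it.
* RMST comparisons are unadjusted two-group contrasts; no proportional
  hazards modelling is provided.
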