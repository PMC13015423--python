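# scarsynapse

Tools for linking a DNA-repair scar to tumor immunogenicity in homologous
recombination-deficient (HRD) cancer.

When homologous recombination fails (e.g. *BRCA1/2* or *PALB2* loss), tumors
resolve double-strand breaks through microhomology-mediated end joining
(MMEJ), an error-prone POLQ-dependent pathway that leaves characteristic
short deletions. `scarsynapse` quantifies this scar and follows its
consequences through the immune system:

* **MMEJ Deletion Footprint (MDF)** — somatic deletions are binned by net
  length (reference minus alternate allele length) into 1–5, 6–13, 14–20 and
  21–50 bp bins; the raw MDF of tumor *i* is the count of 6–20 bp deletions,

  `MDF_i = n_i(6–13 bp) + n_i(14–20 bp)`,

  z-scored across the cohort, `z_i = (MDF_i − mean)/sd` (sample sd), shifted
  so the cohort minimum is 0, and cut into quartiles.
* **Neoantigen coupling** — Pearson/Spearman correlation of MDF with
  predicted neoantigen burden, plus a TMB-adjusted version: ordinary least
  squares of log10(neoantigens+1) on log10(TMB+1), then correlation of the
  residuals with MDF, so the association is not explained by mutation count
  alone.
* **Spatial immune synapse** — the fraction of CD8⁺ T cells within 20 μm of
  an APC-like macrophage (macrophage with HLA-DRA > 0 and CD74 > 0 on the
  log1p scale), tested against a permutation null that reshuffles APC labels
  among macrophages while preserving all cell positions; empirical
  p = (# permuted fractions ≥ observed)/n_perm. Macrophages are also
  stratified into CD8-proximal (≤20 μm) vs CD8-distal for Mann-Whitney
  comparisons of antigen-presentation gene expression.
* **Trajectory binning** — immune cells pooled across tumors, ordered by
  tumor neoantigen burden and split into 30 contiguous bins; per bin the
  cell-type composition, Shannon entropy (bits), curated-program module
  scores and mean tumor-level MDF.
* **Outcomes** — Kaplan-Meier curves, log-rank tests, and restricted mean
  survival time `RMST(τ) = ∫₀^τ S(t) dt` (τ = 24 months by default) with a
  Greenwood-based variance and normal CIs for between-group differences.

Because the cohorts this pipeline targets are controlled-access, the package
includes synthetic generators for every input (variant catalogs, spatial
point patterns, immune census tables, survival tables) with known ground
truth, so every stage is testable end to end. It is aimed at cancer
genomicists and computational immunologists working with somatic variant
calls, spatially resolved single-cell data and clinical outcomes.

## Worked example

Simulate a small cohort, score the MDF, and inspect the coupling:

```python
import scarsynapse as ss

cfg = ss.GenomicSimConfig(n_tumors=8, lambda_del=20, seed=7)
variants, truth = ss.simulate_variant_catalogs(cfg)

records = [
    ss.DeletionRecord(v.Tumor_Sample_Barcode, v.Chromosome, v.Start_Position,
                      ref_len=len(v.Reference_Allele), alt_len=0)
    for v in variants.itertuples() if v.Variant_Type == "DEL"
]
spectra = ss.bin_spectrum(records, tumor_ids=list(truth.tumor_id))
scores = ss.compute_mdf(spectra)
print(scores[["tumor_id", "b6_13", "b14_20", "raw_mdf",
              "z_mdf", "shifted_mdf", "quartile"]].round(3).to_string(index=False))
```

```
tumor_id  b6_13  b14_20  raw_mdf  z_mdf  shifted_mdf  quartile
    T001      1       0        1 -0.666        0.148         1
    T002      4       6       10  0.666        1.479         3
    T003      8       9       17  1.701        2.514         4
    T004      0       1        1 -0.666        0.148         1
    T005      0       1        1 -0.666        0.148         1
    T006      1       0        1 -0.666        0.148         1
    T007      0       0        0 -0.813        0.000         1
    T008      7       6       13  1.109        1.923         4
```

The three simulated HRD tumors (T002, T003, T008) carry raw MDF 10–17 versus
0–1 in the HR-proficient tumors, land in the upper quartiles, and have the
highest simulated neoantigen burdens (6, 15 and 8 versus 0–4) — the pattern
the real analysis quantifies with Mann-Whitney and correlation statistics.

The same workflow is available from the shell:

```bash
scarsynapse simulate catalogs --config cfg.yaml --out sim/
scarsynapse mdf --manifest sim/manifest.csv --dialect maf --out mdf.tsv
scarsynapse stats --tumors sim/truth.csv --mdf mdf.tsv --out stats.tsv
scarsynapse synapse --cells cells.csv --radius 20 --n-perm 500 --seed 1 --out out/
scarsynapse trajectory --census census.csv --tumors tumors.csv --bins 30 --out bins.tsv
scarsynapse outcomes --survival survival.csv --tau 24 --out rmst.tsv
```

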