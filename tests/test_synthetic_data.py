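"""Generator contracts: determinism, validation, and null parameterizations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scarsynapse import (
    GenomicSimConfig,
    SpatialSimConfig,
    simulate_immune_census,
    simulate_spatial_sample,
    simulate_survival,
    simulate_variant_catalogs,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(hrd_fraction=1.5),
            dict(mmej_weight_hrd=-0.1),
            dict(lambda_del=-1.0),
            dict(lambda_del=np.inf),
            dict(coupling_alpha=-0.5),
            dict(n_tumors=0),
        ],
    )
    def test_genomic_config_rejects_bad_values(self, kwargs):
        with pytest.raises(ValueError):
            GenomicSimConfig(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(window=(0.0, 100.0)),
            dict(apc_fraction=2.0),
            dict(attraction=-0.2),
            dict(n_cd8=-1),
            dict(sigma=-1.0),
        ],
    )
    def test_spatial_config_rejects_bad_values(self, kwargs):
        with pytest.raises(ValueError):
            SpatialSimConfig(**kwargs)

    def test_attraction_without_apc_rejected(self):
        with pytest.raises(ValueError, match="APC-like"):
            simulate_spatial_sample(
                SpatialSimConfig(apc_fraction=0.0, attraction=0.5)
            )

    def test_census_gradient_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="gradient_strength"):
            simulate_immune_census(4, 10, 1.5)

    def test_survival_median_must_be_positive(self):
        with pytest.raises(ValueError, match="must be > 0"):
            simulate_survival(5, {"g": 0.0})


class TestDeterminism:
    def test_catalogs_byte_identical_for_same_seed(self):
        cfg = GenomicSimConfig(n_tumors=10, seed=42)
        v1, t1 = simulate_variant_catalogs(cfg)
        v2, t2 = simulate_variant_catalogs(cfg)
        pd.testing.assert_frame_equal(v1, v2)
        pd.testing.assert_frame_equal(t1, t2)
        assert v1.to_csv() == v2.to_csv()

    def test_spatial_and_census_and_survival_reproducible(self):
        s1 = simulate_spatial_sample(SpatialSimConfig(seed=7))
        s2 = simulate_spatial_sample(SpatialSimConfig(seed=7))
        pd.testing.assert_frame_equal(s1, s2)
        c1, u1 = simulate_immune_census(4, 50, 0.5, seed=7)
        c2, u2 = simulate_immune_census(4, 50, 0.5, seed=7)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(u1, u2)
        pd.testing.assert_frame_equal(
            simulate_survival(20, {"a": 10.0}, 0.05, seed=3),
            simulate_survival(20, {"a": 10.0}, 0.05, seed=3),
        )


class TestVariantCatalogs:
    def test_truth_counts_match_emitted_variants(self):
        cfg = GenomicSimConfig(n_tumors=8, seed=1)
        variants, truth = simulate_variant_catalogs(cfg)
        dels = variants[variants["Variant_Type"] == "DEL"]
        per_tumor = dels.groupby("Tumor_Sample_Barcode").size()
        for row in truth.itertuples(index=False):
            assert per_tumor.get(row.tumor_id, 0) == row.n_deletions
            assert row.b1_5 + row.b6_13 + row.b14_20 == row.n_deletions
            assert row.tmb == pytest.approx(
                (row.n_missense + row.n_deletions) / 30.0
            )

    def test_equal_weights_make_classes_indistinguishable(self):
        # degenerate parameterization: pooled HRD and HRP length spectra agree
        ok = 0
        for seed in range(20):
            cfg = GenomicSimConfig(
                n_tumors=60, lambda_del=90, mmej_weight_hrd=0.3,
                mmej_weight_hrp=0.3, seed=seed,
            )
            variants, truth = simulate_variant_catalogs(cfg)
            dels = variants[variants["Variant_Type"] == "DEL"].copy()
            dels["length"] = dels["Reference_Allele"].str.len()
            merged = dels.merge(
                truth[["tumor_id", "subgroup"]],
                left_on="Tumor_Sample_Barcode", right_on="tumor_id",
            )
            hrd = merged.loc[merged["subgroup"] == "HRD", "length"]
            hrp = merged.loc[merged["subgroup"] == "HRP", "length"]
            p = stats.ks_2samp(hrd, hrp).pvalue
            ok += p > 0.01
        assert ok >= 18

    def test_zero_coupling_decouples_neoantigens_from_frameshifts(self):
        cfg = GenomicSimConfig(n_tumors=2000, coupling_alpha=0.0, seed=0)
        _, truth = simulate_variant_catalogs(cfg)
        r = np.corrcoef(truth["frameshift_count"], truth["neoantigen_burden"])[0, 1]
        assert abs(r) < 0.1

    def test_positive_coupling_links_scar_frameshifts_to_neoantigens(self):
        cfg = GenomicSimConfig(n_tumors=500, coupling_alpha=2.0, seed=0)
        _, truth = simulate_variant_catalogs(cfg)
        r = np.corrcoef(
            truth["mmej_frameshift_count"], truth["neoantigen_burden"]
        )[0, 1]
        assert r > 0.5


class TestSpatialSample:
    def test_attraction_zero_matches_area_fraction_oracle(self):
        # oracle: per replicate, the uniform-placement hit probability is the
        # fraction of window area covered by the union of 20-um APC disks,
        # computed by dense grid integration, independent of any KD-tree
        observed, expected = [], []
        for seed in range(60):
            cfg = SpatialSimConfig(
                window=(300.0, 300.0), n_macrophages=30, apc_fraction=0.3,
                n_cd8=100, attraction=0.0, seed=seed,
            )
            cells = simulate_spatial_sample(cfg)
            mac = cells[cells["cell_type"] == "Macrophage"]
            apc = mac[mac["apc_truth"]]
            cd8 = cells[cells["cell_type"] == "CD8T"]
            d = np.sqrt(
                (cd8["x_um"].to_numpy()[:, None] - apc["x_um"].to_numpy()) ** 2
                + (cd8["y_um"].to_numpy()[:, None] - apc["y_um"].to_numpy()) ** 2
            )
            observed.append((d.min(axis=1) <= 20).mean())
            g = np.linspace(0.5, 299.5, 300)
            gx, gy = np.meshgrid(g, g)
            cov = np.zeros(gx.shape, dtype=bool)
            for x, y in zip(apc["x_um"], apc["y_um"]):
                cov |= (gx - x) ** 2 + (gy - y) ** 2 <= 400.0
            expected.append(cov.mean())
        diff = np.mean(observed) - np.mean(expected)
        # Monte-Carlo error of the mean over 60x100 uniform draws is ~0.006
        assert abs(diff) < 0.02

    def test_zero_cd8_yields_valid_table(self):
        cells = simulate_spatial_sample(SpatialSimConfig(n_cd8=0, seed=0))
        assert (cells["cell_type"] == "CD8T").sum() == 0
        assert (cells["cell_type"] == "Macrophage").sum() == 300

    def test_apc_truth_matches_expression_rule_without_effect(self):
        cells = simulate_spatial_sample(SpatialSimConfig(seed=5))
        mac = cells[cells["cell_type"] == "Macrophage"]
        coexpr = (mac["HLA-DRA"] > 0) & (mac["CD74"] > 0)
        assert (coexpr == mac["apc_truth"]).all()

    def test_expr_effect_zero_keeps_expression_independent_of_geometry(self):
        # proximal-vs-distal Mann-Whitney p should be null-distributed
        from scarsynapse import stratify_and_compare_expression

        ps = []
        for seed in range(40):
            cells = simulate_spatial_sample(
                SpatialSimConfig(expr_effect=0.0, seed=seed)
            )
            out = stratify_and_compare_expression(cells)
            ps.extend(out["pvalue"].dropna().tolist())
        assert np.mean(np.asarray(ps) < 0.05) < 0.2

    def test_expr_effect_raises_proximal_expression(self):
        cells = simulate_spatial_sample(
            SpatialSimConfig(expr_effect=2.0, attraction=0.5, seed=0)
        )
        from scarsynapse import stratify_and_compare_expression

        out = stratify_and_compare_expression(cells)
        assert (out["median_proximal"] > out["median_distal"]).all()


class TestImmuneCensus:
    def test_zero_gradient_composition_flat(self):
        ok = 0
        for seed in range(20):
            cells, _ = simulate_immune_census(8, 300, 0.0, seed=seed)
            table = pd.crosstab(cells["cell_type"], cells["tumor_id"])
            p = stats.chi2_contingency(table)[1]
            ok += p > 0.01
        assert ok >= 18

    def test_full_gradient_macrophage_proportion_declines(self):
        for seed in range(10):
            cells, tumors = simulate_immune_census(10, 500, 1.0, seed=seed)
            prop = (
                cells.groupby("tumor_id")["cell_type"]
                .apply(lambda s: (s == "Macrophage").mean())
                .reindex(tumors["tumor_id"])
            )
            rank = tumors["neoantigen_burden"].rank()
            slope = np.polyfit(rank, prop, 1)[0]
            assert slope < 0

    def test_burdens_and_mdf_increase_together(self):
        _, tumors = simulate_immune_census(12, 50, 0.5, seed=0)
        assert tumors["neoantigen_burden"].is_monotonic_increasing
        r = np.corrcoef(tumors["neoantigen_burden"], tumors["shifted_mdf"])[0, 1]
        assert r > 0.5


class TestSurvival:
    def test_no_censoring_all_events_observed(self):
        df = simulate_survival(50, {"a": 12.0, "b": 6.0}, censor_rate=0.0, seed=0)
        assert (df["event"] == 1).all()
        assert len(df) == 100

    def test_censoring_produces_censored_records(self):
        df = simulate_survival(200, {"a": 12.0}, censor_rate=0.1, seed=0)
        frac_censored = (df["event"] == 0).mean()
        # exponential competing risks: P(censor first) = c/(c+lambda) ~ 0.63
        assert 0.5 < frac_censored < 0.8

    def test_equal_medians_logrank_null(self):
        from scarsynapse import logrank

        ps = []
        for seed in range(40):
            df = simulate_survival(
                40, {"a": 12.0, "b": 12.0}, censor_rate=0.02, seed=seed
            )
            ps.append(logrank(df["time"], df["event"], df["group"])[1])
        assert np.mean(np.asarray(ps) < 0.05) < 0.25
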