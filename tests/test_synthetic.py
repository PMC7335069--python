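"""Synthetic-data generator: geometry, atlas, cohort, signatures, manifest."""

import numpy as np
import pandas as pd
import pytest

from neurovuln import msn, contrasts
from neurovuln.synthetic import (
    CellSpec,
    CnvSpec,
    GroundTruthManifest,
    SyntheticConfig,
    generate_cohort,
    generate_dataset,
    generate_geometry,
    generate_individual_expression,
)
from neurovuln.synthetic.expression import ConfigError, generate_expression_atlas
from neurovuln.synthetic.geometry import DegenerateGeometryError


class TestGeometry:
    def test_counts_and_unit_norm(self):
        geo = generate_geometry(152, seed=1)
        assert geo.n_regions == 304
        np.testing.assert_allclose(
            np.linalg.norm(geo.coords, axis=1), 1.0, atol=1e-9
        )

    def test_mirror_symmetry(self):
        geo = generate_geometry(152, seed=1)
        left = geo.coords[geo.hemispheres == "L"]
        right = geo.coords[geo.hemispheres == "R"]
        np.testing.assert_allclose(left, right * [-1, 1, 1], atol=1e-12)

    def test_region_ids_unique(self):
        geo = generate_geometry(30, seed=2)
        assert len(set(geo.region_ids)) == 60

    def test_min_pairwise_distance_positive(self):
        geo = generate_geometry(20, seed=7)
        d = np.linalg.norm(
            geo.coords[:, None, :] - geo.coords[None, :, :], axis=2
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() > 1e-3

    def test_degenerate_size_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            generate_geometry(9)


class TestExpressionAtlas:
    def test_shapes(self, small_geometry):
        donors, ann, manifest = generate_expression_atlas(
            small_geometry, 200, 6, 5, CnvSpec(size=10), seed=4
        )
        assert len(donors) == 6
        for d in donors:
            assert d.shape == (20, 200)
        assert len(ann) == 200
        assert set(manifest.planted_cnv_set) <= set(ann["gene"])

    def test_planted_coupling_realized(self):
        geo = generate_geometry(152, seed=0)
        rs = []
        for seed in range(20):
            _, _, manifest = generate_expression_atlas(
                geo, 300, 2, 5, CnvSpec(size=40, coupling_r=0.7), seed=seed
            )
            rs.append(manifest.realized_coupling_r)
        assert abs(np.mean(rs) - 0.7) < 0.05
        assert np.max(np.abs(np.array(rs) - 0.7)) < 0.12

    def test_null_coupling_near_zero(self):
        geo = generate_geometry(152, seed=0)
        rs = [
            generate_expression_atlas(
                geo, 300, 2, 5, CnvSpec(size=40, coupling_r=0.0), seed=seed
            )[2].realized_coupling_r
            for seed in range(20)
        ]
        assert np.mean(np.abs(rs)) < 0.15

    def test_cnv_larger_than_genome_rejected(self, small_geometry):
        with pytest.raises(ConfigError):
            generate_expression_atlas(
                small_geometry, 60, 2, 5, CnvSpec(size=70), seed=1
            )

    def test_too_many_classes_rejected(self, small_geometry):
        with pytest.raises(ConfigError, match="n_classes"):
            generate_expression_atlas(
                small_geometry, 500, 2, 5, CnvSpec(size=10), seed=1,
                cell_spec=CellSpec(n_classes=7),
            )

    def test_spans_chromosome_reserves_label(self, small_geometry):
        _, ann, manifest = generate_expression_atlas(
            small_geometry, 200, 2, 5, CnvSpec(size=10, spans_chromosome=True),
            seed=4,
        )
        on_x = ann[ann["chromosome"] == "X"]["gene"].tolist()
        assert sorted(on_x) == sorted(manifest.planted_cnv_set)


class TestCohort:
    def test_minimal_cohort_fits(self, small_dataset):
        geo = small_dataset.geometry
        cohort = generate_cohort(
            geo, small_dataset.manifest, "case_control", 5, 5, 0.5, seed=1
        )
        ms_tab = msn.cohort_regional_ms(cohort.features, cohort.subjects, cohort.regions)
        cmap = contrasts.fit_regional_contrast(ms_tab, cohort.covariates, "case_control")
        assert np.all(np.isfinite(cmap.t_stat))

    def test_planted_sign_in_top_regions(self, small_dataset):
        ds = small_dataset
        ms_tab = msn.cohort_regional_ms(
            ds.cohort.features, ds.cohort.subjects, ds.cohort.regions
        )
        cmap = contrasts.fit_regional_contrast(ms_tab, ds.cohort.covariates, "case_control")
        change = np.asarray(ds.manifest.planted_change_map)
        top = np.argsort(change)[-15:]
        bottom = np.argsort(change)[:15]
        assert cmap.t_stat[top].mean() > cmap.t_stat[bottom].mean()

    def test_null_effect_type_one_error(self):
        """effect_size = 0: ~5% of regions exceed the nominal threshold."""
        from scipy import stats as st

        geo = generate_geometry(30, seed=0)
        hits, total = 0, 0
        for seed in range(40):
            _, _, manifest = generate_expression_atlas(
                geo, 80, 2, 4, CnvSpec(size=8), seed=seed
            )
            cohort = generate_cohort(
                geo, manifest, "case_control", 10, 10, effect_size=0.0, seed=seed
            )
            ms_tab = msn.cohort_regional_ms(
                cohort.features, cohort.subjects, cohort.regions
            )
            cmap = contrasts.fit_regional_contrast(
                ms_tab, cohort.covariates, "case_control"
            )
            crit = st.t.ppf(0.975, 20 - 4)
            hits += int(np.sum(np.abs(cmap.t_stat) > crit))
            total += len(cmap.t_stat)
        assert 0.025 < hits / total < 0.075

    def test_aneuploidy_covariates(self, small_dataset):
        cohort = generate_cohort(
            small_dataset.geometry, small_dataset.manifest, "aneuploidy",
            12, 10, 1.0, seed=3,
        )
        cov = cohort.covariates
        assert set(cov.loc[cov["dx"] == 1, "group"]) <= {"XXX", "XXY", "XXYY"}
        assert (cov.loc[cov["group"] == "XXYY", "yan"] == 1).all()
        assert (cov.loc[cov["dx"] == 1, "xan"] == 1).all()
        assert cov["age"].between(5, 25).all()

    def test_cohort_size_bounds(self, small_dataset):
        with pytest.raises(ValueError):
            generate_cohort(
                small_dataset.geometry, small_dataset.manifest,
                "case_control", 4, 10, 1.0, seed=0,
            )


class TestSignatures:
    def test_counts(self, small_dataset):
        assert len(small_dataset.signatures) == 21  # 7 classes x 3 sets

    def test_noiseless_within_class_identical(self, small_geometry):
        donors, ann, manifest = generate_expression_atlas(
            small_geometry, 400, 1, 8, CnvSpec(size=10), seed=6,
            cell_spec=CellSpec(noise_sd=0.0, genes_per_set=5),
            donor_noise_sd=0.0,
        )
        from neurovuln import atlas as atl, cells
        from neurovuln.synthetic import generate_cell_signatures

        sigs = generate_cell_signatures(manifest)
        expr = atl.aggregate_donor_expression(donors, ann)
        cbr = cells.cell_by_region_matrix(expr, sigs)
        truth = manifest.planted_classes
        for cls in set(truth.values()):
            members = [s for s, c in truth.items() if c == cls]
            sub = cbr.loc[members].to_numpy()
            r = np.corrcoef(sub)
            np.testing.assert_allclose(r, 1.0, atol=1e-9)

    def test_noisy_within_class_exceeds_between(self, small_dataset):
        from neurovuln import atlas as atl, cells

        ds = small_dataset
        expr = atl.aggregate_donor_expression(ds.donors, ds.annotations)
        cbr = cells.cell_by_region_matrix(expr, ds.signatures)
        truth = ds.manifest.planted_classes
        corr = np.corrcoef(cbr.to_numpy())
        names = list(cbr.index)
        within, between = [], []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                (within if truth[names[i]] == truth[names[j]] else between).append(
                    corr[i, j]
                )
        assert np.mean(within) > np.mean(between)


class TestIndividualExpression:
    def test_column_count(self, rng):
        cfg = SyntheticConfig(
            cells=None, n_per_hemisphere=30, n_genes=150, n_donors=2, k_factors=5,
            design="aneuploidy", n_cases=18, n_controls=8,
            cnv=CnvSpec(size=20, coupling_r=0.7, n_ds=12, n_dsss=0),
            individual_beta=0.5,
        )
        ds = generate_dataset(cfg, seed=2)
        table = ds.individual_expression
        assert table.drop(columns="group").shape[1] == 11

    def test_strong_beta_couples_expression_to_ms_deviation(self):
        cfg = SyntheticConfig(
            cells=None, n_per_hemisphere=40, n_genes=150, n_donors=2, k_factors=5,
            design="aneuploidy", n_cases=45, n_controls=10,
            cnv=CnvSpec(size=20, coupling_r=0.7, n_ds=12, n_dsss=0),
            individual_beta=0.8, individual_noise_sd=0.3,
        )
        ds = generate_dataset(cfg, seed=3)
        from neurovuln.synthetic.individual_expr import carrier_ms_deviation_scores

        table = ds.individual_expression
        burden = table.drop(columns="group").mean(axis=1)
        scores = carrier_ms_deviation_scores(ds.cohort, ds.manifest, table.index)
        assert np.corrcoef(burden, scores)[0, 1] > 0.5

    def test_beta_without_carriers_rejected(self, small_dataset):
        from neurovuln.synthetic.individual_expr import ConfigError as IndivError

        cohort = generate_cohort(
            small_dataset.geometry, small_dataset.manifest,
            "case_control", 5, 5, 0.0, seed=1,
        )
        cohort.covariates["dx"] = 0
        with pytest.raises(IndivError):
            generate_individual_expression(
                cohort, small_dataset.manifest, 5, beta=0.5, seed=0
            )


class TestManifestAndDeterminism:
    def test_manifest_round_trip(self, small_dataset, tmp_path):
        m = small_dataset.manifest
        m.to_json(tmp_path / "m.json")
        back = GroundTruthManifest.from_json(tmp_path / "m.json")
        assert back.planted_cnv_set == m.planted_cnv_set
        np.testing.assert_allclose(back.latent_factors, m.latent_factors)
        assert back.ds_flags == m.ds_flags

    def test_coupling_bounds_enforced(self):
        with pytest.raises(ValueError):
            GroundTruthManifest(seed=0, coupling_r=1.5)

    def test_identical_seed_identical_dataset(self):
        cfg = SyntheticConfig(
            n_per_hemisphere=25, n_genes=300, n_donors=2, k_factors=8,
            n_cases=8, n_controls=8, cells=CellSpec(genes_per_set=4),
            cnv=CnvSpec(size=10),
        )
        a = generate_dataset(cfg, seed=42)
        b = generate_dataset(cfg, seed=42)
        np.testing.assert_array_equal(a.cohort.features, b.cohort.features)
        for da, db in zip(a.donors, b.donors):
            np.testing.assert_array_equal(da.to_numpy(), db.to_numpy())
        assert a.manifest.planted_classes == b.manifest.planted_classes

    def test_different_seed_differs(self):
        cfg = SyntheticConfig(
            n_per_hemisphere=25, n_genes=300, n_donors=2, k_factors=8,
            n_cases=8, n_controls=8, cells=None, cnv=CnvSpec(size=10),
        )
        a = generate_dataset(cfg, seed=1)
        b = generate_dataset(cfg, seed=2)
        assert not np.array_equal(a.cohort.features, b.cohort.features)
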