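"""End-to-end orchestration of the synthetic study.

``run_pipeline`` executes: simulate -> MSN construction -> group contrast
-> atlas aggregation -> PLS gene ranking -> median-rank enrichment ->
cell-class decoding -> dosage-sensitivity validation -> spin-test map
comparisons -> subject-level coupling, writing TSV/JSON outputs and a run
manifest.  Every stochastic stage derives its seed from the master seed,
so identical configs and seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as atl
from . import cells as cell_mod
from . import contrasts, enrichment, individual, io, msn, pls, spin
from .synthetic import (
    CellSpec,
    CnvSpec,
    SyntheticConfig,
    generate_dataset,
)

log = logging.getLogger("neurovuln")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=lambda: SyntheticConfig(
        design="aneuploidy",
        n_cases=55,
        n_controls=55,
        individual_beta=0.8,
        cnv=CnvSpec(size=40, coupling_r=0.7, sign=1, spans_chromosome=True, n_ds=16, n_dsss=8),
        cells=CellSpec(couple_class_to_cnv="Oligo"),
    ))
    n_perm: int = 1000
    n_spins: int = 1000
    alpha: float = 0.05
    max_k: int = 10
    brain_filter: bool = True
    run_lofo: bool = False
    bonferroni: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", {})
        missing = object()
        cnv = syn.pop("cnv", missing)
        cells = syn.pop("cells", missing)
        scfg = SyntheticConfig(**syn)
        if cnv is not missing and cnv is not None:
            scfg.cnv = CnvSpec(**cnv)
        if cells is not missing:
            scfg.cells = CellSpec(**cells) if cells else None
        return cls(synthetic=scfg, **raw)


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, (np.floating, float)):
        return float(x)
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, (np.bool_, bool)):
        return bool(x)
    return x


def run_pipeline(config: RunConfig, outdir, seed: int) -> dict:
    """Execute every stage; returns the result dict written to results.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(
            ["simulate", "enrich", "cells", "spin", "individual", "ds"],
            ss.spawn(6),
        )
    }
    results: dict = {"seed": int(seed), "stage_seeds": stage_seed}

    # --- simulate ---------------------------------------------------------
    log.info("stage: simulate")
    ds = generate_dataset(config.synthetic, stage_seed["simulate"])
    manifest = ds.manifest
    io.write_cohort_tsv(ds.cohort, outdir / "cohort_features.tsv", outdir / "cohort_covariates.tsv")
    ds.geometry.to_frame().to_csv(outdir / "geometry.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT)
    ds.annotations.to_csv(outdir / "gene_annotations.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT)
    manifest.to_json(outdir / "ground_truth_manifest.json")
    if ds.signatures:
        io.write_gmt([s.genes for s in ds.signatures], outdir / "cell_signatures.gmt")

    # --- MSN + contrast ---------------------------------------------------
    log.info("stage: build-msn / contrast")
    ms_table = msn.cohort_regional_ms(ds.cohort.features, ds.cohort.subjects, ds.cohort.regions)
    io.write_matrix_tsv(ms_table, outdir / "regional_ms.tsv", index_label="subject")
    model = "aneuploidy" if config.synthetic.design == "aneuploidy" else "case_control"
    change = contrasts.fit_regional_contrast(ms_table, ds.cohort.covariates, model)
    pd.DataFrame(
        {"region": change.regions, "t": change.t_stat, "z": change.z_for_plot, "p": change.p_value}
    ).to_csv(outdir / "change_map.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT)
    planted = np.asarray(manifest.planted_change_map)
    results["contrast_vs_planted_map_r"] = float(np.corrcoef(change.t_stat, planted)[0, 1])

    # --- atlas + PLS ranking ---------------------------------------------
    log.info("stage: atlas / rank-genes")
    expr = atl.aggregate_donor_expression(ds.donors, ds.annotations)
    io.write_matrix_tsv(expr.matrix, outdir / "expression_atlas.tsv")
    lh_regions = expr.regions
    change_lh = pd.Series(change.t_stat, index=change.regions).loc[lh_regions]
    model1 = pls.fit_pls_component(expr.matrix, change_lh)
    ranked = pls.rank_genes(model1)
    ranked.table.to_csv(outdir / "ranked_genes.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT)
    results["pls_component1_var_explained"] = float(model1.var_explained[0])
    results["pls_component1_maximal"] = bool(model1.component1_maximal)
    set_mean = expr.matrix[manifest.planted_cnv_set].mean(axis=1).to_numpy()
    f1 = np.asarray(manifest.lh_factors)[:, 0]
    results["realized_expression_coupling_r"] = float(np.corrcoef(set_mean, f1)[0, 1])

    # --- enrichment -------------------------------------------------------
    log.info("stage: enrich")
    sign = manifest.cnv_sign
    direction = enrichment.DIRECTION_BY_SIGN["gain" if sign == 1 else "loss"]
    cnv_res = enrichment.test_gene_set(
        ranked, manifest.planted_cnv_set, direction,
        n_perm=config.n_perm, seed=stage_seed["enrich"],
    )
    chrom_genes = expr.chromosome_genes(manifest.cnv_chromosome)
    cis_res = None
    if len(chrom_genes) > len(manifest.planted_cnv_set):
        cis_res = enrichment.test_gene_set(
            ranked, manifest.planted_cnv_set, direction,
            n_perm=config.n_perm, seed=stage_seed["enrich"] + 1,
            chromosome_genes=chrom_genes,
        )
    profile = enrichment.chromosome_rank_profile(
        ranked, ds.annotations, seed=stage_seed["enrich"] + 2
    )
    profile.to_csv(outdir / "chromosome_rank_profile.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT)
    extreme = enrichment.p_most_extreme_chromosome(
        ranked, ds.annotations, manifest.cnv_chromosome, direction,
        n_perm=config.n_perm, seed=stage_seed["enrich"] + 3,
    )
    results["cnv_set_median_centered_rank"] = cnv_res.observed
    results["cnv_set_p_rand_trans"] = cnv_res.p
    if cis_res is not None:
        results["cnv_set_p_rand_cis"] = cis_res.p
    results["cnv_most_extreme_chromosome_p"] = extreme.p
    results["cnv_chromosome_observed_most_extreme"] = extreme.meta["observed_extreme"]

    # --- cell decoding ----------------------------------------------------
    if ds.signatures:
        log.info("stage: cell-maps / cell-screen")
        expr_cells = atl.filter_brain_expressed(expr) if config.brain_filter else expr
        cbr = cell_mod.cell_by_region_matrix(expr_cells, ds.signatures)
        io.write_matrix_tsv(cbr, outdir / "cell_by_region.tsv", index_label="signature")
        clustering = cell_mod.cluster_cell_signatures(
            cbr, max_k=min(config.max_k, cbr.shape[0] - 1), seed=stage_seed["cells"]
        )
        assignment, fine, nested = cell_mod.assign_cell_classes(clustering, ds.signatures)
        class_sets = cell_mod.class_gene_sets(ds.signatures)
        class_rows = []
        for label in sorted(class_sets):
            members = [s.name for s in ds.signatures if s.class_assignment == label]
            weights = cell_mod.derive_class_weights(members, cbr)
            cmap = cell_mod.class_expression_map(label, weights, cbr)
            class_rows.append(pd.Series(cmap.expression, index=cmap.regions, name=label))
        pd.DataFrame(class_rows).to_csv(outdir / "cell_class_maps.tsv", sep="\t", index_label="class", float_format=io.FLOAT_FMT)
        brain_flags = manifest.brain_expressed
        hits = cell_mod.cnv_cell_screen(
            ranked, class_sets,
            atl.GeneSet("CNV", list(manifest.planted_cnv_set)),
            brain_flags, n_perm=config.n_perm, seed=stage_seed["cells"] + 1,
            cnv_name=config.synthetic.cnv.name, alpha=config.alpha,
        )
        truth = {
            s: c for s, c in manifest.planted_classes.items()
            if c not in cell_mod.UNASSIGNABLE_LABELS
        }
        agree = _partition_agreement(
            [truth[s] for s in sorted(truth)],
            [assignment.get(s, "NA") for s in sorted(truth)],
        )
        results["cell_coarse_clusters_k"] = int(clustering.chosen_k)
        results["cell_class_recovery_agreement"] = agree
        results["cell_classes_nested_in_coarse"] = bool(nested)
        results["cell_screen_hits"] = [
            {"class": h.cell_class, "p": h.p, "genes": h.genes} for h in hits
        ]

    # --- dosage sensitivity ----------------------------------------------
    if manifest.ds_flags:
        log.info("stage: dosage-sensitivity")
        ds_set = [g for g, f in manifest.ds_flags.items() if f in ("DS", "DSSS")]
        nds_set = [g for g, f in manifest.ds_flags.items() if f == "nDS"]
        med = enrichment.ds_nds_median_test(
            ranked, ds_set, nds_set, n_perm=config.n_perm, seed=stage_seed["ds"]
        )
        deciles = enrichment.decile_enrichment(
            ranked, ds_set, nds_set, n_perm=config.n_perm, seed=stage_seed["ds"] + 1
        )
        deciles.table.to_csv(outdir / "ds_deciles.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dsss = enrichment.extract_dsss(deciles, ds_set, ranked, alpha=config.alpha)
        planted_dsss = sorted(g for g, f in manifest.ds_flags.items() if f == "DSSS")
        results["ds_nds_median_rank_difference"] = med.observed
        results["ds_nds_p_rand"] = med.p
        results["ds_significant_deciles"] = deciles.significant_deciles(config.alpha)
        results["dsss_size"] = len(dsss)
        results["dsss_matches_planted"] = sorted(dsss) == planted_dsss
        if dsss and nds_set:
            diff_map = cell_mod.differential_expression_map(expr, dsss, nds_set)
            lh_mask = np.asarray(manifest.hemispheres) == "L"
            spins_lh = spin.generate_spins(
                ds.geometry.hemisphere("L"), config.n_spins, seed=stage_seed["spin"]
            )
            sp = spin.p_spin(
                diff_map.to_numpy(), change_lh.to_numpy(), spins_lh
            )
            results["dsss_nds_map_vs_change_map_r"] = sp.observed
            results["dsss_nds_map_p_spin"] = sp.p

    # --- individual coupling ---------------------------------------------
    if ds.individual_expression is not None:
        log.info("stage: individual")
        expr_table = ds.individual_expression
        groups = expr_table["group"]
        X = expr_table.drop(columns="group")
        Y = ms_table.loc[X.index]
        Xs = individual.scale_within_group(X, groups)
        Ys = individual.scale_within_group(Y, groups)
        comp = individual.fit_individual_pls(Xs, Ys)
        sig = individual.component_significance(
            Xs, Ys, n_perm=config.n_perm, seed=stage_seed["individual"]
        )
        spins_full = spin.generate_spins(ds.geometry, config.n_spins, seed=stage_seed["spin"] + 1)
        load_cmp = individual.loadings_vs_changemap(
            comp, pd.Series(change.t_stat, index=change.regions), spins_full,
        )
        comp.region_loadings.to_frame().to_csv(outdir / "individual_region_loadings.tsv", sep="\t", index_label="region", float_format=io.FLOAT_FMT)
        results["individual_component_p"] = sig.p
        results["individual_loadings_vs_change_map_r"] = load_cmp["r"]
        results["individual_loadings_p_spin"] = load_cmp["p_spin"].p
        planted_cmp = individual.loadings_vs_changemap(
            comp, pd.Series(planted, index=change.regions), spins_full,
        )
        results["individual_loadings_vs_planted_map_r"] = planted_cmp["r"]
        results["individual_loadings_vs_planted_map_p_spin"] = planted_cmp["p_spin"].p

    # --- leave-one-feature-out -------------------------------------------
    if config.run_lofo:
        log.info("stage: leave-one-feature-out")
        _maps, sims, most = contrasts.leave_one_feature_out_maps(
            ds.cohort.features, ds.cohort.feature_names, ds.cohort.subjects,
            ds.cohort.regions, ds.cohort.covariates, model,
        )
        results["lofo_r_vs_full"] = {k: float(v) for k, v in sims.items()}
        results["lofo_most_contributing_feature"] = most

    results["config"] = _jsonable(asdict(config))
    (outdir / "results.json").write_text(json.dumps(_jsonable(results), sort_keys=True, indent=1))
    return results


def _partition_agreement(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (no sklearn dependency)."""
    a = pd.factorize(pd.Series(labels_a))[0]
    b = pd.factorize(pd.Series(labels_b))[0]
    n = len(a)
    table = pd.crosstab(a, b).to_numpy()
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(table).sum()
    sum_a = comb(table.sum(axis=1)).sum()
    sum_b = comb(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
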