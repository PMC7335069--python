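"""Donor-level expression atlas with planted couplings.

Gene expression is generated by a factor model on the left-hemisphere
parcels: smooth latent regional profiles (low-order spherical-harmonic
combinations) times gene loadings, plus gene-idiosyncratic and donor-level
Gaussian noise.  CNV genes load on factor 1 so that the set-mean regional
expression correlates with factor 1 at the planted strength: each CNV gene
is ``r * f1 + sqrt(1 - r^2) * u + noise`` with ``u`` a single shared
deviation profile, so the set mean keeps population correlation ``r`` with
the gradient rather than averaging the deviations away.  Cell-signature
genes follow their class's regional profile plus noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import ParcellationGeometry, smooth_maps, standardize
from .manifest import CellSpec, CnvSpec, GroundTruthManifest

DEFAULT_CHROMOSOMES = tuple(str(i) for i in range(1, 16)) + ("X", "Y", "PAR")


class ConfigError(ValueError):
    pass


def _gene_name(prefix: str, i: int) -> str:
    return f"{prefix}{i + 1:04d}"


def generate_expression_atlas(
    geometry: ParcellationGeometry,
    n_genes: int,
    n_donors: int,
    k_factors: int,
    cnv_spec: CnvSpec,
    seed: int,
    cell_spec: CellSpec | None = None,
    donor_noise_sd: float = 0.3,
    background_loading_sd: float = 0.3,
    background_noise_sd: float = 0.8,
    cnv_noise_sd: float = 0.3,
    chromosomes: tuple = DEFAULT_CHROMOSOMES,
    brain_expressed_rate: float = 0.6,
) -> tuple[list[pd.DataFrame], pd.DataFrame, GroundTruthManifest]:
    """Donor matrices (regions x genes), gene annotations, and the manifest."""
    if n_genes < 10 * k_factors:
        raise ConfigError(f"n_genes={n_genes} < 10 * k_factors={10 * k_factors}")
    rng = np.random.default_rng(seed)
    lh = geometry.hemisphere("L")
    regions = lh.region_ids

    factors = smooth_maps(geometry.coords, k_factors, rng)
    lh_mask = geometry.hemispheres == "L"
    F = factors[lh_mask]
    F = (F - F.mean(axis=0)) / F.std(axis=0, ddof=1)
    n_reg = F.shape[0]

    # --- gene bookkeeping -------------------------------------------------
    cnv_genes = [f"{cnv_spec.name}_{i + 1:04d}" for i in range(cnv_spec.size)]
    sig_gene_map: dict[str, list[str]] = {}
    planted_classes: dict[str, str] = {}
    class_profiles: dict[str, np.ndarray] = {}
    class_coarse: dict[str, int] = {}
    sig_genes_flat: list[str] = []

    if cell_spec is not None:
        if cell_spec.n_classes > k_factors:
            raise ConfigError(
                f"n_classes={cell_spec.n_classes} > k_factors={k_factors}"
            )
        names = list(cell_spec.class_names[: cell_spec.n_classes])
        coarse_profiles = smooth_maps(
            geometry.coords, 3, np.random.default_rng(rng.integers(2**31 - 1))
        )[lh_mask]
        coarse_profiles = (
            coarse_profiles - coarse_profiles.mean(axis=0)
        ) / coarse_profiles.std(axis=0, ddof=1)
        w = float(cell_spec.fine_w)
        for c, cname in enumerate(names):
            coarse = int(cell_spec.coarse_map.get(cname, c % 3))
            class_coarse[cname] = coarse
            fine = F[:, (1 + c) % k_factors]
            profile = np.sqrt(max(0.0, 1 - w**2)) * coarse_profiles[:, coarse] + w * fine
            if cell_spec.couple_class_to_cnv == cname:
                profile = F[:, 0].copy()
            class_profiles[cname] = standardize(profile)
            for s in range(cell_spec.sets_per_class):
                sig = f"{cname}__s{s + 1}"
                planted_classes[sig] = cname
                genes = [f"{cname}.s{s + 1}.g{g + 1:02d}" for g in range(cell_spec.genes_per_set)]
                sig_gene_map[sig] = genes
                sig_genes_flat.extend(genes)
        if cell_spec.include_unassignable:
            for label, profile in [
                ("Neuron", standardize(
                    class_profiles.get("Neuro-Ex", F[:, 1])
                    + class_profiles.get("Neuro-In", F[:, 2])
                )),
                ("Per", standardize(coarse_profiles[:, 1] + 0.5 * F[:, k_factors - 1])),
            ]:
                sig = f"{label}__s1"
                planted_classes[sig] = label
                class_profiles[label] = profile
                genes = [f"{label}.s1.g{g + 1:02d}" for g in range(cell_spec.genes_per_set)]
                sig_gene_map[sig] = genes
                sig_genes_flat.extend(genes)

    n_reserved = len(cnv_genes) + len(sig_genes_flat)
    if n_reserved >= n_genes:
        raise ConfigError(
            f"{n_reserved} planted genes exceed n_genes={n_genes}"
        )
    bg_genes = [_gene_name("G", i) for i in range(n_genes - n_reserved)]
    genes = cnv_genes + sig_genes_flat + bg_genes

    # --- expression profiles ---------------------------------------------
    profiles = np.empty((n_reg, n_genes))
    loadings = np.zeros((n_genes, k_factors))
    couplings = cnv_spec.gene_couplings()
    if np.any(np.abs(couplings) > 1):
        raise ConfigError("per-gene couplings must lie in [-1, 1]")
    u_shared = standardize(rng.standard_normal(n_reg))
    col = 0
    for i, r in enumerate(couplings):
        e = rng.standard_normal(n_reg)
        profiles[:, col] = r * F[:, 0] + np.sqrt(1 - r**2) * u_shared + cnv_noise_sd * e
        loadings[col, 0] = r
        col += 1
    for sig, sig_genes in sig_gene_map.items():
        nsd = cell_spec.noise_sd if cell_spec is not None else 0.0
        # signature-level deviation does not average away over the set's
        # genes, emulating study-to-study variation within a cell class
        sig_profile = class_profiles[planted_classes[sig]] + nsd * rng.standard_normal(n_reg)
        for _ in sig_genes:
            e = rng.standard_normal(n_reg)
            profiles[:, col] = sig_profile + nsd * e
            col += 1
    n_bg = len(bg_genes)
    lam = rng.normal(0.0, background_loading_sd, size=(n_bg, k_factors))
    noise = rng.standard_normal((n_reg, n_bg))
    profiles[:, col:] = F @ lam.T + background_noise_sd * noise
    loadings[col:] = lam

    baselines = rng.normal(6.0, 1.0, size=n_genes)

    donors = []
    for d in range(n_donors):
        eps = rng.standard_normal((n_reg, n_genes))
        mat = profiles + baselines + donor_noise_sd * eps
        donors.append(pd.DataFrame(mat, index=regions, columns=genes))

    # --- annotations ------------------------------------------------------
    ann = _annotate_genes(
        genes, cnv_genes, sig_genes_flat, cnv_spec, chromosomes, rng,
        brain_expressed_rate,
    )

    set_mean = profiles[:, : cnv_spec.size].mean(axis=1)
    realized_r = float(np.corrcoef(set_mean, F[:, 0])[0, 1])

    sign = 1 if cnv_spec.sign in (1, "gain") else -1
    change_map = -sign * factors[:, 0]
    ds_flags = dict(zip(cnv_genes, cnv_spec.ds_labels())) if cnv_spec.n_ds else {}
    class_genes = {}
    for sig, cname in planted_classes.items():
        class_genes.setdefault(cname, [])
        class_genes[cname].extend(sig_gene_map[sig])

    manifest = GroundTruthManifest(
        seed=int(seed),
        region_ids=list(geometry.region_ids),
        hemispheres=list(geometry.hemispheres),
        latent_factors=factors,
        lh_factors=F,
        gene_names=genes,
        gene_loadings=loadings,
        planted_cnv_set=list(cnv_genes),
        cnv_sign=sign,
        cnv_chromosome=str(cnv_spec.chromosome),
        cnv_interval=_cnv_interval(ann, cnv_genes),
        coupling_r=float(cnv_spec.coupling_r),
        realized_coupling_r=realized_r,
        planted_change_map=change_map,
        planted_classes=planted_classes,
        class_coarse=class_coarse,
        class_genes=class_genes,
        brain_expressed=dict(zip(ann["gene"], ann["brain_expressed"].astype(bool))),
        ds_flags=ds_flags,
        extras={"signature_genes": sig_gene_map},
    )
    manifest.validate_against_genes(genes)
    return donors, ann, manifest


def _annotate_genes(
    genes, cnv_genes, sig_genes, cnv_spec, chromosomes, rng, brain_rate
) -> pd.DataFrame:
    chrom_of: dict[str, str] = {}
    for g in cnv_genes:
        chrom_of[g] = str(cnv_spec.chromosome)
    others = [g for g in genes if g not in chrom_of]
    labels = [c for c in chromosomes]
    if getattr(cnv_spec, "spans_chromosome", False):
        labels = [c for c in labels if c != str(cnv_spec.chromosome)]
    elif str(cnv_spec.chromosome) not in labels:
        labels.append(str(cnv_spec.chromosome))
    for i, g in enumerate(others):
        chrom_of[g] = labels[i % len(labels)]
    # lay genes sequentially per chromosome; CNV genes occupy the start of
    # their chromosome so the planted interval is recoverable from medians
    order: dict[str, int] = {}
    counters: dict[str, int] = {}
    for g in cnv_genes + [g for g in genes if g not in cnv_genes]:
        c = chrom_of[g]
        order[g] = counters.get(c, 0)
        counters[c] = order[g] + 1
    rows = []
    planted = set(cnv_genes) | set(sig_genes)
    for g in genes:
        start = order[g] * 1000.0
        rows.append(
            {
                "gene": g,
                "chromosome": chrom_of[g],
                "start": start,
                "end": start + 500.0,
                "brain_expressed": True if g in planted else bool(rng.random() < brain_rate),
            }
        )
    return pd.DataFrame(rows)


def _cnv_interval(ann: pd.DataFrame, cnv_genes) -> tuple[float, float]:
    sel = ann[ann["gene"].isin(set(cnv_genes))]
    return (float(sel["start"].min()), float(sel["end"].max()))
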