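"""One-call generation of a full synthetic study."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, generate_cohort
from .expression import generate_expression_atlas
from .geometry import ParcellationGeometry, generate_geometry
from .individual_expr import generate_individual_expression
from .manifest import CellSpec, CnvSpec, GroundTruthManifest
from .signatures import generate_cell_signatures


@dataclass
class SyntheticConfig:
    """Study conditions for a full synthetic dataset.

    Defaults emulate the scale of the reference study where desk-scale
    runtime allows: 152 regions per hemisphere, 6 expression donors, a
    40-gene CNV set coupled at r = 0.7, 7 cell classes x 3 study
    signatures, and 11 dosage-sensitive assay genes across >= 2 carrier
    karyotype groups.
    """

    n_per_hemisphere: int = 152
    n_genes: int = 2000
    n_donors: int = 6
    k_factors: int = 8
    cnv: CnvSpec = field(default_factory=CnvSpec)
    cells: CellSpec | None = field(default_factory=CellSpec)
    design: str = "case_control"
    n_cases: int = 40
    n_controls: int = 40
    effect_size: float = 1.0
    donor_noise_sd: float = 0.3
    subject_noise_sd: float = 0.35
    severity_sd: float = 0.6
    individual_beta: float = 0.0
    individual_noise_sd: float = 0.3
    n_ds_assay_genes: int = 11


@dataclass
class SyntheticDataset:
    geometry: ParcellationGeometry
    donors: list[pd.DataFrame]
    annotations: pd.DataFrame
    cohort: CohortTable
    signatures: list
    individual_expression: pd.DataFrame | None
    manifest: GroundTruthManifest


def generate_dataset(config: SyntheticConfig, seed: int) -> SyntheticDataset:
    """Generate every pipeline input from one seed (byte-reproducible)."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]
    geometry = generate_geometry(config.n_per_hemisphere, seed=seeds[0])
    donors, annotations, manifest = generate_expression_atlas(
        geometry,
        n_genes=config.n_genes,
        n_donors=config.n_donors,
        k_factors=config.k_factors,
        cnv_spec=config.cnv,
        seed=seeds[1],
        cell_spec=config.cells,
        donor_noise_sd=config.donor_noise_sd,
    )
    cohort = generate_cohort(
        geometry,
        manifest,
        design=config.design,
        n_cases=config.n_cases,
        n_controls=config.n_controls,
        effect_size=config.effect_size,
        seed=seeds[2],
        subject_noise_sd=config.subject_noise_sd,
        severity_sd=config.severity_sd,
    )
    signatures = (
        generate_cell_signatures(manifest, config.cells, seed=seeds[3])
        if config.cells is not None
        else []
    )
    individual = None
    if config.design == "aneuploidy":
        individual = generate_individual_expression(
            cohort,
            manifest,
            n_ds_genes=config.n_ds_assay_genes,
            beta=config.individual_beta,
            noise_sd=config.individual_noise_sd,
            seed=seeds[3] + 1,
        )
        manifest.individual_beta = float(config.individual_beta)
    return SyntheticDataset(
        geometry=geometry,
        donors=donors,
        annotations=annotations,
        cohort=cohort,
        signatures=signatures,
        individual_expression=individual,
        manifest=manifest,
    )
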