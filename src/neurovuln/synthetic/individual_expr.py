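"""Subject-level carrier expression coupled to anatomical deviation.

Emulates qPCR-style measurements of dosage-sensitive genes in carriers:
per-subject expression is the karyotype-group mean plus ``beta`` times the
subject's morphometric-similarity deviation score along the planted change
map, plus Gaussian noise.  The deviation score is computed from the
cohort's actual MSNs, so the planted coupling propagates through the same
measurement pipeline the analysis uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .. import msn
from ..individual import scale_within_group
from .cohort import CohortTable
from .manifest import GroundTruthManifest


class ConfigError(ValueError):
    pass


def carrier_ms_deviation_scores(
    cohort: CohortTable, manifest: GroundTruthManifest, carriers: pd.Index
) -> pd.Series:
    """Within-group standardized projection of MS maps on the change map."""
    ms_table = msn.cohort_regional_ms(
        cohort.features, cohort.subjects, cohort.regions
    ).loc[carriers]
    groups = cohort.covariates.loc[carriers, "group"]
    scaled = scale_within_group(ms_table, groups)
    change = np.asarray(manifest.planted_change_map, dtype=float)
    raw = scaled.to_numpy() @ (change / np.linalg.norm(change))
    scores = pd.Series(raw, index=carriers)
    return scale_within_group(scores.to_frame("score"), groups)["score"]


def generate_individual_expression(
    cohort: CohortTable,
    manifest: GroundTruthManifest,
    n_ds_genes: int = 11,
    beta: float = 0.8,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Subjects x genes expression table for carriers.

    Gene columns reuse DS-flagged CNV gene names when available (falling
    back to the first CNV genes).  Returns a DataFrame indexed by carrier
    subject with a leading ``group`` column.
    """
    cov = cohort.covariates
    carriers = cov.index[cov["dx"] == 1]
    if len(carriers) == 0:
        if beta != 0:
            raise ConfigError("beta given but the cohort has no carriers")
        carriers = cov.index
    groups = cov.loc[carriers, "group"]
    if groups.nunique() < 2:
        raise ConfigError("need >= 2 karyotype groups of carriers")

    ds_named = [g for g, f in manifest.ds_flags.items() if f in ("DS", "DSSS")]
    pool = ds_named if len(ds_named) >= n_ds_genes else list(manifest.planted_cnv_set)
    if len(pool) < n_ds_genes:
        raise ConfigError(f"only {len(pool)} CNV genes available for {n_ds_genes} assays")
    gene_names = pool[:n_ds_genes]

    rng = np.random.default_rng(seed)
    scores = carrier_ms_deviation_scores(cohort, manifest, carriers)
    loadings = rng.uniform(0.5, 1.0, size=n_ds_genes)
    base = rng.normal(1.0, 0.2, size=n_ds_genes)  # housekeeping-normalized level
    group_shift = {g: 0.3 * i for i, g in enumerate(sorted(groups.unique()))}

    values = np.empty((len(carriers), n_ds_genes))
    for i, sid in enumerate(carriers):
        eps = rng.normal(0.0, noise_sd, size=n_ds_genes)
        values[i] = (
            base
            + group_shift[groups.loc[sid]]
            + beta * scores.loc[sid] * loadings
            + eps
        )
    table = pd.DataFrame(values, index=carriers, columns=gene_names)
    table.insert(0, "group", groups)
    return table
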