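"""Morphometric similarity networks (MSNs).

A subject's MSN is the region-by-region Pearson correlation of their
multivariate anatomical feature profiles.  Five features are used by
default: cortical thickness (CT, mm), surface area (SA, mm^2), gray matter
volume (GM, mm^3), mean curvature (MC, 1/mm) and intrinsic curvature
(IC, dimensionless).  Features are z-scored per feature across regions
within each subject before correlating, so feature units and value ranges
do not dominate the similarity estimate.  Regional (nodal) MS is a region's
mean similarity with every other region; its distribution across regions is
approximately zero-centered because the z-scored feature columns each sum
to ~0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_FEATURES = ("CT", "SA", "GM", "MC", "IC")


class ConstantFeatureError(ValueError):
    """A feature column has zero variance and cannot be z-scored."""


class UndefinedCorrelationError(ValueError):
    """A region's feature vector has zero variance; its MS edges are undefined."""


@dataclass
class MorphometricSimilarityNetwork:
    """Per-subject MSN.

    ``edge_matrix`` is symmetric with NaN on the diagonal (the diagonal is
    an excluded sentinel, never included in nodal averages).
    """

    subject_id: str
    regions: list[str]
    edge_matrix: np.ndarray

    @property
    def regional_ms(self) -> np.ndarray:
        return regional_ms(self)


def zscore_features(features: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score each feature column across regions for one subject.

    Uses the sample (n-1) standard deviation.  Raises
    :class:`ConstantFeatureError` naming the offending feature if a column
    has zero variance.
    """
    if features.shape[0] < 3:
        raise ValueError("need at least 3 regions to z-score features")
    values = features.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [str(features.columns[i]) for i in bad]
        raise ConstantFeatureError(f"zero-variance feature column(s): {names}")
    out = (values - mean) / sd
    return pd.DataFrame(out, index=features.index, columns=features.columns)


def build_msn(
    normalized: pd.DataFrame, subject_id: str = "subject"
) -> MorphometricSimilarityNetwork:
    """Region-by-region Pearson correlation of z-scored feature profiles.

    Each region contributes a vector of feature values (5-long by default);
    edge (i, j) is the correlation of region i's and region j's vectors.
    """
    values = normalized.to_numpy(dtype=float)
    n_regions = values.shape[0]
    if n_regions < 3:
        raise ValueError("need at least 3 regions to build an MSN")
    row_sd = values.std(axis=1)
    bad = np.flatnonzero(row_sd == 0)
    if bad.size:
        names = [str(normalized.index[i]) for i in bad]
        raise UndefinedCorrelationError(
            f"region(s) with zero feature variance: {names}"
        )
    edges = np.corrcoef(values)
    edges = (edges + edges.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(edges, np.nan)
    return MorphometricSimilarityNetwork(
        subject_id=subject_id,
        regions=[str(r) for r in normalized.index],
        edge_matrix=edges,
    )


def regional_ms(network: MorphometricSimilarityNetwork) -> np.ndarray:
    """Nodal similarity: mean of each region's off-diagonal edges."""
    edges = network.edge_matrix
    n = edges.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return np.where(mask, edges, 0.0).sum(axis=1) / (n - 1)


def cohort_regional_ms(
    feature_stack: np.ndarray,
    subjects: list[str],
    regions: list[str],
) -> pd.DataFrame:
    """Subjects x regions table of nodal similarity.

    ``feature_stack`` has shape (n_subjects, n_regions, n_features).
    """
    rows = []
    for i, sid in enumerate(subjects):
        table = pd.DataFrame(feature_stack[i], index=regions)
        net = build_msn(zscore_features(table), subject_id=sid)
        rows.append(regional_ms(net))
    return pd.DataFrame(np.asarray(rows), index=subjects, columns=regions)
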