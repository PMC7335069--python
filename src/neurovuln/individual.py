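"""Subject-level coupling between carrier gene expression and regional MS.

Here PLS operates with *subjects* as the shared dimension: the expression
block is subjects x genes (e.g. qPCR-style measures of dosage-sensitive
genes in carriers) and the anatomy block is subjects x regions (nodal MS).
Both blocks are z-scored per column within each karyotype group first, to
remove between-karyotype offsets.  The first-component cross-block
covariance is the shared-variance statistic; significance comes from
permuting the expression block's subject order.  The component's region
loadings are compared to the group-level change map with a spin test and a
subject bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import PermutationResult, permutation_result
from .spin import SpinNull, map_correlation, p_spin


@dataclass
class IndividualPlsComponent:
    gene_loadings: pd.Series
    region_loadings: pd.Series
    subject_scores_expression: pd.Series  # standardized
    subject_scores_ms: pd.Series  # standardized
    covariance: float  # first singular value of the cross-block covariance


def scale_within_group(
    matrix: pd.DataFrame, groups: pd.Series, min_group: int = 3
) -> pd.DataFrame:
    """Z-score each column within each karyotype group (sample SD)."""
    groups = groups.reindex(matrix.index)
    out = matrix.astype(float).copy()
    for g, idx in groups.groupby(groups).groups.items():
        if len(idx) < min_group:
            raise ValueError(f"group {g!r} has {len(idx)} subjects (< {min_group})")
        sub = out.loc[idx]
        sd = sub.std(axis=0, ddof=1).replace(0, 1.0)
        out.loc[idx] = (sub - sub.mean(axis=0)) / sd
    return out


def _first_cross_component(X0: np.ndarray, Y0: np.ndarray):
    """Dominant singular triplet of the cross-block covariance X0'Y0/(n-1)."""
    n = X0.shape[0]
    S = X0.T @ Y0 / (n - 1)
    u, s, vt = np.linalg.svd(S, full_matrices=False)
    return u[:, 0], float(s[0]), vt[0]


def fit_individual_pls(
    expression: pd.DataFrame, ms: pd.DataFrame
) -> IndividualPlsComponent:
    """First SIMPLS component with subjects as the common dimension.

    Columns of both blocks are centered across subjects.  Polarity: a
    joint sign flip of (gene loadings, region loadings) leaves the score
    correlation invariant, so two conventions pin the component: the mean
    gene loading is non-negative (dosage-sensitive assay genes move
    together, so their shared burden axis is read as positive), and the
    two blocks' standardized subject scores correlate non-negatively.
    """
    if not expression.index.equals(ms.index):
        raise ValueError("expression and MS blocks have mismatched subjects")
    if len(expression) < 5:
        raise ValueError("need at least 5 subjects")
    X = expression.to_numpy(dtype=float)
    Y = ms.to_numpy(dtype=float)
    X0 = X - X.mean(axis=0)
    Y0 = Y - Y.mean(axis=0)
    w, s1, q = _first_cross_component(X0, Y0)
    if w.mean() < 0:
        w, q = -w, -q
    t = X0 @ w
    u = Y0 @ q
    t = (t - t.mean()) / t.std(ddof=1)
    u = (u - u.mean()) / u.std(ddof=1)
    if np.corrcoef(t, u)[0, 1] < 0:
        q, u = -q, -u
    return IndividualPlsComponent(
        gene_loadings=pd.Series(w, index=expression.columns, name="gene_loading"),
        region_loadings=pd.Series(q, index=ms.columns, name="region_loading"),
        subject_scores_expression=pd.Series(t, index=expression.index),
        subject_scores_ms=pd.Series(u, index=ms.index),
        covariance=s1,
    )


def component_significance(
    expression: pd.DataFrame,
    ms: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test of the first-component cross-block covariance.

    The null permutes subject rows of the expression block only (either
    block is equivalent under the null; one is fixed for determinism).
    """
    X = expression.to_numpy(dtype=float)
    Y = ms.to_numpy(dtype=float)
    X0 = X - X.mean(axis=0)
    Y0 = Y - Y.mean(axis=0)
    _, observed, _ = _first_cross_component(X0, Y0)
    rng = np.random.default_rng(seed)
    n = X0.shape[0]
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        S = X0[perm].T @ Y0 / (n - 1)
        null[b] = np.linalg.svd(S, compute_uv=False)[0]
    return permutation_result(
        "first_component_covariance", observed, null, "high", seed
    )


def loadings_vs_changemap(
    component: IndividualPlsComponent,
    change_map: pd.Series,
    spins: SpinNull,
    expression: pd.DataFrame | None = None,
    ms: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Correlate region loadings with the group change map.

    Returns the observed r, the spin-test result (one-sided, positive
    alignment is the directional claim), and - when the raw blocks are
    given - a subject-bootstrap distribution of r with the PLS refitted on
    each resample.
    """
    cm = change_map.reindex(component.region_loadings.index).to_numpy(dtype=float)
    loadings = component.region_loadings.to_numpy(dtype=float)
    r = map_correlation(loadings, cm)
    spin_res = p_spin(loadings, cm, spins, alternative="greater", seed=seed)
    boot = None
    if expression is not None and ms is not None:
        rng = np.random.default_rng(seed)
        n = len(expression)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Xb = expression.to_numpy(dtype=float)[idx]
            Yb = ms.to_numpy(dtype=float)[idx]
            X0 = Xb - Xb.mean(axis=0)
            Y0 = Yb - Yb.mean(axis=0)
            try:
                w, _, q = _first_cross_component(X0, Y0)
            except np.linalg.LinAlgError:  # pragma: no cover - degenerate resample
                boot[b] = np.nan
                continue
            if w.mean() < 0:
                w, q = -w, -q
            if np.corrcoef(X0 @ w, Y0 @ q)[0, 1] < 0:
                q = -q
            boot[b] = np.corrcoef(q, cm)[0, 1]
    return {"r": r, "p_spin": spin_res, "bootstrap_r": boot}
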