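"""Group-level linear models on regional and edge-level morphometric similarity.

Two model families are supported, both ordinary least squares fitted per
response (region or edge):

- ``aneuploidy``:   NS_i ~ intercept + age + sex + Xan + Yan, where Xan and
  Yan are the numbers of supernumerary X and Y chromosomes; the contrast of
  interest is the T statistic of the Xan (or Yan) dosage coefficient.
- ``case_control``: NS_i ~ intercept + age + sex + Dx, with Dx the binary
  patient/control indicator; the contrast is the Dx T statistic
  (patient - control).

Edge-level effects are classified into four categories from the sign of the
mean edge weight in controls and the sign of the edge T statistic:
(+, +) hypercoupling, (-, +) dedifferentiation, (+, -) decoupling,
(-, -) hyperdifferentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import msn

MODELS = ("aneuploidy", "case_control")
EDGE_CATEGORIES = (
    "hypercoupling",
    "dedifferentiation",
    "decoupling",
    "hyperdifferentiation",
)


class SingularDesignError(ValueError):
    """The model matrix is rank deficient."""


@dataclass
class ChangeMap:
    """Per-region signed T statistics for a group contrast."""

    contrast: str
    model: str
    regions: list[str]
    t_stat: np.ndarray
    p_value: np.ndarray
    covariates: list[str] = field(default_factory=list)

    @property
    def z_for_plot(self) -> np.ndarray:
        """T map z-scored across regions (display convention only)."""
        t = self.t_stat
        return (t - t.mean()) / t.std(ddof=1)

    def as_series(self) -> pd.Series:
        return pd.Series(self.t_stat, index=self.regions, name=self.contrast)


@dataclass
class EdgeStats:
    regions: list[str]
    edge_t: np.ndarray
    control_mean_edge: np.ndarray
    category: np.ndarray  # dtype=object, NaN-diagonal excluded


def design_matrix(
    covariates: pd.DataFrame,
    model: str,
    extra: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the model matrix for one of the two model families.

    ``covariates`` must carry ``age`` and ``sex`` (M/F or 0/1) plus
    ``xan``/``yan`` (aneuploidy) or ``dx`` (case_control).  ``extra`` names
    additional covariate columns (e.g. total surface area).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    sex = covariates["sex"]
    if sex.dtype == object:
        sex = sex.map({"M": 0.0, "F": 1.0})
    cols = {"intercept": np.ones(len(covariates)), "age": covariates["age"], "sex": sex}
    if model == "aneuploidy":
        cols["xan"] = covariates["xan"]
        cols["yan"] = covariates["yan"]
    else:
        cols["dx"] = covariates["dx"]
    for name in extra or []:
        cols[name] = covariates[name]
    names = list(cols)
    X = np.column_stack([np.asarray(c, dtype=float) for c in cols.values()])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by rank growth
        aliased, seen = [], np.empty((X.shape[0], 0))
        for j, name in enumerate(names):
            trial = np.column_stack([seen, X[:, j]])
            if np.linalg.matrix_rank(trial) == seen.shape[1]:
                aliased.append(name)
            else:
                seen = trial
        raise SingularDesignError(f"rank-deficient design; aliased columns: {aliased}")
    return X, names


def ols_tstats(
    X: np.ndarray, Y: np.ndarray, coef_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS T statistics for one coefficient across many responses.

    ``Y`` is (n_obs, n_responses).  Returns (t, two-sided p).  Responses
    with zero residual variance get t = 0 when the coefficient estimate is
    also 0 (constant response), matching the convention that a flat
    response carries no group effect.
    """
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n_subjects > n_predictors + 1")
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[coef_index, coef_index])
    b = beta[coef_index]
    # relative tolerance: mean subtraction of a constant leaves O(eps^2) var
    constant = Y.var(axis=0) <= 1e-24 * ((Y**2).mean(axis=0) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / np.where(se > 0, se, 1.0), np.where(b == 0, 0.0, np.inf))
    t = np.where(constant, 0.0, t)
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    return t, pvals


def fit_regional_contrast(
    ms_table: pd.DataFrame,
    covariates: pd.DataFrame,
    model: str = "case_control",
    coef: str | None = None,
    extra_covariates: list[str] | None = None,
) -> ChangeMap:
    """Per-region OLS T statistic for the dosage / diagnosis coefficient.

    ``ms_table`` is subjects x regions (row order must match
    ``covariates``); ``coef`` defaults to ``"dx"`` (case_control) or
    ``"xan"`` (aneuploidy).
    """
    if coef is None:
        coef = "dx" if model == "case_control" else "xan"
    X, names = design_matrix(covariates, model, extra_covariates)
    if coef not in names:
        raise ValueError(f"coefficient {coef!r} not in design ({names})")
    Y = ms_table.to_numpy(dtype=float)
    t, p = ols_tstats(X, Y, names.index(coef))
    return ChangeMap(
        contrast=coef,
        model=model,
        regions=[str(c) for c in ms_table.columns],
        t_stat=t,
        p_value=p,
        covariates=names,
    )


def fit_edge_contrast(
    edge_stack: np.ndarray,
    regions: list[str],
    covariates: pd.DataFrame,
    model: str = "case_control",
    coef: str | None = None,
    control_mask: np.ndarray | None = None,
) -> EdgeStats:
    """Same linear model applied to every off-diagonal MSN edge.

    ``edge_stack`` is (n_subjects, n_regions, n_regions) with NaN
    diagonals.  ``control_mask`` selects the subjects whose mean edge
    weight anchors the edge-effect taxonomy; by default subjects with
    dx == 0 (or xan == yan == 0).
    """
    if coef is None:
        coef = "dx" if model == "case_control" else "xan"
    n_sub, n_reg, _ = edge_stack.shape
    iu = np.triu_indices(n_reg, k=1)
    Y = edge_stack[:, iu[0], iu[1]]
    X, names = design_matrix(covariates, model)
    t_flat, _ = ols_tstats(X, Y, names.index(coef))

    if control_mask is None:
        if model == "case_control":
            control_mask = covariates["dx"].to_numpy() == 0
        else:
            control_mask = (covariates["xan"].to_numpy() == 0) & (
                covariates["yan"].to_numpy() == 0
            )
    ctrl_flat = Y[np.asarray(control_mask, dtype=bool)].mean(axis=0)

    edge_t = np.full((n_reg, n_reg), np.nan)
    ctrl = np.full((n_reg, n_reg), np.nan)
    edge_t[iu] = t_flat
    edge_t[(iu[1], iu[0])] = t_flat
    ctrl[iu] = ctrl_flat
    ctrl[(iu[1], iu[0])] = ctrl_flat

    category = np.full((n_reg, n_reg), None, dtype=object)
    cat_flat = classify_edges(ctrl_flat, t_flat)
    category[iu] = cat_flat
    category[(iu[1], iu[0])] = cat_flat
    return EdgeStats(
        regions=list(regions), edge_t=edge_t, control_mean_edge=ctrl, category=category
    )


def classify_edges(control_weight, edge_t) -> np.ndarray:
    """Four-way edge-effect taxonomy from two signs.

    Exact zeros are assigned to the positive branch (a measure-zero event
    on real data; the tie rule keeps the function total and deterministic).
    """
    cw = np.atleast_1d(np.asarray(control_weight, dtype=float))
    et = np.atleast_1d(np.asarray(edge_t, dtype=float))
    pos_w, pos_t = cw >= 0, et >= 0
    out = np.empty(cw.shape, dtype=object)
    out[pos_w & pos_t] = "hypercoupling"
    out[~pos_w & pos_t] = "dedifferentiation"
    out[pos_w & ~pos_t] = "decoupling"
    out[~pos_w & ~pos_t] = "hyperdifferentiation"
    return out


def edge_annotation_summary(
    change_map: ChangeMap, edge_stats: EdgeStats, k: int = 10
) -> pd.DataFrame:
    """Absolute edge-T sums per category for the top-k +/- regions.

    For the k most positive and k most negative regional T statistics, each
    incident off-diagonal edge contributes |edge T| to its category's sum.
    Per-region category sums therefore partition the region's total
    |edge T| mass.
    """
    n = len(change_map.regions)
    if k > n // 2:
        raise ValueError(f"k={k} exceeds n_regions/2={n // 2}")
    order = np.argsort(change_map.t_stat)
    selected = [(int(i), "negative") for i in order[:k]] + [
        (int(i), "positive") for i in order[-k:][::-1]
    ]
    rows = []
    for idx, side in selected:
        sums = dict.fromkeys(EDGE_CATEGORIES, 0.0)
        for j in range(n):
            if j == idx:
                continue
            sums[edge_stats.category[idx, j]] += abs(edge_stats.edge_t[idx, j])
        rows.append(
            {
                "region": change_map.regions[idx],
                "side": side,
                "t_stat": change_map.t_stat[idx],
                **sums,
            }
        )
    return pd.DataFrame(rows)


def single_feature_contrast(
    feature_table: pd.DataFrame,
    covariates: pd.DataFrame,
    model: str = "case_control",
    coef: str | None = None,
) -> ChangeMap:
    """Change map on a raw regional feature (subjects x regions table)."""
    return fit_regional_contrast(feature_table, covariates, model, coef)


def leave_one_feature_out_maps(
    feature_stack: np.ndarray,
    feature_names: list[str],
    subjects: list[str],
    regions: list[str],
    covariates: pd.DataFrame,
    model: str = "case_control",
    coef: str | None = None,
) -> tuple[dict[str, ChangeMap], pd.Series, str]:
    """Change maps from 4-feature MSNs, one per excluded feature.

    Returns (maps, similarity-to-full-map, most-contributing feature),
    where the most contributing feature is the one whose exclusion
    minimizes the Pearson correlation with the full five-feature map.
    """
    if feature_stack.shape[2] - 1 < 3:
        raise ValueError("need at least 3 features after exclusion")
    full_ms = msn.cohort_regional_ms(feature_stack, subjects, regions)
    full_map = fit_regional_contrast(full_ms, covariates, model, coef)
    maps: dict[str, ChangeMap] = {}
    sims = {}
    for f, name in enumerate(feature_names):
        keep = [j for j in range(len(feature_names)) if j != f]
        ms_tab = msn.cohort_regional_ms(feature_stack[:, :, keep], subjects, regions)
        cmap = fit_regional_contrast(ms_tab, covariates, model, coef)
        maps[name] = cmap
        sims[name] = float(np.corrcoef(cmap.t_stat, full_map.t_stat)[0, 1])
    sims = pd.Series(sims, name="r_vs_full_map")
    return maps, sims, str(sims.idxmin())


def interaction_screen(
    ms_table: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Optional pre-check of Xan x sex and Xan x Yan interactions.

    Reports the minimum (across regions) two-sided p-value per interaction
    term; the dosage model assumes these are non-significant.
    """
    base, names = design_matrix(covariates, "aneuploidy")
    Y = ms_table.to_numpy(dtype=float)
    out = []
    sex = base[:, names.index("sex")]
    xan = base[:, names.index("xan")]
    yan = base[:, names.index("yan")]
    for term, col in [("xan:sex", xan * sex), ("xan:yan", xan * yan)]:
        X = np.column_stack([base, col])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            out.append({"term": term, "min_p": np.nan, "note": "aliased"})
            continue
        _, p = ols_tstats(X, Y, X.shape[1] - 1)
        out.append({"term": term, "min_p": float(np.min(p)), "note": ""})
    return pd.DataFrame(out)
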