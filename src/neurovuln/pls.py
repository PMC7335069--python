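"""SIMPLS partial least squares and gene ranking.

The predictor block X holds regional expression (regions x genes, already
z-scored per gene); the response y is a regional change map.  Both blocks
are centered (no rescaling) and the first SIMPLS component maximizes the
covariance between the score vectors T1 = X0 w1 and U1 = Y0 q1.  For a
univariate response the first-component gene weights are proportional to
the gene-wise covariance vector X0' y0, which serves as an independent
oracle in the tests.

Polarity convention: the signs of (w1, q1, T1, U1) are flipped jointly so
that corr(T1, change map) >= 0.  Genes are then ranked by w1 from most
positive (rank 1, centered rank ~ -(N-1)/2) to most negative (rank N).
Under this convention a gene with a strongly positive weight is expressed
highly where the change map is positive, and occupies an extreme *low*
rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegenerateResponseError(ValueError):
    """The change map is constant; PLS alignment is undefined."""


@dataclass
class PlsModel:
    genes: list[str]
    regions: list[str]
    w1: np.ndarray  # gene weights, unit norm
    q1: float
    T1: np.ndarray  # region scores of the predictor block
    U1: np.ndarray  # region scores of the response
    var_explained: np.ndarray  # per-component fraction of response variance
    component1_maximal: bool


@dataclass
class RankedGeneList:
    """All genes ordered by first-component PLS weight (descending)."""

    table: pd.DataFrame  # columns: gene, weight, rank, centered_rank

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    @property
    def n(self) -> int:
        return len(self.table)

    def centered_ranks(self, genes=None) -> np.ndarray:
        """Centered ranks (rank - (N+1)/2) for ``genes`` (default all)."""
        if genes is None:
            return self.table["centered_rank"].to_numpy()
        lookup = self.table.set_index("gene")["centered_rank"]
        missing = [g for g in genes if g not in lookup.index]
        if missing:
            raise KeyError(f"genes absent from ranked list: {missing[:10]}")
        return lookup.loc[list(genes)].to_numpy()

    def restrict(self, genes) -> "RankedGeneList":
        """Subset to ``genes`` (preserving order) and recompute ranks."""
        keep = self.table[self.table["gene"].isin(set(genes))].copy()
        if keep.empty:
            raise ValueError("restriction leaves no genes")
        keep["rank"] = np.arange(1, len(keep) + 1)
        keep["centered_rank"] = keep["rank"] - (len(keep) + 1) / 2.0
        return RankedGeneList(keep.reset_index(drop=True))


def simpls(X0: np.ndarray, Y0: np.ndarray, k: int):
    """SIMPLS decomposition of centered blocks (de Jong's algorithm).

    Returns (W, T, Q, var_explained) where W is (p, k) predictor weights,
    T (n, k) orthonormal predictor scores, Q (m, k) response loadings and
    ``var_explained`` the per-component fraction of total response variance
    recovered by each component.  The cross-product matrix is deflated by
    an orthonormal basis of the X-loadings rather than by the weights.
    """
    Y0 = np.atleast_2d(Y0.T).T if Y0.ndim == 1 else Y0
    n, p = X0.shape
    S = X0.T @ Y0
    toty = float((Y0**2).sum())
    W = np.zeros((p, k))
    T = np.zeros((n, k))
    Q = np.zeros((Y0.shape[1], k))
    V = np.zeros((p, k))
    var = np.zeros(k)
    for a in range(k):
        u_, s_, vt_ = np.linalg.svd(S, full_matrices=False)
        r = u_[:, 0]
        t = X0 @ r
        t = t - t.mean()
        normt = np.linalg.norm(t)
        if normt <= 1e-12:
            break
        t /= normt
        r /= normt
        pvec = X0.T @ t
        q = Y0.T @ t
        v = pvec.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pvec)
        nv = np.linalg.norm(v)
        if nv <= 1e-12:
            break
        v /= nv
        S = S - np.outer(v, v @ S)
        W[:, a], T[:, a], Q[:, a], V[:, a] = r, t, q, v
        var[a] = float((q**2).sum()) / toty
    return W, T, Q, var


def fit_pls_component(
    atlas_matrix: pd.DataFrame,
    change_map: pd.Series,
    k: int = 5,
) -> PlsModel:
    """First SIMPLS component aligning regional expression with a change map.

    ``atlas_matrix`` is regions x genes; ``change_map`` is indexed by the
    same regions.  Predictor columns and the response are centered only.
    """
    regions = [str(r) for r in atlas_matrix.index]
    y = change_map.reindex(atlas_matrix.index).to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("change map has missing/non-finite values on atlas regions")
    if len(regions) < 3:
        raise ValueError("need at least 3 regions")
    if np.ptp(y) == 0:
        raise DegenerateResponseError("constant change map")
    X = atlas_matrix.to_numpy(dtype=float)
    X0 = X - X.mean(axis=0)
    y0 = y - y.mean()
    k = min(k, len(regions) - 1, X.shape[1])
    W, T, Q, var = simpls(X0, y0[:, None], k)
    w1, t1, q1 = W[:, 0], T[:, 0], float(Q[0, 0])
    # fix polarity: predictor scores correlate non-negatively with the map
    if np.corrcoef(t1, y)[0, 1] < 0:
        w1, t1, q1 = -w1, -t1, -q1
    u1 = y0 * q1
    w1n = w1 / np.linalg.norm(w1)
    return PlsModel(
        genes=[str(g) for g in atlas_matrix.columns],
        regions=regions,
        w1=w1n,
        q1=q1,
        T1=t1,
        U1=u1,
        var_explained=var,
        component1_maximal=bool(var[0] >= var.max() - 1e-12),
    )


def rank_genes(model: PlsModel) -> RankedGeneList:
    """Sort genes by weight descending; rank 1 = most positive weight.

    Ties are broken lexicographically by gene label (stable, documented).
    """
    df = pd.DataFrame({"gene": model.genes, "weight": model.w1})
    df = df.sort_values(["weight", "gene"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    n = len(df)
    df["rank"] = np.arange(1, n + 1)
    df["centered_rank"] = df["rank"] - (n + 1) / 2.0
    return RankedGeneList(df)


def rank_gene_list(
    atlas_matrix: pd.DataFrame, change_map: pd.Series, k: int = 5
) -> RankedGeneList:
    """Convenience: fit the first component and rank all genes."""
    return rank_genes(fit_pls_component(atlas_matrix, change_map, k=k))


def explained_variance_profile(
    atlas_matrix: pd.DataFrame, change_map: pd.Series, k: int = 5
) -> tuple[np.ndarray, bool]:
    """Per-component response-variance fractions and a comp-1-maximal flag."""
    if k < 2:
        raise ValueError("k must be >= 2")
    model = fit_pls_component(atlas_matrix, change_map, k=k)
    return model.var_explained, model.component1_maximal


def lodo_loading_stability(
    lodo_matrices: list[pd.DataFrame],
    full_matrix: pd.DataFrame,
    change_map: pd.Series,
) -> tuple[np.ndarray, float]:
    """Leave-one-donor-out stability of first-component gene weights.

    Fits the PLS on the full atlas and on each leave-one-donor-out atlas
    (polarity fixed against the same change map in every fit) and returns
    the per-leave-out Pearson correlation of gene weights with the
    full-atlas weights, plus their mean.
    """
    if len(lodo_matrices) < 2:
        raise ValueError("need at least 2 leave-one-out atlases")
    full = fit_pls_component(full_matrix, change_map)
    rs = []
    for m in lodo_matrices:
        if list(m.columns) != list(full_matrix.columns):
            raise ValueError("gene sets differ across atlases")
        sub = fit_pls_component(m, change_map)
        rs.append(float(np.corrcoef(sub.w1, full.w1)[0, 1]))
    rs = np.asarray(rs)
    return rs, float(rs.mean())
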