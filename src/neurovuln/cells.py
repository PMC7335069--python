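"""Cell-class decoding of bulk regional expression.

Study-specific cell-type gene sets are turned into regional expression
profiles (median z-scored expression of the set's genes per region).
Hierarchical clustering of the resulting signature x region matrix on
correlation distance, with the cluster count chosen by the gap statistic,
groups signatures into broad expression-defined clusters; finer canonical
cell classes are formed by tree co-membership and named by label
concordance, and are checked to be nested within the coarse clusters.
Class expression maps are weighted averages of member-signature profiles,
with weights decreasing in each signature's PCA-space distance from its
class centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._stats import PermutationResult
from .atlas import ExpressionAtlas, GeneSet
from .enrichment import p_rand_trans, median_rank
from .pls import RankedGeneList

#: study labels that cannot be assigned to one of the canonical classes
UNASSIGNABLE_LABELS = ("Neuron", "Per")

CANONICAL_CLASSES = (
    "Astro",
    "Endo",
    "Micro",
    "Neuro-Ex",
    "Neuro-In",
    "Oligo",
    "OPC",
)


@dataclass
class CellTypeSignature:
    study_id: str
    cell_label: str
    genes: GeneSet
    class_assignment: str | None = None

    @property
    def name(self) -> str:
        return f"{self.cell_label}__{self.study_id}"


@dataclass
class CellClassMap:
    class_label: str
    regions: list[str]
    expression: np.ndarray  # per-region weighted mean (z units)
    weights: dict[str, float] = field(default_factory=dict)


@dataclass
class ClusteringResult:
    signatures: list[str]
    linkage: np.ndarray
    chosen_k: int
    labels: np.ndarray  # cluster index per signature at chosen_k
    gap: np.ndarray
    gap_se: np.ndarray


def cell_by_region_matrix(
    atlas: ExpressionAtlas, signatures: list[CellTypeSignature]
) -> pd.DataFrame:
    """Signatures x regions matrix of median z-scored expression.

    Signatures with no genes in the atlas are dropped with a warning.
    """
    genes = set(atlas.genes)
    rows, index = [], []
    for sig in signatures:
        members = [g for g in sig.genes if g in genes]
        if not members:
            warnings.warn(f"signature {sig.name} has no atlas genes; dropped", stacklevel=2)
            continue
        rows.append(np.median(atlas.matrix[members].to_numpy(dtype=float), axis=1))
        index.append(sig.name)
    return pd.DataFrame(rows, index=index, columns=atlas.regions)


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Sum over clusters of squared distances to the cluster centroid."""
    total = 0.0
    for c in np.unique(labels):
        sub = X[labels == c]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def _cluster_labels(X: np.ndarray, k: int, method: str = "average") -> np.ndarray:
    dist = pdist(X, metric="correlation")
    Z = hierarchy.linkage(dist, method=method)
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def gap_statistic(
    X: np.ndarray,
    max_k: int,
    B_ref: int = 50,
    seed: int | None = None,
    method: str = "average",
) -> tuple[int, np.ndarray, np.ndarray]:
    """Tibshirani gap statistic with uniform-box references and 1-SE rule.

    Rows of ``X`` should be standardized profiles so that the Euclidean
    dispersion used here is monotone in the correlation distance used for
    clustering.  Chooses the smallest k with
    Gap(k) >= Gap(k+1) - SE(k+1).
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    ks = np.arange(1, max_k + 1)
    logW = np.empty(max_k)
    for i, k in enumerate(ks):
        labels = np.ones(n, dtype=int) if k == 1 else _cluster_labels(X, k, method)
        logW[i] = np.log(_within_dispersion(X, labels))
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_logW = np.empty((B_ref, max_k))
    for b in range(B_ref):
        ref = rng.uniform(lo, hi, size=(n, p))
        for i, k in enumerate(ks):
            labels = np.ones(n, dtype=int) if k == 1 else _cluster_labels(ref, k, method)
            ref_logW[b, i] = np.log(_within_dispersion(ref, labels))
    gap = ref_logW.mean(axis=0) - logW
    se = ref_logW.std(axis=0, ddof=1) * np.sqrt(1 + 1.0 / B_ref)
    chosen = int(ks[-1])
    for i in range(max_k - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            chosen = int(ks[i])
            break
    return chosen, gap, se


def cluster_cell_signatures(
    matrix: pd.DataFrame,
    max_k: int = 10,
    B_ref: int = 50,
    seed: int | None = None,
    method: str = "average",
) -> ClusteringResult:
    """Agglomerative clustering on correlation distance, k by gap statistic."""
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("need at least 3 signatures")
    if max_k >= n:
        raise ValueError(f"max_k={max_k} must be < n_signatures={n}")
    X = matrix.to_numpy(dtype=float)
    Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
    Z = hierarchy.linkage(pdist(X, metric="correlation"), method=method)
    k, gap, se = gap_statistic(Xz, max_k, B_ref, seed, method)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusteringResult(
        signatures=[str(s) for s in matrix.index],
        linkage=Z,
        chosen_k=k,
        labels=labels,
        gap=gap,
        gap_se=se,
    )


def assign_cell_classes(
    clustering: ClusteringResult,
    signatures: list[CellTypeSignature],
    unassignable: tuple[str, ...] = UNASSIGNABLE_LABELS,
) -> tuple[dict[str, str], np.ndarray, bool]:
    """Form fine classes by tree co-membership, named by label concordance.

    The dendrogram is cut into as many fine clusters as there are distinct
    retained cell labels; each fine cluster is named by its majority label.
    Signatures with unassignable labels (e.g. an undivided "Neuron" set, or
    the pericyte "Per" set) are excluded before the cut.  Returns
    (assignment per signature name, fine labels aligned to the retained
    signatures, nested flag); nesting of fine classes within the coarse
    clusters is verified and flagged (not fatal) when violated.
    """
    by_name = {s.name: s for s in signatures}
    retained_idx = [
        i
        for i, name in enumerate(clustering.signatures)
        if by_name[name].cell_label not in unassignable
    ]
    names = [clustering.signatures[i] for i in retained_idx]
    labels_true = [by_name[n].cell_label for n in names]
    n_classes = len(set(labels_true))
    full_cut = hierarchy.fcluster(clustering.linkage, t=n_classes, criterion="maxclust")
    fine = full_cut[retained_idx]
    # relabel fine clusters among retained signatures only
    _, fine = np.unique(fine, return_inverse=True)
    if len(np.unique(fine)) < n_classes:
        # excluded signatures absorbed cut slots; cut deeper, retained only
        fine = _cut_subset(clustering, retained_idx, n_classes)
    assignment: dict[str, str] = {}
    for c in np.unique(fine):
        idx = np.flatnonzero(fine == c)
        labels_c = [labels_true[i] for i in idx]
        majority = max(set(labels_c), key=labels_c.count)
        for i in idx:
            assignment[names[i]] = majority
    coarse = clustering.labels[retained_idx]
    nested = all(
        len(np.unique(coarse[fine == c])) == 1 for c in np.unique(fine)
    )
    if not nested:
        warnings.warn("fine classes are not nested within coarse clusters", stacklevel=2)
    for s in signatures:
        s.class_assignment = assignment.get(s.name)
    return assignment, fine, nested


def _cut_subset(clustering: ClusteringResult, retained_idx, k: int) -> np.ndarray:
    """Re-cluster only the retained signatures into k fine clusters."""
    # derive pairwise cophenetic-free distances from original linkage order:
    # simplest faithful fallback is to cut the full tree deeper until the
    # retained signatures span k clusters.
    t = k
    n = len(clustering.signatures)
    while t <= n:
        cut = hierarchy.fcluster(clustering.linkage, t=t, criterion="maxclust")
        sub = cut[retained_idx]
        if len(np.unique(sub)) >= k:
            _, sub = np.unique(sub, return_inverse=True)
            return sub
        t += 1
    _, sub = np.unique(cut[retained_idx], return_inverse=True)
    return sub


def derive_class_weights(
    class_signatures: list[str],
    matrix: pd.DataFrame,
    variance_retained: float = 0.95,
    eps: float = 1e-6,
) -> dict[str, float]:
    """Inverse-distance weights from the class centroid in PCA space.

    Signature profiles are projected onto the principal components
    retaining >= ``variance_retained`` of variance; weight_i is
    proportional to 1 / (d_i + eps) with d_i the Euclidean distance to the
    class centroid, normalized to sum 1.
    """
    if not class_signatures:
        raise ValueError("class has no signatures")
    X = matrix.loc[class_signatures].to_numpy(dtype=float)
    if X.shape[0] == 1:
        return {class_signatures[0]: 1.0}
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    if var.sum() > 0:
        keep = int(np.searchsorted(np.cumsum(var) / var.sum(), variance_retained) + 1)
    else:
        keep = 1
    proj = U[:, :keep] * s[:keep]
    d = np.linalg.norm(proj - proj.mean(axis=0), axis=1)
    w = 1.0 / (d + eps)
    w /= w.sum()
    return dict(zip(class_signatures, w.tolist()))


def class_expression_map(
    class_label: str,
    weights: dict[str, float],
    matrix: pd.DataFrame,
) -> CellClassMap:
    """Per-region weighted mean of member-signature profiles."""
    names = list(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    X = matrix.loc[names].to_numpy(dtype=float)
    return CellClassMap(
        class_label=class_label,
        regions=[str(c) for c in matrix.columns],
        expression=w @ X,
        weights=dict(weights),
    )


def class_gene_sets(
    signatures: list[CellTypeSignature],
) -> dict[str, GeneSet]:
    """Omnibus gene set per assigned class (union over member signatures)."""
    out: dict[str, list[str]] = {}
    for s in signatures:
        if s.class_assignment is None:
            continue
        out.setdefault(s.class_assignment, [])
        for g in s.genes:
            if g not in out[s.class_assignment]:
                out[s.class_assignment].append(g)
    return {
        c: GeneSet(name=c, members=genes, provenance="cell_type")
        for c, genes in out.items()
    }


@dataclass
class CellScreenHit:
    cnv: str
    cell_class: str
    p: float
    direction_median: float
    genes: list[str]


def cnv_cell_screen(
    ranked: RankedGeneList,
    class_sets: dict[str, GeneSet],
    cnv_set: GeneSet,
    brain_expressed: dict[str, bool],
    centile: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    cnv_name: str = "CNV",
    alpha: float = 0.05,
) -> list[CellScreenHit]:
    """Screen cell classes for rank enrichment plus extreme CNV genes.

    The ranked list is first restricted to brain-expressed genes.  A
    (CNV, class) association is reported iff (i) the class gene set has a
    significantly extreme median rank (two-sided P_RAND < alpha) in the
    restricted list, and (ii) at least one gene that is in the CNV set, in
    the class set and brain-expressed sits below the ``centile`` or above
    the ``1 - centile`` rank centile of the restricted list.
    """
    brain_genes = [g for g in ranked.genes if brain_expressed.get(g, False)]
    if not brain_genes:
        raise ValueError("no brain-expressed genes in ranked list")
    sub = ranked.restrict(brain_genes)
    n = sub.n
    lo_cut = -(n + 1) / 2.0 + centile * n
    hi_cut = (n + 1) / 2.0 - centile * n
    hits = []
    rng = np.random.default_rng(seed)
    for label, cset in sorted(class_sets.items()):
        members = [g for g in cset if g in set(sub.genes)]
        if not members:
            warnings.warn(f"class {label} has no ranked genes; skipped", stacklevel=2)
            continue
        observed = median_rank(sub, members)
        res = p_rand_trans(
            sub, len(members), observed, "most_extreme",
            n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
        )
        if res.p >= alpha:
            continue
        overlap = [g for g in cnv_set if g in set(members)]
        if centile <= 0:
            extreme = []
        else:
            cr = {g: r for g, r in zip(sub.genes, sub.centered_ranks())}
            extreme = [g for g in overlap if cr[g] <= lo_cut or cr[g] >= hi_cut]
        if extreme:
            hits.append(
                CellScreenHit(
                    cnv=cnv_name,
                    cell_class=label,
                    p=res.p,
                    direction_median=observed,
                    genes=sorted(extreme),
                )
            )
    return hits


def differential_expression_map(
    atlas: ExpressionAtlas, set_a, set_b
) -> pd.Series:
    """Per-region mean_z(set A) - mean_z(set B)."""
    genes = set(atlas.genes)
    a = [g for g in set_a if g in genes]
    b = [g for g in set_b if g in genes]
    if not a or not b:
        raise ValueError("both gene sets must be nonempty in the atlas")
    diff = atlas.matrix[a].mean(axis=1) - atlas.matrix[b].mean(axis=1)
    diff.name = "differential_expression"
    return diff
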