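"""Assembly of the analysis-ready regional expression atlas.

Donor-level region x gene matrices are aggregated by the elementwise
median across donors, then each gene's regional values are z-scored across
regions (sample SD).  Gene annotations carry chromosome (1..22, X, Y and
PAR as its own label), an optional genomic interval and a brain-expressed
flag.  CNV gene sets are derived either as whole chromosomes or as the
genes encompassed by the median proximal/distal breakpoint interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GeneSet:
    name: str
    members: list[str]
    provenance: str = "custom"  # chromosome | interval | cell_type | DS | nDS | DSSS | custom

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ExpressionAtlas:
    """Z-scored region x gene matrix plus the donor stack and annotations."""

    matrix: pd.DataFrame  # regions x genes, z-score units
    donors: list[pd.DataFrame] = field(default_factory=list)
    annotations: pd.DataFrame | None = None  # gene, chromosome, start, end, brain_expressed

    @property
    def regions(self) -> list[str]:
        return [str(r) for r in self.matrix.index]

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.matrix.columns]

    def chromosome_genes(self, chromosome: str) -> list[str]:
        ann = self._ann()
        return ann.loc[ann["chromosome"].astype(str) == str(chromosome), "gene"].tolist()

    def _ann(self) -> pd.DataFrame:
        if self.annotations is None:
            raise ValueError("atlas has no gene annotations")
        return self.annotations


def zscore_columns(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    sd = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame(
        (values - mean) / sd, index=matrix.index, columns=matrix.columns
    )


def aggregate_donor_expression(
    donors: list[pd.DataFrame],
    annotations: pd.DataFrame | None = None,
) -> ExpressionAtlas:
    """Elementwise median across donors, then per-gene z across regions."""
    if not donors:
        raise ValueError("need at least one donor matrix")
    first = donors[0]
    for d in donors[1:]:
        if not (d.index.equals(first.index) and d.columns.equals(first.columns)):
            raise ValueError("donor matrices have misaligned region/gene axes")
    stack = np.stack([d.to_numpy(dtype=float) for d in donors])
    median = pd.DataFrame(
        np.median(stack, axis=0), index=first.index, columns=first.columns
    )
    return ExpressionAtlas(
        matrix=zscore_columns(median), donors=list(donors), annotations=annotations
    )


def filter_brain_expressed(atlas: ExpressionAtlas) -> ExpressionAtlas:
    """Column subset to brain-expressed genes; z-scores are NOT recomputed.

    Gene ranking always happens on the full atlas; this filter applies to
    the GO export and the cell-class analyses.
    """
    ann = atlas._ann()
    keep = ann.loc[ann["brain_expressed"].astype(bool), "gene"].tolist()
    keep = [g for g in keep if g in set(atlas.genes)]
    if not keep:
        raise ValueError("no brain-expressed genes in atlas")
    return ExpressionAtlas(
        matrix=atlas.matrix[keep],
        donors=atlas.donors,
        annotations=ann[ann["gene"].isin(set(keep))].reset_index(drop=True),
    )


def derive_cnv_gene_set(
    annotations: pd.DataFrame,
    chromosome: str | None = None,
    interval: tuple[float, float] | None = None,
    proximal_breakpoints=None,
    distal_breakpoints=None,
    name: str = "CNV",
) -> GeneSet:
    """Gene set from a chromosome label, an interval, or breakpoint lists.

    Breakpoint lists collapse to [median(proximal), median(distal)].  A
    gene is encompassed iff its annotated start AND end lie within the
    closed interval.  A chromosome spec returns every gene with that label
    (PAR being its own label).
    """
    if proximal_breakpoints is not None or distal_breakpoints is not None:
        if not proximal_breakpoints or not distal_breakpoints:
            raise ValueError("both breakpoint lists must be nonempty")
        interval = (
            float(np.median(np.asarray(proximal_breakpoints, dtype=float))),
            float(np.median(np.asarray(distal_breakpoints, dtype=float))),
        )
    if interval is not None:
        lo, hi = interval
        rows = annotations
        if chromosome is not None:
            rows = rows[rows["chromosome"].astype(str) == str(chromosome)]
        sel = rows[(rows["start"] >= lo) & (rows["end"] <= hi)]
        members = sel["gene"].tolist()
        if not members:
            raise ValueError(f"interval [{lo}, {hi}] selects zero atlas genes")
        return GeneSet(name=name, members=members, provenance="interval")
    if chromosome is not None:
        members = annotations.loc[
            annotations["chromosome"].astype(str) == str(chromosome), "gene"
        ].tolist()
        if not members:
            raise ValueError(f"chromosome {chromosome!r} has zero atlas genes")
        return GeneSet(name=name, members=members, provenance="chromosome")
    raise ValueError("give a chromosome, an interval, or breakpoint lists")


def leave_one_donor_out_atlases(
    donors: list[pd.DataFrame],
    annotations: pd.DataFrame | None = None,
) -> list[ExpressionAtlas]:
    """One aggregated atlas per excluded donor."""
    if len(donors) < 2:
        raise ValueError("need at least 2 donors for leave-one-out")
    out = []
    for i in range(len(donors)):
        rest = [d for j, d in enumerate(donors) if j != i]
        out.append(aggregate_donor_expression(rest, annotations))
    return out
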