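"""Materialize planted cell-type signatures as gene sets."""

from __future__ import annotations

import numpy as np

from ..atlas import GeneSet
from ..cells import CellTypeSignature
from .manifest import CellSpec, GroundTruthManifest


def generate_cell_signatures(
    manifest: GroundTruthManifest,
    cell_spec: CellSpec | None = None,
    seed: int | None = None,
) -> list[CellTypeSignature]:
    """Signature objects for the gene sets planted in the atlas.

    The expression profiles were planted at atlas generation; this step
    assembles the GMT-style signature list (one per study-specific
    cell-type gene set) and, when a class is coupled to the CNV,
    adds the overlap CNV genes to that class's signatures.
    """
    sig_genes = manifest.extras.get("signature_genes", {})
    if not sig_genes:
        raise ValueError("manifest has no planted signatures")
    rng = np.random.default_rng(seed)
    out = []
    for name, genes in sig_genes.items():
        label, study = name.split("__")
        members = list(genes)
        if (
            cell_spec is not None
            and cell_spec.couple_class_to_cnv == label
            and cell_spec.n_cnv_overlap > 0
        ):
            members = members + list(manifest.planted_cnv_set[: cell_spec.n_cnv_overlap])
        out.append(
            CellTypeSignature(
                study_id=study,
                cell_label=label,
                genes=GeneSet(name=name, members=members, provenance="cell_type"),
            )
        )
    return out
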