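"""Ground-truth manifest and planted-structure specifications."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


@dataclass
class CnvSpec:
    """Planted CNV gene set and its coupling to the anatomical gradient.

    ``sign`` is +1 for a gain (duplication) and -1 for a loss (deletion);
    the planted anatomical change map is ``-sign * factor1``, so regions
    of high CNV-set expression lose morphometric similarity under a gain
    and gain it under a loss.  ``coupling_r`` is the target correlation of
    each CNV gene's expression profile (and hence of the set-mean
    gradient) with factor 1.

    Dosage-sensitivity structure is optional: of the ``size`` genes, the
    first ``n_dsss`` get loading ``dsss_r`` (by default strongly opposite
    to the set: dosage-sensitive genes whose gradient aligns with the
    change map itself), the next ``n_ds - n_dsss`` get ``ds_r`` and the
    rest (nDS) get ``nds_r``; ``None`` falls back to ``coupling_r``.
    """

    name: str = "CNV"
    chromosome: str = "X"
    size: int = 40
    #: aneuploidy-style CNV: the set IS the whole chromosome (no other
    #: genes are assigned to it); subchromosomal CNVs share their
    #: chromosome with background genes
    spans_chromosome: bool = False
    sign: int = 1
    coupling_r: float = 0.7
    n_ds: int = 0
    n_dsss: int = 0
    ds_r: float | None = None
    dsss_r: float = -0.9
    nds_r: float | None = None

    def gene_couplings(self) -> np.ndarray:
        r = np.full(self.size, float(self.coupling_r))
        if self.n_ds > 0:
            ds_r = self.coupling_r if self.ds_r is None else self.ds_r
            nds_r = self.coupling_r if self.nds_r is None else self.nds_r
            r[:] = nds_r
            r[: self.n_ds] = ds_r
            r[: self.n_dsss] = self.dsss_r
        return r

    def ds_labels(self) -> list[str]:
        labels = ["nDS"] * self.size
        for i in range(min(self.n_ds, self.size)):
            labels[i] = "DS"
        for i in range(min(self.n_dsss, self.size)):
            labels[i] = "DSSS"
        return labels


@dataclass
class CellSpec:
    """Planted cell-class structure.

    ``coarse_map`` assigns each of the seven canonical classes to one of
    three coarse expression clusters (oligodendrocytes; other glia and
    endothelium; neurons).  ``fine_w`` sets how far each fine class
    departs from its coarse profile (0 = classes within a coarse group
    are identical; 1 = unrelated).  When ``couple_class_to_cnv`` names a
    class, that class's regional profile is replaced by the CNV expression
    gradient (factor 1) and ``n_cnv_overlap`` CNV genes are added to each
    of its signatures' gene sets.
    """

    n_classes: int = 7
    sets_per_class: int = 3
    genes_per_set: int = 12
    noise_sd: float = 0.2
    fine_w: float = 0.45
    class_names: tuple = (
        "Astro",
        "Endo",
        "Micro",
        "Neuro-Ex",
        "Neuro-In",
        "Oligo",
        "OPC",
    )
    coarse_map: dict = field(
        default_factory=lambda: {
            "Oligo": 0,
            "Astro": 1,
            "Endo": 1,
            "Micro": 1,
            "OPC": 1,
            "Neuro-Ex": 2,
            "Neuro-In": 2,
        }
    )
    include_unassignable: bool = False
    couple_class_to_cnv: str | None = None
    n_cnv_overlap: int = 3


@dataclass
class GroundTruthManifest:
    """Everything planted by the generator, for downstream verification."""

    seed: int
    region_ids: list = field(default_factory=list)
    hemispheres: list = field(default_factory=list)
    latent_factors: np.ndarray | None = None  # regions x K
    lh_factors: np.ndarray | None = None  # left-hemisphere view used by the atlas
    gene_names: list = field(default_factory=list)
    gene_loadings: np.ndarray | None = None  # genes x K
    planted_cnv_set: list = field(default_factory=list)
    cnv_sign: int = 1
    cnv_chromosome: str = "X"
    cnv_interval: tuple | None = None
    coupling_r: float = 0.0
    realized_coupling_r: float | None = None
    planted_change_map: np.ndarray | None = None  # all regions, -sign * factor1
    planted_classes: dict = field(default_factory=dict)  # signature -> class
    class_coarse: dict = field(default_factory=dict)  # class -> coarse cluster
    class_genes: dict = field(default_factory=dict)  # class -> gene list
    brain_expressed: dict = field(default_factory=dict)
    ds_flags: dict = field(default_factory=dict)  # gene -> DS | DSSS | nDS
    individual_beta: float = 0.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1.0 <= float(self.coupling_r) <= 1.0):
            raise ValueError("coupling_r must lie in [-1, 1]")

    def validate_against_genes(self, atlas_genes) -> None:
        missing = [g for g in self.planted_cnv_set if g not in set(atlas_genes)]
        if missing:
            raise ValueError(f"planted genes absent from atlas: {missing[:5]}")

    @property
    def change_map_lh(self) -> np.ndarray:
        mask = np.asarray(self.hemispheres) == "L"
        return np.asarray(self.planted_change_map)[mask]

    def to_json(self, path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.integer,)):
                return int(x)
            if isinstance(x, (np.floating,)):
                return float(x)
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        data = {k: conv(v) for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(data, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        data = json.loads(Path(path).read_text())
        for key in ("latent_factors", "lh_factors", "gene_loadings", "planted_change_map"):
            if data.get(key) is not None:
                data[key] = np.asarray(data[key], dtype=float)
        if data.get("cnv_interval") is not None:
            data["cnv_interval"] = tuple(data["cnv_interval"])
        return cls(**data)
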