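"""Curated EMT marker panel.

Three disjoint gene lists cover the epithelial programme (cell-cell
adhesion and apical polarity), the mesenchymal programme (intermediate
filaments, EMT transcription factors, matrix remodelling) and a hybrid
E/M programme of genes peaking in partial-EMT cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

EPITHELIAL_MARKERS: tuple[str, ...] = ("CDH1", "DSP", "OCLN", "CRB3")

MESENCHYMAL_MARKERS: tuple[str, ...] = (
    "VIM", "CDH2", "FOXC2", "SNAI1", "SNAI2", "TWIST1", "FN1", "ITGB6",
    "MMP2", "MMP3", "MMP9", "SOX10", "GSC", "ZEB1", "ZEB2", "TWIST2",
)

HYBRID_MARKERS: tuple[str, ...] = (
    "PDPN", "ITGA5", "ITGA6", "TGFBI", "LAMC2", "MMP10", "LAMA3", "CDH13",
    "SERPINE1", "P4HA2", "TNC", "MMP1",
)


@dataclass(frozen=True)
class MarkerSet:
    """Epithelial / mesenchymal / hybrid marker gene lists.

    The three lists must be disjoint and non-empty.  The default panel
    holds 32 genes in total.
    """

    epithelial: tuple[str, ...] = EPITHELIAL_MARKERS
    mesenchymal: tuple[str, ...] = MESENCHYMAL_MARKERS
    hybrid: tuple[str, ...] = HYBRID_MARKERS

    def __post_init__(self) -> None:
        e, m, h = set(self.epithelial), set(self.mesenchymal), set(self.hybrid)
        if not (e and m and h):
            raise ValueError("all three marker lists must be non-empty")
        if e & m or e & h or m & h:
            raise ValueError("marker lists must be disjoint")

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.epithelial + self.mesenchymal + self.hybrid

    @classmethod
    def from_tsv(cls, path) -> "MarkerSet":
        """Load a panel from a two-column TSV: gene, class.

        Class must be one of ``epithelial``, ``mesenchymal``, ``hybrid``.
        """
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["gene", "class"])
        groups = {k: tuple(g["gene"]) for k, g in df.groupby("class")}
        unknown = set(groups) - {"epithelial", "mesenchymal", "hybrid"}
        if unknown:
            raise ValueError(f"unknown marker class(es): {sorted(unknown)}")
        return cls(
            epithelial=groups.get("epithelial", ()),
            mesenchymal=groups.get("mesenchymal", ()),
            hybrid=groups.get("hybrid", ()),
        )


DEFAULT_MARKERS = MarkerSet()
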