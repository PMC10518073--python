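"""Core data model for single-cell immune repertoire projects.

The central object is :class:`RepertoireProject`, which links receptor
chains (BCR/TCR contigs paired per cell) with an optional gene-expression
matrix and per-cell metadata on the key ``(sample_id, barcode)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

#: Loci whose chains carry a D segment (heavy / beta / gamma / delta).
VDJ_LOCI = frozenset({"IGH", "TRB", "TRG", "TRD"})
#: Loci without a D segment (light / alpha).
VJ_LOCI = frozenset({"IGK", "IGL", "TRA"})
ALL_LOCI = VDJ_LOCI | VJ_LOCI


@dataclass(frozen=True)
class ContigRecord:
    """One assembled receptor chain observed in one cell barcode."""

    barcode: str
    contig_id: str
    locus: str
    v_call: str
    j_call: str
    cdr3_nt: str
    cdr3_aa: str
    d_call: str = ""
    c_call: str = ""
    sequence_nt: str = ""
    umi_count: int = 1
    read_count: int = 0
    productive: bool = True
    high_confidence: bool = True

    def __post_init__(self) -> None:
        if self.locus not in ALL_LOCI:
            raise ValueError(f"unknown locus {self.locus!r}")
        if self.umi_count < 0 or self.read_count < 0:
            raise ValueError("umi_count and read_count must be non-negative")

    @property
    def is_vdj_locus(self) -> bool:
        return self.locus in VDJ_LOCI


@dataclass(frozen=True)
class CellReceptor:
    """The filtered chain pair of one cell.

    After multi-chain resolution a cell retains at most one VDJ-locus
    chain (IGH/TRB/TRG/TRD) and one VJ-locus chain (IGK/IGL/TRA).
    ``chain_category`` records whether both were found (``paired``), only
    one (``vdj_only`` / ``vj_only``), or extra chains had to be dropped
    (``multi_resolved``).
    """

    sample_id: str
    barcode: str
    vdj_chain: Optional[ContigRecord] = None
    vj_chain: Optional[ContigRecord] = None
    chain_category: str = "paired"

    def __post_init__(self) -> None:
        if self.vdj_chain is None and self.vj_chain is None:
            raise ValueError(f"cell {self.barcode!r} has no chains")
        if self.vdj_chain is not None and self.vdj_chain.locus not in VDJ_LOCI:
            raise ValueError("vdj_chain must come from a VDJ locus")
        if self.vj_chain is not None and self.vj_chain.locus not in VJ_LOCI:
            raise ValueError("vj_chain must come from a VJ locus")

    @property
    def chains(self) -> list[ContigRecord]:
        return [c for c in (self.vdj_chain, self.vj_chain) if c is not None]

    @property
    def key(self) -> tuple[str, str]:
        return (self.sample_id, self.barcode)


@dataclass(frozen=True)
class FilterConfig:
    """Contig filtering switches applied by the readers.

    Defaults keep only productive, high-confidence contigs and strip a
    trailing ``-<digit>`` lane suffix from barcodes before matching.
    """

    productive_only: bool = True
    high_confidence_only: bool = True
    strip_barcode_suffix: bool = True


@dataclass
class RepertoireProject:
    """Central project object joining receptors, expression, and metadata.

    Attributes
    ----------
    samples
        Mapping ``sample_id -> list of CellReceptor``.
    gex
        Optional genes x cells count matrix; columns are a MultiIndex of
        ``(sample_id, barcode)`` pairs, rows are gene/feature names.
    cell_meta
        Table indexed by ``(sample_id, barcode)`` with at least the flags
        ``has_vdj`` and ``has_gex``; free-form columns (cluster labels,
        conditions, ...) ride along.
    provenance
        Descriptors of the input files this project was built from.
    """

    samples: dict[str, list[CellReceptor]] = field(default_factory=dict)
    gex: Optional[pd.DataFrame] = None
    cell_meta: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["sample_id", "barcode"])
        )
    )
    provenance: list[str] = field(default_factory=list)

    def cells(self) -> list[CellReceptor]:
        """All cell receptors across samples, in sample then input order."""
        return [cell for sid in self.samples for cell in self.samples[sid]]

    @property
    def n_cells(self) -> int:
        return sum(len(v) for v in self.samples.values())

    def validate(self) -> None:
        """Check the cross-slot invariants; raise ``ValueError`` on breach."""
        seen: set[tuple[str, str]] = set()
        for sid, cells in self.samples.items():
            for cell in cells:
                if cell.sample_id != sid:
                    raise ValueError(f"cell {cell.key} filed under sample {sid!r}")
                if cell.key in seen:
                    raise ValueError(f"duplicate cell key {cell.key}")
                seen.add(cell.key)
        if self.gex is not None:
            if self.gex.columns.duplicated().any():
                raise ValueError("duplicate (sample_id, barcode) columns in gex")
            if (self.gex.to_numpy() < 0).any():
                raise ValueError("negative counts in gex")
        if not self.cell_meta.empty and "has_vdj" in self.cell_meta:
            flagged = set(self.cell_meta.index[self.cell_meta["has_vdj"].astype(bool)])
            if not flagged <= seen:
                raise ValueError("cell_meta marks receptor cells absent from samples")

    def copy(self) -> "RepertoireProject":
        return RepertoireProject(
            samples={k: list(v) for k, v in self.samples.items()},
            gex=None if self.gex is None else self.gex.copy(),
            cell_meta=self.cell_meta.copy(),
            provenance=list(self.provenance),
        )


def _replace_chain(cell: CellReceptor, **kw) -> CellReceptor:
    return replace(cell, **kw)
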