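"""Clonotype calling and clonal-expansion / isotype / gene-usage summaries.

Three strategies are supported:

``cdr3_nt_exact``
    Cells share a clonotype iff their (heavy, light) CDR3 nucleotide pair
    is identical; a missing chain is encoded as a distinct empty token.
``cdr3_aa_exact``
    Same, on amino-acid CDR3s (coarser: synonymous variants merge).
``vj_cdr3_homology``
    Cells are first bucketed by V gene, J gene, and CDR3 length of both
    chains, then single-linkage clustered within a bucket: two cells link
    iff the fraction of matching positions across their concatenated
    CDR3 amino-acid strings is at least ``homology_threshold``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .model import CellReceptor, RepertoireProject

logger = logging.getLogger(__name__)

STRATEGIES = ("cdr3_nt_exact", "cdr3_aa_exact", "vj_cdr3_homology")

#: Placeholder identity for an absent chain; distinct from any real CDR3.
MISSING = "<none>"


@dataclass
class Clonotype:
    """A group of cells inferred to share one ancestral recombination event."""

    clonotype_id: str
    strategy: str
    members: list[tuple[str, str]]
    size: int
    vdj_v: str = ""
    vdj_j: str = ""
    vj_v: str = ""
    vj_j: str = ""
    consensus_cdr3_aa: tuple[str, str] = ("", "")
    isotype_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size != len(self.members) or self.size < 1:
            raise ValueError("size must equal the number of members (>= 1)")
        if sum(self.isotype_counts.values()) > self.size:
            raise ValueError("isotype counts exceed clonotype size")


def _modal(values: list[str]) -> str:
    """Most common non-empty value; ties broken lexicographically."""
    counts = Counter(v for v in values if v)
    if not counts:
        return ""
    top = max(counts.values())
    return min(v for v, n in counts.items() if n == top)


def _chain_attr(cell: CellReceptor, slot: str, attr: str) -> str:
    chain = getattr(cell, slot)
    return getattr(chain, attr) if chain is not None else ""


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def combined_identity(a: tuple[str, str], b: tuple[str, str]) -> float:
    """Fraction of matching positions across two equal-length CDR3 pairs."""
    sa, sb = a[0] + a[1], b[0] + b[1]
    if len(sa) != len(sb):
        raise ValueError("combined identity requires equal concatenated lengths")
    if not sa:
        return 1.0
    return sum(x == y for x, y in zip(sa, sb)) / len(sa)


def _exact_groups(cells: list[CellReceptor], attr: str) -> dict[tuple, list[int]]:
    groups: dict[tuple, list[int]] = {}
    for i, cell in enumerate(cells):
        key = (
            _chain_attr(cell, "vdj_chain", attr) or MISSING,
            _chain_attr(cell, "vj_chain", attr) or MISSING,
        )
        groups.setdefault(key, []).append(i)
    return groups


def _homology_groups(
    cells: list[CellReceptor], threshold: float
) -> dict[tuple, list[int]]:
    buckets: dict[tuple, list[int]] = {}
    for i, cell in enumerate(cells):
        key = (
            _chain_attr(cell, "vdj_chain", "v_call") or MISSING,
            _chain_attr(cell, "vdj_chain", "j_call") or MISSING,
            _chain_attr(cell, "vj_chain", "v_call") or MISSING,
            _chain_attr(cell, "vj_chain", "j_call") or MISSING,
            len(_chain_attr(cell, "vdj_chain", "cdr3_aa")),
            len(_chain_attr(cell, "vj_chain", "cdr3_aa")),
        )
        buckets.setdefault(key, []).append(i)

    groups: dict[tuple, list[int]] = {}
    for key, idx in buckets.items():
        pairs = [
            (
                _chain_attr(cells[i], "vdj_chain", "cdr3_aa"),
                _chain_attr(cells[i], "vj_chain", "cdr3_aa"),
            )
            for i in idx
        ]
        uf = _UnionFind(len(idx))
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if combined_identity(pairs[a], pairs[b]) >= threshold:
                    uf.union(a, b)
        clusters: dict[int, list[int]] = {}
        for local, global_i in enumerate(idx):
            clusters.setdefault(uf.find(local), []).append(global_i)
        for root, members in clusters.items():
            groups[key + (root,)] = members
    return groups


def call_clonotypes(
    project: RepertoireProject,
    strategy: str = "cdr3_nt_exact",
    homology_threshold: float = 0.8,
) -> list[Clonotype]:
    """Partition the project's cells into clonotypes under a strategy.

    Clonotype ids are assigned by descending size, ties broken by the
    lexicographically smallest consensus CDR3 pair, so output is
    deterministic. Every retained cell belongs to exactly one clonotype.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    cells = project.cells()
    if not cells:
        raise ValueError("project has no cells")
    if strategy == "vj_cdr3_homology" and not (0 < homology_threshold <= 1):
        raise ValueError("homology_threshold must lie in (0, 1]")

    if strategy == "cdr3_nt_exact":
        groups = _exact_groups(cells, "cdr3_nt")
    elif strategy == "cdr3_aa_exact":
        groups = _exact_groups(cells, "cdr3_aa")
    else:
        groups = _homology_groups(cells, homology_threshold)

    raw = []
    for members in groups.values():
        mcells = [cells[i] for i in members]
        consensus = (
            _modal([_chain_attr(c, "vdj_chain", "cdr3_aa") for c in mcells]),
            _modal([_chain_attr(c, "vj_chain", "cdr3_aa") for c in mcells]),
        )
        isotypes = Counter(
            c.vdj_chain.c_call
            for c in mcells
            if c.vdj_chain is not None and c.vdj_chain.locus == "IGH" and c.vdj_chain.c_call
        )
        raw.append((len(members), consensus, mcells, isotypes))

    raw.sort(key=lambda r: (-r[0], r[1]))
    clonotypes = []
    for rank, (size, consensus, mcells, isotypes) in enumerate(raw, start=1):
        clonotypes.append(
            Clonotype(
                clonotype_id=f"clonotype_{rank}",
                strategy=strategy,
                members=[c.key for c in mcells],
                size=size,
                vdj_v=_modal([_chain_attr(c, "vdj_chain", "v_call") for c in mcells]),
                vdj_j=_modal([_chain_attr(c, "vdj_chain", "j_call") for c in mcells]),
                vj_v=_modal([_chain_attr(c, "vj_chain", "v_call") for c in mcells]),
                vj_j=_modal([_chain_attr(c, "vj_chain", "j_call") for c in mcells]),
                consensus_cdr3_aa=consensus,
                isotype_counts=dict(sorted(isotypes.items())),
            )
        )
    return clonotypes


def expansion_table(clonotypes: list[Clonotype]) -> pd.DataFrame:
    """Clonal-expansion summary: one row per clonotype with its frequency."""
    if not clonotypes:
        return pd.DataFrame(columns=["clonotype_id", "size", "frequency"])
    total = sum(c.size for c in clonotypes)
    rows = sorted(clonotypes, key=lambda c: (-c.size, c.consensus_cdr3_aa))
    return pd.DataFrame(
        {
            "clonotype_id": [c.clonotype_id for c in rows],
            "size": [c.size for c in rows],
            "frequency": [c.size / total for c in rows],
        }
    )


def isotype_distribution(
    clonotypes: list[Clonotype], per_clonotype: bool = False
) -> pd.DataFrame:
    """Isotype fractions, globally or per clonotype.

    Fractions are over cells with a known isotype (IGH constant-region
    call); cells without one are reported in a separate ``unknown`` row
    whose fraction is relative to all cells.
    """
    known = Counter()
    n_cells = 0
    for c in clonotypes:
        known.update(c.isotype_counts)
        n_cells += c.size
    if not known:
        logger.warning("no isotype information (no IGH c_call); all cells unknown")
        return pd.DataFrame(
            [{"clonotype_id": "all", "isotype": "unknown", "count": n_cells, "fraction": 1.0}]
        )

    def _rows(label: str, counts: Counter, size: int) -> list[dict]:
        total_known = sum(counts.values())
        out = [
            {
                "clonotype_id": label,
                "isotype": iso,
                "count": n,
                "fraction": n / total_known,
            }
            for iso, n in sorted(counts.items())
        ]
        unknown = size - total_known
        if unknown:
            out.append(
                {
                    "clonotype_id": label,
                    "isotype": "unknown",
                    "count": unknown,
                    "fraction": unknown / size,
                }
            )
        return out

    if per_clonotype:
        rows = []
        for c in clonotypes:
            rows.extend(_rows(c.clonotype_id, Counter(c.isotype_counts), c.size))
    else:
        rows = _rows("all", known, n_cells)
    return pd.DataFrame(rows)


def gene_usage(project: RepertoireProject, gene_slot: str = "vdj_v") -> pd.DataFrame:
    """Per-cell V/J gene usage for one chain slot.

    ``gene_slot`` is one of ``vdj_v``, ``vdj_j``, ``vj_v``, ``vj_j``.
    Counts are over cells (one vote per cell), not contigs.
    """
    slots = {
        "vdj_v": ("vdj_chain", "v_call"),
        "vdj_j": ("vdj_chain", "j_call"),
        "vj_v": ("vj_chain", "v_call"),
        "vj_j": ("vj_chain", "j_call"),
    }
    if gene_slot not in slots:
        raise ValueError(f"gene_slot must be one of {sorted(slots)}")
    chain_attr, gene_attr = slots[gene_slot]
    counts = Counter(
        _chain_attr(cell, chain_attr, gene_attr)
        for cell in project.cells()
        if _chain_attr(cell, chain_attr, gene_attr)
    )
    total = sum(counts.values())
    rows = [
        {"gene": g, "count": n, "frequency": n / total}
        for g, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["gene", "count", "frequency"])


def clonotypes_to_frame(clonotypes: list[Clonotype]) -> pd.DataFrame:
    """Flatten clonotypes to the tabular interchange form used by the CLI."""
    total = sum(c.size for c in clonotypes) or 1
    rows = []
    for c in clonotypes:
        rows.append(
            {
                "clonotype_id": c.clonotype_id,
                "strategy": c.strategy,
                "size": c.size,
                "frequency": c.size / total,
                "vdj_v": c.vdj_v,
                "vdj_j": c.vdj_j,
                "vj_v": c.vj_v,
                "vj_j": c.vj_j,
                "consensus_cdr3_aa": ":".join(c.consensus_cdr3_aa),
                "isotype_counts": ";".join(
                    f"{k}:{v}" for k, v in c.isotype_counts.items()
                ),
                "members": ";".join(f"{s}|{b}" for s, b in c.members),
            }
        )
    return pd.DataFrame(rows)
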