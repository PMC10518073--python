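"""Somatic hypermutation quantification and germline-rooted lineage trees.

B-cell clonal families accumulate point mutations during affinity
maturation; this module counts those mutations against a germline
reference and reconstructs the intraclonal tree by neighbor-joining
over unique sequence variants, rooted on the germline.

Distance kernel: Hamming when two sequences are equal-length (they are
implicitly position-aligned), Levenshtein otherwise. Intraclonal variants
are near-identical, so no multiple-sequence-alignment stage is used.

Neighbor-joining follows the classical Q-criterion,

    Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k),

with ties broken on the smallest taxon-index pair and negative branch
lengths clamped to zero, the deficit transferred to the sister branch.
NJ is exact on additive distance matrices: the reconstructed path-length
matrix then equals the input matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

from .model import ContigRecord
from .network import hamming, levenshtein

GERMLINE_LABEL = "germline"


def count_mutations(seq: str, germline: str) -> int:
    """Mutation load of a sequence relative to its germline reference."""
    if not seq or not germline:
        raise ValueError("both sequences must be non-empty")
    if len(seq) == len(germline):
        return hamming(seq, germline)
    return levenshtein(seq, germline)


def _consensus(sequences: Sequence[str]) -> str:
    """Per-position majority-rule consensus; ties to the alphabetical base.

    Positions are counted over the sequences long enough to cover them,
    and the consensus length is the modal sequence length.
    """
    lengths = Counter(len(s) for s in sequences)
    top = max(lengths.values())
    length = min(l for l, n in lengths.items() if n == top)
    out = []
    for pos in range(length):
        column = Counter(s[pos] for s in sequences if len(s) > pos)
        best = max(column.values())
        out.append(min(b for b, n in column.items() if n == best))
    return "".join(out)


def _mismatches_over_aligned(segment: str, target: str, align: str) -> int:
    """Mismatch count of a reference segment against a prefix/suffix window."""
    span = min(len(segment), len(target))
    if align == "prefix":
        return hamming(segment[:span], target[:span])
    return hamming(segment[-span:], target[-span:])


def infer_germline(
    clonotype_members: Sequence[ContigRecord],
    reference_fasta: Optional[str | Path] = None,
) -> str:
    """Reconstruct the clonal germline sequence.

    With a reference FASTA (record ids containing ``V`` / ``J`` mark
    segment type), the germline is the concatenation of the V and J
    segments with the fewest mismatches to the modal member sequence over
    their aligned (prefix / suffix) regions. Without a reference, a
    per-position majority-rule consensus of the members serves as a
    germline proxy.
    """
    sequences = [m.sequence_nt for m in clonotype_members if m.sequence_nt]
    if not sequences:
        raise ValueError("no member sequences available for germline inference")
    if reference_fasta is None:
        return _consensus(sequences)

    counts = Counter(sequences)
    top = max(counts.values())
    modal = min(s for s, n in counts.items() if n == top)

    v_pool: list[tuple[str, str]] = []
    j_pool: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(reference_fasta), "fasta"):
        name = rec.id
        seq = str(rec.seq).upper()
        if "V" in name.upper().replace("IGH", "").replace("IGK", "").replace("IGL", ""):
            v_pool.append((name, seq))
        elif "J" in name.upper():
            j_pool.append((name, seq))
    if not v_pool or not j_pool:
        raise ValueError("reference FASTA must provide both V and J segments")

    best_v = min(
        v_pool, key=lambda nv: (_mismatches_over_aligned(nv[1], modal, "prefix"), nv[0])
    )
    best_j = min(
        j_pool, key=lambda nj: (_mismatches_over_aligned(nj[1], modal, "suffix"), nj[0])
    )
    return best_v[1] + best_j[1]


@dataclass
class LineageTree:
    """Germline-rooted tree over the unique sequence variants of one clone.

    ``children`` maps each node label to its ``(child, branch_length)``
    list; the root is the germline. ``variants`` records, per variant id,
    the sequence, its cell multiplicity, and its mutation count relative
    to the germline.
    """

    clonotype_id: str
    germline: str
    variants: list[tuple[str, str, int, int]]
    children: dict[str, list[tuple[str, float]]]
    root: str = GERMLINE_LABEL

    def tips(self) -> list[str]:
        return [label for label, *_ in self.variants]

    def path_length(self, node: str) -> float:
        """Sum of branch lengths from the root to ``node``."""
        dist = {self.root: 0.0}
        stack = [self.root]
        while stack:
            cur = stack.pop()
            for child, length in self.children.get(cur, []):
                dist[child] = dist[cur] + length
                stack.append(child)
        return dist[node]

    def to_newick(self) -> str:
        return to_newick(self)


def _format_length(x: float) -> str:
    return f"{x:.6g}"


def to_newick(tree: LineageTree) -> str:
    """Serialize with deterministic sibling order (smallest tip label first).

    The germline appears as the labelled root of the tree, e.g.
    ``((v1:1,v2:2):0.5)germline;``.
    """

    def min_tip(node: str) -> str:
        kids = tree.children.get(node, [])
        if not kids:
            return node
        return min(min_tip(c) for c, _ in kids)

    def render(node: str) -> str:
        kids = sorted(tree.children.get(node, []), key=lambda cl: min_tip(cl[0]))
        if not kids:
            return node
        inner = ",".join(
            f"{render(child)}:{_format_length(length)}" for child, length in kids
        )
        label = node if node == tree.root else ""
        return f"({inner}){label}"

    return render(tree.root) + ";"


def neighbor_joining(labels: list[str], dist: np.ndarray) -> dict[str, list[tuple[str, float]]]:
    """NJ over >= 2 taxa; returns an adjacency map (undirected, lengths)."""
    adjacency: dict[str, dict[str, float]] = {}

    def connect(a: str, b: str, length: float) -> None:
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    active = list(range(len(labels)))
    names = list(labels)
    d = dist.astype(float).copy()
    next_inner = 1

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        # clamp-and-transfer: keep li + lj = d(i, j), no negative branches
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = len(names)
        names.append(f"_inner{next_inner}")
        next_inner += 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        connect(names[i], names[u], li)
        connect(names[j], names[u], lj)
        active = [k for k in active if k not in (i, j)] + [u]

    if len(active) == 2:
        i, j = active
        connect(names[i], names[j], d[i, j])
    else:
        a, b, c = active
        u = len(names)
        names.append(f"_inner{next_inner}")
        la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
        lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
        lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
        connect(names[a], names[u], max(la, 0.0))
        connect(names[b], names[u], max(lb, 0.0))
        connect(names[c], names[u], max(lc, 0.0))
    return {k: sorted(v.items()) for k, v in adjacency.items()}


def _root_at(
    adjacency: dict[str, list[tuple[str, float]]], root: str
) -> dict[str, list[tuple[str, float]]]:
    children: dict[str, list[tuple[str, float]]] = {}
    visited = {root}
    stack = [root]
    while stack:
        cur = stack.pop()
        for nb, length in adjacency.get(cur, []):
            if nb in visited:
                continue
            visited.add(nb)
            children.setdefault(cur, []).append((nb, length))
            stack.append(nb)
    return children


def build_lineage(
    clonotype_members: Sequence[ContigRecord],
    germline: str,
    clonotype_id: str = "",
) -> LineageTree:
    """Neighbor-joining lineage over unique variants, rooted on germline.

    Variant ids ``v1, v2, ...`` are assigned by descending multiplicity,
    ties by sequence. A single-variant clone yields the two-node tree
    germline—variant with branch length equal to the mutation count.
    """
    if not germline:
        raise ValueError("germline sequence is required")
    seqs = [m.sequence_nt for m in clonotype_members if m.sequence_nt]
    if not seqs:
        raise ValueError("no member sequences with sequence_nt")
    mult = Counter(seqs)
    ordered = sorted(mult.items(), key=lambda kv: (-kv[1], kv[0]))
    variants = [
        (f"v{i}", seq, n, count_mutations(seq, germline))
        for i, (seq, n) in enumerate(ordered, start=1)
    ]

    if len(variants) == 1:
        vid, _, _, nmut = variants[0]
        children = {GERMLINE_LABEL: [(vid, float(nmut))]}
        return LineageTree(clonotype_id, germline, variants, children)

    labels = [GERMLINE_LABEL] + [v[0] for v in variants]
    seq_of = {GERMLINE_LABEL: germline, **{v[0]: v[1] for v in variants}}
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = float(count_mutations(seq_of[labels[i]], seq_of[labels[j]])) \
                if seq_of[labels[i]] != seq_of[labels[j]] else 0.0
            dist[i, j] = dist[j, i] = dij
    adjacency = neighbor_joining(labels, dist)
    children = _root_at(adjacency, GERMLINE_LABEL)
    return LineageTree(clonotype_id, germline, variants, children)


def lineage_summary(trees: Sequence[LineageTree]):
    """Per-clone summary table: variant count and mean mutation load."""
    import pandas as pd

    rows = []
    for t in trees:
        loads = [nmut for _, _, mult, nmut in t.variants for _ in range(mult)]
        rows.append(
            {
                "clonotype_id": t.clonotype_id,
                "n_variants": len(t.variants),
                "n_cells": sum(m for _, _, m, _ in t.variants),
                "mean_mutations": float(np.mean(loads)),
            }
        )
    return pd.DataFrame(rows)
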