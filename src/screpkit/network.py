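"""CDR3 sequence similarity networks and graph-architecture statistics.

Nodes are CDR3 sequences (one per unique sequence by default, weighted by
multiplicity); an edge joins two nodes whose edit distance is at most the
threshold. The resulting graph's architecture — component structure,
degree distribution, clustering — summarizes repertoire organization.

Construction prunes candidate pairs by sequence length only
(``|len(a) - len(b)| > threshold`` implies the Levenshtein distance
exceeds the threshold), so the optimized graph is provably identical to
exhaustive all-pairs computation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import networkx as nx

DISTANCE_KINDS = ("levenshtein", "hamming", "normalized_levenshtein")


@dataclass(frozen=True)
class NodeRecord:
    """One network node: a sequence with its provenance and clone weight."""

    id: str
    sequence: str
    sample_id: str = ""
    clonotype_id: str = ""
    weight: int = 1


@dataclass
class SimilarityGraph:
    """An undirected CDR3 similarity graph below a distance threshold."""

    nodes: list[NodeRecord]
    edges: list[tuple[str, str, float]]
    threshold: float
    distance_kind: str
    graph: nx.Graph = field(repr=False, default_factory=nx.Graph)


def levenshtein(a: str, b: str) -> int:
    """Minimum number of unit-cost edits (substitution/insertion/deletion)."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def hamming(a: str, b: str) -> int:
    """Position-wise mismatch count; requires equal lengths."""
    if len(a) != len(b):
        raise ValueError(
            f"hamming distance requires equal lengths ({len(a)} vs {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


def edit_distance(a: str, b: str, kind: str = "levenshtein") -> float:
    """Distance between two sequences under the chosen kernel."""
    if kind == "levenshtein":
        return float(levenshtein(a, b))
    if kind == "hamming":
        return float(hamming(a, b))
    if kind == "normalized_levenshtein":
        longest = max(len(a), len(b))
        return levenshtein(a, b) / longest if longest else 0.0
    raise ValueError(f"unknown distance kind {kind!r}; choose from {DISTANCE_KINDS}")


def _prunable(len_a: int, len_b: int, threshold: float, kind: str) -> bool:
    """True if the length difference alone proves distance > threshold."""
    delta = abs(len_a - len_b)
    if kind == "hamming":
        return delta > 0
    if kind == "levenshtein":
        return delta > threshold
    # normalized: distance >= delta / max(len); lower bound must exceed t
    longest = max(len_a, len_b)
    return longest > 0 and delta / longest > threshold


def build_network(
    sequences: Sequence[NodeRecord] | Sequence[str],
    threshold: float = 1.0,
    kind: str = "levenshtein",
    collapse_identical: bool = True,
) -> SimilarityGraph:
    """Build the similarity graph over a set of sequences.

    Plain strings are accepted and wrapped into :class:`NodeRecord`.
    With ``collapse_identical`` duplicate sequences merge into one node
    whose weight is their multiplicity. Edges connect pairs at distance
    <= threshold; hamming pairs of unequal length are never linked.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if kind not in DISTANCE_KINDS:
        raise ValueError(f"unknown distance kind {kind!r}")
    records = [
        r if isinstance(r, NodeRecord) else NodeRecord(id=f"n{i}", sequence=r)
        for i, r in enumerate(sequences)
    ]
    if not records:
        raise ValueError("at least one sequence is required")

    if collapse_identical:
        weights = Counter()
        first: dict[str, NodeRecord] = {}
        for r in records:
            weights[r.sequence] += r.weight
            first.setdefault(r.sequence, r)
        records = [
            NodeRecord(
                id=first[seq].id,
                sequence=seq,
                sample_id=first[seq].sample_id,
                clonotype_id=first[seq].clonotype_id,
                weight=weights[seq],
            )
            for seq in sorted(first)
        ]

    g = nx.Graph()
    for r in records:
        g.add_node(r.id, sequence=r.sequence, sample_id=r.sample_id,
                   clonotype_id=r.clonotype_id, weight=r.weight)

    # sort by length so pruning scans a contiguous window
    by_len = sorted(range(len(records)), key=lambda i: (len(records[i].sequence), records[i].id))
    edges: list[tuple[str, str, float]] = []
    for a_pos, i in enumerate(by_len):
        ra = records[i]
        for j in by_len[a_pos + 1:]:
            rb = records[j]
            if _prunable(len(ra.sequence), len(rb.sequence), threshold, kind):
                if kind != "hamming":
                    break  # lengths only grow from here
                continue
            if kind == "hamming" and len(ra.sequence) != len(rb.sequence):
                continue
            d = edit_distance(ra.sequence, rb.sequence, kind)
            if d <= threshold and ra.id != rb.id:
                u, v = sorted((ra.id, rb.id))
                edges.append((u, v, d))
                g.add_edge(u, v, distance=d)
    edges.sort()
    return SimilarityGraph(
        nodes=records, edges=edges, threshold=threshold, distance_kind=kind, graph=g
    )


def graph_stats(sg: SimilarityGraph) -> dict:
    """Standard architecture statistics of a similarity graph."""
    g = sg.graph
    n = g.number_of_nodes()
    if n == 0:
        return {
            "n_nodes": 0, "n_edges": 0, "n_components": 0,
            "largest_component_fraction": 0.0, "mean_degree": 0.0,
            "transitivity": 0.0, "degree_histogram": [],
        }
    components = list(nx.connected_components(g))
    return {
        "n_nodes": n,
        "n_edges": g.number_of_edges(),
        "n_components": len(components),
        "largest_component_fraction": max(len(c) for c in components) / n,
        "mean_degree": 2 * g.number_of_edges() / n,
        "transitivity": nx.transitivity(g),
        "degree_histogram": nx.degree_histogram(g),
    }
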