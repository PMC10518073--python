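import itertools

import dendropy
import numpy as np
import pytest

from screpkit.lineage import (
    GERMLINE_LABEL,
    build_lineage,
    count_mutations,
    infer_germline,
    neighbor_joining,
    to_newick,
)

from conftest import make_contig


def heavy(seq, barcode="B1"):
    return make_contig(barcode=barcode, contig_id=f"{barcode}_h", sequence_nt=seq)


def tip_distances(adjacency):
    """All-pairs path lengths between labelled nodes of an adjacency map."""
    import networkx as nx

    g = nx.Graph()
    for node, neighbors in adjacency.items():
        for nb, length in neighbors:
            g.add_edge(node, nb, weight=length)
    return dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))


class TestCountMutations:
    @pytest.mark.parametrize(
        "seq, germ, expected",
        [
            ("ACGT", "ACGT", 0),
            ("ACGT", "AGGA", 2),
            ("ACGT", "ACGTT", 1),  # unequal lengths fall back to edit distance
        ],
    )
    def test_examples(self, seq, germ, expected):
        assert count_mutations(seq, germ) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_mutations("", "ACGT")


class TestInferGermline:
    def test_identical_members_yield_that_sequence(self):
        members = [heavy("ACGTACGT", f"B{i}") for i in range(3)]
        assert infer_germline(members) == "ACGTACGT"

    def test_majority_rule_with_alphabetical_ties(self):
        members = [heavy("ACGT", f"B{i}") for i in range(3)] + [heavy("ACTT", "B9")]
        assert infer_germline(members) == "ACGT"
        tied = [heavy("ACGT", "B1"), heavy("ACTT", "B2")]
        assert infer_germline(tied) == "ACGT"  # G < T at the tied position

    def test_reference_segments_chosen_by_fewest_mismatches(self, tmp_path):
        fasta = tmp_path / "ref.fasta"
        fasta.write_text(
            ">IGHV1\nACGACG\n>IGHV2\nTTTTTT\n>IGHJ1\nGGG\n>IGHJ2\nCCC\n"
        )
        members = [heavy("ACGACGAAAGGG", f"B{i}") for i in range(2)]
        assert infer_germline(members, fasta) == "ACGACG" + "GGG"

    def test_no_sequences_rejected(self):
        with pytest.raises(ValueError):
            infer_germline([make_contig(sequence_nt="")])


class TestBuildLineage:
    def test_single_variant_star_tree(self):
        germ = "AAAAAA"
        tree = build_lineage([heavy("AAATTT")], germ)
        assert tree.children == {GERMLINE_LABEL: [("v1", 3.0)]}
        assert tree.variants[0][3] == 3

    def test_cherry_path_lengths_equal_mutation_counts(self):
        germ = "AAAAAAAAAA"
        tree = build_lineage(
            [heavy("AAAAAAAATT", "B1"), heavy("TAAAAAAAAA", "B2")], germ
        )
        for vid, _, _, nmut in tree.variants:
            assert tree.path_length(vid) == pytest.approx(nmut, abs=1e-9)

    def test_variant_ids_ordered_by_multiplicity_then_sequence(self):
        members = [heavy("AAAATT", f"B{i}") for i in range(3)] + [
            heavy("AAAAGG", "B8"), heavy("AAAAGG", "B9"), heavy("AAAACC", "B10")
        ]
        tree = build_lineage(members, "AAAAAA")
        assert [v[0] for v in tree.variants] == ["v1", "v2", "v3"]
        assert tree.variants[0][1] == "AAAATT"  # multiplicity 3
        assert tree.variants[1][1] == "AAAAGG"  # multiplicity 2

    def test_determinism_byte_identical_newick(self):
        members = [heavy(s, f"B{i}") for i, s in enumerate(
            ["AAAATT", "AAAAGG", "AATTTT", "AAAATG", "AAAATT"]
        )]
        a = build_lineage(members, "AAAAAA").to_newick()
        b = build_lineage(list(members), "AAAAAA").to_newick()
        assert a == b


class TestNeighborJoiningAdditive:
    """Caterpillar tree: germline-2-X, v1-3-X, X-4-Y, v2-1-Y, Y-2-Z, v3-5-Z, v4-6-Z."""

    LABELS = [GERMLINE_LABEL, "v1", "v2", "v3", "v4"]

    def additive_matrix(self):
        paths = {
            ("germline", "v1"): 2 + 3,
            ("germline", "v2"): 2 + 4 + 1,
            ("germline", "v3"): 2 + 4 + 2 + 5,
            ("germline", "v4"): 2 + 4 + 2 + 6,
            ("v1", "v2"): 3 + 4 + 1,
            ("v1", "v3"): 3 + 4 + 2 + 5,
            ("v1", "v4"): 3 + 4 + 2 + 6,
            ("v2", "v3"): 1 + 2 + 5,
            ("v2", "v4"): 1 + 2 + 6,
            ("v3", "v4"): 5 + 6,
        }
        n = len(self.LABELS)
        d = np.zeros((n, n))
        for (a, b), value in paths.items():
            i, j = self.LABELS.index(a), self.LABELS.index(b)
            d[i, j] = d[j, i] = value
        return d

    def test_nj_recovers_all_path_lengths(self):
        d = self.additive_matrix()
        adjacency = neighbor_joining(self.LABELS, d)
        dist = tip_distances(adjacency)
        for i, j in itertools.combinations(range(len(self.LABELS)), 2):
            a, b = self.LABELS[i], self.LABELS[j]
            assert dist[a][b] == pytest.approx(d[i, j], abs=1e-9)

    def test_nj_recovers_topology(self):
        # v3 and v4 are a cherry: their shared neighbor is a single inner node
        adjacency = neighbor_joining(self.LABELS, self.additive_matrix())
        nb3 = {n for n, _ in adjacency["v3"]}
        nb4 = {n for n, _ in adjacency["v4"]}
        assert nb3 == nb4 and len(nb3) == 1


class TestNewick:
    def test_two_node_tree_serialization(self):
        tree = build_lineage([heavy("AAATTT")], "AAAAAA")
        assert tree.to_newick() == "(v1:3)germline;"

    def test_round_trip_is_isomorphic(self):
        rng = np.random.default_rng(2)
        germ = "".join(rng.choice(list("ACGT"), size=60))
        members = []
        for i in range(6):
            arr = list(germ)
            for pos in rng.choice(60, size=rng.integers(1, 6), replace=False):
                arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
            members.append(heavy("".join(arr), f"B{i}"))
        tree = build_lineage(members, germ)
        newick = to_newick(tree)

        parsed = dendropy.Tree.get(data=newick, schema="newick")
        # the germline is the labelled root of the serialized tree
        assert parsed.seed_node.label == GERMLINE_LABEL
        root_dist = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in parsed.leaf_node_iter()
        }
        assert set(root_dist) == {vid for vid, *_ in tree.variants}
        # germline-to-tip path lengths survive the round trip
        for vid, *_ in tree.variants:
            assert root_dist[vid] == pytest.approx(tree.path_length(vid), abs=1e-6)

    def test_sibling_order_deterministic(self):
        members = [heavy("AAAATT", "B1"), heavy("AAAAGG", "B2")]
        newick = build_lineage(members, "AAAAAA").to_newick()
        assert newick.index("v1") < newick.index("v2")
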