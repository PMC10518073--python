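import pytest

from screpkit.clonotyping import (
    call_clonotypes,
    clonotypes_to_frame,
    combined_identity,
    expansion_table,
    gene_usage,
    isotype_distribution,
)
from screpkit.io import project_from_cells, read_bundle

from conftest import make_cell, make_contig


def cell_with_cdr3s(barcode, heavy_nt, light_nt, heavy_aa=None, light_aa=None,
                    sample_id="s1", c_call="IGHM", hv="IGHV1", hj="IGHJ1"):
    heavy = make_contig(
        barcode=barcode, contig_id=f"{barcode}_h", cdr3_nt=heavy_nt,
        cdr3_aa=heavy_aa or "X" * (len(heavy_nt) // 3), c_call=c_call,
        v_call=hv, j_call=hj,
    )
    light = make_contig(
        barcode=barcode, contig_id=f"{barcode}_l", locus="IGK",
        v_call="IGKV1", j_call="IGKJ1", cdr3_nt=light_nt,
        cdr3_aa=light_aa or "Y" * (len(light_nt) // 3),
    )
    return make_cell(sample_id=sample_id, barcode=barcode, heavy=heavy, light=light)


class TestStrategies:
    def test_identical_nt_pairs_form_one_clonotype(self):
        cells = [cell_with_cdr3s(f"B{i}", "TGTGCCAGA", "TGTCAACAG") for i in range(3)]
        (clono,) = call_clonotypes(project_from_cells(cells), "cdr3_nt_exact")
        assert clono.size == 3

    def test_homology_threshold_splits_near_identical_cdr3s(self):
        # combined CDR3s: CARDYW+CQQYSW vs CARDFW+CQQYSW -> 11/12 = 0.917
        cells = [
            cell_with_cdr3s("B1", "A" * 18, "C" * 18, "CARDYW", "CQQYSW"),
            cell_with_cdr3s("B2", "G" * 18, "C" * 18, "CARDFW", "CQQYSW"),
        ]
        assert combined_identity(("CARDYW", "CQQYSW"), ("CARDFW", "CQQYSW")) == pytest.approx(11 / 12)
        project = project_from_cells(cells)
        assert len(call_clonotypes(project, "vj_cdr3_homology", 0.8)) == 1
        assert len(call_clonotypes(project, "vj_cdr3_homology", 0.95)) == 2

    def test_single_linkage_is_transitive_through_intermediates(self):
        # A~B and B~C above threshold links {A,B,C} even though A~C is not
        a, b, c = "CARDDDDDDW", "CARDDDDEEW", "CARDDEEEEW"
        light = "CQQYSW"
        cells = [
            cell_with_cdr3s("B1", "A" * 30, "C" * 18, a, light),
            cell_with_cdr3s("B2", "G" * 30, "C" * 18, b, light),
            cell_with_cdr3s("B3", "T" * 30, "C" * 18, c, light),
        ]
        ab = combined_identity((a, light), (b, light))
        ac = combined_identity((a, light), (c, light))
        assert ac < 0.8 <= ab
        (clono,) = call_clonotypes(project_from_cells(cells), "vj_cdr3_homology", 0.8)
        assert clono.size == 3

    def test_unknown_strategy_rejected(self):
        project = project_from_cells([cell_with_cdr3s("B1", "TGT", "TGC")])
        with pytest.raises(ValueError, match="unknown strategy"):
            call_clonotypes(project, "nope")

    def test_partition_property_all_strategies(self, sim_bundle):
        bundle, _ = sim_bundle
        project = read_bundle(bundle)
        for strategy in ("cdr3_nt_exact", "cdr3_aa_exact", "vj_cdr3_homology"):
            clonos = call_clonotypes(project, strategy)
            members = [m for c in clonos for m in c.members]
            assert len(members) == project.n_cells
            assert len(set(members)) == project.n_cells
            assert sum(c.size for c in clonos) == project.n_cells

    def test_nt_clonotypes_refine_aa_clonotypes(self, sim_bundle):
        bundle, _ = sim_bundle
        project = read_bundle(bundle)
        aa_of = {
            m: c.clonotype_id
            for c in call_clonotypes(project, "cdr3_aa_exact")
            for m in c.members
        }
        for clono in call_clonotypes(project, "cdr3_nt_exact"):
            assert len({aa_of[m] for m in clono.members}) == 1

    def test_raising_threshold_never_merges_clonotypes(self, sim_bundle):
        bundle, _ = sim_bundle
        project = read_bundle(bundle)
        counts = [
            len(call_clonotypes(project, "vj_cdr3_homology", t))
            for t in (0.5, 0.7, 0.85, 0.95, 1.0)
        ]
        assert counts == sorted(counts)


class TestSummaries:
    def test_expansion_frequencies(self):
        cells = (
            [cell_with_cdr3s(f"A{i}", "TGTGCCAGA", "TGTCAACAG") for i in range(5)]
            + [cell_with_cdr3s(f"B{i}", "TGTGCCAAA", "TGTCAACAG") for i in range(3)]
            + [cell_with_cdr3s(f"C{i}", "TGTGCCTTT", "TGTCAACAG") for i in range(2)]
        )
        table = expansion_table(call_clonotypes(project_from_cells(cells)))
        assert list(table["size"]) == [5, 3, 2]
        assert list(table["frequency"]) == pytest.approx([0.5, 0.3, 0.2])
        assert table["frequency"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_clonotype_frequency_one(self):
        cells = [cell_with_cdr3s("B1", "TGTGCCAGA", "TGTCAACAG")]
        table = expansion_table(call_clonotypes(project_from_cells(cells)))
        assert list(table["frequency"]) == [1.0]

    def test_isotype_fractions(self):
        cells = [
            cell_with_cdr3s(f"B{i}", "TGTGCCAGA", "TGTCAACAG",
                            c_call="IGHM" if i < 4 else "IGHG1")
            for i in range(5)
        ]
        table = isotype_distribution(call_clonotypes(project_from_cells(cells)))
        fractions = dict(zip(table["isotype"], table["fraction"]))
        assert fractions == pytest.approx({"IGHM": 0.8, "IGHG1": 0.2})

    def test_all_unknown_isotypes(self, caplog):
        cells = [
            cell_with_cdr3s(f"B{i}", "TGTGCCAGA", "TGTCAACAG", c_call="")
            for i in range(3)
        ]
        table = isotype_distribution(call_clonotypes(project_from_cells(cells)))
        assert list(table["isotype"]) == ["unknown"]
        assert list(table["fraction"]) == [1.0]

    def test_gene_usage_counts_cells(self):
        cells = [
            cell_with_cdr3s("B1", "TGTGCCAGA", "TGTCAACAG", hv="IGHV1-1"),
            cell_with_cdr3s("B2", "TGTGCCAAA", "TGTCAACAG", hv="IGHV1-1"),
            cell_with_cdr3s("B3", "TGTGCCTTT", "TGTCAACAG", hv="IGHV3-2"),
        ]
        table = gene_usage(project_from_cells(cells), "vdj_v")
        freq = dict(zip(table["gene"], table["frequency"]))
        assert freq == pytest.approx({"IGHV1-1": 2 / 3, "IGHV3-2": 1 / 3})
        assert table["frequency"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_clonotype_frame_serializes_isotype_counts(self):
        cells = [cell_with_cdr3s("B1", "TGTGCCAGA", "TGTCAACAG", c_call="IGHM")]
        frame = clonotypes_to_frame(call_clonotypes(project_from_cells(cells)))
        assert frame.loc[0, "isotype_counts"] == "IGHM:1"
        assert frame.loc[0, "members"] == "s1|B1"
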