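import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from screpkit.clonotyping import call_clonotypes, expansion_table
from screpkit.io import read_bundle, read_cellranger_vdj
from screpkit.lineage import count_mutations
from screpkit.simulate import (
    GroundTruthLedger,
    SimulationConfig,
    builtin_germline_pool,
    draw_clone_sizes,
    estimate_powerlaw_alpha,
    simulate_repertoire,
)


def bundle_digest(path: Path) -> dict[str, str]:
    return {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(path.iterdir())
        if f.is_file()
    }


class TestDeterminismAndFormats:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        config = SimulationConfig(seed=7, n_cells=100)
        a, _ = simulate_repertoire(config, tmp_path / "a")
        b, _ = simulate_repertoire(SimulationConfig(seed=7, n_cells=100), tmp_path / "b")
        assert bundle_digest(a) == bundle_digest(b)

    def test_different_seed_changes_output(self, tmp_path):
        a, _ = simulate_repertoire(SimulationConfig(seed=1, n_cells=50), tmp_path / "a")
        b, _ = simulate_repertoire(SimulationConfig(seed=2, n_cells=50), tmp_path / "b")
        assert bundle_digest(a) != bundle_digest(b)

    def test_contig_csv_and_airr_agree_on_chain_counts(self, sim_bundle):
        bundle, ledger = sim_bundle
        via_csv = read_cellranger_vdj(
            bundle / "filtered_contig_annotations.csv", "sim"
        )
        via_airr = read_bundle(bundle).cells()
        assert len(via_csv) == len(via_airr) == len(ledger.per_cell)
        chains_csv = sorted(
            (c.barcode, ch.locus, ch.cdr3_nt) for c in via_csv for ch in c.chains
        )
        chains_airr = sorted(
            (c.barcode, ch.locus, ch.cdr3_nt) for c in via_airr for ch in c.chains
        )
        assert chains_csv == chains_airr

    def test_ledger_round_trips_through_json(self, sim_bundle):
        bundle, ledger = sim_bundle
        back = GroundTruthLedger.from_json(bundle / "ground_truth.json")
        back.validate()
        assert back.per_cell == ledger.per_cell
        assert back.clone_sizes() == ledger.clone_sizes()

    def test_invalid_config_rejected_before_writing(self, tmp_path):
        out = tmp_path / "never"
        with pytest.raises(ValueError, match="isotype_probs"):
            simulate_repertoire(
                SimulationConfig(isotype_probs={"IGHM": 0.5}), out
            )
        assert not out.exists()

    def test_builtin_pool_is_stable(self):
        a, b = builtin_germline_pool(), builtin_germline_pool()
        assert a == b
        assert len(a["IGH_V"]) == 10 and len(a["IGH_J"]) == 5


class TestGroundTruth:
    def test_mutation_counts_match_ledger_exactly(self, sim_bundle):
        """No back-mutation by construction: introduced == Hamming to germline."""
        bundle, ledger = sim_bundle
        cells = {c.barcode: c for c in read_bundle(bundle).cells()}
        germline = {c["clone_id"]: c for c in ledger.per_clone}
        for row in ledger.per_cell:
            cell = cells[row["barcode"]]
            clone = germline[row["clone_id"]]
            assert count_mutations(cell.vdj_chain.sequence_nt, clone["germline_vdj"]) \
                == row["n_mutations_vdj"]
            assert count_mutations(cell.vj_chain.sequence_nt, clone["germline_vj"]) \
                == row["n_mutations_vj"]

    def test_shm0_clonotypes_equal_truth_partition(self, sim_bundle_shm0):
        bundle, ledger = sim_bundle_shm0
        project = read_bundle(bundle)
        clonos = call_clonotypes(project, "cdr3_nt_exact")
        predicted = {}
        for c in clonos:
            for _, barcode in c.members:
                predicted[barcode] = c.clonotype_id
        truth = {row["barcode"]: row["clone_id"] for row in ledger.per_cell}
        barcodes = sorted(truth)
        ari = adjusted_rand_score(
            [truth[b] for b in barcodes], [predicted[b] for b in barcodes]
        )
        assert ari == 1.0
        # and expansion sizes match the simulator's clone-size ledger
        assert sorted(expansion_table(clonos)["size"]) == sorted(ledger.clone_sizes())

    def test_degenerate_isotype_distribution(self, tmp_path):
        config = SimulationConfig(seed=3, n_cells=40, isotype_probs={"IGHM": 1.0})
        _, ledger = simulate_repertoire(config, tmp_path / "b")
        assert {row["isotype"] for row in ledger.per_cell} == {"IGHM"}

    def test_clone_sizes_sum_to_n_cells(self):
        rng = np.random.default_rng(0)
        for law in ("powerlaw", "uniform"):
            config = SimulationConfig(n_cells=137, clone_size_law=law)
            assert sum(draw_clone_sizes(config, rng)) == 137

    def test_uniform_law_sizes_nearly_equal(self):
        rng = np.random.default_rng(0)
        config = SimulationConfig(n_cells=100, clone_size_law="uniform", n_clones=7)
        sizes = draw_clone_sizes(config, rng)
        assert len(sizes) == 7 and max(sizes) - min(sizes) <= 1


class TestPowerlawEstimator:
    def test_recovers_known_alpha(self):
        rng = np.random.default_rng(123)
        sizes = rng.zipf(2.0, 5000)
        assert estimate_powerlaw_alpha(sizes) == pytest.approx(2.0, abs=0.2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        sizes = list(rng.zipf(2.5, 500))
        shuffled = list(sizes)
        rng.shuffle(shuffled)
        assert estimate_powerlaw_alpha(sizes) == estimate_powerlaw_alpha(shuffled)

    def test_all_equal_sizes_flagged_as_non_powerlaw(self):
        with pytest.warns(UserWarning, match="not be power-law|non|degenerate"):
            estimate_powerlaw_alpha([3, 3, 3, 3])
        # all-singleton repertoires drive the estimate to the upper edge
        with pytest.warns(UserWarning):
            alpha = estimate_powerlaw_alpha([1, 1, 1, 1])
        assert alpha >= 5.98

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_powerlaw_alpha([5])
        with pytest.raises(ValueError):
            estimate_powerlaw_alpha([0, 2])


def test_mean_shm_tracks_configured_rate(tmp_path):
    config = SimulationConfig(seed=21, n_cells=2000, shm_rate=0.01)
    _, ledger = simulate_repertoire(config, tmp_path / "b")
    germ_len = {
        c["clone_id"]: len(c["germline_vdj"]) + len(c["germline_vj"])
        for c in ledger.per_clone
    }
    expected = np.mean([config.shm_rate * germ_len[r["clone_id"]] for r in ledger.per_cell])
    observed = np.mean([r["n_mutations_introduced"] for r in ledger.per_cell])
    assert observed == pytest.approx(expected, rel=0.1)
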