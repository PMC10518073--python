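import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from screpkit.model import CellReceptor, ContigRecord
from screpkit.simulate import SimulationConfig, simulate_repertoire


def make_contig(
    barcode="B1",
    contig_id="c1",
    locus="IGH",
    v_call="IGHV1-1",
    j_call="IGHJ1",
    cdr3_nt="TGTGCCAGA",
    cdr3_aa="CAR",
    **kw,
):
    return ContigRecord(
        barcode=barcode,
        contig_id=contig_id,
        locus=locus,
        v_call=v_call,
        j_call=j_call,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        **kw,
    )


def make_cell(sample_id="s1", barcode="B1", heavy=None, light=None, **heavy_kw):
    """A paired cell with defaultable heavy/light chains."""
    if heavy is None:
        heavy = make_contig(barcode=barcode, contig_id=f"{barcode}_h", **heavy_kw)
    if light is None:
        light = make_contig(
            barcode=barcode,
            contig_id=f"{barcode}_l",
            locus="IGK",
            v_call="IGKV1-1",
            j_call="IGKJ1",
            cdr3_nt="TGTCAACAG",
            cdr3_aa="CQQ",
        )
    category = "paired" if heavy and light else ("vdj_only" if heavy else "vj_only")
    return CellReceptor(
        sample_id=sample_id,
        barcode=barcode,
        vdj_chain=heavy,
        vj_chain=light,
        chain_category=category,
    )


def dp_levenshtein(a: str, b: str) -> int:
    """Independent Wagner-Fischer dynamic-programming oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def random_cdr3s(rng: np.random.Generator, n: int, lo: int = 8, hi: int = 18) -> list[str]:
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return [
        "".join(rng.choice(aa, size=int(rng.integers(lo, hi + 1)))) for _ in range(n)
    ]


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A 300-cell simulated sample shared across tests (seed 11)."""
    out = tmp_path_factory.mktemp("sim") / "bundle"
    config = SimulationConfig(seed=11, n_cells=300)
    bundle, ledger = simulate_repertoire(config, out)
    return bundle, ledger


@pytest.fixture(scope="session")
def sim_bundle_shm0(tmp_path_factory):
    """A mutation-free 400-cell sample: clonotypes must equal the truth."""
    out = tmp_path_factory.mktemp("sim0") / "bundle"
    config = SimulationConfig(seed=5, n_cells=400, shm_rate=0.0)
    bundle, ledger = simulate_repertoire(config, out)
    return bundle, ledger
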