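"""Readers and writers for the standard repertoire and expression formats.

Supported inputs: 10x Genomics Cellranger ``filtered_contig_annotations.csv``,
AIRR Rearrangement TSV, and MatrixMarket triplets with barcode/feature
sidecars for gene expression. A *project bundle* is a directory holding an
AIRR TSV plus optional MTX triplet and metadata TSV; it is the on-disk form
of :class:`~screpkit.model.RepertoireProject`.
"""

from __future__ import annotations

import logging
import os
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .model import (
    VDJ_LOCI,
    VJ_LOCI,
    CellReceptor,
    ContigRecord,
    FilterConfig,
    RepertoireProject,
)

logger = logging.getLogger(__name__)

_BARCODE_SUFFIX = re.compile(r"-\d+$")

CELLRANGER_REQUIRED = (
    "barcode",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3",
    "cdr3_nt",
    "umis",
    "reads",
    "productive",
    "high_confidence",
)

AIRR_REQUIRED = (
    "sequence_id",
    "sequence",
    "locus",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "cell_id",
    "duplicate_count",
)

#: Column order of the AIRR Rearrangement files this package writes.
AIRR_COLUMNS = (
    "sequence_id",
    "sequence",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "junction",
    "junction_aa",
    "productive",
    "cell_id",
    "repertoire_id",
    "duplicate_count",
    "consensus_count",
    "high_confidence",
)


class FormatError(ValueError):
    """An input file does not match its declared format."""


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"true", "t", "1", "yes"}


def strip_barcode_suffix(barcode: str) -> str:
    """Remove a trailing ``-<digits>`` lane suffix (``AAAC-1`` -> ``AAAC``)."""
    return _BARCODE_SUFFIX.sub("", barcode)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {', '.join(missing)}")


def _pair_contigs(
    contigs: Sequence[ContigRecord],
    sample_id: str,
    config: FilterConfig,
) -> list[CellReceptor]:
    """Filter contigs and resolve them to at most one chain per locus class.

    Filtering order: non-productive, then low-confidence, then zero-UMI
    records are dropped; per (barcode, locus class) the contig with the
    highest UMI count wins (ties: higher read count, then lexicographically
    smallest contig_id).
    """
    kept = [c for c in contigs if c.productive or not config.productive_only]
    kept = [c for c in kept if c.high_confidence or not config.high_confidence_only]
    kept = [c for c in kept if c.umi_count >= 1]

    by_barcode: dict[str, dict[str, list[ContigRecord]]] = {}
    order: list[str] = []
    for c in kept:
        if c.barcode not in by_barcode:
            by_barcode[c.barcode] = {"vdj": [], "vj": []}
            order.append(c.barcode)
        by_barcode[c.barcode]["vdj" if c.is_vdj_locus else "vj"].append(c)

    cells: list[CellReceptor] = []
    for barcode in sorted(order):
        slots = by_barcode[barcode]
        resolved = False
        best: dict[str, Optional[ContigRecord]] = {"vdj": None, "vj": None}
        for cls, candidates in slots.items():
            if not candidates:
                continue
            winner = min(
                candidates, key=lambda c: (-c.umi_count, -c.read_count, c.contig_id)
            )
            best[cls] = winner
            if len(candidates) > 1:
                resolved = True
        if resolved:
            category = "multi_resolved"
        elif best["vdj"] is not None and best["vj"] is not None:
            category = "paired"
        elif best["vdj"] is not None:
            category = "vdj_only"
        else:
            category = "vj_only"
        cells.append(
            CellReceptor(
                sample_id=sample_id,
                barcode=barcode,
                vdj_chain=best["vdj"],
                vj_chain=best["vj"],
                chain_category=category,
            )
        )
    return cells


def read_cellranger_vdj(
    contig_csv_path: os.PathLike | str,
    sample_id: str,
    filter_config: FilterConfig = FilterConfig(),
) -> list[CellReceptor]:
    """Read a Cellranger ``filtered_contig_annotations.csv`` into cell receptors.

    An optional non-standard ``sequence_nt`` column is honoured when present
    (the annotation CSV itself carries no assembled sequence; full sequences
    normally travel in the companion FASTA or an AIRR export).
    """
    df = pd.read_csv(contig_csv_path, dtype=str, keep_default_na=False)
    _require_columns(df, CELLRANGER_REQUIRED, "contig annotation CSV")

    contigs: list[ContigRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        locus = row["chain"]
        if locus not in VDJ_LOCI | VJ_LOCI:
            continue
        barcode = row["barcode"]
        if filter_config.strip_barcode_suffix:
            barcode = strip_barcode_suffix(barcode)
        contigs.append(
            ContigRecord(
                barcode=barcode,
                contig_id=row.get("contig_id", "") or f"contig_{i}",
                locus=locus,
                v_call=row["v_gene"],
                d_call=row.get("d_gene", "") if row.get("d_gene", "") != "None" else "",
                j_call=row["j_gene"],
                c_call=row.get("c_gene", "") if row.get("c_gene", "") != "None" else "",
                cdr3_nt=row["cdr3_nt"],
                cdr3_aa=row["cdr3"],
                sequence_nt=row.get("sequence_nt", ""),
                umi_count=int(row["umis"] or 0),
                read_count=int(row["reads"] or 0),
                productive=_as_bool(row["productive"]),
                high_confidence=_as_bool(row["high_confidence"]),
            )
        )
    cells = _pair_contigs(contigs, sample_id, filter_config)
    if not cells:
        logger.warning("no cells retained from %s after filtering", contig_csv_path)
    return cells


def read_airr(
    tsv_path: os.PathLike | str,
    sample_id: str,
    filter_config: FilterConfig = FilterConfig(),
) -> list[CellReceptor]:
    """Read an AIRR Rearrangement TSV into cell receptors.

    ``junction`` maps to ``cdr3_nt`` and ``duplicate_count`` to the UMI
    count. Rows without a ``cell_id`` cannot be linked to a cell and are
    skipped (counted in the log). When a ``repertoire_id`` column is
    present it overrides ``sample_id`` row-wise, so multi-sample files
    written by :func:`write_airr` round-trip.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, AIRR_REQUIRED, "AIRR Rearrangement TSV")

    skipped = 0
    per_sample: dict[str, list[ContigRecord]] = {}
    for row in df.itertuples(index=False):
        row = row._asdict()
        if not row["cell_id"]:
            skipped += 1
            continue
        locus = row["locus"]
        if locus not in VDJ_LOCI | VJ_LOCI:
            continue
        sid = row.get("repertoire_id", "") or sample_id
        barcode = row["cell_id"]
        if filter_config.strip_barcode_suffix:
            barcode = strip_barcode_suffix(barcode)
        per_sample.setdefault(sid, []).append(
            ContigRecord(
                barcode=barcode,
                contig_id=row["sequence_id"],
                locus=locus,
                v_call=row["v_call"],
                d_call=row.get("d_call", ""),
                j_call=row["j_call"],
                c_call=row.get("c_call", ""),
                cdr3_nt=row["junction"],
                cdr3_aa=row["junction_aa"],
                sequence_nt=row["sequence"],
                umi_count=int(row["duplicate_count"] or 0),
                read_count=int(row.get("consensus_count", "") or 0),
                productive=_as_bool(row["productive"]),
                high_confidence=_as_bool(row.get("high_confidence", "T")),
            )
        )
    if skipped:
        logger.warning("skipped %d AIRR rows lacking cell_id in %s", skipped, tsv_path)

    cells: list[CellReceptor] = []
    for sid in per_sample:
        cells.extend(_pair_contigs(per_sample[sid], sid, filter_config))
    if not cells:
        logger.warning("no cells retained from %s after filtering", tsv_path)
    return cells


def write_airr(project: RepertoireProject, tsv_path: os.PathLike | str) -> int:
    """Write every retained chain as one AIRR Rearrangement row.

    Returns the number of rows written. ``read_airr`` on the output
    reproduces all chain-level fields exactly.
    """
    rows = []
    for cell in project.cells():
        for chain in cell.chains:
            rows.append(
                {
                    "sequence_id": chain.contig_id,
                    "sequence": chain.sequence_nt,
                    "locus": chain.locus,
                    "v_call": chain.v_call,
                    "d_call": chain.d_call,
                    "j_call": chain.j_call,
                    "c_call": chain.c_call,
                    "junction": chain.cdr3_nt,
                    "junction_aa": chain.cdr3_aa,
                    "productive": "T" if chain.productive else "F",
                    "cell_id": cell.barcode,
                    "repertoire_id": cell.sample_id,
                    "duplicate_count": chain.umi_count,
                    "consensus_count": chain.read_count,
                    "high_confidence": "T" if chain.high_confidence else "F",
                }
            )
    df = pd.DataFrame(rows, columns=list(AIRR_COLUMNS))
    df.to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    return len(rows)


def project_from_cells(cells: Iterable[CellReceptor]) -> RepertoireProject:
    """Assemble a project from loose cell receptors, building cell_meta flags."""
    samples: dict[str, list[CellReceptor]] = {}
    for cell in cells:
        samples.setdefault(cell.sample_id, []).append(cell)
    keys = [(c.sample_id, c.barcode) for sid in samples for c in samples[sid]]
    meta = pd.DataFrame(
        {"has_vdj": True, "has_gex": False},
        index=pd.MultiIndex.from_tuples(
            keys or [], names=["sample_id", "barcode"]
        ),
    )
    if not keys:
        meta = RepertoireProject().cell_meta
    return RepertoireProject(samples=samples, cell_meta=meta)


def _read_feature_names(features_path: os.PathLike | str) -> list[str]:
    feats = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    # cellranger writes (id, name, type); single-column files are plain names
    return list(feats[0])


def attach_gex(
    project: RepertoireProject,
    mtx_path: os.PathLike | str,
    barcodes_path: os.PathLike | str,
    features_path: os.PathLike | str,
    sample_id: str,
    strip_suffix: bool = True,
) -> RepertoireProject:
    """Attach a genes x cells MatrixMarket count matrix to one sample.

    Barcodes are normalized by stripping a trailing ``-<digit>`` suffix
    before matching against VDJ barcodes (disable with ``strip_suffix``).
    Cells present in only one modality are kept and flagged in cell_meta.
    """
    mat = scipy.io.mmread(os.fspath(mtx_path)).tocsc()
    barcodes = [ln.strip() for ln in Path(barcodes_path).read_text().splitlines() if ln.strip()]
    features = _read_feature_names(features_path)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape[0]}x{mat.shape[1]} but sidecars list "
            f"{len(features)} features and {len(barcodes)} barcodes"
        )
    if strip_suffix:
        barcodes = [strip_barcode_suffix(b) for b in barcodes]

    out = project.copy()
    columns = pd.MultiIndex.from_arrays(
        [[sample_id] * len(barcodes), barcodes], names=["sample_id", "barcode"]
    )
    gex = pd.DataFrame(np.asarray(mat.todense()), index=features, columns=columns)
    if out.gex is None:
        out.gex = gex
    else:
        if sample_id in out.gex.columns.get_level_values("sample_id"):
            raise FormatError(f"GEX for sample {sample_id!r} already attached")
        out.gex = pd.concat([out.gex, gex], axis=1).fillna(0).astype(gex.dtypes.iloc[0])

    vdj_keys = {c.key for c in out.samples.get(sample_id, [])}
    gex_keys = set(columns)
    overlap = len(vdj_keys & gex_keys)
    if overlap == 0:
        logger.warning(
            "no barcode overlap between GEX and VDJ for sample %s", sample_id
        )
    meta = out.cell_meta
    for key in sorted(gex_keys):
        if key not in meta.index:
            meta.loc[key, ["has_vdj", "has_gex"]] = [False, True]
        else:
            meta.loc[key, "has_gex"] = True
    out.cell_meta = meta
    logger.info("sample %s: %d barcodes shared between GEX and VDJ", sample_id, overlap)
    return out


def merge_projects(projects: Sequence[RepertoireProject]) -> RepertoireProject:
    """Union samples, metadata, and GEX from several projects.

    Sample ids must be unique across inputs. The merged gene set is the
    union; cells missing from a project's matrix are zero-filled and a
    per-cell ``gex_source`` flag records which input supplied counts.
    """
    seen: dict[str, int] = {}
    for p in projects:
        for sid in p.samples:
            seen[sid] = seen.get(sid, 0) + 1
    dupes = sorted(s for s, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate sample_id(s) across projects: {', '.join(dupes)}")

    merged = RepertoireProject()
    gex_parts = []
    metas = []
    for i, p in enumerate(projects):
        for sid, cells in p.samples.items():
            merged.samples[sid] = list(cells)
        if p.gex is not None:
            gex_parts.append((i, p.gex))
        if not p.cell_meta.empty:
            metas.append(p.cell_meta)
        merged.provenance.extend(p.provenance)

    if metas:
        merged.cell_meta = pd.concat(metas)
    if gex_parts:
        frames = [g for _, g in gex_parts]
        merged.gex = pd.concat(frames, axis=1).reindex(
            sorted(set().union(*[set(f.index) for f in frames]))
        ).fillna(0).astype(int)
        source = pd.Series(
            {
                col: f"input_{i}"
                for i, frame in gex_parts
                for col in frame.columns
            }
        )
        meta = merged.cell_meta
        for key, src in source.items():
            if key in meta.index:
                meta.loc[key, "gex_source"] = src
        merged.cell_meta = meta
    merged.validate()
    return merged


# ---------------------------------------------------------------------------
# Project bundles: the on-disk directory form of RepertoireProject
# ---------------------------------------------------------------------------

BUNDLE_AIRR = "airr_rearrangement.tsv"
BUNDLE_MTX = "matrix.mtx"
BUNDLE_BARCODES = "barcodes.tsv"
BUNDLE_FEATURES = "features.tsv"
BUNDLE_META = "metadata.tsv"


def write_bundle(project: RepertoireProject, out_dir: os.PathLike | str) -> Path:
    """Write a project to a bundle directory; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_airr(project, out / BUNDLE_AIRR)
    if project.gex is not None:
        sparse = scipy.sparse.csc_matrix(project.gex.to_numpy())
        scipy.io.mmwrite(os.fspath(out / BUNDLE_MTX), sparse, field="integer")
        keys = [f"{sid}:{bc}" for sid, bc in project.gex.columns]
        (out / BUNDLE_BARCODES).write_text("\n".join(keys) + "\n")
        (out / BUNDLE_FEATURES).write_text("\n".join(project.gex.index) + "\n")
    if not project.cell_meta.empty:
        project.cell_meta.reset_index().to_csv(
            out / BUNDLE_META, sep="\t", index=False, lineterminator="\n"
        )
    return out


def read_bundle(
    bundle_dir: os.PathLike | str,
    filter_config: FilterConfig = FilterConfig(),
) -> RepertoireProject:
    """Read a bundle directory back into a project."""
    bundle = Path(bundle_dir)
    airr = bundle / BUNDLE_AIRR
    if not airr.exists():
        raise FileNotFoundError(f"bundle {bundle} has no {BUNDLE_AIRR}")
    cells = read_airr(airr, sample_id=bundle.name, filter_config=filter_config)
    project = project_from_cells(cells)
    project.provenance.append(str(bundle))

    mtx = bundle / BUNDLE_MTX
    if mtx.exists():
        mat = scipy.io.mmread(os.fspath(mtx)).tocsc()
        lines = [
            ln.strip()
            for ln in (bundle / BUNDLE_BARCODES).read_text().splitlines()
            if ln.strip()
        ]
        # barcodes are either "sample:barcode" keys (bundle writer) or
        # plain cellranger barcodes belonging to the bundle's single sample
        keys: list[tuple[str, str]] = []
        for ln in lines:
            if ":" in ln:
                sid, bc = ln.split(":", 1)
            else:
                sids = sorted(project.samples)
                if len(sids) != 1:
                    raise FormatError(
                        "plain barcodes.tsv requires a single-sample bundle"
                    )
                sid, bc = sids[0], ln
            if filter_config.strip_barcode_suffix:
                bc = strip_barcode_suffix(bc)
            keys.append((sid, bc))
        features = _read_feature_names(bundle / BUNDLE_FEATURES)
        columns = pd.MultiIndex.from_tuples(keys, names=["sample_id", "barcode"])
        project.gex = pd.DataFrame(
            np.asarray(mat.todense()), index=features, columns=columns
        )

    meta_path = bundle / BUNDLE_META
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "barcode": str})
        project.cell_meta = meta.set_index(["sample_id", "barcode"])
    return project
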