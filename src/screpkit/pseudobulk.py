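"""Pseudobulk aggregation and two-group differential expression.

Single-cell counts are summed within (sample x cluster) units so that
replicate-aware bulk-style statistics apply: per unit, counts are
normalized to counts-per-million and log2(x + 1) transformed; per gene,
a Welch unequal-variance t test compares the two groups of units, with
Benjamini-Hochberg step-up control of the false discovery rate across
genes within the contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import RepertoireProject

logger = logging.getLogger(__name__)


@dataclass
class PseudobulkMatrix:
    """Genes x (sample, cluster) unit matrix of summed counts."""

    counts: pd.DataFrame  # genes x MultiIndex(sample_id, cluster)
    cells_per_unit: pd.Series
    sample_groups: Optional[dict[str, str]] = None  # sample_id -> condition label

    @property
    def units(self) -> list[tuple[str, str]]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class DEResult:
    """Differential-expression call for one gene."""

    gene: str
    log2_fc: float
    statistic: float
    df: float
    p_value: float
    fdr: float
    mean_a: float
    mean_b: float


def pseudobulk(
    project: RepertoireProject,
    group_by: Optional[str] = None,
    cluster_by: str = "cluster",
    min_cells: int = 10,
) -> PseudobulkMatrix:
    """Sum cell counts into per-(sample, cluster) pseudobulk units.

    ``group_by`` optionally names a cell_meta column holding each
    sample's condition label; the per-sample labels are carried on the
    result for the downstream contrast. Units with fewer than
    ``min_cells`` member cells are excluded (and logged). Column sums are
    conserved exactly: each unit's total equals the summed counts of its
    member cells.
    """
    if project.gex is None:
        raise ValueError("project has no attached GEX matrix")
    if cluster_by not in project.cell_meta.columns:
        raise ValueError(f"cell_meta has no column {cluster_by!r}")

    clusters = project.cell_meta[cluster_by].dropna()
    cols = [key for key in project.gex.columns if key in clusters.index]
    unit_of = {
        key: (key[0], str(clusters.loc[key])) for key in cols
    }
    groups: dict[tuple[str, str], list] = {}
    for key, unit in unit_of.items():
        groups.setdefault(unit, []).append(key)

    kept, dropped = {}, []
    for unit in sorted(groups):
        members = groups[unit]
        if len(members) < min_cells:
            dropped.append(unit)
            continue
        kept[unit] = project.gex[members].sum(axis=1)
    if dropped:
        logger.info("excluded %d unit(s) below min_cells=%d: %s",
                    len(dropped), min_cells, dropped)
    if not kept:
        logger.warning("all pseudobulk units fell below min_cells=%d", min_cells)
        empty = pd.DataFrame(
            index=project.gex.index,
            columns=pd.MultiIndex.from_arrays([[], []], names=["sample_id", "cluster"]),
        )
        return PseudobulkMatrix(counts=empty, cells_per_unit=pd.Series(dtype=int))

    counts = pd.DataFrame(kept)
    counts.columns = pd.MultiIndex.from_tuples(kept.keys(), names=["sample_id", "cluster"])
    cells = pd.Series({u: len(groups[u]) for u in kept}, name="n_cells")
    sample_groups = None
    if group_by is not None:
        if group_by not in project.cell_meta.columns:
            raise ValueError(f"cell_meta has no column {group_by!r}")
        labels = project.cell_meta[group_by].dropna()
        sample_groups = {
            sid: str(sub.iloc[0])
            for sid, sub in labels.groupby(level="sample_id")
        }
    return PseudobulkMatrix(
        counts=counts.astype(np.int64), cells_per_unit=cells, sample_groups=sample_groups
    )


def pseudobulk_from_counts(
    counts: pd.DataFrame, cells_per_unit: Optional[pd.Series] = None
) -> PseudobulkMatrix:
    """Wrap an existing genes x units count table (e.g. simulated units)."""
    if cells_per_unit is None:
        cells_per_unit = pd.Series(1, index=counts.columns)
    return PseudobulkMatrix(counts=counts, cells_per_unit=cells_per_unit)


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million then log2(x + 1), per unit column."""
    lib = counts.sum(axis=0).astype(float)
    cpm = counts / lib.replace(0, np.nan) * 1e6
    return np.log2(cpm.fillna(0.0) + 1.0)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch t statistic, Welch-Satterthwaite df, two-sided p.

    Genes with zero variance in both groups get statistic 0 and p 1 when
    the means agree; a mean difference with zero variance is reported at
    the smallest representable p.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    zero_se = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    df = np.where(np.isfinite(df), df, max(na + nb - 2, 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return t, df, p


def de_test(
    pb: PseudobulkMatrix,
    group_assignment: Mapping[str, str],
    cluster: Optional[str] = None,
    min_replicates: int = 2,
) -> list[DEResult]:
    """Welch t differential expression between groups A and B of units.

    ``group_assignment`` maps sample ids to ``"A"`` / ``"B"``; units from
    unassigned samples are ignored. When ``cluster`` is given only units
    of that cluster enter the contrast (BH correction is applied within
    the contrast only). Genes with zero counts everywhere are excluded
    before testing. ``log2_fc`` is mean log-CPM of A minus mean of B.
    """
    counts = pb.counts
    if cluster is not None:
        counts = counts.loc[:, counts.columns.get_level_values("cluster") == str(cluster)]
    sample_ids = counts.columns.get_level_values("sample_id")
    in_a = [g == "A" for g in (group_assignment.get(s) for s in sample_ids)]
    in_b = [g == "B" for g in (group_assignment.get(s) for s in sample_ids)]
    cols_a = counts.columns[np.asarray(in_a)]
    cols_b = counts.columns[np.asarray(in_b)]
    for name, cols in (("A", cols_a), ("B", cols_b)):
        if len(cols) < min_replicates:
            raise ValueError(
                f"group {name} has {len(cols)} unit(s); "
                f"min_replicates={min_replicates} required"
            )

    sub = counts[list(cols_a) + list(cols_b)]
    expressed = sub.sum(axis=1) > 0
    sub = sub.loc[expressed]
    logged = log_cpm(sub)
    a = logged[list(cols_a)].to_numpy()
    b = logged[list(cols_b)].to_numpy()
    t, df, p = _welch(a, b)
    fdr = multipletests(p, method="fdr_bh")[1]

    ma, mb = a.mean(axis=1), b.mean(axis=1)
    results = [
        DEResult(
            gene=g,
            log2_fc=float(ma[i] - mb[i]),
            statistic=float(t[i]),
            df=float(df[i]),
            p_value=float(p[i]),
            fdr=float(fdr[i]),
            mean_a=float(ma[i]),
            mean_b=float(mb[i]),
        )
        for i, g in enumerate(sub.index)
    ]
    results.sort(key=lambda r: (r.p_value, r.gene))
    return results


def de_results_to_frame(results: Sequence[DEResult], cluster: str = "") -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene,
            "cluster": cluster,
            "log2_fc": r.log2_fc,
            "statistic": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "mean_a": r.mean_a,
            "mean_b": r.mean_b,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["gene", "cluster", "log2_fc", "statistic", "df",
                 "p_value", "fdr", "mean_a", "mean_b"],
    )
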