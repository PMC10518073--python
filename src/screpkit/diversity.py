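"""Clonal diversity, evenness, rarefaction, and between-sample overlap.

All metrics operate on a :class:`ClonalFrequencyVector` — the clone-size
vector of one sample. Shannon entropy is reported in nats by default
(``base=2`` gives bits); rarefaction uses the exact hypergeometric
expectation of richness at a reduced sampling depth,

    E[S_m] = sum_i [ 1 - C(N - N_i, m) / C(N, m) ],

which diagnoses whether sampling depth was sufficient to recover the
clonal richness of the repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln


@dataclass
class ClonalFrequencyVector:
    """Clone sizes of one sample; optionally labelled by clonotype id."""

    sample_id: str
    counts: np.ndarray
    labels: Optional[list[str]] = None
    total: int = field(init=False)

    def __init__(
        self,
        sample_id: str,
        counts: Sequence[int],
        labels: Optional[Sequence[str]] = None,
    ) -> None:
        self.sample_id = sample_id
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.counts.size and (self.counts < 1).any():
            raise ValueError("all clone counts must be >= 1")
        if labels is not None and len(labels) != self.counts.size:
            raise ValueError("labels length must match counts")
        self.labels = list(labels) if labels is not None else None
        self.total = int(self.counts.sum())

    @property
    def richness(self) -> int:
        return int(self.counts.size)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.total

    def _require_nonempty(self) -> None:
        if self.counts.size == 0:
            raise ValueError(f"sample {self.sample_id!r}: empty frequency vector")


def shannon(v: ClonalFrequencyVector, base: Optional[float] = None) -> float:
    """Shannon entropy H = -sum p_i log p_i (nats unless ``base`` given)."""
    v._require_nonempty()
    p = v.proportions
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


def pielou_evenness(v: ClonalFrequencyVector) -> float:
    """Evenness J = H / ln(S); defined as 1.0 for a single clone."""
    v._require_nonempty()
    if v.richness == 1:
        return 1.0
    return shannon(v) / np.log(v.richness)


def inverse_simpson(v: ClonalFrequencyVector) -> float:
    """Inverse Simpson index D = 1 / sum p_i**2; equals S iff uniform."""
    v._require_nonempty()
    p = v.proportions
    return float(1.0 / (p**2).sum())


def gini_simpson(v: ClonalFrequencyVector) -> float:
    """Gini-Simpson index 1 - sum p_i**2."""
    v._require_nonempty()
    p = v.proportions
    return float(1.0 - (p**2).sum())


def gini(v: ClonalFrequencyVector) -> float:
    """Gini inequality coefficient of clone sizes.

    G = sum_ij |x_i - x_j| / (2 n sum_i x_i); 0 for a perfectly even
    repertoire, (n-1)/n when one clone holds everything. A single-clone
    vector is defined as 0.
    """
    v._require_nonempty()
    x = np.sort(v.counts)
    n = x.size
    if n == 1:
        return 0.0
    # identity: sum_ij |x_i - x_j| = 2 * sum_i (2i - n + 1) x_(i) for sorted x
    i = np.arange(1, n + 1)
    num = float((2 * i - n - 1) @ x)
    return num / (n * x.sum())


def rarefaction_curve(
    v: ClonalFrequencyVector, depths: Optional[Sequence[int]] = None
) -> list[tuple[int, float]]:
    """Expected richness at each subsampling depth (exact hypergeometric).

    Default depths: 10 evenly spaced values from 10% to 100% of the total.
    The curve is non-decreasing and hits the observed richness at
    ``m == total`` exactly.
    """
    v._require_nonempty()
    if depths is None:
        depths = sorted(
            {max(1, round(v.total * f / 10)) for f in range(1, 11)}
        )
    n_total = v.total
    counts = v.counts
    out = []
    for m in depths:
        m = int(m)
        if not 1 <= m <= n_total:
            raise ValueError(f"depth m={m} outside [1, {n_total}]")
        if m == n_total:
            out.append((m, float(v.richness)))
            continue
        # P(clone i unseen) = C(N - N_i, m) / C(N, m), via log-gamma
        rest = n_total - counts
        with np.errstate(invalid="ignore"):
            log_unseen = (
                gammaln(rest + 1)
                - gammaln(rest - m + 1)
                + gammaln(n_total - m + 1)
                - gammaln(n_total + 1)
            )
        p_unseen = np.where(rest >= m, np.exp(log_unseen), 0.0)
        out.append((m, float((1.0 - p_unseen).sum())))
    return out


def overlap(
    a: ClonalFrequencyVector,
    b: ClonalFrequencyVector,
    method: str = "morisita_horn",
) -> float:
    """Between-sample clonal overlap in [0, 1].

    ``jaccard`` works on presence/absence of shared clonotypes;
    ``morisita_horn`` is abundance-weighted:
    2 sum x_i y_i / ((sum x_i^2 / X^2 + sum y_i^2 / Y^2) X Y).
    Vectors are aligned on their clonotype labels when both carry them,
    otherwise positionally.
    """
    if a.counts.size == 0 and b.counts.size == 0:
        raise ValueError("both frequency vectors are empty")
    if a.labels is not None and b.labels is not None:
        keys = sorted(set(a.labels) | set(b.labels))
        xa = dict(zip(a.labels, a.counts))
        xb = dict(zip(b.labels, b.counts))
        x = np.array([xa.get(k, 0) for k in keys], dtype=float)
        y = np.array([xb.get(k, 0) for k in keys], dtype=float)
    else:
        n = max(a.counts.size, b.counts.size)
        x = np.zeros(n)
        y = np.zeros(n)
        x[: a.counts.size] = a.counts
        y[: b.counts.size] = b.counts

    if method == "jaccard":
        pa, pb = x > 0, y > 0
        union = (pa | pb).sum()
        return float((pa & pb).sum() / union) if union else 0.0
    if method == "morisita_horn":
        bigx, bigy = x.sum(), y.sum()
        if bigx == 0 or bigy == 0:
            return 0.0
        num = 2.0 * float(x @ y)
        den = ((x @ x) / bigx**2 + (y @ y) / bigy**2) * bigx * bigy
        return float(num / den) if den else 0.0
    raise ValueError(f"unknown overlap method {method!r}")


#: Scalar metrics exposed to the CLI / diversity tables, by name.
SCALAR_METRICS = {
    "richness": lambda v: float(v.richness),
    "shannon": shannon,
    "pielou_evenness": pielou_evenness,
    "inverse_simpson": inverse_simpson,
    "gini_simpson": gini_simpson,
    "gini": gini,
}


def diversity_table(
    vectors: Sequence[ClonalFrequencyVector],
    metrics: Optional[Sequence[str]] = None,
):
    """Long-format table of (sample_id, metric, value) for chosen metrics."""
    import pandas as pd

    names = list(metrics) if metrics else list(SCALAR_METRICS)
    unknown = [m for m in names if m not in SCALAR_METRICS]
    if unknown:
        raise ValueError(f"unknown metric(s): {', '.join(unknown)}")
    rows = [
        {"sample_id": v.sample_id, "metric": m, "value": SCALAR_METRICS[m](v)}
        for v in vectors
        for m in names
    ]
    return pd.DataFrame(rows, columns=["sample_id", "metric", "value"])
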