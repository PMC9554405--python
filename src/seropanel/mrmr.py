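"""mRMR feature ranking with subsample stability scoring.

Analytes are discretized into equal-frequency bins (terciles by default),
relevance and redundancy are plug-in mutual information (bits), selection is
the greedy MID (difference) criterion, and stability comes from repeating
the selection on many stratified 80% subsamples of the patients, counting
per analyte how often it lands in the top 5 and top 20 of a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

__all__ = [
    "DiscretizedMatrix",
    "StabilityRanking",
    "discretize",
    "mutual_information",
    "mrmr_rank",
    "stability_select",
]


@dataclass
class DiscretizedMatrix:
    """Integer bin labels per sample x analyte plus the binning spec."""

    labels: pd.DataFrame
    bins: int
    cut_points: dict[str, np.ndarray]
    zero_information: tuple[str, ...] = ()


def _rank_labels(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency labels per column; tie blocks take the lower bin.

    The label of a value is floor((rank_min - 1) * bins / n) where rank_min
    is competition ranking, i.e. every member of a tie block inherits the
    bin of the block's first sorted position.
    """
    n = values.shape[0]
    ranks = rankdata(values, method="min", axis=0).astype(np.int64)
    return (ranks - 1) * bins // n


def discretize(values: pd.DataFrame, bins: int = 3) -> DiscretizedMatrix:
    """Per-analyte equal-frequency binning into ``bins`` integer labels.

    Constant analytes collapse to a single bin and are flagged
    zero-information; analytes with fewer distinct values than bins get
    correspondingly fewer effective bins (logged).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    arr = values.to_numpy(dtype=float)
    labels = _rank_labels(arr, bins)
    n = arr.shape[0]
    cuts = {}
    flat: list[str] = []
    for j, col in enumerate(values.columns):
        v = np.sort(arr[:, j])
        n_distinct = np.unique(v).size
        if n_distinct == 1:
            flat.append(col)
            cuts[col] = np.array([])
            continue
        if n_distinct < bins:
            log.info("analyte %s has %d distinct values < %d bins", col, n_distinct, bins)
        cuts[col] = np.array([v[(k * n) // bins] for k in range(1, bins)])
    return DiscretizedMatrix(
        labels=pd.DataFrame(labels, index=values.index, columns=values.columns),
        bins=bins,
        cut_points=cuts,
        zero_information=tuple(flat),
    )


def mutual_information(x, y) -> float:
    """Plug-in mutual information (log base 2) of two discrete label vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("label vectors must have equal length")
    if x.size == 0:
        raise ValueError("need at least one sample")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / x.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])))


def _mi_columns(X: np.ndarray, nbx: int, y: np.ndarray, ny: int) -> np.ndarray:
    """MI (bits) of every column of an integer label matrix against ``y``.

    One batched bincount over all columns; zero joint cells contribute 0.
    """
    n, p = X.shape
    flat = (X * ny + y[:, None]) + np.arange(p, dtype=np.int64) * (nbx * ny)
    joint = np.bincount(flat.ravel(), minlength=p * nbx * ny).reshape(p, nbx, ny) / n
    px = joint.sum(axis=2, keepdims=True)
    py = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return np.nansum(terms, axis=(1, 2))


def _greedy_mid(X: np.ndarray, nbx: int, y_idx: np.ndarray, ny: int, k: int) -> list[int]:
    """Greedy MID order of column indices; ties break on lowest index."""
    relevance = _mi_columns(X, nbx, y_idx, ny)
    p = X.shape[1]
    selected: list[int] = []
    available = np.ones(p, dtype=bool)
    redundancy_sum = np.zeros(p)
    for step in range(k):
        score = relevance.copy() if step == 0 else relevance - redundancy_sum / step
        score[~available] = -np.inf
        pick = int(np.argmax(score))  # first maximum: catalogue (column) order
        selected.append(pick)
        available[pick] = False
        if step < k - 1:
            redundancy_sum += _mi_columns(X, nbx, X[:, pick], nbx)
    return selected


def mrmr_rank(discretized: DiscretizedMatrix | pd.DataFrame, class_labels, k: int) -> list[str]:
    """Greedy MID selection of ``k`` analytes.

    First pick maximizes relevance I(f; y); each subsequent pick maximizes
    relevance minus mean redundancy against the already selected set.  Exact
    score ties break deterministically by column (catalogue) order.
    """
    frame = discretized.labels if isinstance(discretized, DiscretizedMatrix) else discretized
    if k > frame.shape[1]:
        raise ValueError("k exceeds number of analytes")
    y = np.asarray(class_labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes for relevance")
    X = frame.to_numpy(dtype=np.int64)
    nbx = int(X.max()) + 1
    picks = _greedy_mid(X, nbx, y_idx.astype(np.int64), int(classes.size), k)
    return [frame.columns[i] for i in picks]


@dataclass
class StabilityRanking:
    """Top-5/top-20 membership counts over resampled mRMR runs."""

    table: pd.DataFrame  # analyte-indexed: count_top5, count_top20, rank
    n_rep: int
    k: int

    def top(self, n: int = 5) -> list[str]:
        return list(self.table.sort_values("rank").index[:n])


def stability_select(
    log10_values: pd.DataFrame,
    class_labels: pd.Series,
    n_rep: int = 1000,
    frac: float = 0.8,
    seed: int = 0,
    bins: int = 3,
    k: int = 20,
) -> StabilityRanking:
    """Stability-scored mRMR over stratified patient subsamples.

    Each replicate draws ``ceil(frac * n_c)`` patients per class without
    replacement (stratified, so no class can empty), re-discretizes the
    subsample, runs greedy MID with ``k`` picks (20, or the analyte count if
    smaller), and credits the first 5 picks to ``count_top5`` and all ``k``
    to ``count_top20``.  The final score orders lexicographically by
    (count_top5, count_top20) descending with catalogue-order ties;
    replicate r uses the derived seed ``seed + r`` for auditability.
    """
    y = pd.Series(class_labels).reindex(log10_values.index)
    classes, y_all = np.unique(y.to_numpy(), return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    k = min(k, log10_values.shape[1])
    idx_by_class = [np.flatnonzero(y_all == c) for c in range(classes.size)]
    for c, idx in zip(classes, idx_by_class):
        if int(np.ceil(frac * len(idx))) < 2:
            raise ValueError(f"class {c!r} too small for frac={frac}")

    V = log10_values.to_numpy(dtype=float)
    y_all = y_all.astype(np.int64)
    ny = int(classes.size)
    p = V.shape[1]
    count5 = np.zeros(p, dtype=np.int64)
    count20 = np.zeros(p, dtype=np.int64)
    for r in range(n_rep):
        rng = np.random.default_rng(seed + r)
        take = np.sort(
            np.concatenate(
                [
                    rng.choice(idx, size=int(np.ceil(frac * len(idx))), replace=False)
                    for idx in idx_by_class
                ]
            )
        )
        labels = _rank_labels(V[take], bins)
        picks = _greedy_mid(labels, bins, y_all[take], ny, k)
        count5[picks[:5]] += 1
        count20[picks] += 1

    analytes = list(log10_values.columns)
    table = pd.DataFrame(
        {"count_top5": count5, "count_top20": count20}, index=pd.Index(analytes, name="analyte")
    )
    order_idx = sorted(range(p), key=lambda i: (-count5[i], -count20[i], i))
    rank = np.empty(p, dtype=np.int64)
    for pos, i in enumerate(order_idx, start=1):
        rank[i] = pos
    table["rank"] = rank
    return StabilityRanking(table=table, n_rep=n_rep, k=k)
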