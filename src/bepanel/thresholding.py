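"""Per-gene optimal cutpoint search, gene ranking, and single-gene AUC.

For each gene the thresholding function scans every candidate expression
cutpoint under both orientations (positive-if-high and positive-if-low)
and keeps the cutpoint maximizing the F1 score between the two sample
classes.  Because F1 is piecewise constant between observed values, the
candidate grid of midpoints between consecutive distinct values — plus
one sentinel below the minimum and one above the maximum, so the trivial
all-positive and all-negative classifiers are representable — loses
nothing relative to a continuum search.

Both orientations are searched because candidate biomarkers include both
up- and down-regulated genes.  Ties in F1 are broken toward higher
specificity (a clinical preference for fewer false positives), then
toward the cutpoint closest to the median of the observed values, then
toward the positive-if-high orientation with the smaller cutpoint, which
makes the result deterministic.

Single-gene discrimination is also summarized by the ROC AUC; for a
single feature any monotone score yields the same ranking, so this is
the rank-based (Mann-Whitney) AUC of the raw values, reported unfolded
(values below 0.5 indicate down-regulation in the positive class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .containers import ExpressionMatrix, SampleAnnotation, two_group_view
from .exceptions import DataError
from .metrics import METRIC_NAMES, ConfusionCounts, MetricSuite, compute_metrics

POSITIVE_IF_HIGH = "positive_if_ge"
POSITIVE_IF_LOW = "positive_if_lt"


@dataclass(frozen=True)
class ThresholdResult:
    """One gene's optimal cutpoint, its orientation, and the metrics there."""

    gene_id: str
    cutpoint: float
    direction: str  # POSITIVE_IF_HIGH or POSITIVE_IF_LOW
    counts: ConfusionCounts
    metrics: MetricSuite
    auc: float | None = None


def candidate_cutpoints(values: np.ndarray) -> np.ndarray:
    """Strictly increasing candidate cutpoints for one gene.

    Midpoints between consecutive distinct sorted values, bracketed by
    two sentinels placed half the smallest adjacent gap below the
    minimum and above the maximum (gap 1 when all values coincide).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DataError("need at least 2 values")
    if not np.isfinite(values).all():
        raise DataError("values must be finite")
    u = np.unique(values)
    if u.size == 1:
        half = 1.0
        return np.array([u[0] - half, u[0] + half])
    gaps = np.diff(u)
    half = gaps.min() / 2.0
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - half], mids, [u[-1] + half]])


def _counts_at_cuts(
    values: np.ndarray, labels: np.ndarray, cuts: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (tp, fp, tn, fn) for predict-positive-if-value>=cut."""
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    npos = int(y.sum())
    nneg = y.size - npos
    # pos_below[i]: positives among the i smallest values
    pos_below = np.concatenate([[0], np.cumsum(y)])
    idx = np.searchsorted(v, cuts, side="left")
    tp = npos - pos_below[idx]
    n_ge = y.size - idx
    fp = n_ge - tp
    fn = npos - tp
    tn = nneg - fp
    return tp, fp, tn, fn


def _f1(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray) -> np.ndarray:
    den = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, 2 * tp / den, 0.0)


def best_threshold(
    values: np.ndarray, labels: np.ndarray, gene_id: str = "", with_auc: bool = True
) -> ThresholdResult:
    """Cutpoint and orientation maximizing F1 over the candidate grid.

    ``labels`` is a 0/1 vector (1 = positive class) aligned with
    ``values``; both classes must be present.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape:
        raise DataError("values and labels must be aligned")
    if labels.min(initial=1) == labels.max(initial=0):
        raise DataError("need two classes")

    cuts = candidate_cutpoints(values)
    tp, fp, tn, fn = _counts_at_cuts(values, labels, cuts)

    # positive-if-high uses (tp, fp, tn, fn); positive-if-low swaps the
    # predicted side: everything below the cut is called positive.
    cand_counts = np.concatenate(
        [
            np.stack([tp, fp, tn, fn], axis=1),
            np.stack([fn, tn, fp, tp], axis=1),
        ]
    )
    cand_cuts = np.concatenate([cuts, cuts])
    cand_dirs = [POSITIVE_IF_HIGH] * len(cuts) + [POSITIVE_IF_LOW] * len(cuts)

    f1 = _f1(cand_counts[:, 0], cand_counts[:, 1], cand_counts[:, 3])
    best_f1 = f1.max()
    tied = np.flatnonzero(f1 == best_f1)

    # tie-breaks: specificity desc, |cut - median| asc, high-orientation
    # first, then smaller cutpoint
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = np.where(
            cand_counts[tied, 2] + cand_counts[tied, 1] > 0,
            cand_counts[tied, 2] / (cand_counts[tied, 2] + cand_counts[tied, 1]),
            0.0,
        )
    med = np.median(values)
    dist = np.abs(cand_cuts[tied] - med)
    dir_rank = np.array([0 if cand_dirs[i] == POSITIVE_IF_HIGH else 1 for i in tied])
    keys = list(zip(-spec, dist, dir_rank, cand_cuts[tied]))
    winner = tied[min(range(len(tied)), key=keys.__getitem__)]

    counts = ConfusionCounts(*(float(c) for c in cand_counts[winner]))
    auc = single_gene_auc(values, labels) if with_auc else None
    return ThresholdResult(
        gene_id=gene_id,
        cutpoint=float(cand_cuts[winner]),
        direction=cand_dirs[winner],
        counts=counts,
        metrics=compute_metrics(counts),
        auc=auc,
    )


def single_gene_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) ROC AUC of raw values against labels.

    Not folded around 0.5: a gene down-regulated in the positive class
    scores below 0.5.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.min(initial=1) == labels.max(initial=0):
        raise DataError("need two classes")
    return float(roc_auc_score(labels, np.asarray(values, dtype=float)))


RANK_COLUMNS = (
    ["gene_id", "direction", "cutpoint", "tp", "fp", "tn", "fn"]
    + list(METRIC_NAMES)
    + ["auc"]
)


def rank_genes(matrix: ExpressionMatrix, ann: SampleAnnotation) -> pd.DataFrame:
    """Threshold every gene and rank by F1 (desc), AUC (desc), gene ID.

    Returns one row per gene with the cutpoint, orientation, confusion
    counts and all nine metrics at the optimum, sorted best-first.
    """
    if matrix.n_genes == 0:
        raise DataError("empty expression matrix")
    sub, y = two_group_view(matrix, ann)
    x = sub.df.to_numpy()
    rows = []
    for i, gene in enumerate(sub.gene_ids):
        r = best_threshold(x[i], y, gene_id=gene)
        rows.append(
            [gene, r.direction, r.cutpoint, r.counts.tp, r.counts.fp, r.counts.tn,
             r.counts.fn]
            + [r.metrics[m] for m in METRIC_NAMES]
            + [r.auc]
        )
    out = pd.DataFrame(rows, columns=RANK_COLUMNS)
    out = out.sort_values(
        ["f1", "auc", "gene_id"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    return out
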