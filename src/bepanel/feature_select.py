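"""Multi-method feature-selection consensus, correlation pruning, panels.

Four standard selectors are run on standardized features and their votes
tallied per gene: an L1-penalized linear classifier (genes with nonzero
weight), mutual-information ranking (top k), recursive feature
elimination with a linear classifier (k survivors), and a univariate
F-score top-k.  A gene enters the consensus when at least ``min_votes``
(default 2) of the four methods select it — a method selects a gene at
most once, so "appearing at least twice" can only mean agreement across
methods.

Highly correlated features are then pruned greedily: genes are visited
in descending priority (their single-gene thresholding F1) and kept only
if their absolute Pearson correlation with every already-kept gene stays
at or below ``r_max`` (default 0.9), so the individually stronger member
of a redundant pair survives.

Finally, :func:`assemble_panel` intersects the eligibility set with an
F1 floor over the ranked-gene table, truncates to the top ``top_n``
genes, and appends any forced genes (canonically TP53 and CDH1) not
already present — the diagnostic configuration (F1 > 0.7, top 16, two
forced genes) yields at most 18 genes, the prognostic one (F1 > 0.67,
top 13) at most 15.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.feature_selection import (
    RFE,
    SelectKBest,
    f_classif,
    mutual_info_classif,
)
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .containers import ExpressionMatrix, SampleAnnotation, two_group_view
from .exceptions import ConfigError, DataError

logger = logging.getLogger(__name__)

SELECTOR_NAMES = ("lasso", "mutual_info", "rfe", "select_k_best")


@dataclass(frozen=True)
class SelectionVote:
    gene_id: str
    methods: frozenset[str]

    @property
    def votes(self) -> int:
        return len(self.methods)


def run_selectors(
    matrix: ExpressionMatrix,
    ann: SampleAnnotation,
    k: int,
    seed: int = 0,
) -> list[SelectionVote]:
    """Run the four selectors and tally per-gene votes.

    ``k`` is the number of genes each top-k selector keeps (the L1
    selector keeps whatever is nonzero). Deterministic given ``seed``.
    """
    if k <= 0:
        raise ConfigError("k must be positive")
    sub, y = two_group_view(matrix, ann)
    if k > sub.n_genes:
        raise ConfigError(f"k={k} exceeds gene count {sub.n_genes}")
    genes = np.array(sub.gene_ids)
    x = StandardScaler().fit_transform(sub.df.to_numpy().T)  # samples x genes

    selected: dict[str, np.ndarray] = {}

    lasso = LogisticRegression(
        l1_ratio=1.0, C=1.0, solver="liblinear", random_state=seed
    ).fit(x, y)
    selected["lasso"] = genes[np.abs(lasso.coef_[0]) > 0]

    mi = mutual_info_classif(x, y, random_state=seed)
    selected["mutual_info"] = genes[np.argsort(-mi, kind="stable")[:k]]

    rfe = RFE(
        LogisticRegression(solver="liblinear", random_state=seed),
        n_features_to_select=k,
        step=1,
    ).fit(x, y)
    selected["rfe"] = genes[rfe.support_]

    skb = SelectKBest(f_classif, k=k).fit(x, y)
    selected["select_k_best"] = genes[skb.get_support()]

    methods_per_gene: dict[str, set[str]] = {}
    for method, gs in selected.items():
        for g in gs:
            methods_per_gene.setdefault(str(g), set()).add(method)
    return [
        SelectionVote(gene_id=g, methods=frozenset(ms))
        for g, ms in sorted(methods_per_gene.items())
    ]


def consensus_select(votes: Iterable[SelectionVote], min_votes: int = 2) -> set[str]:
    """Genes selected by at least ``min_votes`` of the four methods."""
    if min_votes < 1:
        raise ConfigError("min_votes must be >= 1")
    return {v.gene_id for v in votes if v.votes >= min_votes}


def correlation_prune(
    matrix: ExpressionMatrix,
    genes: Iterable[str],
    r_max: float = 0.9,
    priority: Mapping[str, float] | None = None,
) -> set[str]:
    """Greedy redundancy pruning at |Pearson r| > ``r_max``.

    Genes are visited in descending ``priority`` (ties toward the
    lexicographically smaller gene ID); a gene is kept iff its absolute
    correlation with every already-kept gene is <= ``r_max``.  Genes
    with constant expression have undefined correlations and are treated
    as uncorrelated (kept), with a logged notice.
    """
    genes = list(genes)
    if not genes:
        return set()
    missing = [g for g in genes if g not in matrix.df.index]
    if missing:
        raise DataError(f"genes absent from matrix: {missing}")
    if priority is None:
        priority = {g: 0.0 for g in genes}
    undefined = [g for g in genes if g not in priority]
    if undefined:
        raise DataError(f"priority undefined for genes: {undefined}")

    x = matrix.df.loc[genes].to_numpy()
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "constant-expression genes treated as uncorrelated: %s",
            [g for g, c in zip(genes, constant) if c],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)  # constant genes: uncorrelated

    order = sorted(range(len(genes)), key=lambda i: (-priority[genes[i]], genes[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(corr[i, j]) <= r_max for j in kept):
            kept.append(i)
    return {genes[i] for i in kept}


def assemble_panel(
    ranked: pd.DataFrame,
    eligible: Iterable[str],
    f1_min: float = 0.7,
    top_n: int = 16,
    forced: Iterable[str] = (),
) -> list[str]:
    """Ordered gene panel: top-``top_n`` eligible genes above the F1
    floor, plus forced genes appended without duplication.

    ``ranked`` is the output of :func:`bepanel.thresholding.rank_genes`
    (already sorted best-first). Forced genes must appear in it.
    """
    forced = list(forced)
    ranked_genes = list(ranked["gene_id"])
    absent = [g for g in forced if g not in ranked_genes]
    if absent:
        raise DataError(f"forced genes absent from ranked table: {absent}")
    eligible = set(eligible)
    keep = ranked[(ranked["gene_id"].isin(eligible)) & (ranked["f1"] > f1_min)]
    panel = list(keep["gene_id"].head(top_n))
    for g in forced:
        if g not in panel:
            panel.append(g)
    return panel
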