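"""Synthetic expression cohorts with known ground truth.

Real Barrett's-esophagus cohorts of the kind this pipeline was designed
for (two-group designs of roughly 21 NDBE vs 40 LGD samples with an
optional 27-sample HGD group, or 135 non-progressed vs 65 progressed BE)
live behind controlled-access or multi-platform public accessions.  This
module generates cohorts of the same shape with *planted* discriminative
genes, so that every downstream stage — thresholding, candidate filters,
feature selection, the exhaustive classifier search — can be tested for
parameter recovery against a known truth.

Generative model (all on the log2 scale)::

    x[g, s] = mu_g + delta_g * m(s) + b(batch(s)) + eps,   eps ~ N(0, sigma^2)

where ``mu_g`` is a per-gene baseline drawn uniformly from
``baseline_range``; ``delta_g`` is ``±effect_size`` for the planted
discriminative genes (signs alternating, so both up- and down-regulated
biomarkers exist) and 0 otherwise; ``m(s)`` is 0 for negative samples, 1
for positive samples and 1.5 for the optional third (HGD-like) group —
a monotone progression that guarantees direction consistency; ``b`` is a
per-dataset additive batch offset.

This is a Gaussian log-scale model, not a count model: every in-scope
stage consumes normalized log-scale values, so count-level realism
(library sizes, dispersion, dropout) is deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .candidate_filter import DEResult
from .containers import (
    NEGATIVE,
    POSITIVE,
    THIRD,
    ExpressionMatrix,
    SampleAnnotation,
)
from .exceptions import ConfigError

THIRD_GROUP_MULTIPLIER = 1.5


@dataclass
class SyntheticConfig:
    """Parameters of one generated cohort.

    Defaults emulate the diagnostic cohort shape (21 negative vs 40
    positive samples); ``noise_sd`` is the log2-scale Gaussian noise SD
    and ``effect_size`` the log2 shift added to positive samples for
    planted genes, i.e. ``effect_size=1`` is a two-fold change.
    """

    n_neg: int = 21
    n_pos: int = 40
    n_third: int = 0
    n_genes: int = 500
    n_discriminative: int = 10
    effect_size: float = 2.0
    noise_sd: float = 1.0
    batch_offsets: Sequence[float] = ()
    batch_assignment: Mapping[str, int] | None = None
    baseline_range: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neg < 2 or self.n_pos < 2:
            raise ConfigError("need at least 2 samples per class")
        if self.n_third < 0:
            raise ConfigError("n_third must be >= 0")
        if not 0 <= self.n_discriminative <= self.n_genes:
            raise ConfigError("n_discriminative must lie in [0, n_genes]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.baseline_range[0] > self.baseline_range[1]:
            raise ConfigError("baseline_range must be (low, high) with low <= high")


@dataclass
class SyntheticTruth:
    """The planted ground truth a generated cohort encodes."""

    discriminative_genes: set[str]
    effects: dict[str, float]  # gene -> signed log2 shift; 0 for background
    batch_offsets: dict[str, float] = field(default_factory=dict)  # sample -> offset


def _sample_ids(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    ids, labels = [], []
    for i in range(cfg.n_neg):
        ids.append(f"N{i + 1:03d}")
        labels.append(NEGATIVE)
    for i in range(cfg.n_pos):
        ids.append(f"P{i + 1:03d}")
        labels.append(POSITIVE)
    for i in range(cfg.n_third):
        ids.append(f"T{i + 1:03d}")
        labels.append(THIRD)
    return ids, labels


def _batch_of(cfg: SyntheticConfig, sample_ids: list[str]) -> list[int]:
    n_batches = max(1, len(cfg.batch_offsets))
    if cfg.batch_assignment is not None:
        missing = [s for s in sample_ids if s not in cfg.batch_assignment]
        if missing:
            raise ConfigError(f"batch_assignment lacks samples {missing}")
        batches = [int(cfg.batch_assignment[s]) for s in sample_ids]
        if any(not 0 <= b < n_batches for b in batches):
            raise ConfigError("batch indices out of range for batch_offsets")
        return batches
    # round-robin keeps batches balanced within each contiguous class block
    return [i % n_batches for i in range(len(sample_ids))]


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """Generate one cohort; bit-reproducible for a given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)

    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    sample_ids, labels = _sample_ids(cfg)
    batches = _batch_of(cfg, sample_ids)
    offsets = list(cfg.batch_offsets) if cfg.batch_offsets else [0.0]

    mu = rng.uniform(*cfg.baseline_range, size=cfg.n_genes)
    disc_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_discriminative, replace=False))
    delta = np.zeros(cfg.n_genes)
    signs = np.where(np.arange(cfg.n_discriminative) % 2 == 0, 1.0, -1.0)
    delta[disc_idx] = signs * cfg.effect_size

    mult = np.array(
        [
            0.0 if l == NEGATIVE else 1.0 if l == POSITIVE else THIRD_GROUP_MULTIPLIER
            for l in labels
        ]
    )
    batch_shift = np.array([offsets[b] for b in batches])
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(sample_ids)))
    values = mu[:, None] + delta[:, None] * mult[None, :] + batch_shift[None, :] + noise

    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    ann = SampleAnnotation(
        pd.DataFrame({"label": labels, "batch": batches}, index=sample_ids)
    )
    truth = SyntheticTruth(
        discriminative_genes={gene_ids[i] for i in disc_idx},
        effects={g: float(d) for g, d in zip(gene_ids, delta)},
        batch_offsets={s: float(offsets[b]) for s, b in zip(sample_ids, batches)},
    )
    return matrix, ann, truth


def _de_contrast(
    name: str, matrix: ExpressionMatrix, pos_samples: list[str], neg_samples: list[str]
) -> DEResult:
    """Empirical logFC + Welch t-test + BH FDR for one contrast."""
    xp = matrix.df[pos_samples].to_numpy()
    xn = matrix.df[neg_samples].to_numpy()
    logfc = xp.mean(axis=1) - xn.mean(axis=1)
    res = stats.ttest_ind(xp, xn, axis=1, equal_var=False)
    p = np.nan_to_num(res.pvalue, nan=1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    fdr = stats.false_discovery_control(p, method="bh")
    table = pd.DataFrame(
        {"logFC": logfc, "p": p, "fdr": fdr}, index=matrix.gene_ids
    )
    return DEResult(name=name, table=table)


def generate_de_tables(
    cfg: SyntheticConfig,
    truth: SyntheticTruth | None = None,
    matrix: ExpressionMatrix | None = None,
    ann: SampleAnnotation | None = None,
) -> tuple[DEResult, DEResult | None, list[DEResult]]:
    """DE summary tables for the generated cohort.

    Returns the primary positive-vs-negative contrast, the third-group
    contrast (``None`` when the cohort has no third group), and one
    per-dataset (batch) positive-vs-negative table for every batch that
    contains both classes.  When no matrix is supplied the cohort is
    regenerated deterministically from ``cfg``.
    """
    if matrix is None or ann is None:
        matrix, ann, _ = generate_cohort(cfg)

    by_label: dict[str, list[str]] = {NEGATIVE: [], POSITIVE: [], THIRD: []}
    for s in matrix.sample_ids:
        by_label[ann.label_of(s)].append(s)

    primary = _de_contrast("positive_vs_negative", matrix, by_label[POSITIVE], by_label[NEGATIVE])
    third = None
    if by_label[THIRD]:
        third = _de_contrast("third_vs_negative", matrix, by_label[THIRD], by_label[NEGATIVE])

    per_dataset: list[DEResult] = []
    batches = sorted(set(ann.df["batch"]))
    if len(batches) > 1:
        for b in batches:
            in_b = set(ann.df.index[ann.df["batch"] == b])
            pos = [s for s in by_label[POSITIVE] if s in in_b]
            neg = [s for s in by_label[NEGATIVE] if s in in_b]
            if len(pos) >= 2 and len(neg) >= 2:
                per_dataset.append(
                    _de_contrast(f"positive_vs_negative_batch{b}", matrix, pos, neg)
                )
    return primary, third, per_dataset
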