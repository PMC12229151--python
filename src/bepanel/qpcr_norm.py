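"""RT-qPCR Cq normalization against a reference-gene geometric mean.

A target gene's quantification cycle (Cq) is normalized by subtracting
the geometric mean of the reference genes' Cq values measured in the
same sample (the multi-reference generalization of the delta-Cq method).
Technical replicates are first averaged arithmetically per (sample,
gene).  Note the sign convention: a *lower* normalized value means
*higher* expression — downstream plots of "expression level" must negate.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError

LONG_COLUMNS = ("sample_id", "gene_id", "replicate", "cq")


def normalize_cq(target_cq: float, reference_cqs: Sequence[float]) -> float:
    """``target_cq - geometric_mean(reference_cqs)``.

    All Cq values must be positive (cycles); at least one reference is
    required.
    """
    refs = np.asarray(reference_cqs, dtype=float)
    if refs.size == 0:
        raise DataError("need at least one reference Cq")
    if target_cq <= 0 or (refs <= 0).any():
        raise DataError("Cq values must be positive")
    return float(target_cq - np.exp(np.mean(np.log(refs))))


def normalize_table(
    long: pd.DataFrame, reference_genes: Iterable[str]
) -> pd.DataFrame:
    """Normalize a long-format Cq table to a wide delta-Cq table.

    ``long`` has columns (sample_id, gene_id, replicate, cq).  Replicates
    are averaged per (sample, gene); then, per sample, the geometric mean
    of the reference genes' mean Cq is subtracted from every target
    gene's mean Cq.  Returns samples × target genes; reference genes are
    not reported as targets.
    """
    missing = [c for c in LONG_COLUMNS if c not in long.columns]
    if missing:
        raise DataError(f"long-format table lacks columns {missing}")
    refs = sorted(set(reference_genes))
    if not refs:
        raise DataError("need at least one reference gene")
    if (long["cq"] <= 0).any():
        bad = long.loc[long["cq"] <= 0].iloc[0]
        raise DataError(
            f"nonpositive Cq for sample {bad['sample_id']!r}, gene {bad['gene_id']!r}"
        )

    mean_cq = long.groupby(["sample_id", "gene_id"])["cq"].mean().unstack("gene_id")
    absent = [g for g in refs if g not in mean_cq.columns]
    if absent:
        raise DataError(f"reference genes missing from data: {absent}")
    if mean_cq[refs].isna().any().any():
        bad = mean_cq[refs].isna().any(axis=1)
        raise DataError(
            f"samples lacking reference measurements: {sorted(mean_cq.index[bad])}"
        )
    geo = np.exp(np.log(mean_cq[refs]).mean(axis=1))
    targets = [g for g in mean_cq.columns if g not in refs]
    out = mean_cq[targets].sub(geo, axis=0)
    out.index.name = "sample_id"
    return out
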