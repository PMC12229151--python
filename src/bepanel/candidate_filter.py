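"""Direction-consistency filters over differential-expression summaries.

The diagnostic candidate list is assembled from DE summary tables (logFC,
p, FDR per gene and contrast) through three paths that all demand a
consistent direction of change along the metaplasia → dysplasia axis:

* path A — significant in the primary (LGD vs NDBE) contrast at
  |logFC| ≥ 1 and FDR < 0.05, with the same sign and FDR < 0.05 in the
  secondary (HGD vs NDBE) contrast;
* path B — the converse: |logFC| ≥ 2 and FDR < 0.05 in HGD vs NDBE with
  the same sign and p < 0.05 in LGD vs NDBE;
* path C — per-dataset analyses: |logFC| > 1 and FDR < 0.05 in *both*
  datasets with matching sign, also matching the reference contrast.

The union of the three paths plus a small forced set (canonically TP53
and CDH1, included for their established role in Barrett's biology)
forms the candidate panel.  This module consumes DE tables; producing
them from raw counts is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .exceptions import DataError

logger = logging.getLogger(__name__)

DE_COLUMNS = ("logFC", "p", "fdr")


@dataclass
class DEResult:
    """One contrast's per-gene differential-expression summary."""

    name: str
    table: pd.DataFrame  # index: gene IDs; columns: logFC, p, fdr

    def __post_init__(self) -> None:
        missing = [c for c in DE_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"DE table {self.name!r} lacks columns {missing}")
        if self.table.index.has_duplicates:
            dups = sorted(set(self.table.index[self.table.index.duplicated()]))
            raise DataError(f"DE table {self.name!r} has duplicate genes {dups}")
        if (self.table["fdr"] < 0).any():
            raise DataError(f"DE table {self.name!r} has negative FDR values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def row(self, gene: str) -> pd.Series:
        return self.table.loc[gene]


def _common_genes(genes: Iterable[str], *tables: DEResult) -> list[str]:
    """Genes present in every table; absentees are logged and dropped."""
    kept = []
    for g in genes:
        absent = [t.name for t in tables if g not in t.table.index]
        if absent:
            logger.warning("gene %s missing from DE table(s) %s; excluded", g, absent)
        else:
            kept.append(g)
    return kept


def consistent_de_filter(
    primary: DEResult,
    secondary: DEResult,
    lfc_min: float = 1.0,
    primary_fdr_max: float = 0.05,
    secondary_mode: str = "fdr",
    secondary_alpha: float = 0.05,
) -> set[str]:
    """Two-contrast direction-consistency filter (paths A and B).

    A gene passes iff |primary.logFC| >= ``lfc_min``, primary FDR <
    ``primary_fdr_max``, the secondary logFC has the same sign, and the
    secondary contrast is significant at ``secondary_alpha`` on the
    chosen column (``fdr`` or ``pvalue``).
    """
    if secondary_mode not in ("fdr", "pvalue"):
        raise DataError(f"secondary_mode must be 'fdr' or 'pvalue', got {secondary_mode!r}")
    sec_col = "fdr" if secondary_mode == "fdr" else "p"

    out: set[str] = set()
    for g in _common_genes(primary.gene_ids, secondary):
        prow, srow = primary.row(g), secondary.row(g)
        if (
            abs(prow["logFC"]) >= lfc_min
            and prow["fdr"] < primary_fdr_max
            and np.sign(srow["logFC"]) == np.sign(prow["logFC"])
            and srow[sec_col] < secondary_alpha
        ):
            out.add(g)
    return out


def two_dataset_consistency(
    de_a: DEResult,
    de_b: DEResult,
    reference: DEResult,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> set[str]:
    """Path C: per-dataset replication with a reference-contrast sign check.

    A gene passes iff it clears |logFC| > ``lfc_min`` and FDR <
    ``fdr_max`` in *both* per-dataset tables with matching sign, and that
    sign also matches the reference contrast.
    """
    out: set[str] = set()
    for g in _common_genes(de_a.gene_ids, de_b, reference):
        ra, rb, rr = de_a.row(g), de_b.row(g), reference.row(g)
        sign = np.sign(ra["logFC"])
        if (
            abs(ra["logFC"]) > lfc_min
            and ra["fdr"] < fdr_max
            and abs(rb["logFC"]) > lfc_min
            and rb["fdr"] < fdr_max
            and np.sign(rb["logFC"]) == sign
            and np.sign(rr["logFC"]) == sign
        ):
            out.add(g)
    return out


def assemble_candidates(
    path_a: Iterable[str],
    path_b: Iterable[str],
    path_c: Iterable[str] = (),
    forced: Iterable[str] = (),
) -> list[str]:
    """Deduplicated union of the filter paths plus forced genes.

    Ordering is deterministic: path A, then B, then C, then forced, each
    internally lexicographic; a gene appears once, at its first position.
    """
    out: list[str] = []
    seen: set[str] = set()
    for group in (path_a, path_b, path_c, forced):
        for g in sorted(group):
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out


def expression_filter(
    matrix: ExpressionMatrix, genes: Iterable[str], min_level: float = 1.0
) -> set[str]:
    """Keep genes whose across-sample mean expression exceeds ``min_level``.

    The mean is used to summarize "expressed above the floor"; strictly
    greater-than is applied.
    """
    genes = list(genes)
    unknown = [g for g in genes if g not in matrix.df.index]
    if unknown:
        raise DataError(f"genes absent from matrix: {unknown}")
    means = matrix.df.loc[genes].mean(axis=1)
    return set(means.index[means > min_level])
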