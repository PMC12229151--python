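"""In-memory containers shared across the pipeline.

An :class:`ExpressionMatrix` is a genes × samples table of normalized
log2-scale expression (log-CPM for RNA-seq, normalized intensity for
microarray).  A :class:`SampleAnnotation` maps sample IDs to a binary
class label (``negative`` = non-dysplastic / non-progressed, ``positive``
= dysplastic / progressed, plus an optional ``third`` high-grade group)
and an optional batch / dataset ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

NEGATIVE = "negative"
POSITIVE = "positive"
THIRD = "third"
LABELS = (NEGATIVE, POSITIVE, THIRD)


@dataclass
class ExpressionMatrix:
    """Genes × samples real-valued expression table on a log2 scale."""

    df: pd.DataFrame  # index: gene IDs, columns: sample IDs

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dups = sorted(set(self.df.index[self.df.index.duplicated()]))
            raise DataError(f"duplicate gene IDs: {dups}")
        if self.df.columns.has_duplicates:
            dups = sorted(set(self.df.columns[self.df.columns.duplicated()]))
            raise DataError(f"duplicate sample IDs: {dups}")
        values = self.df.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                "non-finite expression value at gene "
                f"{self.df.index[bad[0]]!r}, sample {self.df.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_genes(self) -> int:
        return self.df.shape[0]

    @property
    def n_samples(self) -> int:
        return self.df.shape[1]

    def gene_values(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.df.index:
            raise DataError(f"unknown gene {gene_id!r}")
        return self.df.loc[gene_id].to_numpy(dtype=float)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.df.index]
        if missing:
            raise DataError(f"unknown genes: {missing}")
        return ExpressionMatrix(self.df.loc[list(genes)])


@dataclass
class SampleAnnotation:
    """Sample → (class label, batch) mapping."""

    df: pd.DataFrame = field()  # index: sample IDs; columns: label, batch

    def __post_init__(self) -> None:
        if "label" not in self.df.columns:
            raise DataError("annotation needs a 'label' column")
        if "batch" not in self.df.columns:
            self.df = self.df.assign(batch=0)
        bad = sorted(set(self.df["label"]) - set(LABELS))
        if bad:
            raise DataError(f"unknown class labels {bad}; expected one of {LABELS}")
        if self.df.index.has_duplicates:
            raise DataError("duplicate sample IDs in annotation")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def label_of(self, sample_id: str) -> str:
        return str(self.df.loc[sample_id, "label"])

    def binary_labels(self, sample_ids) -> np.ndarray:
        """0/1 vector (positive class = 1) for a two-group operation.

        Samples must be annotated and belong to the negative/positive
        groups; the optional third group is excluded upstream.
        """
        missing = [s for s in sample_ids if s not in self.df.index]
        if missing:
            raise DataError(f"unannotated samples: {missing}")
        labels = self.df.loc[list(sample_ids), "label"]
        extra = sorted(set(labels) - {NEGATIVE, POSITIVE})
        if extra:
            raise DataError(
                f"two-group operation got labels {extra}; subset samples first"
            )
        y = (labels == POSITIVE).to_numpy(dtype=int)
        if y.min(initial=1) == y.max(initial=0):
            raise DataError("need two classes")
        return y

    def samples_with_labels(self, wanted=(NEGATIVE, POSITIVE)) -> list[str]:
        mask = self.df["label"].isin(wanted)
        return list(self.df.index[mask])


def two_group_view(
    matrix: ExpressionMatrix, ann: SampleAnnotation
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Restrict a matrix to negative/positive samples and return (matrix, y)."""
    keep = [s for s in matrix.sample_ids if ann.label_of(s) != THIRD]
    sub = ExpressionMatrix(matrix.df[keep])
    y = ann.binary_labels(keep)
    return sub, y
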