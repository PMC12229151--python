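"""File formats, run configuration and manifests.

Everything on disk is delimited text with dot decimals.  Writers emit
newline-terminated TSV; readers accept tab- or comma-delimited files
(delimiter detected from the header line) but never comma decimals.
Expression matrices are stored genes-as-rows: first column gene IDs,
header row of sample IDs.  DE tables carry their contrast name in a
``# contrast=<name>`` metadata line.  Every pipeline run can emit a
manifest (parameters, seed, input digests, package version) from which
the run is reproducible; manifests are timestamp-free so identical runs
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

from .candidate_filter import DEResult
from .containers import ExpressionMatrix, SampleAnnotation
from .exceptions import ConfigError, DataError


def _detect_sep(path: Path) -> str:
    with path.open() as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise DataError(f"{path}: empty file")


def read_expression(path) -> ExpressionMatrix:
    """Read a genes × samples matrix from TSV/CSV.

    Duplicate gene IDs, ragged rows and non-numeric cells are rejected
    with coordinates in the message.
    """
    path = Path(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except pd.errors.ParserError as e:  # ragged rows etc.
        raise DataError(f"{path}: malformed table ({e})") from e
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise DataError(f"{path}: duplicate gene IDs {dups}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise DataError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        if df[col].isna().any():
            gene = df.index[df[col].isna()][0]
            raise DataError(f"{path}: missing value at gene {gene!r}, sample {col!r}")
    return ExpressionMatrix(df.astype(float))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.df.rename_axis("gene_id").to_csv(path, sep="\t")


def read_annotation(path) -> SampleAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0, comment="#")
    df.index = df.index.astype(str)
    return SampleAnnotation(df)


def write_annotation(ann: SampleAnnotation, path) -> None:
    ann.df.rename_axis("sample_id").to_csv(path, sep="\t")


def read_de_table(path) -> DEResult:
    path = Path(path)
    name = path.stem
    for line in path.read_text().splitlines():
        if line.startswith("# contrast="):
            name = line.split("=", 1)[1].strip()
            break
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0, comment="#")
    df.index = df.index.astype(str)
    return DEResult(name=name, table=df)


def write_de_table(de: DEResult, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# contrast={de.name}\n")
        de.table.rename_axis("gene_id").to_csv(fh, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Generic TSV writer for ranked tables, leaderboards, curves."""
    df.to_csv(path, sep="\t", index=index)


@dataclass
class RunConfig:
    """Stage parameters with the pipeline's canonical defaults."""

    seed: int = 0
    lfc_min_primary: float = 1.0
    lfc_min_secondary: float = 2.0
    fdr_max: float = 0.05
    secondary_alpha: float = 0.05
    expression_min_level: float = 1.0
    f1_min_diagnostic: float = 0.7
    f1_min_prognostic: float = 0.67
    f1_min_consensus: float = 0.96
    correlation_max: float = 0.9
    frequency_cutoff: float = 0.5
    n_runs: int = 100
    min_votes: int = 2
    top_n_diagnostic: int = 16
    top_n_prognostic: int = 13
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"{path}: unknown configuration keys {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_path, parameters: dict, input_paths=()) -> None:
    """Record parameters, seed and input digests for reproducibility."""
    from . import __version__

    manifest = {
        "bepanel_version": __version__,
        "parameters": parameters,
        "inputs": {str(p): _digest(Path(p)) for p in input_paths},
    }
    Path(out_path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
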