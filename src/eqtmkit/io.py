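"""On-disk dataset formats and lossless round-trip read/write.

Matrices are plain TSV (first column row id, header = sample ids); the
sample table is CSV; CpG annotation and gene models are TSV; the planted
truth registry is JSON.  Reading validates value ranges (β in [0, 1],
counts non-negative integers) and raises named parse errors pointing at the
offending row and column.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .methylation import CELL_TYPES, FEATURES
from .simulate import Cohort, SyntheticTruth

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly

FILES = {
    "beta": "beta.tsv",
    "counts": "counts.tsv",
    "samples": "samples.csv",
    "cpg_annotation": "cpg_annotation.tsv",
    "gene_models": "gene_models.tsv",
    "truth": "truth.json",
}


class DatasetFormatError(ValueError):
    """A dataset file failed validation."""


def _check_unique(index: pd.Index, what: str, path: Path) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][:3].tolist()
        raise DatasetFormatError(f"{path}: duplicate {what} ids {dup}")


def read_beta(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index.name = "cpg_id"
    _check_unique(df.index, "CpG", path)
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or np.isnan(vals).any():
        raise DatasetFormatError(f"{path}: non-numeric or missing β values")
    bad = np.argwhere((vals < 0) | (vals > 1))
    if len(bad):
        i, j = bad[0]
        raise DatasetFormatError(
            f"{path}: β value {vals[i, j]} out of [0, 1] at row "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    return df


def read_counts(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    # tolerate featureCounts-style headers: six annotation columns before samples
    fc_cols = {"Chr", "Start", "End", "Strand", "Length"}
    if fc_cols <= set(df.columns[:5]):
        df = df.drop(columns=list(df.columns[:5]))
    df.index.name = "gene_id"
    _check_unique(df.index, "gene", path)
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise DatasetFormatError(f"{path}: non-numeric counts")
    bad = np.argwhere(vals < 0)
    if len(bad):
        i, j = bad[0]
        raise DatasetFormatError(
            f"{path}: negative count at row {df.index[i]!r}, column "
            f"{df.columns[j]!r}"
        )
    if not np.array_equal(vals, np.floor(vals)):
        raise DatasetFormatError(f"{path}: non-integer counts")
    return df.astype(np.int64)


def read_samples(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index.name = "sample_id"
    _check_unique(df.index, "sample", path)
    required = {"group", "age", "sex"} | {f"cf_{ct}" for ct in CELL_TYPES}
    missing = required - set(df.columns)
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {sorted(missing)}")
    if not set(df["group"]) <= {"case", "control"}:
        raise DatasetFormatError(f"{path}: group must be case/control")
    frac = df[[f"cf_{ct}" for ct in CELL_TYPES]].to_numpy()
    if np.abs(frac.sum(axis=1) - 1.0).max() > 1e-6:
        raise DatasetFormatError(f"{path}: cell fractions do not sum to 1")
    return df


def read_cpg_annotation(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    df.index.name = "cpg_id"
    _check_unique(df.index, "CpG", path)
    bad = set(df["feature"]) - set(FEATURES)
    if bad:
        raise DatasetFormatError(f"{path}: unknown features {sorted(bad)}")
    return df


def read_gene_models(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    _check_unique(df.index, "gene", path)
    required = {"chrom", "start", "end", "strand", "tss",
                "first_exon_start", "first_exon_end"}
    missing = required - set(df.columns)
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_dataset(cohort: Cohort, directory) -> dict:
    """Write all cohort tables; returns a manifest with SHA-256 checksums."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.beta.to_csv(directory / FILES["beta"], sep="\t", float_format=_FLOAT_FMT)
    cohort.counts.to_csv(directory / FILES["counts"], sep="\t")
    cohort.samples.to_csv(directory / FILES["samples"], float_format=_FLOAT_FMT)
    cohort.cpg_annotation.to_csv(directory / FILES["cpg_annotation"], sep="\t")
    cohort.gene_models.to_csv(directory / FILES["gene_models"], sep="\t")
    (directory / FILES["truth"]).write_text(
        json.dumps(cohort.truth.to_dict(), indent=1)
    )
    manifest = {
        name: {
            "file": fname,
            "sha256": hashlib.sha256((directory / fname).read_bytes()).hexdigest(),
        }
        for name, fname in FILES.items()
    }
    (directory / "dataset_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_dataset(directory) -> Cohort:
    """Read a cohort written by :func:`write_dataset` (lossless round trip)."""
    directory = Path(directory)
    for fname in FILES.values():
        if not (directory / fname).exists():
            raise FileNotFoundError(f"missing dataset file: {directory / fname}")
    truth = SyntheticTruth.from_dict(
        json.loads((directory / FILES["truth"]).read_text())
    )
    return Cohort(
        beta=read_beta(directory / FILES["beta"]),
        counts=read_counts(directory / FILES["counts"]),
        samples=read_samples(directory / FILES["samples"]),
        cpg_annotation=read_cpg_annotation(directory / FILES["cpg_annotation"]),
        gene_models=read_gene_models(directory / FILES["gene_models"]),
        truth=truth,
    )
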