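"""Reading and writing the package's file formats.

Matrices travel as TSV (genomics convention) with a header row of sample
ids and a first column of feature ids; gzip is handled transparently by
file extension.  Missing values are a hard error — the tensor methods
require complete data and no imputation is performed.  Annotations come as
TSV (feature_id, chromosome) or BED (0-based half-open; coordinates are
carried as metadata only), category sets as one-id-per-line text files.
All numeric output uses 17 significant digits so written values round-trip
exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import FeatureAnnotation
from .tensor_core import OmicsTensor

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "assemble_tensor",
    "read_annotation",
    "read_id_set",
    "read_config",
    "write_config",
]

FLOAT_FMT = "%.17g"


class DataError(ValueError):
    """A problem with the content of an input file."""


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV matrix (header = sample ids, first
    column = feature ids).  Duplicate feature ids, missing values and
    non-numeric cells are errors that name the offending row/column."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: cannot parse TSV: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise DataError(f"{path}: duplicate feature ids: {dups}")
    if df.columns.has_duplicates:
        raise DataError(f"{path}: duplicate sample ids in header")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        cell = df.iat[r, c]
        what = "missing value" if (pd.isna(cell) or cell in ("NA", "")) else f"non-numeric cell {cell!r}"
        raise DataError(
            f"{path}: {what} at feature {df.index[r]!r} (line {r + 2}), "
            f"sample {df.columns[c]!r}"
        )
    numeric.index.name = df.index.name or "feature_id"
    return numeric


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), sep="\t", float_format=FLOAT_FMT)


def assemble_tensor(
    matrices: dict[str, pd.DataFrame], strict_order: bool = False
) -> OmicsTensor:
    """Stack per-data-type matrices (features x samples) into an order-3
    tensor (type x sample x feature).

    All matrices must share the same feature-id and sample-id sets; rows
    and columns are reordered to the first matrix's order unless
    ``strict_order``, in which case orderings must already be identical.
    """
    if len(matrices) < 2:
        raise DataError("assemble_tensor needs at least two data-type matrices")
    names = list(matrices)
    first = matrices[names[0]]
    feat = list(first.index)
    samp = list(first.columns)
    aligned = []
    for name in names:
        df = matrices[name]
        if set(df.index) != set(feat):
            offenders = sorted(set(df.index) ^ set(feat))[:10]
            raise DataError(
                f"feature ids of {name!r} differ from {names[0]!r}; "
                f"first offenders: {offenders}"
            )
        if set(df.columns) != set(samp):
            offenders = sorted(set(df.columns) ^ set(samp))[:10]
            raise DataError(
                f"sample ids of {name!r} differ from {names[0]!r}; "
                f"first offenders: {offenders}"
            )
        if strict_order:
            if list(df.index) != feat or list(df.columns) != samp:
                raise DataError(
                    f"{name!r}: id ordering differs and strict_order is set"
                )
            aligned.append(df)
        else:
            aligned.append(df.loc[feat, samp])
    values = np.stack([df.to_numpy(dtype=float).T for df in aligned], axis=0)
    return OmicsTensor(
        values, mode1_labels=names, mode2_labels=samp, feature_ids=feat
    )


def read_annotation(path: str | Path) -> FeatureAnnotation:
    """Read a feature annotation table.

    TSV: columns ``feature_id`` and optional ``chromosome`` (header
    required).  BED: ``chrom  start  end  feature_id`` without header,
    0-based half-open coordinates (kept as metadata, unused by statistics).
    """
    path = Path(path)
    if path.suffix.lower() == ".bed" or path.name.endswith(".bed.gz"):
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "feature_id"],
            usecols=[0, 1, 2, 3],
            dtype={"chrom": str, "feature_id": str},
        )
        ids = df["feature_id"].tolist()
        chrom = dict(zip(df["feature_id"], df["chrom"]))
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "feature_id" not in df.columns:
            raise DataError(f"{path}: annotation TSV needs a 'feature_id' column")
        ids = df["feature_id"].tolist()
        chrom = (
            dict(zip(df["feature_id"], df["chromosome"]))
            if "chromosome" in df.columns
            else None
        )
    return FeatureAnnotation(feature_ids=ids, chromosome=chrom)


def read_id_set(path: str | Path) -> set[str]:
    """One feature id per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_config(path: str | Path, allowed: set[str] | None = None) -> dict[str, str]:
    """Flat ``key = value`` config file; '#' comments; unknown keys rejected
    when an allowed set is given."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for n, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise DataError(f"{path}:{n}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in out:
                raise DataError(f"{path}:{n}: duplicate key {key!r}")
            out[key] = value
    if allowed is not None:
        unknown = set(out) - allowed
        if unknown:
            raise DataError(f"{path}: unknown config keys: {sorted(unknown)}")
    return out


def write_config(cfg: dict, path: str | Path) -> None:
    """Emit the resolved configuration verbatim into the output directory."""
    with open(path, "w") as fh:
        for key, value in cfg.items():
            fh.write(f"{key} = {value}\n")


def write_truth_json(data, path: str | Path) -> None:
    """Serialise a SimulatedDataset's ground truth and config."""
    cfg = data.config
    payload = {
        "config": {
            "n_genes": cfg.n_genes,
            "n_samples": cfg.n_samples,
            "e": cfg.e,
            "sigma": cfg.sigma,
            "iv_genes": cfg.iv_genes,
            "iv_samples": cfg.iv_samples,
            "jv_samples": cfg.jv_samples,
            "jv_genes_per_type": cfg.jv_genes_per_type,
            "distribution": cfg.distribution,
            "seed": cfg.seed,
        },
        "snr": cfg.snr,
        "jv_genes": [sorted(int(i) for i in s) for s in data.jv_genes],
        "jv_samples": sorted(int(i) for i in data.jv_samples),
        "iv_genes": [sorted(int(i) for i in s) for s in data.iv_genes],
        "iv_samples": [sorted(int(i) for i in s) for s in data.iv_samples],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
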