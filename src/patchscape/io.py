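"""Reading and writing the pipeline's file formats.

All tables are delimited text with a header (CSV by default, separator
sniffed from the extension); phylogenies are Newick.  A column-name
*dialect* maps arbitrary input headers onto the canonical field names so the
pipeline is not married to any one file's schema.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import dendropy
import numpy as np
import pandas as pd

from .datatypes import (
    ERA_YEARS,
    DistanceMatrix,
    FormatError,
    OccupancyMatrix,
    PatchTable,
    Phylogeny,
    TraitTable,
    ValidationError,
)

__all__ = [
    "read_patch_table",
    "write_patch_table",
    "read_trait_table",
    "read_occupancy",
    "write_occupancy",
    "read_phylogeny",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_results",
]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _read_table(path, index_col=0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep(path), index_col=index_col)
    if df.index.name is None and df.shape[1] == 0:
        raise FormatError(f"{path} parsed to an empty table")
    return df


def read_patch_table(
    path, dialect: Optional[Mapping[str, str]] = None
) -> PatchTable:
    """Read a per-patch attribute table.

    Parameters
    ----------
    path
        Delimited text file; first column is the patch id.
    dialect
        Optional map from input column names to canonical names
        (``area_m2``, ``age_class``, ``TWI``, ``present_1843`` ...).  Columns
        not mentioned are passed through unchanged.
    """
    df = _read_table(path)
    if dialect:
        df = df.rename(columns=dict(dialect))
    if "area_m2" not in df.columns:
        raise FormatError(
            f"patch table {path} lacks required column 'area_m2' "
            f"(have: {list(df.columns)[:10]}); supply a dialect map"
        )
    bad = df.index[~(pd.to_numeric(df["area_m2"], errors="coerce") > 0)]
    if len(bad):
        raise ValidationError(
            f"rows with non-positive or unparseable area_m2: {list(bad)}"
        )
    for year in ERA_YEARS:
        col = f"present_{year}"
        if col in df.columns:
            df[col] = df[col].astype(int)
    return PatchTable(df)


def write_patch_table(table: PatchTable, path) -> None:
    table.df.to_csv(path, sep=_sep(path), index_label="patch_id")


def read_trait_table(values_path, metadata_path) -> TraitTable:
    """Read species × trait values plus the trait metadata table.

    The metadata declares, per trait, its ``block`` and ``scale`` and may
    carry ``lo`` / ``hi`` range bounds and a ``transform`` directive
    (``log`` or ``log10``) applied to the raw values on read (used e.g. for
    plant height, specific leaf area and seed mass).  Missing cells stay NaN.
    """
    values = _read_table(values_path)
    meta = _read_table(metadata_path)
    extra = set(values.columns) - set(meta.index)
    if extra:
        raise FormatError(
            f"traits missing from metadata {metadata_path}: {sorted(extra)}"
        )
    if "transform" in meta.columns:
        for trait, tf in meta["transform"].dropna().items():
            if trait not in values.columns:
                continue
            if tf == "log":
                values[trait] = np.log(values[trait])
            elif tf == "log10":
                values[trait] = np.log10(values[trait])
            elif tf not in ("", "none"):
                raise FormatError(f"unknown transform '{tf}' for trait '{trait}'")
    return TraitTable(values, meta)


def impute_genus_means(table: TraitTable, genus: pd.Series) -> TraitTable:
    """Fill missing continuous trait values with the genus mean.

    Off by default in the pipeline; applied only when a genus column is
    supplied.  Traits whose genus has no observed value stay missing.
    """
    values = table.values.copy()
    for trait in values.columns:
        if table.meta.loc[trait, "scale"] != "continuous":
            continue
        means = values[trait].groupby(genus.reindex(values.index)).transform("mean")
        values[trait] = values[trait].fillna(means)
    return TraitTable(values, table.meta)


def read_occupancy(path) -> OccupancyMatrix:
    """Read a patches × species 0/1 matrix (patches as rows)."""
    df = _read_table(path)
    arr = df.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        bad = df.columns[(~np.isin(arr, (0, 1))).any(axis=0)]
        raise ValidationError(f"non-binary occupancy entries in columns: {list(bad)}")
    return OccupancyMatrix(df)


def write_occupancy(occ: OccupancyMatrix, path) -> None:
    occ.df.to_csv(path, sep=_sep(path), index_label="patch_id")


def read_phylogeny(path) -> Phylogeny:
    """Read a rooted Newick tree whose tips are species ids."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"could not parse Newick file {path}: {exc}") from exc
    return Phylogeny(tree)


def read_distance_matrix(path) -> DistanceMatrix:
    df = _read_table(path)
    if list(df.index) != list(df.columns):
        raise FormatError("distance matrix rows and columns must match")
    mask = df.isna().to_numpy()
    return DistanceMatrix(list(df.index), df.fillna(0.0).to_numpy(), mask)


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    dist.to_frame().to_csv(path, sep=_sep(path))


def write_results(bundle: Mapping[str, pd.DataFrame], out_dir, manifest: dict = None) -> list:
    """Persist a dict of result tables as CSV plus a JSON run manifest.

    Returns the list of files written.  Numbers round-trip losslessly
    (``repr`` precision floats).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in bundle.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, float_format="%.17g")
        written.append(path)
    if manifest is not None:
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        written.append(path)
    return written
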