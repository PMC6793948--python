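"""Shared domain containers for the patch-network analysis pipeline.

Everything downstream (landscape metrics, diversity indices, inference)
speaks in terms of these light wrappers around :class:`pandas.DataFrame`,
:class:`numpy.ndarray` and :class:`dendropy.Tree`.  Each container validates
its invariants on construction, so code receiving one may assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ABIOTIC_VARS",
    "ERA_YEARS",
    "PatchTable",
    "TraitTable",
    "OccupancyMatrix",
    "Phylogeny",
    "DistanceMatrix",
    "DiversityProfile",
    "VarianceDecomposition",
]


class FormatError(ValueError):
    """A file or table does not have the expected structure."""


class ValidationError(ValueError):
    """Structurally well-formed data violates a domain invariant."""


#: Abiotic variables carried per patch: topographic wetness index
#: (dimensionless), slope (degrees), elevation above the main water course
#: (m) and potential direct solar irradiation in June.
ABIOTIC_VARS = ("TWI", "slope", "elevation", "PDSI_June")

#: Historical map years, oldest first.
ERA_YEARS = (1843, 1954, 1980)

#: Landscape metrics derived from geometry + era presence.
DERIVED_VARS = ("I_2000", "I_1843", "I_1980", "A_1843", "A_1980", "age")


def _check_unique(labels: Iterable, what: str) -> None:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if list(labels).count(x) > 1})
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class PatchTable:
    """Per-patch attributes: abiotic variables, geometry, era presence and
    derived landscape metrics.

    ``df`` is indexed by patch id.  Required columns: ``age_class`` (``old`` /
    ``new``) and ``area_m2``.  Optional: the abiotic variables, ``x``/``y``
    patch-centre coordinates (planar metres) with ``radius_m`` for disc
    geometry, ``present_<year>`` era flags (0/1) and the derived columns.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "patch_id")
        if "area_m2" not in self.df.columns:
            raise FormatError("patch table requires an 'area_m2' column")
        area = self.df["area_m2"]
        bad = self.df.index[~(area > 0) | area.isna()]
        if len(bad):
            raise ValidationError(
                f"area_m2 must be positive; offending patches: {list(bad)[:5]}"
            )
        if "age_class" in self.df.columns:
            extra = set(self.df["age_class"].dropna()) - {"old", "new"}
            if extra:
                raise ValidationError(f"unknown age_class values: {sorted(extra)}")
        for col in ("A_1843", "A_1980", "A_1954"):
            if col in self.df.columns:
                vals = self.df[col].dropna()
                if ((vals < 0) | (vals > 1)).any():
                    raise ValidationError(f"{col} must lie in [0, 1]")
        if "age" in self.df.columns:
            vals = self.df["age"].dropna()
            if (vals <= 0).any():
                raise ValidationError("age must be positive")

    @property
    def patch_ids(self) -> list:
        return list(self.df.index)

    def era_presence(self, patch_id) -> dict:
        """Era-year -> bool presence map for one patch."""
        row = self.df.loc[patch_id]
        return {
            year: bool(row[f"present_{year}"])
            for year in ERA_YEARS
            if f"present_{year}" in self.df.columns
        }

    def subset(self, age_class: str) -> "PatchTable":
        return PatchTable(self.df[self.df["age_class"] == age_class].copy())


@dataclass
class TraitTable:
    """Species × trait values plus per-trait metadata.

    ``values``: DataFrame indexed by species id, one column per trait; NaN
    marks a missing measurement (kept explicit, never silently imputed).
    ``meta``: DataFrame indexed by trait name with columns ``block``
    (``vegetative`` / ``phenology`` / ``seed`` / ``ecological``), ``scale``
    (``binary`` / ``ordinal`` / ``continuous``) and optional ``lo`` / ``hi``
    declared range bounds.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    VALID_BLOCKS = ("vegetative", "phenology", "seed", "ecological")
    VALID_SCALES = ("binary", "ordinal", "continuous")

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "species_id")
        missing_meta = set(self.values.columns) - set(self.meta.index)
        if missing_meta:
            raise FormatError(
                f"traits present in values but not in metadata: {sorted(missing_meta)}"
            )
        for col in ("block", "scale"):
            if col not in self.meta.columns:
                raise FormatError(f"trait metadata requires a '{col}' column")
        bad_block = set(self.meta["block"]) - set(self.VALID_BLOCKS)
        if bad_block:
            raise ValidationError(f"unknown trait blocks: {sorted(bad_block)}")
        bad_scale = set(self.meta["scale"]) - set(self.VALID_SCALES)
        if bad_scale:
            raise ValidationError(f"unknown trait scales: {sorted(bad_scale)}")
        for trait in self.values.columns:
            scale = self.meta.loc[trait, "scale"]
            vals = self.values[trait].dropna()
            if scale == "binary":
                if not vals.isin([0, 1]).all():
                    raise ValidationError(
                        f"binary trait '{trait}' has values outside {{0, 1}}"
                    )
            elif scale == "ordinal":
                if not np.allclose(vals, np.round(vals)):
                    raise ValidationError(f"ordinal trait '{trait}' has non-integers")
                lo = self.meta.loc[trait].get("lo", np.nan)
                hi = self.meta.loc[trait].get("hi", np.nan)
                if np.isfinite(lo) and (vals < lo).any():
                    raise ValidationError(f"ordinal trait '{trait}' below range {lo}")
                if np.isfinite(hi) and (vals > hi).any():
                    raise ValidationError(f"ordinal trait '{trait}' above range {hi}")

    @property
    def species_ids(self) -> list:
        return list(self.values.index)

    def traits_in_block(self, block: str) -> list:
        return [t for t in self.values.columns if self.meta.loc[t, "block"] == block]

    def restrict(self, traits: Sequence[str]) -> "TraitTable":
        return TraitTable(self.values[list(traits)], self.meta.loc[list(traits)])

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())


@dataclass
class OccupancyMatrix:
    """Binary patches × species presence/absence matrix."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "patch_id")
        _check_unique(self.df.columns, "species_id")
        arr = self.df.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("occupancy entries must be 0 or 1")
        self.df = self.df.astype(np.int8)

    @property
    def patch_ids(self) -> list:
        return list(self.df.index)

    @property
    def species_ids(self) -> list:
        return list(self.df.columns)

    def richness(self) -> pd.Series:
        """Species count per patch."""
        return self.df.sum(axis=1).astype(int)

    def community(self, patch_id) -> list:
        row = self.df.loc[patch_id]
        return list(row.index[row == 1])


@dataclass
class Phylogeny:
    """Rooted tree over the species pool, tips labelled by species id."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        _check_unique(labels, "tip label")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError("negative branch length in phylogeny")

    @property
    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def check_species(self, species: Iterable[str]) -> None:
        """Raise if any species is missing from the tips, naming the set."""
        missing = set(species) - set(self.tip_labels)
        if missing:
            raise ValidationError(
                f"species absent from phylogeny tips: {sorted(missing)}"
            )


@dataclass
class DistanceMatrix:
    """Symmetric species-pair dissimilarities with an explicit missing mask.

    ``mask[i, j]`` is True where the dissimilarity is undefined (e.g. a pair
    sharing no non-missing traits).  The diagonal is always zero/unmasked.
    """

    labels: list
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        _check_unique(self.labels, "distance label")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if self.mask is None:
            self.mask = np.zeros((n, n), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        vals = np.where(self.mask, 0.0, self.values)
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(vals < -1e-12):
            raise ValidationError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, species: Sequence) -> np.ndarray:
        lookup = {lab: i for i, lab in enumerate(self.labels)}
        missing = [s for s in species if s not in lookup]
        if missing:
            raise ValidationError(f"species absent from distance matrix: {missing}")
        return np.array([lookup[s] for s in species], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        return out.mask(pd.DataFrame(self.mask, index=self.labels, columns=self.labels))


@dataclass
class DiversityProfile:
    """Per-patch diversity summary: SD (richness), FD and PD (mean pairwise
    dissimilarity on functional and phylogenetic distances) and community
    means (CM) per trait."""

    df: pd.DataFrame  # columns: SD, FD, PD, CM_<trait>...

    def __post_init__(self) -> None:
        for col in ("SD",):
            if col not in self.df.columns:
                raise FormatError("diversity profile requires an 'SD' column")
        sd = self.df["SD"]
        if (sd < 0).any() or not np.allclose(sd, np.round(sd)):
            raise ValidationError("SD must be a non-negative integer count")

    @property
    def cm_columns(self) -> list:
        return [c for c in self.df.columns if c.startswith("CM_")]


@dataclass
class VarianceDecomposition:
    """Adjusted explained-variation fractions (%) of one response over the
    abiotic (abi), present-day (pre) and historical (his) predictor blocks.

    Seven fractions — three unique, three pairwise-shared, one shared by all
    — sum exactly to the total explained variation (TVE) of the full model.
    Adjusted fractions may legitimately be negative.
    """

    response: str
    family: str
    fractions: dict = field(default_factory=dict)
    tve: float = 0.0
    n: int = 0

    KEYS = (
        "unique_abi",
        "unique_pre",
        "unique_his",
        "shared_abi_pre",
        "shared_abi_his",
        "shared_pre_his",
        "shared_all",
    )

    def __post_init__(self) -> None:
        missing = set(self.KEYS) - set(self.fractions)
        if missing:
            raise ValidationError(f"missing partition fractions: {sorted(missing)}")
        total = sum(self.fractions[k] for k in self.KEYS)
        if abs(total - self.tve) > 1e-9:
            raise ValidationError(
                f"fractions sum to {total!r}, expected TVE {self.tve!r}"
            )

    def to_series(self) -> pd.Series:
        out = {k: self.fractions[k] for k in self.KEYS}
        out["TVE"] = self.tve
        return pd.Series(out, name=f"{self.response}")
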