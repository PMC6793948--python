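"""Taxonomic, functional and phylogenetic alpha-diversity of communities.

Three facets per patch:

* **SD** — species richness, the count of pool species present;
* **FD** — mean pairwise dissimilarity (MPD) on a mixed-type Gower distance
  combining three trait blocks (vegetative, phenology, seed), with the
  Podani (1999) rank-based extension for ordinal traits;
* **PD** — MPD on cophenetic (path-length) phylogenetic distances.

MPD averages the between-species dissimilarities over all unordered pairs
present in a community (diagonal excluded, presence/absence weighting), which
makes it largely insensitive to richness itself.  Community means (CM) are
unweighted averages of a trait over the species present.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import (
    DistanceMatrix,
    DiversityProfile,
    OccupancyMatrix,
    Phylogeny,
    TraitTable,
    ValidationError,
)

__all__ = [
    "gower_block_distance",
    "combine_blocks",
    "cophenetic_distance",
    "mpd",
    "mpd_all",
    "species_richness",
    "community_mean",
    "diversity_profile",
]


def _podani_pair_matrix(values: np.ndarray) -> np.ndarray:
    """Podani (1999) ordinal dissimilarity for one trait over all pairs.

    Values are ranked (average ranks over ties, computed on the non-missing
    species); for a pair with distinct values,

        d_ij = (|r_i - r_j| - (T_i - 1)/2 - (T_j - 1)/2)
               / (r_max - r_min - (T_max - 1)/2 - (T_min - 1)/2)

    with T_x the number of species tied at x's value and r_max/r_min the
    ranks of the extreme values.  Equal values give 0; the result lies in
    [0, 1].  Missing entries propagate NaN.
    """
    out = np.full((len(values), len(values)), np.nan)
    ok = ~np.isnan(values)
    vals = values[ok]
    if len(vals) == 0:
        return out
    ranks = rankdata(vals)
    uniq, counts = np.unique(vals, return_counts=True)
    tie = dict(zip(uniq, counts))
    t = np.array([tie[v] for v in vals], dtype=float)
    r_min, r_max = ranks.min(), ranks.max()
    t_min, t_max = tie[uniq[0]], tie[uniq[-1]]
    denom = r_max - r_min - (t_max - 1) / 2.0 - (t_min - 1) / 2.0
    if denom <= 0:  # single distinct value: no spread, trait contributes 0
        d = np.zeros((len(vals), len(vals)))
    else:
        d = (
            np.abs(ranks[:, None] - ranks[None, :])
            - (t[:, None] - 1) / 2.0
            - (t[None, :] - 1) / 2.0
        ) / denom
        d[vals[:, None] == vals[None, :]] = 0.0
    idx = np.where(ok)[0]
    out[np.ix_(idx, idx)] = d
    return out


def _trait_pair_matrix(values: np.ndarray, scale: str) -> np.ndarray:
    """Per-trait pairwise dissimilarity in [0, 1]; NaN where undefined."""
    if scale == "ordinal":
        return _podani_pair_matrix(values)
    diff = np.abs(values[:, None] - values[None, :])
    if scale == "binary":
        return (diff > 0).astype(float) + np.where(np.isnan(diff), np.nan, 0.0)
    # continuous: range-normalised
    ok = ~np.isnan(values)
    if ok.sum() == 0:
        return diff  # all NaN
    rng = np.nanmax(values) - np.nanmin(values)
    if rng == 0:
        warnings.warn("zero-range continuous trait contributes 0", stacklevel=3)
        return np.where(np.isnan(diff), np.nan, 0.0)
    return diff / rng


def gower_block_distance(traits: TraitTable) -> DistanceMatrix:
    """Gower mixed-type distance over the traits of one block.

    Per pair: the mean of per-trait dissimilarities (continuous range-
    normalised, binary 0/1 mismatch, ordinal Podani).  Traits missing for
    either member of a pair are dropped for that pair, the rest re-weighted
    equally; a pair sharing no non-missing trait is masked.
    """
    if traits.values.shape[1] == 0:
        raise ValidationError("block contains no traits")
    n = len(traits.values)
    stack = np.empty((traits.values.shape[1], n, n))
    for t, trait in enumerate(traits.values.columns):
        scale = traits.meta.loc[trait, "scale"]
        stack[t] = _trait_pair_matrix(
            traits.values[trait].to_numpy(dtype=float), scale
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    mask = np.isnan(stack).all(axis=0)
    mean = np.where(mask, 0.0, mean)
    np.fill_diagonal(mean, 0.0)
    np.fill_diagonal(mask, False)
    return DistanceMatrix(traits.species_ids, mean, mask)


def combine_blocks(blocks: Sequence[DistanceMatrix]) -> DistanceMatrix:
    """Unweighted mean of per-block distances, pairwise over available
    (unmasked) blocks; masked only where every block is masked."""
    if not blocks:
        raise ValidationError("no blocks to combine")
    labels = blocks[0].labels
    for b in blocks[1:]:
        if b.labels != labels:
            raise ValidationError("block distance matrices have different labels")
    vals = np.stack([np.where(b.mask, np.nan, b.values) for b in blocks])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=0)
    mask = np.isnan(vals).all(axis=0)
    mean = np.where(mask, 0.0, mean)
    return DistanceMatrix(labels, mean, mask)


def cophenetic_distance(tree: Phylogeny, normalize: bool = True) -> DistanceMatrix:
    """Pairwise path-length (cophenetic) distances between tree tips.

    With ``normalize`` the matrix is divided by its maximum so entries lie in
    [0, 1], giving PD on the same bounded scale as the Gower FD.
    """
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    if normalize:
        top = vals.max()
        if top > 0:
            vals = vals / top
    return DistanceMatrix(labels, vals)


def mpd(community: Sequence, dist: DistanceMatrix) -> float:
    """Mean pairwise dissimilarity among the species of one community.

    NaN (with a warning) for communities of fewer than two species, or when
    every relevant pair is masked.
    """
    idx = dist.index_of(list(community))
    if len(idx) < 2:
        warnings.warn("MPD undefined for communities of < 2 species", stacklevel=2)
        return float("nan")
    sub = dist.values[np.ix_(idx, idx)]
    submask = dist.mask[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    vals = sub[iu][~submask[iu]]
    if len(vals) == 0:
        return float("nan")
    return float(vals.mean())


def mpd_all(occ: OccupancyMatrix, dist: DistanceMatrix) -> pd.Series:
    """Vectorised MPD for every patch of an occupancy matrix."""
    idx = dist.index_of(occ.species_ids)
    d = np.where(dist.mask, 0.0, dist.values)[np.ix_(idx, idx)]
    avail = (~dist.mask[np.ix_(idx, idx)]).astype(float)
    np.fill_diagonal(avail, 0.0)
    occ_arr = occ.df.to_numpy(dtype=float)
    pair_sum = np.einsum("pi,ij,pj->p", occ_arr, d, occ_arr)
    pair_n = np.einsum("pi,ij,pj->p", occ_arr, avail, occ_arr)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = pair_sum / pair_n
    return pd.Series(out, index=occ.patch_ids)


def species_richness(occ: OccupancyMatrix) -> pd.Series:
    """SD per patch: the number of pool species present."""
    return occ.richness()


def community_mean(row: pd.Series, trait_values: pd.Series) -> float:
    """Unweighted mean trait value over the species present in one patch,
    skipping missing trait values; NaN (with a warning) if none usable."""
    present = row.index[row == 1]
    vals = trait_values.reindex(present).dropna()
    if len(vals) == 0:
        warnings.warn("community mean undefined: no usable trait values",
                      stacklevel=2)
        return float("nan")
    return float(vals.mean())


def diversity_profile(
    occ: OccupancyMatrix,
    fdist: Optional[DistanceMatrix] = None,
    pdist: Optional[DistanceMatrix] = None,
    traits: Optional[TraitTable] = None,
) -> DiversityProfile:
    """Per-patch SD, FD, PD and community means in one table.

    FD and PD are NaN for patches with fewer than two species.
    """
    out = pd.DataFrame({"SD": species_richness(occ)})
    few = out["SD"] < 2
    if fdist is not None:
        out["FD"] = mpd_all(occ, fdist)
        out.loc[few, "FD"] = np.nan
    if pdist is not None:
        out["PD"] = mpd_all(occ, pdist)
        out.loc[few, "PD"] = np.nan
    if traits is not None:
        occ_arr = occ.df.to_numpy(dtype=float)
        tv = traits.values.reindex(occ.species_ids)
        for trait in tv.columns:
            vals = tv[trait].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            weights = occ_arr[:, ok]
            counts = weights.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cm = weights @ vals[ok] / counts
            out[f"CM_{trait}"] = cm
    return DiversityProfile(out)
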