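"""Seeded synthetic patch-network studies with known assembly drivers.

The generator emulates the structure of a fragmented dry-grassland survey:
272 patches (about 216 persisting since before the newest historical map —
"old" — and 56 recent "new" patches) scattered over an 8 × 8 km extent, a
pool of 99 species carrying 12 traits in three blocks (vegetative,
phenology, seed) plus three ordinal ecological-preference indicators, a
pure-birth phylogeny, and a presence/absence occupancy matrix produced by a
logistic patch-occupancy model:

    P(s present in j) = logistic(b0 + b_env * match(s, j) + b_abi * suit_j
                                 + b_area * logA_j + b_iso * I_j
                                 + b_age * age_j + b_tx * trait_s * env_j)

``match`` is a Gaussian niche kernel between a species' latent environmental
optimum (evolved on the tree, so it carries phylogenetic signal) and the
patch's abiotic value.  Every ingredient is a pure function of
``(SimConfig, seed)``; the true coefficients are recorded so downstream
inference can be validated against them.

Landscape-history metrics (isolation, historical area fractions, age) are
*not* simulated: they are computed from the generated geometries and era
flags by :mod:`patchscape.landscape`, the same code path real data takes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from . import io as ps_io
from .datatypes import (
    OccupancyMatrix,
    PatchTable,
    Phylogeny,
    TraitTable,
    ValidationError,
)
from .landscape import HabitatSnapshot, derive_landscape_metrics

__all__ = [
    "OccupancyBetas",
    "SimConfig",
    "SyntheticStudy",
    "generate_landscape",
    "generate_species_pool",
    "simulate_occupancy",
    "generate_study",
]


@dataclass
class OccupancyBetas:
    """Coefficients of the logistic occupancy model (on standardised
    predictors, so magnitudes are comparable across drivers)."""

    b0: float = -1.1  # baseline: mean occupancy ~0.3 of the pool
    b_env: float = 0.9  # abiotic niche matching (environmental filtering)
    b_abi: float = 0.3  # direct abiotic suitability (slope) acting on all species
    b_area: float = 0.5  # present-day patch area (log10)
    b_iso: float = -0.35  # present-day isolation (dispersal limitation)
    b_age: float = 0.35  # patch age (colonisation credit)
    b_tx: float = 0.2  # trait × environment interaction


@dataclass
class SimConfig:
    """Generative conditions of a synthetic study."""

    n_patches: int = 272
    fraction_old: float = 216 / 272
    extent_m: float = 8000.0
    # log10 patch area, m^2 (moments of the surveyed old patches)
    log10_area_mean: float = 3.32
    log10_area_sd: float = 0.63
    # abiotic fields: per-variable (mean, sd); spatially autocorrelated
    abiotic_params: dict = field(
        default_factory=lambda: {
            "TWI": (8.3, 1.0),
            "slope": (12.0, 5.0),
            "elevation": (70.0, 34.0),
            "PDSI_June": (5540.0, 200.0),
        }
    )
    spatial_range_m: float = 800.0  # exponential-kernel correlation length
    nugget: float = 0.1
    # backward era persistence: P(on 1954 map | on 1980), P(on 1843 | on 1954)
    p_1954_given_1980: float = 0.7
    p_1843_given_1954: float = 0.6
    n_background_pgh: int = 150  # extra historical habitat units per map
    bg_presence: float = 0.6  # P a background unit appears on a given map
    survey_year: int = 2009
    pre_map_anchor: int = 1788
    # species pool
    n_species: int = 99
    bm_sigma: float = 1.0  # Brownian rate for trait evolution
    niche_sd: float = 1.0  # Gaussian niche kernel width (in abiotic SD units)
    betas: OccupancyBetas = field(default_factory=OccupancyBetas)
    min_richness: int = 3
    redraw_sparse: bool = False  # default: flag-and-keep patches below minimum

    def __post_init__(self):
        if self.n_patches < 10:
            raise ValidationError("n_patches must be >= 10")
        if self.n_species < 5:
            raise ValidationError("n_species must be >= 5")
        if not 0 <= self.fraction_old <= 1:
            raise ValidationError("fraction_old must lie in [0, 1]")
        if isinstance(self.betas, dict):
            self.betas = OccupancyBetas(**self.betas)


@dataclass
class SyntheticStudy:
    patches: PatchTable
    snapshots: dict
    traits: TraitTable
    phylogeny: Phylogeny
    occupancy: OccupancyMatrix
    truth: dict
    sparse_patches: list = field(default_factory=list)


def _gaussian_field(rng, coords: np.ndarray, n_vars: int, range_m: float,
                    nugget: float) -> np.ndarray:
    """Draw ``n_vars`` independent standardised fields with exponential
    spatial covariance exp(-d/range) over the given coordinates."""
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    cov = (1 - nugget) * np.exp(-d / range_m) + nugget * np.eye(len(coords))
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(coords)))
    return chol @ rng.standard_normal((len(coords), n_vars))


def generate_landscape(cfg: SimConfig, seed: int) -> tuple:
    """Patch table (with geometry, abiotic values and era flags) plus the
    era habitat snapshots, landscape metrics already derived."""
    rng = np.random.default_rng(seed)
    n, nb = cfg.n_patches, cfg.n_background_pgh
    coords = rng.uniform(0, cfg.extent_m, size=(n + nb, 2))
    z = _gaussian_field(rng, coords, len(cfg.abiotic_params),
                        cfg.spatial_range_m, cfg.nugget)
    abiotic = {}
    for k, (var, (mu, sd)) in enumerate(cfg.abiotic_params.items()):
        vals = mu + sd * z[:, k]
        if var == "slope":
            vals = np.clip(vals, 0.5, 89.0)
        abiotic[var] = vals

    log10_area = rng.normal(cfg.log10_area_mean, cfg.log10_area_sd, n + nb)
    area = 10.0**log10_area
    radius = np.sqrt(area / math.pi)

    # backward era persistence for the surveyed patches
    present_1980 = rng.random(n) < cfg.fraction_old
    present_1954 = present_1980 & (rng.random(n) < cfg.p_1954_given_1980)
    present_1843 = present_1954 & (rng.random(n) < cfg.p_1843_given_1954)

    ids = [f"P{i:03d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "age_class": np.where(present_1980, "old", "new"),
            "area_m2": area[:n],
            "x": coords[:n, 0],
            "y": coords[:n, 1],
            "radius_m": radius[:n],
            "present_1843": present_1843.astype(int),
            "present_1954": present_1954.astype(int),
            "present_1980": present_1980.astype(int),
        },
        index=pd.Index(ids, name="patch_id"),
    )
    for var in cfg.abiotic_params:
        df[var] = abiotic[var][:n]
    patches = PatchTable(df)

    # era snapshots: patch units present on that map + background PGH units
    bg_ids = [f"B{i:03d}" for i in range(nb)]
    bg = pd.DataFrame(
        {
            "x": coords[n:, 0],
            "y": coords[n:, 1],
            "radius_m": radius[n:],
            "area_m2": area[n:],
        },
        index=pd.Index(bg_ids, name="unit_id"),
    )
    for var in cfg.abiotic_params:
        bg[var] = abiotic[var][n:]
    bg_1980 = rng.random(nb) < cfg.bg_presence
    bg_1954 = rng.random(nb) < cfg.bg_presence
    bg_1843 = rng.random(nb) < cfg.bg_presence
    snapshots = {}
    for era, patch_flag, bg_flag in (
        (1843, present_1843, bg_1843),
        (1954, present_1954, bg_1954),
        (1980, present_1980, bg_1980),
    ):
        cols = ["x", "y", "radius_m", "area_m2", *cfg.abiotic_params]
        units = pd.concat([df.loc[patch_flag, cols], bg.loc[bg_flag, cols]])
        snapshots[era] = HabitatSnapshot(era, units)

    patches = derive_landscape_metrics(
        patches,
        snapshots,
        survey_year=cfg.survey_year,
        pre_map_anchor=cfg.pre_map_anchor,
        cell_m=max(1.0, float(np.max(radius)) / 40.0),
    )
    return patches, snapshots


def _pure_birth_newick(rng, n_tips: int, labels: list) -> str:
    """Yule tree: lineages split at exponential waiting times, the splitting
    lineage chosen uniformly; all tips extended to the present."""
    birth = [0.0, 0.0]
    children: dict = {}
    t = 0.0
    nodes = [0, 1]  # active lineage ids
    next_id = 2
    birth_time = {0: 0.0, 1: 0.0}
    while len(nodes) < n_tips:
        t += rng.exponential(1.0 / len(nodes))
        k = int(rng.integers(len(nodes)))
        parent = nodes[k]
        a, b = next_id, next_id + 1
        next_id += 2
        children[parent] = (a, b, t)
        birth_time[a] = birth_time[b] = t
        nodes[k] = a
        nodes.append(b)
    t_end = t + rng.exponential(1.0 / len(nodes))
    tip_label = dict(zip(nodes, labels))

    def render(node) -> str:
        if node in children:
            a, b, split = children[node]
            length = split - birth_time[node]
            return f"({render(a)},{render(b)}):{length:.8f}"
        length = t_end - birth_time[node]
        return f"{tip_label[node]}:{length:.8f}"

    return f"({render(0)},{render(1)});"


def _brownian_tips(rng, tree: dendropy.Tree, sigma: float) -> dict:
    """Brownian-motion tip values: independent Gaussian increments with
    variance sigma^2 * branch length along every edge."""
    value = {}
    for node in tree.preorder_node_iter():
        parent = value.get(node.parent_node, 0.0)
        length = node.edge.length or 0.0
        value[node] = parent + rng.normal(0.0, sigma * math.sqrt(max(length, 0.0)))
    return {
        leaf.taxon.label: value[leaf] for leaf in tree.leaf_node_iter()
    }


#: Trait layout mirroring a 12-trait / 3-block grassland pool plus three
#: ordinal ecological-preference indicators.
TRAIT_SPECS = [
    # name, block, scale, lo, hi
    ("CLON", "vegetative", "binary", 0, 1),
    ("PER", "vegetative", "binary", 0, 1),
    ("PHEI", "vegetative", "continuous", -1.12, 0.13),
    ("SLA", "vegetative", "continuous", 7.56, 39.35),
    ("BFLOW", "phenology", "ordinal", 3, 8),
    ("MFLOW", "phenology", "continuous", 1, 6),
    ("EFLOW", "phenology", "ordinal", 4, 10),
    ("ENDO", "seed", "continuous", 0, 1),
    ("EPI", "seed", "continuous", 0, 1),
    ("SBL", "seed", "continuous", 0, 1),
    ("SMASS", "seed", "continuous", -3.30, 1.43),
    ("TV", "seed", "continuous", 0.26, 4.30),
    ("LIGHT", "ecological", "ordinal", 5, 9),
    ("MOIST", "ecological", "ordinal", 2, 7),
    ("NUT", "ecological", "ordinal", 1, 6),
]


def _latent_to_scale(latent: np.ndarray, scale: str, lo: float, hi: float,
                     rng) -> np.ndarray:
    """Map a latent Brownian tip vector onto a trait scale, respecting the
    declared range (binary/ordinal by quantile thresholding)."""
    order = np.argsort(np.argsort(latent))
    q = (order + 0.5) / len(latent)
    if scale == "binary":
        return (latent > np.median(latent)).astype(float)
    if scale == "ordinal":
        levels = np.arange(lo, hi + 1)
        return levels[np.minimum((q * len(levels)).astype(int), len(levels) - 1)].astype(float)
    return lo + q * (hi - lo)


def generate_species_pool(cfg: SimConfig, seed: int) -> tuple:
    """Trait table + pure-birth phylogeny; traits evolve by Brownian motion
    on the tree (zero rate collapses every species to one phenotype)."""
    rng = np.random.default_rng(seed + 1)
    labels = [f"sp{i:03d}" for i in range(cfg.n_species)]
    newick = _pure_birth_newick(rng, cfg.n_species, labels)
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    values = {}
    for name, block, scale, lo, hi in TRAIT_SPECS:
        tips = _brownian_tips(rng, tree, cfg.bm_sigma)
        latent = np.array([tips[lab] for lab in labels])
        if cfg.bm_sigma == 0:
            values[name] = np.full(cfg.n_species, float(lo))
        else:
            values[name] = _latent_to_scale(latent, scale, lo, hi, rng)
    vdf = pd.DataFrame(values, index=pd.Index(labels, name="species_id"))
    meta = pd.DataFrame(
        [(name, block, scale, lo, hi) for name, block, scale, lo, hi in TRAIT_SPECS],
        columns=["trait", "block", "scale", "lo", "hi"],
    ).set_index("trait")
    # latent environmental optimum, also evolved on the tree
    opt_tips = _brownian_tips(rng, tree, max(cfg.bm_sigma, 1e-9))
    env_opt = np.array([opt_tips[lab] for lab in labels])
    traits = TraitTable(vdf, meta)
    return traits, Phylogeny(tree), pd.Series(env_opt, index=labels)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_occupancy(
    patches: PatchTable,
    traits: TraitTable,
    env_optimum: pd.Series,
    cfg: SimConfig,
    seed: int,
) -> tuple:
    """Bernoulli occupancy draws from the logistic assembly model.

    The niche axis is the patch TWI (standardised); species optima are their
    standardised latent Brownian values, so environmental filtering selects
    phylogenetically clustered subsets.  Returns the matrix, the true
    parameter record, and the list of patches below the richness minimum.
    """
    rng = np.random.default_rng(seed + 2)
    df = patches.df
    b = cfg.betas
    env = _zscore(df["TWI"].to_numpy(dtype=float))
    log_a = _zscore(np.log10(df["area_m2"].to_numpy(dtype=float)))
    iso = df["I_2000"].to_numpy(dtype=float)
    if np.isnan(iso).any():  # empty neighbourhoods count as maximally isolated
        iso = np.where(np.isnan(iso), np.nanmax(iso) + 1.0, iso)
    iso = _zscore(iso)
    age = _zscore(df["age"].to_numpy(dtype=float)) if "age" in df else np.zeros(len(df))
    opt = _zscore(env_optimum.to_numpy(dtype=float))
    match = np.exp(-((opt[None, :] - env[:, None]) ** 2) / (2 * cfg.niche_sd**2))
    match = _zscore(match.ravel()).reshape(match.shape)
    sla = _zscore(traits.values["SLA"].to_numpy(dtype=float))
    interaction = _zscore((sla[None, :] * env[:, None]).ravel()).reshape(match.shape)
    suit = _zscore(df["slope"].to_numpy(dtype=float))
    eta = (
        b.b0
        + b.b_env * match
        + (b.b_abi * suit + b.b_area * log_a + b.b_iso * iso + b.b_age * age)[
            :, None
        ]
        + b.b_tx * interaction
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    occ = (rng.random(prob.shape) < prob).astype(np.int8)
    if prob.sum(axis=1).max() < cfg.min_richness:
        raise ValidationError(
            "infeasible occupancy config: expected richness below the minimum everywhere"
        )
    if cfg.redraw_sparse:
        for _ in range(100):
            sparse = occ.sum(axis=1) < cfg.min_richness
            if not sparse.any():
                break
            occ[sparse] = (rng.random((sparse.sum(), prob.shape[1])) < prob[sparse]).astype(np.int8)
    matrix = OccupancyMatrix(
        pd.DataFrame(occ, index=df.index, columns=list(traits.species_ids))
    )
    sparse = list(df.index[occ.sum(axis=1) < cfg.min_richness])
    truth = {"betas": asdict(b), "niche_sd": cfg.niche_sd, "niche_axis": "TWI"}
    return matrix, truth, sparse


def generate_study(cfg: SimConfig, seed: int,
                   out_dir: Optional[str] = None) -> SyntheticStudy:
    """Compose landscape, species pool and occupancy into a full study.

    With ``out_dir``, writes the standard-format file bundle (patch table,
    trait values + metadata, occupancy, Newick tree) plus ``truth.json``
    recording every generative parameter.
    """
    patches, snapshots = generate_landscape(cfg, seed)
    traits, phylo, env_opt = generate_species_pool(cfg, seed)
    occupancy, truth, sparse = simulate_occupancy(
        patches, traits, env_opt, cfg, seed
    )
    truth = {
        "seed": seed,
        "config": {**asdict(cfg)},
        "occupancy": truth,
        "sparse_patches": sparse,
    }
    study = SyntheticStudy(patches, snapshots, traits, phylo, occupancy,
                           truth, sparse)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ps_io.write_patch_table(patches, out / "patches.csv")
        traits.values.to_csv(out / "trait_values.csv", index_label="species_id")
        traits.meta.to_csv(out / "trait_metadata.csv", index_label="trait")
        ps_io.write_occupancy(occupancy, out / "occupancy.csv")
        (out / "phylogeny.nwk").write_text(
            phylo.tree.as_string(schema="newick").strip() + "\n"
        )
        import json

        (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str))
    return study
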