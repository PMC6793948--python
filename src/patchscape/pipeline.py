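"""End-to-end orchestration: landscape metrics → diversity → inference,
run separately per patch age class, with persisted tables and a manifest.

The result bundle mirrors the output tables of a community-assembly study:
a group-comparison table (means ± SD, ranges, Welch t with BH-FDR adjusted
p per variable), per-block PCA summaries, GLM coefficient tables with
significance stars and AIC ranks, diversity correlations, and the
seven-fraction adjusted variance partitioning per response.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import diversity as dv
from . import inference as inf
from .datatypes import (
    DiversityProfile,
    OccupancyMatrix,
    PatchTable,
    Phylogeny,
    TraitTable,
    ValidationError,
)

__all__ = ["RunConfig", "ResultBundle", "predictor_blocks", "summarize_groups",
           "run_full_analysis"]

#: default block membership (post-screening candidates, priority order)
DEFAULT_BLOCKS = {
    "abiotic": ["TWI", "slope", "elevation", "PDSI_June"],
    "present": ["logA", "I_2000"],
    "historical": ["age", "I_1843", "I_1980", "A_1843", "A_1980"],
}

FAMILY_BY_RESPONSE = {"SD": "poisson", "FD": "gaussian", "PD": "gaussian"}


@dataclass
class RunConfig:
    """Settings of one full analysis run."""

    blocks: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_BLOCKS.items()}
    )
    responses: Sequence[str] = ("SD", "FD", "PD")
    families: Mapping[str, str] = field(
        default_factory=lambda: dict(FAMILY_BY_RESPONSE)
    )
    collinearity_threshold: float = 0.5
    fdr_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        bad = set(self.responses) - {"SD", "FD", "PD"}
        if bad:
            raise ValidationError(f"unknown responses: {sorted(bad)}")
        for r in self.responses:
            if self.families.get(r) not in ("poisson", "gaussian"):
                raise ValidationError(f"invalid family for response {r}")


@dataclass
class ResultBundle:
    """All result tables of one run, keyed for :func:`patchscape.io.write_results`."""

    tables: dict
    manifest: dict

    def table(self, name: str) -> pd.DataFrame:
        return self.tables[name]


def _with_loga(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["logA"] = np.log10(out["area_m2"])
    return out


def predictor_blocks(
    patches: PatchTable,
    block_vars: Optional[Mapping[str, Sequence[str]]] = None,
    threshold: float = 0.5,
) -> tuple:
    """Screened raw-variable blocks plus their two-axis PCA score matrices.

    Zero-variance variables (e.g. age within the new class, where every
    patch shares one appearance window) are dropped automatically; the
    collinearity screen then runs within each block in the declared priority
    order, never leaving fewer than two variables.  Returns
    ``(raw_blocks, score_blocks, pca_axes, screen_report)``.
    """
    block_vars = block_vars or DEFAULT_BLOCKS
    data = _with_loga(patches.df)
    raw = {}
    scores = {}
    axes = {}
    report = {}
    for name, candidates in block_vars.items():
        avail = [v for v in candidates if v in data.columns]
        if len(avail) < 2:
            raise ValidationError(f"block '{name}' has fewer than 2 variables")
        sub = data[avail]
        kept, dropped = inf.collinearity_screen(
            sub, threshold=threshold, priority=avail, min_keep=2
        )
        report[name] = {"kept": kept, "dropped": dropped}
        raw[name] = sub[kept]
        pca = inf.block_pca(raw[name], inf.BlockSpec(name, kept))
        axes[name] = pca
        scores[name] = pca.scores
    return raw, scores, axes, report


def summarize_groups(
    patches: PatchTable,
    profile: DiversityProfile,
    variables: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Old-vs-new comparison table: per variable, mean ± SD and range per
    class, Welch two-sample t p-value and its BH-FDR adjustment.

    Variables constant in both classes are flagged (``tested = False``) and
    excluded from the FDR family.
    """
    data = _with_loga(patches.df).join(profile.df, how="left")
    if variables is None:
        variables = [
            c
            for c in data.columns
            if c not in ("age_class", "x", "y", "radius_m", "area_m2")
            and not c.startswith("present_")
            and pd.api.types.is_numeric_dtype(data[c])
        ]
    cls = data["age_class"]
    if not {"old", "new"} <= set(cls):
        raise ValidationError("both age classes must be non-empty")
    rows = []
    for var in variables:
        a = data.loc[cls == "old", var].dropna()
        b = data.loc[cls == "new", var].dropna()
        row = {
            "variable": var,
            "mean_old": a.mean(),
            "sd_old": a.std(ddof=1),
            "min_old": a.min(),
            "max_old": a.max(),
            "mean_new": b.mean(),
            "sd_new": b.std(ddof=1),
            "min_new": b.min(),
            "max_new": b.max(),
        }
        constant = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
        if constant or len(a) < 2 or len(b) < 2:
            warnings.warn(f"variable '{var}' not testable; flagged", stacklevel=2)
            row.update({"tested": False, "p_raw": np.nan})
        else:
            row.update({"tested": True, **{
                "p_raw": inf.welch_t_test(a, b)["p"],
                "t": inf.welch_t_test(a, b)["t"],
            }})
        rows.append(row)
    table = pd.DataFrame(rows).set_index("variable")
    tested = table["tested"].fillna(False).astype(bool)
    table["p_fdr"] = np.nan
    if tested.any():
        table.loc[tested, "p_fdr"] = inf.fdr_adjust(table.loc[tested, "p_raw"])
    table["significant"] = table["p_fdr"] < alpha
    return table


def _responses_frame(profile: DiversityProfile) -> pd.DataFrame:
    return profile.df


def run_full_analysis(
    patches: PatchTable,
    occupancy: OccupancyMatrix,
    traits: TraitTable,
    phylogeny: Optional[Phylogeny] = None,
    config: Optional[RunConfig] = None,
) -> ResultBundle:
    """Execute the whole analysis and return the table bundle.

    Stages: combined Gower functional distances and (optionally)
    cophenetic phylogenetic distances → per-patch diversity profile →
    old-vs-new group comparison with FDR → per class: block screening + PCA,
    GLMs of each response on the six PCA axes, adjusted variance
    partitioning, per-variable GLMs with AIC ranks, and FD–SD / PD–SD
    correlations.  Patches with undefined FD/PD (richness < 2) are excluded
    from the FD/PD models only.
    """
    config = config or RunConfig()
    phylogeny.check_species(occupancy.species_ids) if phylogeny else None

    func_traits = traits.restrict(
        [t for t in traits.values.columns
         if traits.meta.loc[t, "block"] != "ecological"]
    )
    blocks = [
        dv.gower_block_distance(func_traits.restrict(func_traits.traits_in_block(b)))
        for b in ("vegetative", "phenology", "seed")
    ]
    fdist = dv.combine_blocks(blocks)
    pdist = dv.cophenetic_distance(phylogeny) if phylogeny else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile = dv.diversity_profile(occupancy, fdist, pdist, traits)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        groups = summarize_groups(patches, profile, alpha=config.fdr_alpha)

    tables = {"group_comparison": groups, "diversity_profile": profile.df}
    partition_rows = []
    for age_class in ("old", "new"):
        sub = patches.subset(age_class)
        if len(sub.df) < 10:
            raise ValidationError(f"age class '{age_class}' too small to analyse")
        raw, scores, axes, screen = predictor_blocks(
            sub, config.blocks, config.collinearity_threshold
        )
        pca_rows = []
        for name, pca in axes.items():
            tbl = pca.loadings.copy()
            tbl.loc["proportion_%"] = pca.proportion
            tbl.loc["cumulative_%"] = pca.cumulative
            tbl["block"] = name
            pca_rows.append(tbl)
        tables[f"pca_{age_class}"] = pd.concat(pca_rows)

        prof = profile.df.loc[sub.df.index]
        glm_tables = []
        corr_rows = []
        for resp in config.responses:
            if resp not in prof.columns:
                continue
            y = prof[resp].dropna()
            if resp == "SD":
                y = y.astype(int)
            fam = config.families[resp]
            part = inf.variance_partition(y, scores, fam, response=resp)
            row = part.to_series()
            row["age_class"] = age_class
            partition_rows.append(row)
            tbl, _ = inf.per_variable_glms(y, raw, fam, response=resp)
            tbl["response"] = resp
            tbl["age_class"] = age_class
            glm_tables.append(tbl)
            if resp in ("FD", "PD"):
                common = y.index.intersection(prof["SD"].dropna().index)
                res = inf.pearson(prof.loc[common, resp], prof.loc[common, "SD"])
                corr_rows.append(
                    {"age_class": age_class, "pair": f"{resp}-SD", **res}
                )
        tables[f"glm_{age_class}"] = pd.concat(glm_tables, ignore_index=True)
        tables[f"correlations_{age_class}"] = pd.DataFrame(corr_rows)
    partition = pd.DataFrame(partition_rows)
    partition.index = [
        f"{row['age_class']}_{s.name}" for s, (_, row) in
        zip(partition_rows, partition.iterrows())
    ]
    partition.index.name = "model"
    tables["variance_partition"] = partition

    manifest = {
        "config": {
            "blocks": {k: list(v) for k, v in config.blocks.items()},
            "responses": list(config.responses),
            "families": dict(config.families),
            "collinearity_threshold": config.collinearity_threshold,
            "fdr_alpha": config.fdr_alpha,
            "seed": config.seed,
        },
        "n_patches": len(patches.df),
        "n_species": len(occupancy.species_ids),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    return ResultBundle(tables, manifest)
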