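"""Three facets of community diversity on a five-species toy pool.

SD counts species; FD is the mean pairwise Gower dissimilarity (three trait
blocks combined, Podani handling for ordinal traits); PD is the mean
pairwise cophenetic distance on a small phylogeny.  Community means (CM)
summarise the trait values of the species present.
"""

import numpy as np
import pandas as pd

import patchscape as ps

species = [f"sp{i}" for i in range(5)]
values = pd.DataFrame(
    {
        "clonality": [0, 1, 1, 0, 1],           # binary, vegetative
        "height": [0.1, 0.4, 0.8, 0.2, 1.6],    # continuous, vegetative
        "flowering_start": [3, 5, 5, 8, 4],     # ordinal month, phenology
        "seed_mass": [0.2, 1.5, 0.9, np.nan, 2.4],  # continuous, seed (1 NA)
    },
    index=pd.Index(species, name="species_id"),
)
meta = pd.DataFrame(
    {
        "block": ["vegetative", "vegetative", "phenology", "seed"],
        "scale": ["binary", "continuous", "ordinal", "continuous"],
        "lo": [0, np.nan, 3, np.nan],
        "hi": [1, np.nan, 10, np.nan],
    },
    index=pd.Index(values.columns, name="trait"),
)
traits = ps.TraitTable(values, meta)

blocks = [
    ps.gower_block_distance(traits.restrict(traits.traits_in_block(b)))
    for b in ("vegetative", "phenology", "seed")
]
fdist = ps.combine_blocks(blocks)

import dendropy

tree = ps.Phylogeny(dendropy.Tree.get(
    data="((sp0:1,sp1:1):2,((sp2:1.5,sp3:1.5):0.5,sp4:2):1);",
    schema="newick", preserve_underscores=True))
pdist = ps.cophenetic_distance(tree)  # normalised to [0, 1]

occ = ps.OccupancyMatrix(pd.DataFrame(
    [[1, 1, 1, 0, 0], [1, 0, 0, 1, 1], [0, 0, 1, 0, 0]],
    index=["patch_A", "patch_B", "patch_C"], columns=species))

profile = ps.diversity_profile(occ, fdist, pdist, traits)
print(profile.df.round(3).to_string())
# SD is the species count; FD/PD are mean pairwise dissimilarities over the
# species present (NaN for patch_C, where a single species leaves no pair);
# CM_* are unweighted means of each trait over the present species.
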