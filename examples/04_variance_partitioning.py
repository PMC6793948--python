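"""Full pipeline: which predictor block drives species richness?

Generates a synthetic study whose occupancy is driven mostly by present-day
landscape configuration (patch area + isolation), runs the analysis, and
shows that the variance partitioning attributes the largest unique fraction
of SD to the present-day block.
"""

import patchscape as ps

betas = ps.OccupancyBetas(b0=-0.9, b_env=0.3, b_abi=0.1,
                          b_area=0.8, b_iso=-0.5, b_age=0.1, b_tx=0.1)
study = ps.generate_study(ps.SimConfig(betas=betas), seed=42)

bundle = ps.run_full_analysis(
    study.patches, study.occupancy, study.traits, study.phylogeny
)

part = bundle.table("variance_partition")
print("adjusted variance partitioning (%, rows = age class x response):")
print(part.drop(columns="age_class").round(2).to_string())
print()
groups = bundle.table("group_comparison")
print("old-vs-new comparison of the diversity metrics:")
print(groups.loc[["SD", "FD", "PD"],
                 ["mean_old", "sd_old", "mean_new", "sd_new",
                  "p_raw", "p_fdr"]].round(4).to_string())
# unique_* are each block's exclusive adjusted contributions; shared_* the
# overlaps (negative values are legitimate for adjusted fractions); TVE is
# the adjusted explained variation of the full six-axis model.  The
# present-day block should carry the largest unique fraction for SD here,
# matching the generating coefficients.
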