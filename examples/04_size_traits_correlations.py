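"""Linear size traits, per-image averaging and trait correlations.

Measures length (max Feret) and width (perpendicular caliper), derives
the Q ratio and integrated size, averages traits per image, and
reports the Spearman correlation structure among traits.
"""

from sporemorph import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    mode="polygons",
    outdir="scratch/example04_run",
    seed=3,
    n_species=5,
    n_specimens=2,
    spores_per_specimen=(8, 14),
    spores_per_image=(1, 3),
    n_reps=1,
)
res = run_pipeline(cfg)

print(res.traits[["image_id", "species_id", "length_um", "width_um", "q_ratio", "size_int", "n_spores"]].head())
print(f"\n{len(res.traits)} image-level observations from {len(res.spores)} spores")

rho, p, mask = res.spearman
show = ["length_um", "width_um", "q_ratio", "size_int", "sym_pc1"]
print("\nSpearman rho (x = not significant at alpha 0.05):")
for a in show:
    row = "  ".join(
        f"{rho.loc[a, b]:+.2f}" if mask.loc[a, b] or a == b else "   x "
        for b in show
    )
    print(f"{a:10s} {row}")
# Typical structure: sym_pc1 (relative thickness) correlates negatively
# with length and positively with width; Q is driven mostly by length.
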