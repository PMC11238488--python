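"""Call differentially activated reactions (DARs) between two conditions.

Uses planted-shift synthetic solution matrices: one reaction's activation
frequency drops from 0.95 (control) to 0.05 (treated), the rest hover at
0.5 on both sides. The R2 statistic and the baseline-noise filter should
recover exactly the planted shift.
"""

from mmoa import PlantedShiftSpec, dar_pipeline, generate_solution_sets

spec = PlantedShiftSpec(
    n_reactions=12,
    n_solutions=5000,
    shifted={"R004": (0.95, 0.05)},
    noise_frequency=0.5,
    seed=42,
)
ctrl, trt, truth = generate_solution_sets(spec)
print(f"{len(ctrl)} control and {len(trt)} treated solutions over {spec.n_reactions} reactions")

# two identical control enumerations -> zero baseline noise
table = dar_pipeline(ctrl, trt, control_sets=[ctrl, ctrl])
print("\nDAR table (R2 = squared activation-frequency difference, DAR threshold 0.2):")
print(table.round(3).to_string())

dars = list(table.index[table["dar"]])
print(f"\ncalled DARs: {dars}")
print("R004 swings from nearly always active to nearly never active (R2 ~ 0.81),")
print("so it is called as a down-activated DAR; the unshifted reactions stay near")
print("R2 ~ 0 and are never called.")
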