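"""Sweeping the network over connectivity and input-rate grids.

Separation efficiency depends on how densely EC projects to DG (r) and how
vigorously the active inputs fire (p).  This script runs a reduced sweep
(a coarse grid, a handful of trials) and prints the resulting surface with
and without feedback inhibition, plus the per-r trend of S against p.
The full paper-scale grids live in the `separation_surfaces` experiment
recipe.
"""

from dgpatsep import NetworkConfig, separation_trends, sweep_separation

config = NetworkConfig()
table = sweep_separation(
    r_values=[0.05, 0.15, 0.3],
    p_values=[0.2, 0.5, 0.8],
    alpha_values=[None, 0.2],
    trials=5,
    config=config,
    seed=0,
)

print("Mean separation efficiency (zero-filled over silent trials):")
for alpha, label in ((float("nan"), "no inhibition"), (0.2, "alpha = 0.2")):
    sub = table[table["alpha"].isna()] if label == "no inhibition" else \
        table[table["alpha"] == alpha]
    print(f"\n  {label}:")
    surface = sub.pivot(index="r", columns="p",
                        values="mean_separation_zerofill")
    print(surface.round(3).to_string())

print("\nTrend of S versus p per connectivity rate (no inhibition):")
print(separation_trends(table).to_string(index=False))
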