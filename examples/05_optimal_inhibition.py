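"""Searching for the inhibition strength that best separates patterns.

Inhibition silences over-recruited granule cells, so some amount of it
should sharpen the population code; too much silences everything.  This
script scans a small alpha grid on a reduced sweep, prints the resulting
curve of grid-averaged separation efficiency, and reports the argmax.
"""

from dgpatsep import NetworkConfig, optimal_alpha_separation

best, curve = optimal_alpha_separation(
    alpha_grid=[0.05, 0.1, 0.2, 0.4, 0.7, 1.0],
    r_values=[0.1, 0.2, 0.3],
    p_values=[0.3, 0.6, 0.9],
    trials=5,
    config=NetworkConfig(),
    seed=0,
)

print("Grid-averaged separation efficiency per inhibition strength:")
print(curve.round(4).to_string(index=False))
print(f"\nBest alpha on this grid: {best}")
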