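"""One end-to-end trial of the EC -> DG spiking network.

800 entorhinal-cortex neurons project onto 4000 dentate-gyrus granule
cells through random wiring; 40 disjoint patterns of 20 EC neurons are
presented one after another for 500 bins of 10 ms each.  A granule cell
"responds to" a pattern when it spikes at least once during its
presentation.  The resulting activation matrix summarizes how the
population tells the patterns apart.
"""

from dgpatsep import NetworkConfig, simulate_trial
from dgpatsep.separation import (
    firing_frequency_from_counts,
    separation_efficiency,
)

config = NetworkConfig(r=0.1, seed=42)

for alpha, label in ((None, "without inhibition"), (0.2, "with alpha = 0.2")):
    activation, counts = simulate_trial(config, p=0.5, alpha=alpha)
    frac = activation.n_activated / config.n_dg
    sep = separation_efficiency(activation)
    freq = firing_frequency_from_counts(counts, config.n_bins)
    print(f"Trial {label}:")
    print(f"  activated granule cells: {activation.n_activated} / "
          f"{config.n_dg} ({frac:.1%})")
    print(f"  separation efficiency S: {sep:.3f}")
    print(f"  firing frequency of activated cells: {freq:.4f} per bin\n")
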