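"""Stochastic two-layer spiking network: entorhinal cortex (EC) input layer
projecting onto dentate-gyrus (DG) granule cells.

The EC layer holds ``n_ec`` binary-spiking neurons (default 800) and the DG
layer ``n_dg`` granule cells (default 4000, the 1:5 EC:DG ratio).  An input
pattern is a set of ``pattern_size`` EC neurons (default 20); the default
40 patterns tile the EC exactly and are pairwise disjoint ("fully
separated" inputs).  During the presentation of one pattern, each of its
neurons spikes independently with probability ``p`` in each of ``n_bins``
time bins of ``bin_ms`` milliseconds (defaults 500 x 10 ms); all other EC
neurons are silent.

Each granule cell is a leaky integrate-and-fire unit on the time-bin grid:
its membrane potential decays toward rest with factor ``exp(-bin_ms/tau_m)``
per bin, increments by one EPSP per connected EC spike, and emits a
candidate spike (followed by a reset to rest) upon crossing threshold.

Feedback inhibition deletes each candidate spike independently with
probability ``P_I = exp(-alpha / f)``, where ``f`` is the mean number of
spikes per bin arriving from the cell's connected EC inputs over the whole
presentation -- the summed drive a feedback interneuron would see.  Strongly
driven cells therefore lose a larger fraction of their spikes, which is
what sparsifies the DG code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "NetworkConfig",
    "GranuleCellParams",
    "SpikeRaster",
    "ActivationMatrix",
    "generate_connectivity",
    "generate_pattern_set",
    "simulate_ec_spikes",
    "simulate_dg_response",
    "build_activation_matrix",
    "simulate_trial",
    "trial_rngs",
]


@dataclass(frozen=True)
class GranuleCellParams:
    """Leaky integrate-and-fire parameters of a DG granule cell.

    ``spikes_to_threshold`` sets the EPSP amplitude as
    ``(v_threshold - v_rest) / spikes_to_threshold``: the number of
    simultaneous input spikes that takes the cell from rest to threshold in
    one bin.  In the ``tau_m -> 0`` (memoryless) limit the cell fires in a
    bin exactly when that bin's input count reaches ``spikes_to_threshold``,
    which is the firing-threshold parameter ``theta`` of the single-neuron
    encoding model.

    The defaults place the population in the sparse-coding operating
    regime the model is designed to study: only a minority of granule
    cells responds to any pattern, feedback inhibition improves the
    grid-averaged separation efficiency, and the separation-versus-input-
    rate trend flips sign in the interior of the connectivity grid.  With
    much lower thresholds or slower membranes the 500-bin presentations
    saturate the population (every cell responds to every pattern) and the
    separation statistic degenerates; see ``docs/methods.md``.
    """

    v_rest: float = -75.0
    v_threshold: float = -45.0
    tau_m: float = 10.0
    spikes_to_threshold: int = 10
    refractory_bins: int = 0

    def __post_init__(self) -> None:
        if not self.v_threshold > self.v_rest:
            raise ValueError("v_threshold must exceed v_rest")
        if not self.tau_m > 0:
            raise ValueError("tau_m must be positive")
        if not (isinstance(self.spikes_to_threshold, (int, np.integer))
                and self.spikes_to_threshold >= 1):
            raise ValueError("spikes_to_threshold must be an integer >= 1")
        if self.refractory_bins < 0:
            raise ValueError("refractory_bins must be >= 0")

    @property
    def epsp(self) -> float:
        """Per-spike membrane increment (mV)."""
        return (self.v_threshold - self.v_rest) / self.spikes_to_threshold


@dataclass(frozen=True)
class NetworkConfig:
    """Geometry and run parameters of the EC -> DG network."""

    n_ec: int = 800
    n_dg: int = 4000
    r: float = 0.1
    n_bins: int = 500
    bin_ms: float = 10.0
    pattern_size: int = 20
    n_patterns: int = 40
    alpha: float | None = None
    seed: int = 0
    cell: GranuleCellParams = field(default_factory=GranuleCellParams)

    def __post_init__(self) -> None:
        for name in ("n_ec", "n_dg", "n_bins", "pattern_size", "n_patterns"):
            val = getattr(self, name)
            if not (isinstance(val, (int, np.integer)) and val >= 1):
                raise ValueError(f"{name} must be a positive integer, got {val!r}")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must be in [0, 1], got {self.r!r}")
        if not self.bin_ms > 0:
            raise ValueError("bin_ms must be positive")
        if self.n_patterns * self.pattern_size > self.n_ec:
            raise ValueError(
                f"n_patterns * pattern_size = {self.n_patterns * self.pattern_size} "
                f"exceeds n_ec = {self.n_ec}: disjoint patterns are infeasible"
            )
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError(f"alpha must be positive or None, got {self.alpha!r}")


@dataclass(frozen=True)
class SpikeRaster:
    """Binary neuron x time-bin spike record for one pattern presentation."""

    layer: Literal["EC", "DG"]
    spikes: np.ndarray  # uint8, (n_neurons, n_bins)
    pattern_id: int

    def __post_init__(self) -> None:
        if self.spikes.ndim != 2:
            raise ValueError("spikes must be a 2-D neurons x bins array")
        if not np.isin(self.spikes, (0, 1)).all():
            raise ValueError("spikes must be binary")


@dataclass(frozen=True)
class ActivationMatrix:
    """Which DG neurons were activated (>= 1 spike) by which input pattern.

    ``activation[i, j]`` is 1 when DG neuron ``i`` spiked at least once
    while pattern ``j`` was presented.  ``per_neuron_counts[i]`` is
    ``N_i = sum_j activation[i, j]``, the number of patterns that recruit
    neuron ``i``.
    """

    activation: np.ndarray  # uint8, (n_dg, n_patterns)
    per_neuron_counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        act = np.asarray(self.activation)
        if act.ndim != 2 or not np.isin(act, (0, 1)).all():
            raise ValueError("activation must be a binary 2-D matrix")
        object.__setattr__(self, "activation", act.astype(np.uint8))
        object.__setattr__(self, "per_neuron_counts", act.sum(axis=1))

    @property
    def n_patterns(self) -> int:
        return self.activation.shape[1]

    @property
    def n_activated(self) -> int:
        """K: number of DG neurons recruited by at least one pattern."""
        return int((self.per_neuron_counts > 0).sum())


def trial_rngs(seed: int | np.random.SeedSequence) -> dict[str, np.random.Generator]:
    """Named independent RNG streams for one trial.

    Separate streams for connectivity, pattern partition, EC spiking and
    inhibitory spike deletion, so that toggling inhibition does not perturb
    the other draws.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(4)
    names = ("connectivity", "patterns", "ec", "inhibition")
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def generate_connectivity(
    config: NetworkConfig, rng: np.random.Generator
) -> np.ndarray:
    """Random EC->DG connectivity: entry (i, j) is 1 with probability r.

    Returns a ``(n_dg, n_ec)`` uint8 matrix.
    """
    return (rng.random((config.n_dg, config.n_ec)) < config.r).astype(np.uint8)


def generate_pattern_set(
    config: NetworkConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random disjoint input patterns: ``n_patterns`` sets of EC indices.

    A fresh random subset of ``n_patterns * pattern_size`` EC neurons is
    partitioned into patterns of ``pattern_size``; patterns are pairwise
    disjoint (zero overlap).
    """
    chosen = rng.choice(
        config.n_ec, size=config.n_patterns * config.pattern_size, replace=False
    )
    return [
        np.sort(chosen[i * config.pattern_size:(i + 1) * config.pattern_size])
        for i in range(config.n_patterns)
    ]


def simulate_ec_spikes(
    pattern: np.ndarray,
    p: float,
    config: NetworkConfig,
    rng: np.random.Generator,
    pattern_id: int = 0,
) -> SpikeRaster:
    """EC raster for one pattern presentation.

    Neurons in the pattern spike independently with probability ``p`` per
    bin; all other EC neurons are silent.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p!r}")
    spikes = np.zeros((config.n_ec, config.n_bins), dtype=np.uint8)
    spikes[np.asarray(pattern)] = (
        rng.random((len(pattern), config.n_bins)) < p
    ).astype(np.uint8)
    return SpikeRaster(layer="EC", spikes=spikes, pattern_id=pattern_id)


def _lif_candidates(
    input_counts: np.ndarray, cell: GranuleCellParams, bin_ms: float
) -> np.ndarray:
    """Candidate DG spikes from per-bin connected input counts.

    ``input_counts`` is (n_cells, n_bins); returns a uint8 array of the
    same shape.  The membrane decays toward rest each bin, then integrates
    the bin's inputs; crossing threshold emits a spike and resets.
    """
    n_cells, n_bins = input_counts.shape
    decay = np.exp(-bin_ms / cell.tau_m)
    gap = cell.v_threshold - cell.v_rest
    v = np.zeros(n_cells)  # potential above rest
    refr = np.zeros(n_cells, dtype=np.int32)
    out = np.zeros((n_cells, n_bins), dtype=np.uint8)
    for t in range(n_bins):
        v *= decay
        active = refr == 0
        v += np.where(active, cell.epsp * input_counts[:, t], 0.0)
        fired = active & (v >= gap)
        out[fired, t] = 1
        v[fired] = 0.0
        refr[~active] -= 1
        refr[fired] = cell.refractory_bins
    return out


def simulate_dg_response(
    ec_raster: SpikeRaster,
    connectivity: np.ndarray,
    config: NetworkConfig,
    rng: np.random.Generator | None = None,
    alpha: float | None = None,
    cell: GranuleCellParams | None = None,
) -> SpikeRaster:
    """DG raster in response to one EC presentation.

    Candidate spikes come from the leaky integrate-and-fire dynamics; when
    ``alpha`` is set each candidate spike is deleted independently with
    probability ``exp(-alpha / f)``, where ``f`` is the cell's mean
    connected-input spike count per bin over the presentation.  ``rng`` is
    required when ``alpha`` is set (it drives the deletions only).
    """
    cell = cell or config.cell
    if connectivity.shape != (config.n_dg, config.n_ec):
        raise ValueError(
            f"connectivity shape {connectivity.shape} does not match "
            f"(n_dg, n_ec) = {(config.n_dg, config.n_ec)}"
        )
    if ec_raster.spikes.shape != (config.n_ec, config.n_bins):
        raise ValueError("EC raster shape does not match the configuration")
    input_counts = connectivity.astype(np.int32) @ ec_raster.spikes.astype(np.int32)
    spikes = _lif_candidates(input_counts, cell, config.bin_ms)
    if alpha is not None:
        if rng is None:
            raise ValueError("an rng is required when inhibition is enabled")
        f = input_counts.sum(axis=1) / config.n_bins  # summed drive per bin
        with np.errstate(divide="ignore"):
            p_del = np.where(f > 0, np.exp(-alpha / np.where(f > 0, f, 1.0)), 0.0)
        deleted = rng.random(spikes.shape) < p_del[:, None]
        spikes = np.where(deleted, 0, spikes).astype(np.uint8)
    return SpikeRaster(layer="DG", spikes=spikes, pattern_id=ec_raster.pattern_id)


def build_activation_matrix(dg_rasters: Sequence[SpikeRaster]) -> ActivationMatrix:
    """Activation matrix N_{i,j} from one DG raster per pattern."""
    if not dg_rasters:
        raise ValueError("at least one DG raster is required")
    shapes = {r.spikes.shape for r in dg_rasters}
    if len(shapes) != 1:
        raise ValueError(f"rasters have inconsistent shapes: {shapes}")
    activation = np.stack(
        [(raster.spikes.sum(axis=1) > 0) for raster in dg_rasters], axis=1
    )
    return ActivationMatrix(activation=activation.astype(np.uint8))


def simulate_trial(
    config: NetworkConfig,
    p: float,
    seed: int | np.random.SeedSequence | None = None,
    alpha: float | None = None,
    connectivity: np.ndarray | None = None,
) -> tuple[ActivationMatrix, np.ndarray]:
    """One full trial: patterns -> EC spikes -> DG responses -> activation.

    Presents every pattern once.  ``alpha`` overrides ``config.alpha`` when
    given.  Returns the activation matrix and the per-(neuron, pattern)
    DG spike counts (shape ``(n_dg, n_patterns)``).  Passing
    ``connectivity`` reuses a fixed wiring across trials.
    """
    rngs = trial_rngs(config.seed if seed is None else seed)
    alpha = config.alpha if alpha is None else alpha
    if connectivity is None:
        connectivity = generate_connectivity(config, rngs["connectivity"])
    patterns = generate_pattern_set(config, rngs["patterns"])
    rasters = []
    for j, pattern in enumerate(patterns):
        ec = simulate_ec_spikes(pattern, p, config, rngs["ec"], pattern_id=j)
        dg = simulate_dg_response(
            ec, connectivity, config, rngs["inhibition"], alpha=alpha
        )
        rasters.append(dg)
    activation = build_activation_matrix(rasters)
    counts = np.stack([r.spikes.sum(axis=1) for r in rasters], axis=1)
    return activation, counts
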