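"""Pattern-separation efficiency of the DG population, and the trial-averaged
parameter sweeps that locate the optimal feedback-inhibition strength.

Separation efficiency
---------------------
Given the activation matrix ``N_{i,j}`` (DG neuron i activated by input
pattern j) with ``L`` patterns, each activated neuron contributes
``1 - N_i / L`` where ``N_i`` is the number of patterns recruiting it, and

    S = (1/K) * sum_{i : N_i > 0} (1 - N_i / L),

``K`` being the number of activated neurons.  ``S`` is maximal
(``1 - 1/L``) when every recruited neuron responds to exactly one pattern
and 0 when every recruited neuron responds to all of them.  With no
activated neuron at all, separation is undefined and ``S`` is reported as
NaN with a warning; trial averages in the sweeps additionally report a
zero-filled mean (silent trial counted as S = 0), which is the convention
under which separation-versus-p trends are evaluated at very low
connectivity, where some trials recruit no neuron at all.

Sweeps
------
``sweep_separation`` runs end-to-end trials (pattern partition -> EC spikes
-> LIF granule cells -> spike deletion -> activation matrix -> S) over a
(r, p, alpha) grid.  Two statistically equivalent engines are provided:

* ``method="full"`` simulates every EC and DG raster explicitly.
* ``method="factorized"`` (default) exploits the model's structure: with
  disjoint patterns and i.i.d. Bernoulli connectivity, a (neuron, pattern)
  pair's response depends only on ``k``, the number of the pattern's
  neurons the cell is wired to (``k ~ Binomial(pattern_size, r)``), and the
  membrane dynamics do not depend on the inhibition parameter, so candidate
  spike trajectories can be pre-simulated per ``k`` into a pool and
  re-thinned for every alpha.  This is what makes grid x alpha x trial
  sweeps tractable on one CPU; the two engines agree in distribution (up to
  pool-reuse correlations that vanish as the pool grows).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .network import (
    ActivationMatrix,
    GranuleCellParams,
    NetworkConfig,
    SpikeRaster,
    _lif_candidates,
    simulate_trial,
)

__all__ = [
    "separation_efficiency",
    "average_firing_frequency",
    "firing_frequency_from_counts",
    "sweep_separation",
    "optimal_alpha_separation",
    "separation_trends",
    "DEFAULT_SEP_R_GRID",
    "DEFAULT_SEP_P_GRID",
    "DEFAULT_SEP_ALPHA_GRID",
]

DEFAULT_SEP_R_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 10))
DEFAULT_SEP_P_GRID = tuple(np.round(np.arange(0.1, 0.901, 0.1), 10))
#: The alpha grid over which the separation optimum is searched.
DEFAULT_SEP_ALPHA_GRID = tuple(np.round(np.arange(0.05, 1.001, 0.05), 10))

_SWEEP_COLUMNS = [
    "r", "p", "alpha", "n_trials", "mean_separation", "se_separation",
    "mean_separation_zerofill", "mean_dg_firing", "mean_activated_fraction",
    "n_silent_trials", "seed",
]


def separation_efficiency(
    activation: ActivationMatrix | np.ndarray, form: str = "per_neuron"
) -> float:
    """Separation efficiency S of a DG activation matrix, in [0, 1].

    ``form="per_neuron"`` (default) computes the bounded statistic
    ``(1/K) sum_i (1 - N_i/L)`` over activated neurons.  ``form="literal"``
    evaluates the unreduced double sum over all active (neuron, pattern)
    entries, ``(1/K) sum_i sum_{j: N_ij=1} (1 - N_ij/L)``, which equals
    ``(1 - 1/L) * mean(N_i)`` and is not confined to [0, 1]; it is kept
    only for comparison.

    Returns NaN (with a warning) when no neuron is activated.
    """
    act = activation.activation if isinstance(activation, ActivationMatrix) else \
        np.asarray(activation)
    if act.ndim != 2 or act.shape[1] < 1:
        raise ValueError("activation must be a 2-D matrix with >= 1 pattern")
    if form not in ("per_neuron", "literal"):
        raise ValueError(f"form must be 'per_neuron' or 'literal', got {form!r}")
    L = act.shape[1]
    counts = act.sum(axis=1)
    active = counts > 0
    k = int(active.sum())
    if k == 0:
        warnings.warn("no DG neuron activated: separation efficiency undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    if form == "per_neuron":
        return float(np.mean(1.0 - counts[active] / L))
    return float(np.sum(counts[active] * (1.0 - 1.0 / L)) / k)


def average_firing_frequency(dg_rasters: Sequence[SpikeRaster]) -> float:
    """Mean spike probability per bin of activated DG neurons.

    Takes one DG raster per pattern presentation.  Only (neuron,
    presentation) pairs in which the neuron is activated (>= 1 spike)
    enter the denominator: ``total spikes / (n_bins * number of activated
    pairs)``.  Returns 0 when nothing is activated.  For a pre-computed
    spike-count matrix use :func:`firing_frequency_from_counts`.
    """
    if isinstance(dg_rasters, np.ndarray):
        raise TypeError(
            "pass spike rasters, or use firing_frequency_from_counts for counts"
        )
    if len(dg_rasters) == 0:
        raise ValueError("at least one raster is required")
    n_bins = dg_rasters[0].spikes.shape[1]
    counts = np.stack([r.spikes.sum(axis=1) for r in dg_rasters], axis=1)
    return firing_frequency_from_counts(counts, n_bins)


def firing_frequency_from_counts(counts: np.ndarray, n_bins: int) -> float:
    """Firing frequency from a ``(n_dg, n_patterns)`` spike-count matrix."""
    active = counts > 0
    n_pairs = int(active.sum())
    if n_pairs == 0:
        return 0.0
    return float(counts[active].sum() / (n_pairs * n_bins))


# ---------------------------------------------------------------------------
# factorized sweep engine
# ---------------------------------------------------------------------------

class _ChainPool:
    """Pre-simulated granule-cell responses for one EC firing probability.

    For every possible within-pattern connection count ``k`` (0 ..
    pattern_size) the pool holds ``pool_size`` independent LIF trajectories
    summarized as (candidate spike count, total input spikes) over one
    presentation.  Candidate dynamics are alpha-independent, so one pool
    serves every inhibition strength.
    """

    def __init__(
        self,
        p: float,
        config: NetworkConfig,
        pool_size: int,
        rng: np.random.Generator,
    ) -> None:
        self.pool_size = pool_size
        kmax = config.pattern_size
        self.candidates = np.zeros((kmax + 1, pool_size), dtype=np.int32)
        self.input_totals = np.zeros((kmax + 1, pool_size), dtype=np.int64)
        cell = config.cell
        for k in range(1, kmax + 1):
            x = rng.binomial(k, p, size=(pool_size, config.n_bins)).astype(np.int32)
            spikes = _lif_candidates(x, cell, config.bin_ms)
            self.candidates[k] = spikes.sum(axis=1)
            self.input_totals[k] = x.sum(axis=1)


def _factorized_trial(
    config: NetworkConfig,
    pool: _ChainPool,
    alphas: Sequence[float | None],
    rng: np.random.Generator,
) -> dict[float | None, tuple[float, float, float]]:
    """One trial under every alpha; returns alpha -> (S, firing, frac).

    S is NaN for a silent trial.  Draws the per-(neuron, pattern)
    connection counts directly from Binomial(pattern_size, r) -- exactly
    the distribution induced by Bernoulli wiring onto disjoint patterns --
    and the candidate trajectories from the pre-simulated pool.
    """
    shape = (config.n_dg, config.n_patterns)
    k = rng.binomial(config.pattern_size, config.r, size=shape)
    idx = rng.integers(0, pool.pool_size, size=shape)
    candidates = pool.candidates[k, idx]
    f = pool.input_totals[k, idx] / config.n_bins
    out: dict[float | None, tuple[float, float, float]] = {}
    L = config.n_patterns
    for alpha in alphas:
        if alpha is None:
            surviving = candidates
        else:
            with np.errstate(divide="ignore"):
                retain = np.where(
                    f > 0, -np.expm1(-alpha / np.where(f > 0, f, 1.0)), 1.0
                )
            surviving = rng.binomial(candidates, retain)
        act = surviving > 0
        n_i = act.sum(axis=1)
        k_act = int((n_i > 0).sum())
        s = float(np.mean(1.0 - n_i[n_i > 0] / L)) if k_act else float("nan")
        ff = firing_frequency_from_counts(surviving, config.n_bins)
        out[alpha] = (s, ff, k_act / config.n_dg)
    return out


def sweep_separation(
    r_values: Sequence[float] = DEFAULT_SEP_R_GRID,
    p_values: Sequence[float] = DEFAULT_SEP_P_GRID,
    alpha_values: Sequence[float | None] = (None,),
    trials: int = 20,
    config: NetworkConfig | None = None,
    seed: int = 0,
    method: str = "factorized",
    pool_size: int = 1000,
    fix_connectivity: bool = False,
    progress: bool = False,
) -> pd.DataFrame:
    """Trial-averaged separation sweep over a (r, p, alpha) grid.

    Every grid cell runs ``trials`` independent end-to-end simulations;
    ``alpha_values`` may mix ``None`` (no inhibition) with positive
    inhibition strengths, all evaluated on the same trials (paired seeds).
    Returns one row per (r, p, alpha) with trial means, the standard error
    of S, the zero-filled mean of S, the mean firing frequency of activated
    neurons, the mean activated fraction, and the silent-trial count.

    ``method="full"`` uses the explicit raster-level simulator (slow; for
    validation); ``fix_connectivity`` applies to it only -- the default
    redraws the wiring every trial.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not len(r_values) or not len(p_values) or not len(alpha_values):
        raise ValueError("sweep grids must be non-empty")
    if method not in ("factorized", "full"):
        raise ValueError(f"method must be 'factorized' or 'full', got {method!r}")
    base = config or NetworkConfig()
    root = np.random.SeedSequence(seed)
    pool_ss, cells_ss = root.spawn(2)
    rows = []
    pools: dict[float, _ChainPool] = {}
    if method == "factorized":
        pool_rng = np.random.default_rng(pool_ss)
        for p in p_values:
            pools[p] = _ChainPool(p, base, pool_size, pool_rng)
    cell_seeds = cells_ss.spawn(len(r_values) * len(p_values))
    i = 0
    for r in r_values:
        for p in p_values:
            cfg = _with(base, r=float(r))
            trial_seeds = cell_seeds[i].spawn(trials)
            i += 1
            per_alpha: dict[float | None, list[tuple[float, float, float]]] = {
                a: [] for a in alpha_values
            }
            connectivity = None
            for t in range(trials):
                if method == "factorized":
                    trng = np.random.default_rng(trial_seeds[t])
                    res = _factorized_trial(cfg, pools[p], alpha_values, trng)
                else:
                    res = {}
                    if fix_connectivity and connectivity is None:
                        from .network import generate_connectivity, trial_rngs
                        connectivity = generate_connectivity(
                            cfg, trial_rngs(trial_seeds[t])["connectivity"]
                        )
                    for a in alpha_values:
                        act, counts = simulate_trial(
                            cfg, p, seed=trial_seeds[t], alpha=a,
                            connectivity=connectivity,
                        )
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore", RuntimeWarning)
                            s = separation_efficiency(act)
                        res[a] = (
                            s,
                            firing_frequency_from_counts(counts, cfg.n_bins),
                            act.n_activated / cfg.n_dg,
                        )
                for a, v in res.items():
                    per_alpha[a].append(v)
            for a in alpha_values:
                arr = np.array(per_alpha[a], dtype=float)
                s_vals, ff_vals, frac_vals = arr[:, 0], arr[:, 1], arr[:, 2]
                silent = int(np.isnan(s_vals).sum())
                defined = s_vals[~np.isnan(s_vals)]
                mean_s = float(defined.mean()) if defined.size else float("nan")
                se_s = (
                    float(defined.std(ddof=1) / np.sqrt(defined.size))
                    if defined.size > 1 else float("nan")
                )
                rows.append((
                    float(r), float(p), np.nan if a is None else float(a),
                    trials, mean_s, se_s,
                    float(np.nan_to_num(s_vals, nan=0.0).mean()),
                    float(ff_vals.mean()), float(frac_vals.mean()),
                    silent, seed,
                ))
            if progress:
                print(f"sweep: r={r} p={p} done", flush=True)
    return pd.DataFrame(rows, columns=_SWEEP_COLUMNS)


def _with(config: NetworkConfig, **updates) -> NetworkConfig:
    from dataclasses import replace
    return replace(config, **updates)


def optimal_alpha_separation(
    alpha_grid: Sequence[float] = DEFAULT_SEP_ALPHA_GRID,
    r_values: Sequence[float] = DEFAULT_SEP_R_GRID,
    p_values: Sequence[float] = DEFAULT_SEP_P_GRID,
    trials: int = 20,
    config: NetworkConfig | None = None,
    seed: int = 0,
    sweep: pd.DataFrame | None = None,
    **sweep_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Inhibition strength maximizing grid-averaged separation efficiency.

    Averages the zero-filled mean separation over the (r, p) grid for every
    alpha and returns ``(best_alpha, curve)`` where ``curve`` has one row
    per alpha.  Ties break toward the smallest alpha.  A pre-computed
    ``sweep`` table (from :func:`sweep_separation`) may be passed to avoid
    re-simulation.
    """
    alpha_grid = [float(a) for a in alpha_grid]
    if not alpha_grid:
        raise ValueError("alpha_grid must be non-empty")
    if any(a <= 0 for a in alpha_grid):
        raise ValueError("alpha_grid entries must be positive")
    if sweep is None:
        sweep = sweep_separation(
            r_values, p_values, alpha_grid, trials, config, seed, **sweep_kwargs
        )
    grouped = (
        sweep.dropna(subset=["alpha"])
        .groupby("alpha")
        .agg(
            mean_separation=("mean_separation_zerofill", "mean"),
            mean_dg_firing=("mean_dg_firing", "mean"),
            mean_activated_fraction=("mean_activated_fraction", "mean"),
        )
        .reindex(alpha_grid)
        .reset_index()
    )
    best = float(grouped["alpha"][int(np.argmax(grouped["mean_separation"].to_numpy()))])
    return best, grouped


def separation_trends(sweep: pd.DataFrame) -> pd.DataFrame:
    """Sign of the separation-versus-p trend per connectivity rate.

    Works on the no-inhibition rows of a sweep table, using the zero-filled
    mean (a silent cell counts as zero separation).  Returns one row per r
    with the Spearman rank correlation of mean S against p and its sign
    (+1 increasing, -1 decreasing, 0 flat).
    """
    noinh = sweep[sweep["alpha"].isna()]
    if noinh.empty:
        raise ValueError("sweep contains no no-inhibition (alpha = NaN) rows")
    rows = []
    for r, grp in noinh.groupby("r"):
        grp = grp.sort_values("p")
        rho = spearmanr(grp["p"], grp["mean_separation_zerofill"]).statistic
        if np.isnan(rho):
            rho = 0.0
        rows.append((float(r), float(rho), int(np.sign(rho))))
    return pd.DataFrame(rows, columns=["r", "spearman_rho", "trend"])
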