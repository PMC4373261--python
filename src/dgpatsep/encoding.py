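"""Exact probabilistic model of a single dentate-gyrus neuron's encoding
efficiency.

A layer of ``S`` input (entorhinal-cortex) neurons projects onto one granule
cell.  A stimulus of intensity ``m`` activates ``m`` of the ``S`` input
neurons; each input neuron is connected to the granule cell independently
with probability ``r`` (the connectivity rate), and each activated input
neuron emits a spike with probability ``p`` in a given event.  The granule
cell fires (``T = 1``) when at least ``theta`` of its activated, connected
inputs spike simultaneously.

The model is fully analytic: the number of connected neurons ``n`` is
Binomial(S, r); the overlap ``m'`` between the ``m`` activated neurons and a
random ``n``-subset is hypergeometric; the spike count among the ``m'``
effective inputs is Binomial(m', p).  Encoding efficiency is the mutual
information ``I(T; m)`` between the binary output and the stimulus
intensity, in bits.

Feedback inhibition is a spike-deletion process driven by the neuron's own
average activity ``f``: each spike is deleted with probability
``P_I = exp(-alpha / f)``, so a smaller ``alpha`` means stronger inhibition.
Because the printed source equations for the inhibited firing probability
are mutually inconsistent, three readings are implemented (see
:func:`apply_inhibition`); the default scales the firing probability by the
spike-retention factor ``1 - P_I``.

Everything in this module is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, rel_entr

__all__ = [
    "EncodingParams",
    "FiringProfile",
    "InhibitionMode",
    "connected_count_pmf",
    "input_count_pmf",
    "firing_prob_given_m",
    "firing_profile",
    "mutual_information",
    "inhibition_probability",
    "apply_inhibition",
    "mi_surface",
    "optimal_alpha_mi",
    "uniform_stimulus_prior",
    "DEFAULT_P_GRID",
    "DEFAULT_R_GRID",
    "DEFAULT_THETA_GRID",
    "DEFAULT_ALPHA_GRID",
]

#: Default sweep grids for the encoding-efficiency surfaces.
DEFAULT_P_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 10))
DEFAULT_R_GRID = tuple(np.round(np.arange(0.05, 1.001, 0.05), 10))
DEFAULT_THETA_GRID = (2, 3, 4, 5)
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.001, 0.1), 10))

#: Supported readings of the inhibited firing probability.
#:
#: ``"scaled"``      -- q * (1 - P_I) with P_I = exp(-alpha/f)       (default)
#: ``"subtractive"`` -- max(q - P_I, 0) with P_I = exp(-alpha/f)
#: ``"scaled-const"``-- q * (1 - exp(-alpha)), no dependence on f
InhibitionMode = str
_INHIBITION_MODES = ("scaled", "subtractive", "scaled-const")


@dataclass(frozen=True)
class EncodingParams:
    """Parameter bundle for the single-neuron encoding model.

    Parameters
    ----------
    r : float
        Connectivity rate between the input layer and the neuron, in [0, 1].
    p : float
        Firing probability of an activated input neuron, in [0, 1].
    theta : int
        Firing threshold: minimum number of coincident input spikes needed
        for the neuron to fire.  The model is defined for ``theta >= 2``.
    S : int
        Number of neurons in the input layer (default 100).
    alpha : float or None
        Feedback-inhibition parameter; ``None`` disables inhibition.
        Smaller values mean stronger inhibition.
    """

    r: float
    p: float
    theta: int
    S: int = 100
    alpha: float | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.S, (int, np.integer)) and self.S >= 1):
            raise ValueError(f"S must be a positive integer, got {self.S!r}")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must be in [0, 1], got {self.r!r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p!r}")
        if not (isinstance(self.theta, (int, np.integer)) and 2 <= self.theta <= self.S):
            raise ValueError(
                f"theta must be an integer in [2, S={self.S}], got {self.theta!r}"
            )
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError(f"alpha must be positive or None, got {self.alpha!r}")


@dataclass(frozen=True)
class FiringProfile:
    """Firing behaviour of the single neuron across stimulus intensities.

    Attributes
    ----------
    per_m_firing_prob : ndarray, shape (S+1,)
        ``P(T = 1 | m)`` for every stimulus intensity ``m``.  Inhibited
        values when the profile was built with inhibition applied.
    stimulus_prior : ndarray, shape (S+1,)
        ``P(m)``; sums to one.
    marginal_firing_prob : float
        ``P(T = 1)``, the prior-weighted mean of ``per_m_firing_prob``.
    mean_firing_prob : float
        ``f``, the prior-weighted mean of the *uninhibited* firing
        probabilities; this is the drive of the feedback-inhibition rule.
    """

    per_m_firing_prob: np.ndarray
    stimulus_prior: np.ndarray
    marginal_firing_prob: float
    mean_firing_prob: float


def uniform_stimulus_prior(S: int) -> np.ndarray:
    """Uniform prior over stimulus intensities m = 0..S."""
    return np.full(S + 1, 1.0 / (S + 1))


def connected_count_pmf(r: float, S: int) -> np.ndarray:
    """Distribution of the number of connected input neurons.

    Each of the ``S`` input neurons is connected independently with
    probability ``r``, so the count ``n`` is Binomial(S, r).

    Returns
    -------
    ndarray, shape (S+1,)
        ``P(n)`` for n = 0..S.
    """
    if not (isinstance(S, (int, np.integer)) and S >= 1):
        raise ValueError(f"S must be a positive integer, got {S!r}")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r!r}")
    # log-space evaluation: scipy's binom.pmf overflows internally for
    # probabilities near the floating-point minimum
    k = np.arange(S + 1)
    if r == 0.0 or r == 1.0:
        pmf = np.zeros(S + 1)
        pmf[S if r == 1.0 else 0] = 1.0
        return pmf
    log_coef = gammaln(S + 1) - gammaln(k + 1) - gammaln(S - k + 1)
    return np.exp(log_coef + k * np.log(r) + (S - k) * np.log1p(-r))


def input_count_pmf(m: int, n: int, S: int) -> np.ndarray:
    """Distribution of the number of activated *and* connected inputs.

    Given ``m`` activated neurons and a uniformly random ``n``-subset of
    connected neurons, the overlap ``m'`` is hypergeometric:
    ``P(m') = C(m, m') C(S-m, n-m') / C(S, n)``.

    Returns
    -------
    ndarray, shape (S+1,)
        ``P(m')`` for m' = 0..S; zero outside the feasible support
        ``max(0, n+m-S) <= m' <= min(m, n)``.
    """
    if not (isinstance(S, (int, np.integer)) and S >= 1):
        raise ValueError(f"S must be a positive integer, got {S!r}")
    for name, val in (("m", m), ("n", n)):
        if not (isinstance(val, (int, np.integer)) and 0 <= val <= S):
            raise ValueError(f"{name} must be an integer in [0, S={S}], got {val!r}")
    # scipy convention: hypergeom(M=population, n=successes, N=draws)
    return stats.hypergeom.pmf(np.arange(S + 1), S, m, n)


@lru_cache(maxsize=8)
def _hypergeom_tensor(S: int) -> np.ndarray:
    """H[n, m, mp] = P(m' = mp | m, n, S); cached per layer size."""
    idx = np.arange(S + 1)
    n = idx[:, None, None]
    m = idx[None, :, None]
    mp = idx[None, None, :]
    return stats.hypergeom.pmf(mp, S, m, n)


def _input_count_matrix(r: float, S: int) -> np.ndarray:
    """M[m, mp] = P(m' = mp | m) = sum_n P(m'|m,n,S) P(n|r,S)."""
    weights = connected_count_pmf(r, S)
    return np.tensordot(weights, _hypergeom_tensor(S), axes=(0, 0))


def _fire_given_input(p: float, theta: int, S: int) -> np.ndarray:
    """P(at least theta of m' inputs spike), for m' = 0..S."""
    return stats.binom.sf(theta - 1, np.arange(S + 1), p)


def _per_m_firing(params: EncodingParams) -> np.ndarray:
    """Uninhibited P(T=1|m) for m = 0..S."""
    M = _input_count_matrix(params.r, params.S)
    return np.clip(M @ _fire_given_input(params.p, params.theta, params.S), 0.0, 1.0)


def firing_prob_given_m(m: int, params: EncodingParams) -> float:
    """Uninhibited firing probability of the neuron at stimulus intensity m.

    ``P(T=1|m) = sum_{m'} P(spikes >= theta | m') sum_n P(m'|m,n,S) P(n|r,S)``.
    Monotone non-decreasing in m, p and r; non-increasing in theta.
    """
    if not (isinstance(m, (int, np.integer)) and 0 <= m <= params.S):
        raise ValueError(f"m must be an integer in [0, S={params.S}], got {m!r}")
    return float(_per_m_firing(params)[m])


def inhibition_probability(alpha: float, f: float) -> float:
    """Per-spike deletion probability ``P_I = exp(-alpha / f)``.

    ``f`` is the average firing probability driving the feedback loop.
    Strictly increasing in ``f`` and decreasing in ``alpha`` (smaller alpha
    = stronger inhibition).  Defined as 0 at ``f = 0``: no activity, no
    feedback.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha!r}")
    if f < 0:
        raise ValueError(f"f must be non-negative, got {f!r}")
    if f == 0:
        return 0.0
    return float(np.exp(-alpha / f))


def apply_inhibition(
    firing_prob: float | np.ndarray,
    alpha: float,
    f: float,
    mode: InhibitionMode = "scaled",
) -> float | np.ndarray:
    """Firing probability after feedback inhibition.

    Modes
    -----
    ``"scaled"`` (default)
        ``q * (1 - P_I)``: each spike independently survives with
        probability ``1 - P_I``.
    ``"subtractive"``
        ``max(q - P_I, 0)``: the deletion probability is subtracted from
        the firing probability, silencing weakly driven states outright.
    ``"scaled-const"``
        ``q * (1 - exp(-alpha))``: the activity-independent variant in
        which the deletion probability ignores ``f``.

    The result never exceeds the uninhibited probability and converges to
    it as ``alpha -> inf``.
    """
    if mode not in _INHIBITION_MODES:
        raise ValueError(f"mode must be one of {_INHIBITION_MODES}, got {mode!r}")
    q = np.asarray(firing_prob, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("firing_prob must be in [0, 1]")
    if mode == "scaled-const":
        out = q * (1.0 - np.exp(-alpha))
    else:
        pi = inhibition_probability(alpha, f)
        if mode == "scaled":
            out = q * (1.0 - pi)
        else:
            out = np.maximum(q - pi, 0.0)
    if np.isscalar(firing_prob):
        return float(out)
    return out


def firing_profile(
    params: EncodingParams,
    prior: np.ndarray | None = None,
    inhibition_mode: InhibitionMode = "scaled",
) -> FiringProfile:
    """Full firing profile of the neuron, inhibition applied if configured."""
    prior = _check_prior(prior, params.S)
    q = _per_m_firing(params)
    f = float(prior @ q)
    if params.alpha is not None:
        q = np.asarray(apply_inhibition(q, params.alpha, f, inhibition_mode))
    return FiringProfile(
        per_m_firing_prob=q,
        stimulus_prior=prior,
        marginal_firing_prob=float(prior @ q),
        mean_firing_prob=f,
    )


def _check_prior(prior: np.ndarray | None, S: int) -> np.ndarray:
    if prior is None:
        return uniform_stimulus_prior(S)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (S + 1,):
        raise ValueError(f"prior must have length S+1={S + 1}, got {prior.shape}")
    if np.any(prior < 0) or abs(prior.sum() - 1.0) > 1e-9:
        raise ValueError("prior must be a probability vector summing to 1")
    return prior


def _binary_mi_bits(q: np.ndarray, prior: np.ndarray) -> float:
    """I(T; m) for a binary channel, with the 0 log 0 = 0 convention."""
    pt1 = float(prior @ q)
    total = 0.0
    for cond, marg in ((q, pt1), (1.0 - q, 1.0 - pt1)):
        # sum_m P(m) * cond_m * log(cond_m / marg)  ==  KL contribution
        total += rel_entr(prior * cond, prior * marg).sum()
    return float(total / np.log(2.0))


def mutual_information(
    params: EncodingParams,
    prior: np.ndarray | None = None,
    inhibition_mode: InhibitionMode = "scaled",
) -> float:
    """Mutual information I(T; m) between output and stimulus intensity.

    Computed from the joint distribution ``P(m) P(t|m)``; in [0, 1] bits
    since the output is binary.  Zero when the output is independent of the
    stimulus (e.g. ``r = 0`` or ``p = 0``).
    """
    profile = firing_profile(params, prior, inhibition_mode)
    return _binary_mi_bits(profile.per_m_firing_prob, profile.stimulus_prior)


def mi_surface(
    r_values: Sequence[float] = DEFAULT_R_GRID,
    p_values: Sequence[float] = DEFAULT_P_GRID,
    theta_values: Sequence[int] = DEFAULT_THETA_GRID,
    alpha_values: Sequence[float | None] = (None,),
    S: int = 100,
    prior: np.ndarray | None = None,
    inhibition_mode: InhibitionMode = "scaled",
) -> pd.DataFrame:
    """Mutual-information surface over a parameter grid.

    Returns a table with one row per (r, p, theta, alpha) combination and
    columns ``r, p, theta, alpha, mi_bits`` (alpha is NaN for the
    no-inhibition rows).  Deterministic.
    """
    for name, vals in (("r_values", r_values), ("p_values", p_values),
                       ("theta_values", theta_values), ("alpha_values", alpha_values)):
        if len(vals) == 0:
            raise ValueError(f"{name} must be non-empty")
    prior_arr = _check_prior(prior, S)
    rows = []
    for r in r_values:
        M = _input_count_matrix(r, S)
        for theta in theta_values:
            for p in p_values:
                q0 = np.clip(M @ _fire_given_input(p, theta, S), 0.0, 1.0)
                f = float(prior_arr @ q0)
                for alpha in alpha_values:
                    if alpha is None:
                        q = q0
                    else:
                        q = np.asarray(apply_inhibition(q0, alpha, f, inhibition_mode))
                    rows.append(
                        (r, p, theta, np.nan if alpha is None else alpha,
                         _binary_mi_bits(q, prior_arr))
                    )
    return pd.DataFrame(rows, columns=["r", "p", "theta", "alpha", "mi_bits"])


def optimal_alpha_mi(
    r_values: Iterable[float],
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    theta: int = 2,
    S: int = 100,
    p_values: Sequence[float] = DEFAULT_P_GRID,
    prior: np.ndarray | None = None,
    inhibition_mode: InhibitionMode = "scaled",
) -> dict[float, float]:
    """Inhibition parameter maximizing mean MI over the p grid, per r.

    Ties are broken toward the smallest alpha.  Returns ``{r: alpha}``.
    """
    alpha_grid = list(alpha_grid)
    r_values = list(r_values)
    if not alpha_grid or not r_values:
        raise ValueError("alpha_grid and r_values must be non-empty")
    if any(a is None or a <= 0 for a in alpha_grid):
        raise ValueError("alpha_grid entries must be positive")
    table = mi_surface(
        r_values=r_values, p_values=p_values, theta_values=[theta],
        alpha_values=alpha_grid, S=S, prior=prior, inhibition_mode=inhibition_mode,
    )
    result: dict[float, float] = {}
    for r in r_values:
        sub = table[table["r"] == r].groupby("alpha")["mi_bits"].mean()
        means = sub.reindex(alpha_grid)
        # argmax with ties toward the smallest alpha: first occurrence wins
        best = means.index[int(np.argmax(means.to_numpy()))]
        result[r] = float(best)
    return result
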