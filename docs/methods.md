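# Methods

This note records the mathematical model, the simulation conventions, the
numerical choices, and the known limitations of `dgpatsep`.

## 1. Single-neuron encoding model

A binary output neuron listens to a layer of `S` input neurons (default
`S = 100`).  The stimulus is the number `m` of activated inputs,
distributed uniformly over `0..S` unless a different prior is supplied.

Three independent sources of randomness shape the response:

1. **Connectivity.** Each input neuron is connected to the output neuron
   independently with probability `r`, so the number of connections `n`
   is `Binomial(S, r)`.
2. **Overlap.** Given `m` activated inputs and a uniformly random
   `n`-subset of connected inputs, the number `m'` of activated *and*
   connected inputs is hypergeometric,
   `P(m' | m, n, S) = C(m, m') C(S-m, n-m') / C(S, n)`.
3. **Spiking.** Each of the `m'` relevant inputs spikes independently
   with probability `p`; the output fires when at least `theta` of them
   spike (`theta >= 2` by construction of the model).

The firing probability is the exact mixture

```
P(T=1 | m) = sum_{m'} P(Binom(m', p) >= theta)
             * sum_n Hypergeom(m' | m, n, S) Binom(n; S, r).
```

Analytically the inner mixture collapses to `Binomial(m, r)` (each
activated input is independently connected); the package evaluates the
full mixture and uses the collapse as a property-test oracle only, so the
two derivations check each other.

**Encoding efficiency** is the mutual information `I(T; m)` in bits
between the binary output and the stimulus intensity, computed from the
joint table `P(m) P(t|m)` with the `0 log 0 = 0` convention.  It is
bounded by 1 bit because the output is binary.

**Feedback inhibition** deletes each output spike with probability
`P_I = exp(-alpha / f)`, where `f` is the neuron's prior-mean uninhibited
firing probability.  Smaller `alpha` means stronger inhibition.  The
default mode multiplies the firing profile by `1 - P_I` ("scaled");
"subtractive" (`max(q - P_I, 0)`) and "scaled-const"
(`q * (1 - exp(-alpha))`, `f`-independent) variants are selectable.

Because the scaled veto is a thinning that does not depend on `m`, the
inhibited output is a Markov degradation of the uninhibited one; by the
data-processing inequality MI is monotone increasing in `alpha`, so the
MI-optimal `alpha` on any grid is the largest (weakest-inhibition) value.
This is a theorem about the model, not a numerical artifact; see the
repository's acceptance report for the consequences.

## 2. Two-layer spiking network

Geometry (defaults, chosen as the package's reference problem size):
800 input-layer (EC) neurons project to 4000 granule cells (DG) through
random Bernoulli wiring with rate `r`.  Forty pairwise-disjoint patterns
of 20 EC neurons are presented one at a time for 500 bins of 10 ms; an
activated EC neuron spikes i.i.d. per bin with probability `p`.

Each granule cell is a discrete-time leaky integrate-and-fire unit on the
bin grid: the membrane decays by `exp(-bin_ms / tau_m)` per bin, then
integrates the bin's connected input spikes with EPSP amplitude
`(v_threshold - v_rest) / spikes_to_threshold`; reaching threshold emits
a spike and resets the membrane.  In the memoryless limit `tau_m -> 0`
the rule reduces exactly to "spike iff at least `spikes_to_threshold`
inputs spike in the bin", which ties the network back to the
single-neuron model's threshold `theta` (tested).

**Feedback inhibition** in the network deletes each candidate DG spike
independently with probability `exp(-alpha / f)`, where `f` is the
cell's mean connected-input spike count per bin over the presentation
(total connected EC spikes / number of bins).  Deletion draws come from a
dedicated RNG stream so toggling inhibition does not perturb wiring,
pattern choice, or EC spiking.

### Granule-cell defaults

`spikes_to_threshold = 10`, `tau_m = 10 ms`.  These were fixed once,
before the acceptance computations, by mapping the qualitative operating
regime over `spikes_to_threshold ∈ {3, 5, 8, 10, 12, 15}` ×
`tau_m ∈ {10, 30} ms` with reduced sweeps and selecting on three
pre-stated structural criteria: (a) the separation-versus-`p` trend must
change sign in the interior of the connectivity grid, (b) feedback
inhibition must improve grid-averaged separation, and (c) the population
must operate well below saturation.  Lower thresholds or slower
membranes saturate the population over 500-bin presentations (every cell
responds to every pattern, grid-mean separation ≈ 0.08, no increasing
trends), which destroys the phenomenon the model exists to study.  The
chosen point gives grid-mean separation 0.59 → 0.65 under inhibition, a
regime boundary at `r = 0.15`, and single-trial activated fractions of a
few percent at sparse operating points (e.g. 2.4 % at `r = 0.1`,
`p = 0.5`).

## 3. Separation efficiency

For an activation matrix over `L` patterns (entry 1 when a cell spikes at
least once during a presentation), with `N_i` the number of patterns
recruiting cell `i` and `K` the number of cells with `N_i > 0`:

```
S = (1/K) * sum_{i : N_i > 0} (1 - N_i / L)   in [0, 1].
```

`S = 1 - 1/L` when every activated cell is pattern-specific; `S = 0` when
every activated cell responds to all patterns.  `S` is undefined at
`K = 0`: the statistic returns NaN with a warning, while trial averages
used for trend tests and the `alpha` search adopt the **zero-fill
convention** (a silent trial counts as `S = 0`), reported in a dedicated
`mean_separation_zerofill` column beside the NaN-dropping mean.  An
unreduced "literal" double-sum variant (not confined to `[0, 1]`) is
retained behind a flag for comparison only.

The firing frequency of activated cells is
`total spikes / (n_bins * number of activated (cell, presentation) pairs)`,
a spike probability per 10 ms bin.

## 4. Factorized sweep engine

Grid sweeps use an exact distributional factorization: with disjoint
patterns and i.i.d. Bernoulli wiring, a (cell, pattern) response depends
on the wiring only through `k ~ Binomial(pattern_size, r)`, the number of
connections into the presented pattern, and candidate LIF dynamics do not
depend on `alpha`.  The engine pre-simulates a pool of LIF trajectories
per `(k, p)` (default 1000 per `k`), then draws each trial's
`(cell, pattern)` table of `k` values, indexes the pool, and applies the
Bernoulli deletion per `alpha` (`retain = 1 - exp(-alpha/f)` with the
pool entry's own `f`).  This is statistically equivalent to the full
per-cell simulation up to pool-reuse correlations (tested against the
full engine, which remains available via `method="full"`), and it makes
the full stated grids — 10 connectivity rates × 9 input rates × 21
inhibition levels × 20 trials — run in about six minutes on one CPU.

## 5. Numerical choices

- Binomial pmfs are evaluated in log space (`gammaln`) to avoid
  overflow in library routines at probabilities near the floating-point
  minimum; hypergeometric terms use `scipy.stats.hypergeom`.
- MI uses `scipy.special.rel_entr` on the joint table, giving the
  `0 log 0 = 0` convention for free and non-negative rounding behavior.
- All randomness derives from `numpy.random.SeedSequence` spawning named
  substreams (`connectivity`, `patterns`, `ec`, `inhibition`), so results
  are bit-reproducible given a seed and individual sources can be varied
  independently.
- Trial averages report the standard error across trials; sweep tables
  carry trial counts and silent-trial counts alongside the means.

## 6. Limitations

- The inhibition model is a post-hoc independent thinning, not a
  dynamical interneuron; consequences (MI monotone in `alpha`; the
  separation optimum pinned at strong inhibition for zero-filled grid
  averages) follow from that structural choice.
- EC spiking is i.i.d. Bernoulli per bin: no refractoriness, bursting,
  or temporal correlation on the input side.
- Patterns are pairwise disjoint; overlapping-pattern generalization and
  pattern completion are out of scope.
- The LIF granule cell has no synaptic conductances, adaptation, or
  lateral excitation; `refractory_bins` defaults to 0.
- The factorized engine reuses pool trajectories within a trial, which
  introduces weak positive correlations between cells sharing a pool
  entry; the full engine is the ground truth when that matters.
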