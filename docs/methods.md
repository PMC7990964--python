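# Methods

## Model overview

The package models aversive olfactory conditioning as a single learned
scalar: the synaptic strength `w` of the KC→MBON pathway carrying the
conditioned odor. The odor indicator `o(t) ∈ {0, 1}` and shock voltage
`S(t) ≥ 0` are defined on a uniform grid by the protocol builders; the odor
value is `v = w·o` and the internal shock representation follows the
Weber–Fechner law `s = α·log(S/S₀)` for `S ≥ S₀`, zero below the detection
threshold. A Stevens-law alternative `s = (S/S₀)^α` is available behind the
`law` switch; it is zeroed below threshold as well (the power-law form itself
would give 1 at threshold — the discontinuity is a documented convention,
and all fitting uses the Weber–Fechner pathway). Behavior is a memoryless
Bernoulli readout: a fly avoids the conditioned odor with probability
`p_cs(v) = 1/(1+e^{−v})`, so the expected learning index is `tanh(v/2)` and,
when learning converges (`v → s`), the LI converges to the unconditioned
performance index `PI(S)`.

## Plasticity rules and the adaptive learning rate

Five weight-update rules are implemented (predictive, Hebbian, linear STDP,
nonlinear STDP, covariance; see the module docstring of
`mbpredict.plasticity` for the equations). The presynaptic eligibility trace
`õ` and shock trace `s̃` are first-order low-pass filters of `o` and `s`.
The learning rate adapts: a step increase `Δs` of the shock representation
bumps `η` by `Δη·Δs` and `η` otherwise decays with time constant `τ_η`. The
AIC comparison uses the adaptive-rate variant of every rule, matching the
free-parameter counts of the fitted summaries (predictive 5, Hebbian 5,
linear STDP 8 — one rate process per branch — nonlinear STDP 10, covariance
6). Fixed-rate variants are implemented and exposed for completeness.

Conventions chosen where the source equations leave freedom:

* `η(0) = 0` for adaptive-rate rules (a naive fly; all drive comes from
  shock onsets). Configurable via `eta_init`.
* The two STDP rate processes are paired one-per-branch
  (`(Δη₁, τ_η₁)` with the potentiating term, `(Δη₂, τ_η₂)` with the
  depressing term).
* The weight is not clipped; transiently negative `w` is permitted
  (`clip_weight=True` restores clipping at 0).
* Learning is not simulated during the choice test; the readout uses
  `w(train_end)`.
* The CS− odor period is part of every protocol timeline but carries no
  odor flag: the single-weight model tracks the CS+ pathway only.

## Numerical integration

Explicit Euler for `w` with exact exponential updates for the filters and
the rate decay. The state recorded at `t_i` is the pre-update value; the
input held on `[t_i, t_i + dt)` drives the filter state at `t_{i+1}`, which
makes the filter output the exact ODE solution for piecewise-constant input
(a step response hits `1 − e^{−1}` at exactly one time constant). Default
grid `dt = 0.01 s` — both pulse durations (1.5 s and 1.25 s) are exact
multiples — with a dt-halving convergence test requiring end-weight changes
below `1e-3` across the full 28-condition battery. Divergence (`|w| > 1e6`
or non-finite) aborts a single integration with a diagnostic and propagates
as an infinite objective during fitting. The battery integrations run in a
compiled (numba) core; a recording integrator and the fast battery path are
cross-checked against each other and against a hand-stepped scalar oracle.

## Protocols

Pulses occupy half-open intervals `[onset, onset + duration)`. Sequence
packagings distribute `n ∈ {1, 2, 4, 8}` pulses of `100/n` V across the
60 s CS+ window: onsets 15 s apart for `n ≤ 4` (the spacing printed for the
repeated-training blocks) and `60/n` s for `n = 8`, referenced by pulse end
for end-alignment and by pulse onset for beginning-alignment. Repeated
training uses 150 s blocks (60 s CS+ with pulses ending at 15/30/45/60 s,
30 s air, 60 s CS−) separated by 90 s, with a 90 s break before `train_end`;
the half block carries two pulses ending at 45 and 60 s. Continuous pairing
holds the voltage on for the whole CS+ window. Trace conditioning presents
10 s of odor followed, after a variable inter-stimulus interval, by four
1.25 s pulses of 90 V at 0.2 Hz. The fixed battery enumerates 8 sequence,
8 repeated and 12 continuous conditions (28 in total), in a documented
order.

## Fitting and model comparison

The objective is the mean squared error between the model's analytic
expected LI (`tanh(w_end/2)`, deterministic and smooth) and the
per-condition mean LI of a dataset. The stochastic population simulation is
used for generating data and for variance studies, not inside the
objective — the "model mean" is available in closed form and the optimizer
needs smoothness.

Fits run the battery at `dt = 0.05 s`: the integration error there
(~`1e-3` in `w`) is far below the sampling noise of the synthetic
per-condition means (σ ≈ 0.04 at 80 flies × 8 trials). Optimization is
multi-start bounded L-BFGS-B with the original protocol's iteration cap
(3000) and tolerance (`1e-6`). Because the free parameters span five orders
of magnitude (rates ~0.05, time constants up to 1500 s), the search runs in
a unit cube over log-scaled parameters: starts are sampled log-uniformly
from the box `S₀ ∈ [1, 20] V`, `α ∈ [0.01, 20]`, time constants
`∈ [0.5, 1500] s`, rate increments `Δη ∈ [10⁻⁴, 10]`, STDP gains
`∈ [0.01, 20]` (enveloping every fitted value), and starts landing on the
divergence plateau are resampled before polishing. Rate increments are kept
non-negative: a negative `Δη` makes the learning rate negative and the
predictive rule anti-stable, so the bound doubles as a stability constraint.

AIC uses the natural logarithm of the MSE (after dividing the summed squared
error by n = 28): `AIC = 2k + n·log(MSE) + 2C` with
`C = (n/2)(ln 2π + 1) + 1`; reconstructing the published −AIC column from
the published (k, MSE) pairs to two decimals confirms this reading of the
formula. Relative likelihoods are `exp(ΔAIC/2)` against the minimum-AIC
model.

## Synthetic data

The experimental per-condition LI means exist only as figure points, so the
generator emulates them: expected LI per condition from a ground-truth rule,
then Bernoulli counts for `n_fly = 80` flies × `n_trial = 8` trials
(group sizes inside the reported 60–100 range; per-condition trial counts
are not printed and are free fixture parameters). One master seed spawns an
independent substream per condition, making datasets bit-reproducible and
stable under battery extension. The canonical fixture
(`make_paper_fixture(0)`) is committed as package data and regenerated
bit-identically in the tests.

What the generator deliberately does **not** emulate: extra experimental
variance beyond the Bernoulli choice model (real flies show equal or larger
LI variance than the 1-state Markov model), flies remaining in the test
tube (<5%; indices are defined on choosers only), odor-identity
counterbalancing, and CS−-pathway plasticity. Passing recovery tests
therefore show that the pipeline identifies the generating rule under the
model's own noise assumptions — not that it would do so under all real-data
noise sources.

## Circuit models

Both mushroom-body circuits use leaky rate neurons with `τ = 10 ms`,
integrated on a 1 ms grid (stability guard `dt ≤ τ/2`); circuit-level
simulations use the faster published rate process (`τ_η = 26.7 s`,
`Δη = 0.74`). The error-driven circuit reproduces the phenomenological
predictive rule's learned weight to better than 2% on battery protocols
(separation of timescales), settles at `e = s − v` with frozen weights, and
shows the negative prediction error at the odor-alone test. The
target-driven circuit's odor-alone steady state matches
`(1−λ)/(1−λ(1−λ))·s₀` (≈ 0.99 at λ = 0.1) to `1e-6`. The MBON→DAN
plasticity uses the raw postsynaptic rate `v` as printed (no eligibility
trace of `v`); the weight appearing in both its rate and plasticity
equations is implemented as the single MBON→DAN object.

For the valence extension the saturating DAN transfer `φ` defaults to
clipping into `[0, 1]` (a logistic variant is configurable, with
`φ(0) = 0.5` as its documented difference). The novelty–familiarity rule
tracks `n_K = 100` per-synapse weights with spontaneous KC/DAN rates
`o₀ = d₀ = 0.05` and MBON drive defined as the mean of `w_i·o_i`; none of
these magnitudes are experimentally pinned down — they are configurable
defaults chosen so that an odor activating ~10% of KCs at unit rate gives
`mean(õ) > 2·o₀`, the regime in which all four signed phenomena (repetition
suppression, heterosynaptic potentiation, passive recovery to
`w·o₀ = d₀`, DAN-alone potentiation) hold. The base rate `η₀` sets only the
recovery timescale; tests use a large `η₀` to reach the spontaneous
equilibrium within a short simulated window.

## Experiment sizes

The recovery experiment refits the predictive rule with 32 optimizer starts.
The model-selection experiment uses 6 starts per rule across 10 dataset
seeds; under-optimizing an alternative rule can only raise its MSE, so the
selection outcome (predictive wins) is conservative with respect to the
start count. The qualitative-pattern checks compare expected LIs for
orderings and sampled means (3σ of the binomial difference) for the
saturation claims.

## Known limitations

* The within-window pulse positions of the 2- and 8-pulse packagings are
  inferred (figure-only in the source); the 15 s / 60-per-n spacing
  convention is documented above. Under the printed parameters the expected
  LIs of the two strongest end-aligned packagings (1×100 V, 2×50 V) are
  near-coincident — the learning-rate accumulation across pulses almost
  exactly offsets the weaker per-pulse drive — so ordering claims between
  those two conditions are not meaningful.
* The exact composition of the 28 fitted conditions (8+8+12) is likewise
  inferred from the experiment descriptions.
* Fitted MSE values against the real behavioral data are not reproducible
  here (the data exist only as figure points); the published (k, MSE)
  summaries enter the AIC reconstruction as inputs.
* Blocking, odor-concentration specificity and relief learning are
  discussed qualitatively in the source material and are out of scope.
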