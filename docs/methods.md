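# Methods

This note documents the model implemented by `gamem`, the calibrated
defaults, the derivations behind the closed forms, the numerical choices,
and what the synthetic experiments do and do not establish.

## 1. The bistable memory element

Each pseudo-synapse follows the Langevin equation

    dM/dt = β Mⁿ/(Kⁿ + Mⁿ) + g − δM + σ ξ(t),   ⟨ξ(t)ξ(t′)⟩ = δ(t−t′),

i.e. cooperative positive transcriptional feedback (Hill form), linear
degradation, an additive input g contributed by external factors, and
Gaussian white noise standing in for bursty gene expression.  The model is
the rate-equation (chemical Langevin) level; elementary-reaction
stochastic kinetics are out of scope.  The boundary at M = 0 is
reflecting, since concentrations are non-negative and additive noise would
otherwise exit the domain.

Writing the drift as −dE/dM defines the energy E(M) (convention E(0) = 0),
evaluated by adaptive quadrature of the Hill term plus closed-form
polynomial terms.  In the bistable input range E has two minima and one
maximum; the energy gaps ΔE_low, ΔE_high between each minimum and the
saddle control noise-induced switching through the Kramers rate

    k = (1/2π) √(E″_well |E″_saddle|) · exp(−2ΔE/σ²).

Only the exponential dependence is treated as quantitative; the prefactor
is the standard curvature formula, and validation asserts the exponent
slope (escape-time log-linearity in ΔE/σ², slope 2 ± 15%) plus a
factor-of-two check of the mean first-passage time, not the prefactor
itself.  First passage is counted well-to-well (reaching the opposite
stable point), which is what the Kramers formula estimates; passage to the
saddle alone would be systematically faster by roughly a factor of two.

### Units and calibrated defaults

Everything is dimensionless: concentrations in units of K, time in units
of the protein lifetime 1/δ.  The shipped defaults are

| parameter | value | meaning |
|---|---|---|
| β | 1.8 | maximal feedback synthesis rate |
| K | 1 | half-activation concentration |
| n | 4 | Hill coefficient of the feedback |
| δ | 1 | degradation rate (time unit) |
| σ | 0.18 | noise magnitude |
| g_maintenance | 0.163 | symmetric landscape, equal gaps ≈ 0.113 |
| g_pairing | 0.38 | CS+US input, low-state gap ≈ 0.005 |
| g_us_alone | 0.005 | US-alone input, high-state gap ≈ 0.009 |
| trial duration | 12 | one stimulus presentation |

With δ = 0.4/min (an actively degraded regulatory protein), one time unit
is 2.5 min, a trial is 30 min, and consecutive hourly trials are separated
by a 12-unit maintenance gap.  Fixed points at maintenance are
M_low ≈ 0.164, M_unstable ≈ 0.926, M_high ≈ 1.810.

Why these values: n = 2, though supported, cannot give a balanced double
well (its low well is intrinsically shallow — gap_low ≪ gap_high
throughout the bistable range), so the default uses n = 4, whose landscape
admits a symmetric maintenance point.  σ and the encoding levels were set
with the included calibration routines (`symmetric_input`,
`calibrate_input`, both bisection on simulated switch probabilities) so
that one pairing trial flips low→high with p ≈ 0.59, one US-alone trial
flips high→low with q ≈ 0.28, and spontaneous switching at maintenance is
≈3% over a 13-trial protocol — i.e. encoding transitions dominate the
maintenance leak by well over an order of magnitude while three pairings
reliably acquire and four US-alone trials reliably extinguish an
association.  The encoding levels sit close to the saddle-node boundaries
(gaps of order σ²), so within-trial transitions are fast; the maintenance
gaps are ≈7σ², so stored states persist for days of simulated time.

### Integration

Euler–Maruyama with reflection at 0; default dt = 0.02 time units with a
stability guard dt·δ < 0.1 (violations raise an error naming a usable
step).  One root seed per run; per-trajectory child streams derive from
`numpy.random.SeedSequence.spawn`, so ensembles are reproducible and
independent of ensemble size ordering.  Long first-passage loops run in a
numba kernel with per-path seeds.

## 2. Network, encoding, retrieval

The N pseudo-synapses are identical and share one parameter set
(heterogeneity is a configuration extension, off by default).  The
multiplexer coupling maps (c_i, u) to an input level; CS alone equals no
stimulus (a naive cell shows no response to the CS, and probe trials never
alter the stored state).  The readout

    dR/dt = u·u_gain + Σᵢ cᵢ h(Mᵢ) − δ_R R,
    h(M) = cm_gain · M^h / (threshold^h + M^h)

uses a Hill AND-gate calibrated so h(M_low)/h(M_high) < 0.02 (threshold
0.545 ≈ geometric mean of the stable points, h = 8).  R carries no
intrinsic noise — stochasticity enters only through the Mᵢ; readout noise
is a known caveat for single cells but averages out in populations.
Defaults u_gain = cm_gain = δ_R = 1 put the unconditioned response and one
fully active learned pair both at R* = 1; classification thresholds the
mean of R over the second half of a probe trial (default threshold 0.5 for
single-pathway demonstrations).

In the ensemble experiments, probe responses are computed as the
steady-state sum Σᵢ sᵢ h(Mᵢ)/δ_R rather than integrating R through each
probe window: the trial-averaged R is an affine map of that sum, and the
SNR is invariant under affine maps.  Full R integration is used in
`simulate_gam` traces.

## 3. Markov approximation and single-network capacity

During one pairing trial a synapse flips low→high with probability p if
its receptor is active, high→low with probability q if inactive
(p = 1 − e^{−λ_lh T}, q = 1 − e^{−λ_hl T}).  With patterns iid
Bernoulli(f), the per-synapse chain has stationary high fraction
ρ = fp/(fp + (1−f)q) and per-pattern retention factor
λ = 1 − fp − (1−f)q.

The closed forms in `gamem.markov` were derived from the per-synapse joint
law (the printed forms in the sources this model descends from are not
recoverable) and frozen only after agreeing with the Monte-Carlo oracle:
conditioning on the probed pattern's bit and ageing through the x−1
subsequent patterns gives

    P(M = high | bit = 1, age x) = ρ + (1−ρ) p λ^{x−1},

so the response to the learned pattern is Binomial(N, μ_x) with
μ_x = f(ρ + (1−ρ)p λ^{x−1}) and the response to a fresh random pattern is
Binomial(N, fρ).  Signal = difference of means (exactly geometric in age,
the palimpsest property); noise = root of summed variances; capacity = the
oldest age with SNR strictly greater than 1 (ties count as forgotten; age
1 is the most recent, and random probes are reported under a sentinel
age).  The SNR is monotone decreasing in age, so the capacity search uses
geometric bracketing of the real-valued SNR = 1 crossing (λ^{x−1} extends
smoothly to real x) with integer verification; the search bound
50√N(1 + 1/(fp + (1−f)q)) sits safely beyond the geometric-decay horizon.

The (p, q) optimizer scans a 50×50 log grid on [10⁻⁵, 1]² (ties toward
smaller p + q) and polishes with Nelder–Mead on (log p, log q) against the
continuous crossing age — deterministic given its configuration.  At fixed
f the optimized capacity scales as √N (log-log slope 0.5 over
N ∈ {64 … 4096}), with optimal transition probabilities shrinking roughly
as 1/√N: large networks store more by learning more slowly.

## 4. Population capacity

Z identical cells share the stimulus sequence but flip independently.
Given the pattern history, cell states at synapse i are iid
Bernoulli(π_i), where the conditional probability π follows the random
recursion π → (1−p)π + p (bit 1, prob f) or π → (1−q)π (bit 0).  The law
of total variance splits the per-cell response variance into

    Var(r/Z) = N·E[s π(1−π)]/Z  (private; vanishes as Z→∞)
             + N·Var(s π)       (shared; irreducible).

First and second moments of π (stationary and age-conditioned) follow from
the linear moment maps of the recursion in closed form; the tests verify
them against exact two-step enumeration, fixed-point iteration, and direct
simulation, and the population Monte-Carlo samples responses exactly as
sums of Binomial(Z, π_i) draws (with an explicit per-cell simulation
cross-checked against the binomial route at small Z).

**When does the population beat √N?**  The shared per-synapse component
for a random probe is f·Var(π) + f(1−f)ρ² — an encoding-fluctuation term
and a probe-realization term.  Scanning q/p at fixed f
(`shared_variance_scan`) shows the ρ² term dominates unless the high→low
flux is large relative to the sparseness ((1−f)q ≳ 2f(1−f), driving
ρ → 0).  At fixed moderate sparseness (f = 0.2) the ρ² term caps the
optimized Z→∞ slope near 0.6 over N ∈ {64 … 4096} (and 0.5
asymptotically).  In the sparse-stimulus regime f = c/N — the regime this
package adopts for the population scaling experiment, with c = 2 — the
probe term is subdominant, the optimal q scales as 1/N (vs 1/√N for the
single network), and the capacity is proportional to N (measured slope
0.98).  Both regimes are exposed (`--sparse/--fixed-f`), and the
population capacity exceeds the single-network capacity at every N in
either regime.

## 5. Synthetic stimuli

Patterns are iid Bernoulli(f) bits (the modeled stimulus statistics); an
exact-count variant (round(fN) active bits) exists for variance-reduction
experiments only.  Trials are piecewise-constant input windows (default 30
min, classified on their second half, 15 min); between trials all inputs
are at maintenance.  The conditioning schedule (US; CS probe; 3 pairings;
2 probes; 4 US-alone; 2 probes, hourly) is the canonical
acquisition/extinction experiment.

## 6. What the experiments show — and what they do not

The Markov-vs-dynamics comparison (N = 100, ages 1–8, 300 repetitions,
flip probabilities measured from the element by 2000-path simulation)
checks that the binary abstraction of a calibrated, well-separated
bistable landscape predicts full-dynamics retrieval statistics within
Monte-Carlo error.  It does not certify the approximation for shallow
landscapes, strong noise (σ² ≳ gaps), or trial durations comparable to the
within-well relaxation time, where partial transits blur the binary
picture.  The generator's stimuli are uncorrelated; structured or
correlated stimulus ensembles, inter-cell signaling, readout noise, and
evolutionary-timescale adaptation are all outside the model.  Problem
sizes in the shipped tests (repetition counts, N grids) were chosen to
resolve the asserted effects a few standard errors beyond their
thresholds; statistical assertions use 3·SE bands with seeded generators.

## 7. Degenerate inputs and edge cases

p = q = 0 has no stationary law (`stationary_fraction` raises; SNR is
defined as 0); p = q = 1 copies the most recent pattern exactly and stores
a single association.  Monostable input levels raise `BistabilityError`
from gap/capacity routines; inputs with no non-negative drift root are
rejected as nonphysical.  g at a saddle-node boundary yields a vanishing
gap and is excluded from calibrated couplings (all four coupling levels
must keep the element bistable; the default US-alone level is 0.005, just
inside the boundary at g = 0 where the low state degenerates onto M = 0).
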