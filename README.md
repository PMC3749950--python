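# gamem — genetic associative memory

Can a single cell, with no nervous system, learn Pavlovian associations?
`gamem` implements a model of associative learning in gene regulatory
networks built from stochastic bistable elements, for researchers in
systems and synthetic biology who want to simulate such circuits and for
theorists interested in the memory capacity of bounded, binary storage
elements.

## The model

**Memory.** A protein M activates its own synthesis through a cooperative
positive feedback loop:

    dM/dt = β Mⁿ/(Kⁿ + Mⁿ) + g − δM + σ ξ(t)

For suitable parameters the drift has three zero crossings — two stable
expression levels (M_low, M_high) separated by an unstable point — so M is
a binary memory, a "pseudo-synapse".  Writing the drift as −dE/dM, the
energy gaps ΔE between each well and the saddle set the noise-induced
transition rates exponentially, rate ∝ exp(−2ΔE/σ²).

**Encoding.** The external input g is a stochastic multiplexer: without
the unconditioned stimulus (US) it sits at a maintenance level with deep
wells on both sides, so states persist; the US alone lowers the barrier of
the high state (pushing M low), while the US together with an active
receptor C_i lowers the barrier of the low state (pushing M high).
Repeated CS+US pairings thus stochastically copy the receptor pattern of
the conditioned stimulus (CS) into the N pseudo-synapses.

**Retrieval.** A response protein R is driven by the US directly
(unconditioned response) or through cooperative C_i·M_i AND-gates
(conditioned response): dR/dt = u·r_U + Σᵢ cᵢ h(Mᵢ) − δ_R R.

**Capacity.** Approximating each pseudo-synapse by a two-state Markov
chain — flip low→high with probability p when paired with an active
receptor, high→low with probability q when the receptor is inactive — and
probing with the pattern learned x patterns ago, the retrieval
signal-to-noise ratio is

    SNR(x) = N f (1−ρ) p λ^(x−1) / √(Var_learned + Var_random),

with sparseness f, stationary high fraction ρ = fp/(fp + (1−f)q) and
retention factor λ = 1 − fp − (1−f)q.  The capacity — the oldest age with
SNR > 1 — scales as √N for a single network at optimal (p, q).  For a
clonal population of Z non-interacting networks sharing the stimuli, the
private encoding noise averages out; with sparse stimuli the capacity of a
large population grows linearly in N.

## Worked example

```python
from gamem import MarkovParams, capacity, optimize_probs
from gamem.population import PopulationParams, population_capacity

params = MarkovParams(p=0.35, q=0.15, f=0.2, N=1024)
res = capacity(params)
print("capacity:", res.capacity)
print("snr ages 1-6:", [round(v, 3) for v in res.snr_curve.values[:6]])

p, q, best = optimize_probs(0.2, 1024)
print(f"optimal p={p:.3f}, q={q:.3f}, capacity={best.capacity}")

pop = population_capacity(PopulationParams("inf", MarkovParams(p, q, 0.2, 1024)))
print("infinite-population capacity at the same parameters:", pop.capacity)
```

prints

```
capacity: 7
snr ages 1-6: [3.409, 2.815, 2.318, 1.904, 1.56, 1.276]
optimal p=0.235, q=0.104, capacity=7
infinite-population capacity at the same parameters: 11
```

At N=1024 pseudo-synapses and sparseness 0.2, a single network holds 7
associations before the retrieval SNR of the oldest drops below 1 (the
curve decays geometrically with the age of the memory — newer memories
overwrite older ones).  An infinite population of identical cells, with no
interaction between them, holds 11 at the same per-cell parameters, and
far more once (p, q) are re-optimized for the population.

The same computations are available from the shell:

```
gamem capacity --f 0.2 --N 1024 --optimize --out capacity.json
gamem scaling-experiment --mode population --n-list 64,256,1024,4096 --out scaling.csv
gamem simulate-gam --config examples/run.yaml --out run/
gamem validate            # oracle-agreement suite; exit 1 on failure
```

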