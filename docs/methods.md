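# Methods

## Model

A diploid, randomly mating Wright–Fisher population of census size `N`
carries a quantitative trait determined additively by unlinked loci:
an individual's genetic value is `G_i = Σ_l a_l g_il` over segregating
loci plus a substitution offset (the summed `2a` of loci fixed since the
reference epoch), and its phenotype adds an optional environmental
deviate of sd `env_sd`. Fitness is Gaussian around an optimum:
`exp(−(z−opt)²/(2w²))`; `w²` plays the role of the usual
stabilizing-selection variance `V_S`. Mutations arise at rate `U` per
diploid genome per generation at fresh sites (infinite sites), with
effects drawn from a symmetric mean-zero distribution; loci segregate
independently (free recombination).

When the population mean sits at the optimum, the marginal fitnesses of
the three genotypes at a locus of effect `a` are
`1 − c·(g − 2p)²·a²/a²`-quadratic with `c = a²/(2(w² + V_P))`, which
yields the deterministic per-generation frequency change

    Δp = c p q (2p − 1) / (1 − 2 c p q).

`p = 1/2` is an unstable equilibrium: stabilizing selection on the trait
is underdominant at the locus level, and the expected per-generation
loss of heterozygosity is `(1/2N) + c (1 − 2p)²` once drift is included.
The population-scaled strength is `S = 2 N a² / w²`.

## Analytic layer

Three routes to the retention of ancestral heterozygosity/variance:

1. **Closed forms.** `(1 − 1/2N)^t (1 − a²/(4(w²+V_P)))^t` and its
   exponential equivalent `exp(−F_ST (1 + S/4))` with `F_ST = t/2N`.
   These replace `(1−2p)²` by its nominal value 1/2 and are therefore
   frequency-independent approximations.
2. **Wright–Fisher matrix.** The full `(2N+1)`-state transition matrix
   with the deterministic Δp folded into the binomial resampling
   probability, iterated from the stationary distribution of segregating
   counts under unit mutational influx at count 1 (solved as a linear
   system). Exact for the finite-N model; limited to `N ≤ 500`.
3. **Diffusion.** The backward Kolmogorov operator
   `L g = m g' + (v/2) g''` with `m = (S/2) x(1−x)(2x−1)`,
   `v = x(1−x)` (time in units of `2N` generations), discretized with
   nonuniform central differences on a Chebyshev-extrema frequency grid
   (dense near the absorbing boundaries) and integrated by
   Crank–Nicolson (`dt = 10⁻³`, banded solves). Propagating the
   heterozygosity functional `h = 2x(1−x)` gives `E[H_τ | x₀]`;
   integrating against the stationary sojourn density
   `t(x) ∝ (Sc_T − Sc(x)) / (x(1−x) ψ(x))`, `ψ = exp(S x(1−x))`,
   entry at `p₀ = 1/(2N)`, gives the retention `R(a, t)`.

Routes 2 and 3 agree within ~1% for `S ≤ 20`, `t/2N ≤ 0.1`; the closed
forms track them within ~2% for `S ≤ 8` but undershoot the true decay
by ~20% at `S = 20`, where the surviving-allele mass is concentrated
near the frequency boundaries and `E[(1−2p)²]` is far above 1/2. The
package exposes both tiers deliberately: the closed forms for intuition
and cheap bounds, the diffusion for quantitative prediction.

The equilibrium density of genic variance by effect size is
`v(a) = N U · 2μ(a) · a² · ∫ 2x(1−x) t(x; S(a)) dx`, checked for mass
conservation by grid doubling (rejected if the total shifts by more
than 0.2%). In the neutral limit it reduces to `v(a) ∝ μ(a) a²` and its
integral to the classic `2 N U E[a²]`.

Cross-population predictions treat each ancestral locus's two
descendant lineages as independent diffusions from the shared ancestral
frequency: the variance a score ascertained in A explains in B sums
`E[H_B | x₀] · P(ascertained in A | x₀)` over the stationary density,
with the ascertainment probability obtained by propagating the
scheme's indicator function (all segregating; per-locus variance above
the top-`q` equilibrium threshold; MAF above `m`). For subset schemes
the A-side variance share is evaluated at equilibrium, which is exact
at `t = 0` and a good approximation while A's locus distribution has
re-equilibrated (the simulator is the arbiter in tests).

## Simulator implementation

Per generation: phenotypes → Gaussian fitness → multinomial parent
sampling → independent Mendelian transmission per locus (two
`Bernoulli(g/2)` draws via vectorized uniform comparisons) → Poisson
`N·U` new mutations at fresh sites → absorption bookkeeping (lost loci
dropped; fixed loci folded into the substitution offset, `+2a` each).
Neutral markers (zero effect) travel through the same pedigree and are
sampled fresh at the split, so the marker panel is polymorphic in the
ancestor. F_ST is estimated from them with a Hudson-type
ratio-of-averages using population frequencies, including boundary
frequencies of markers absorbed after the split.

**Warm start.** `init="stationary"` samples segregating loci from the
single-locus stationary density (count Poisson with mean
`N U E[T_sojourn]`, effects accept–rejected by expected lifetime,
frequencies inverse-CDF sampled from the sojourn density bucketed on an
S grid) with Hardy–Weinberg genotypes, then zeroes the mean phenotype
via the reference offset. This is exact for a neutral trait and leaves
only weak multi-locus couplings to relax under selection, so burn-ins
of order `N`–`2N` generations suffice instead of `10N` from a cold
start. A cold start with the default `burn_in = 10N` remains available.

**Stationarity flag.** After burn-in the V_a series over the last `N`
generations is regressed on time; the run is flagged non-equilibrated
when the fitted drift is both statistically clear (p < 0.01) and larger
than half the mean level, or when `U = 0` (no equilibrium exists). V_a
relaxes on the coalescent timescale, so any sharper test rejects
stationary-but-wandering series; the flag is deliberately low-power and
meant to catch decaying or grossly under-equilibrated runs.

**Desk scaling.** Effect-size sds are quoted at a reference size of
10 000 diploids; at smaller `N` sampled effects are multiplied by
`sqrt(10000/N)`, preserving every allele's `S`, and divergence is
measured in `t/2N`. Retention curves, accuracy ratios and the Q_X null
are invariant under this rescaling (tested); the segregating locus
count is not (it scales with `N U log 2N`), which matters only for
count-based quantities such as the top-5% variance share — those are
computed at the `N` stated below.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| `N` | 1000 (sim), 10 000 (theory reference) | desk scale preserving S; full scale by config |
| `w` | 5 (phenotype units) | intermediate selection; `w=4` strong, `None` neutral |
| `U` | 0.02 / diploid genome / generation | equilibrium `V_a ≈ 2Uw² ≈ 1`, so `V_P/w² ≈ 0.03–0.04 ≪ 1`, and thousands of segregating loci at full scale |
| effects | Gaussian sd 0.1 (reference scale) | typical `S ≈ 8` at `w = 5`; sd 0.05 variant for weaker selection |
| heavy tail | `0.8·N(0, 0.02) + 0.2·N(0, 0.3)` | nearly neutral bulk plus a strongly selected minority carrying a large variance share: steep early decay of ancestral variance flattening toward the neutral rate |
| `env_sd` | 0 | isolates the genetic mechanism; `V_P = V_A` |
| `neutral_loci` | 200 | few-percent relative error on F_ST at `F ≈ 0.05` |
| optimum shift | 2 phenotypic SD, both populations | measured from the equilibrated ancestor's `V_P` |

## Statistics

- `Q_X = (Z_A − Z_B)² / (4 V_a F_ST)`, `Z = 2 Σ p a` over ascertained
  loci including boundary frequencies (a fixed locus contributes `2a`).
  The standardizing `V_a` uses frequencies averaged across the two
  populations (`2 p̄ (1−p̄) a²` per ascertained locus), symmetric in A
  and B and equal to the usual V_a when they coincide; population-A
  frequencies are available as a sensitivity switch. F_ST defaults to
  the marker estimate, with the expected `t/2N` as an option. The
  neutral null is χ² with one degree of freedom (two populations), and
  `(|Z_A−Z_B|/√V_a)² = 4·Q_X·F_ST` holds algebraically on every record.
- Two-deme `Q_ST = B/(B + 2W)` with `B = (Z̄_A − Z̄_B)²` (substitution
  offsets included) and `W` the mean within-population variance of
  genetic values; its neutral expectation is `2 F_ST` as `F_ST → 0`.
  Because `B` has a single degree of freedom, per-replicate ratios are
  Jensen-biased (≈ 25% low at `F = 0.05`); ensemble summaries therefore
  pool `B` and `W` across replicates before forming the ratio, and a
  large ensemble is used (the pooled `B` is χ²₁-skewed, so the ratio's
  Monte-Carlo error only shrinks as `sqrt(2/replicates)`). The pooled
  estimator still carries the intrinsic finite-divergence saturation
  `2F/(1+2F)`, ≈ −9% at `F = 0.05`, partly offset by the downward bias
  of the marker F̂; the measured ratio at the study conditions centres
  near 1.8–1.9 rather than exactly 2, which is the finite-divergence
  value of the statistic, not an estimation error.

## What the generator does and does not emulate

The synthetic populations reproduce the statistical structure the
analysis assumes: mutation–selection–drift equilibrium, unlinked loci,
perfectly known effects, a clean two-population split without
migration, shared environments, strictly additive traits. They do not
emulate linkage or LD tagging (the Bulmer effect is excluded by
design — the LD term of `V_A` is tracked and verified small, not
modelled), effect-size estimation error, stratification, GxE/GxG, or
pleiotropy. Passing tests therefore demonstrate the selective mechanism
in isolation; they say nothing about how much of the *empirical*
portability gap this mechanism explains.

## Problem sizes used in tests and the acceptance script

Neutral-retention and Q_X-null ensembles: `N = 500`, 100 and 500
replicates. Q_ST/F_ST: `N = 500`, `t = 0.05·2N`, 200 replicates in the
test and 2400 in the acceptance script (see the Monte-Carlo argument
above). Top-5% variance share: `N = 1000`, 50 replicate equilibria,
warm-started and settled for `N` generations. Optimum-shift false
signals: `N = 500`, `w = 4`, 150 replicates over
`t/2N ∈ {0.025, 0.05, 0.1, 0.15}`; at this scale the run demonstrates
the inflation (false-positive rate significantly above 5%, peaking well
below the strong-selection ceiling of ~30–35%) rather than a
full-scale rate curve.

## Known limitations

- The diffusion layer treats loci independently given the trait-level
  parameters; the weak multi-locus coupling that keeps the mean at the
  optimum is present only in the simulator (visible as the
  compensating non-ascertained score differences).
- The closed forms are not quantitative beyond `S ≈ 8` (see above).
- The stationarity diagnostic has deliberately low power; it cannot
  certify equilibrium, only flag clear departures.
- Subset-scheme analytic portability uses the equilibrium A-side share;
  at large `t/2N` combined with very heavy tails this approximation
  degrades and the simulator should be preferred.
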