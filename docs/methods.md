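# Methods

## Model

Each population is haploid Wright–Fisher: N transmitting lineages, discrete
non-overlapping generations, constant size, no mutation, no selection. The
state is the carrier frequency p of a single Y-haplogroup; one generation is
a with-replacement resample of the whole pool, so the next carrier count is
Binomial(N, p). Frequencies 0 and 1 are absorbing. The production code draws
the binomial count directly instead of resampling N individual labels; the
two are distributionally identical, and the literal label-resampling form is
kept (`drift_step_literal`) as the independent oracle the test suite checks
the shortcut against (chi-square homogeneity at N = 50 on 10⁴ one-step
draws).

Admixture is a single pulse: the recipient frequency becomes
(1−α)·p_recipient + α·p_source in one generation, rounded to the nearest
multiple of 1/N so that drift resumes from an integral allele count. The
source is unchanged — under constant population sizes the pulse is a
replacement of part of the recipient pool, not a transfer that depletes the
source. The rounding choice matters at most 1/N = 2×10⁻⁴ and is invisible at
the reported precision.

Observed samples are binomial draws of the observed sample size from the
final-generation population frequency. A simulated sample frequency f
matches an observed population when |f − p_adj| ≤ 2·√(p_adj(1−p_adj)/2n)
(closed interval), where p_adj is the observed frequency, replaced by
1/(n+1) when the observed count is zero. Two conventions deserve comment:

- The tolerance denominator is 2n, not the textbook binomial-SE n. The 2n
  form is kept as the canonical rule of this framework;
  `tolerance_variant="textbook"` switches to the conventional SE (a √2-wider
  band) for sensitivity analysis.
- The zero rule 1/(n+1) is the standard pseudo-count reading; at the
  Indo-European pool (0 of 2677) it yields p_adj = 1/2678 and a band that
  admits simulated samples with 0, 1 or 2 carriers and rejects 3.

## Parameters

| parameter | default | meaning |
|---|---|---|
| N (`effective_size`) | 5000 | haploid lineages per population; sets drift variance p(1−p)/N per generation |
| `total_generations` | 100 | time since the three populations diverged (≈3000 y at 30 y/generation) |
| `admixture_generation` | 30 | pulse time, generations before present (Models B/C) |
| priors | U(0,1) | starting source frequency and every admixture proportion |
| `blocks` × `sims_per_block` | 100 × 100 | success-rate replication protocol (10 000 conditioned simulations) |
| `n_accepted` | 1000 | accepted rejection-sampling draws for Model C |
| observed pools | 0/2677, 4/95, 124/957 | Indo-European, Hungarian Sekler, Southern Ural/West Siberian carrier counts |

The generation time (30 y) is documentation only and never enters the
computation. The source population drifts for `total_generations −
admixture_generation` = 70 generations before the pulse, aligning all three
models on one 100-generation horizon; since the pulse time is the only
stated anchor, `pre_admixture_generations` exposes this choice (0 makes the
source start at its prior frequency at the pulse).

## Scoring and estimation

Models A and B are scored per block: raw simulations are run until
`sims_per_block` pass the model's conditioning criteria (A: Siberian sample
matches; B: Siberian and Sekler match), kept in draw order; the success
criterion (A: both remaining samples match; B: the Indo-European sample
matches) is evaluated on exactly those retained simulations. The mean and
sample SD (ddof = 1) of per-block success percentages are reported.
Defining Model A's success as both non-conditioning samples matching, and
Model B's as the Indo-European match alone, follows from what conditioning
leaves to test; re-checking the conditioned populations would be vacuously
true. A cap of 10⁷ raw attempts per still-missing conditioned simulation
aborts configurations whose conditioning event is effectively unreachable,
with the attempt counts in the diagnostic.

Model C accepts a parameter draw only when all three samples match, so its
"success rate" is 100% by construction and the information is in the
accepted draws. Summaries are the arithmetic mean and the empirical
2.5th–97.5th percentile interval per parameter (the min–max range is also
emitted; `interval="minmax"` swaps the convention). The "source carrier
frequency" summarized is the source population frequency at the final
generation, before sampling — the only model quantity that is a frequency
*among* that population; the starting frequency and the sampled frequency
are stored in the draws table for comparison. Accepted draws also record
the three sample frequencies that matched, so acceptance is auditable after
the fact.

## Implementation and numerics

The model runners simulate replicates in vectorised batches (default
20 000, grown adaptively as the conditioning rate is learned) with one
binomial call per generation across the whole batch. Populations whose
outcome cannot affect conditioning are simulated only for retained draws —
valid because, given the shared parameters, populations drift
independently. Batches short-circuit once every replicate is absorbed.
All randomness flows through one `numpy.random.Generator`; the replication
protocol spawns one child stream per block, so results are bit-reproducible
for a fixed master seed and numpy version. Ties in the pulse rounding
follow IEEE round-half-to-even via `np.round`.

## Synthetic data

The generator (`driftpulse.synthetic`) emulates exactly the statistical
structure the models assume: forward drift of one source, an optional
single pulse into one or two recipient pools, binomial sampling at the
observed sample sizes, and an optional split of each pool's sample across
sub-populations that share the pool frequency. It does *not* emulate
within-pool population structure, spatial gradients, variable population
sizes, mutation, or continuous migration — so passing the recovery tests
shows the estimator is self-consistent under the model's own assumptions,
not that real populations satisfy them. Ground truth is written as a JSON
sidecar next to each generated table.

The parameter-recovery check generates observations under known
(p₀, α_Sekler, α_IndoEuropean) = (0.4, 0.3, 0.0) and refits them with the
Model C sampler, requiring the 95% interval to cover the true α_Sekler in
≥ 90% of 20 repetitions. It runs at sample sizes 500/95/500 with 200
accepted draws per repetition — sizes chosen so each repetition's
Indo-European zero-match (the acceptance bottleneck) resolves in seconds
while leaving the inference problem qualitatively unchanged.

## Known limitations

- The tolerance's 2n denominator is retained as canonical even though the
  textbook SE uses n; conclusions are insensitive (the band only widens by
  √2), but absolute success rates shift.
- Success rates for Models A and B are small probabilities estimated from
  10⁴ conditioned simulations; their means carry Monte-Carlo error of a few
  hundredths of a percentage point, matching the spread seen across seeds.
- The framework models exactly three pools with at most one pulse each;
  multi-pulse histories, continuous migration and likelihood-based ABC are
  out of scope.
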