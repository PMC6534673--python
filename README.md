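# driftpulse

Forward-time Wright–Fisher simulation and resampling-based model selection
for Y-chromosome haplogroup frequencies.

## The problem

The haplogroup N3a4-B539 is observed at very different frequencies in three
population pools: 0% in a large Indo-European sample (0 of 2677 men), 4% in
Hungarian Seklers (4 of 95) and 13% in Southern Ural/West Siberian
populations (124 of 957). Can pure genetic drift from a shared ancestor
explain this pattern, or is admixture from the Siberian source required —
and if so, did the two European populations receive the same pulse or
different ones?

`driftpulse` answers this by simulation. Each population is a haploid
Wright–Fisher population of constant size N = 5000 transmitting lineages
carrying a biallelic marker (carrier / non-carrier); each generation the
carrier count is resampled as Binomial(N, p). Admixture is a single pulse:
a proportion α of the recipient gene pool is replaced by the source pool in
one generation. At the final generation a sample of the observed size n is
drawn from each population, and the simulated sample frequency is compared
with the observed frequency p under the tolerance

    tolerance = 2·SE = 2·√( p(1−p) / 2n ),

with p replaced by the pseudo-count frequency 1/(n+1) when the observed
count is zero. A simulated sample "matches" when it falls within the
tolerance band.

Three models are scored:

- **Model A (pure drift)** — three populations inherit one shared starting
  frequency ~ U(0,1) and drift independently for 100 generations.
  Simulations are retained (conditioned) when the Siberian sample matches;
  a retained simulation succeeds when the Sekler and Indo-European samples
  match too.
- **Model B (shared pulse)** — the source drifts from a U(0,1) start; 30
  generations before present one pulse with a shared α ~ U(0,1) seeds both
  European populations (previously without the haplogroup); all three then
  drift to the present. Conditioning: Siberian and Sekler samples match.
  Success: the Indo-European sample matches.
- **Model C (independent pulses)** — as B but with independent α values
  into the Seklers and the Indo-Europeans. This is a rejection sampler:
  draws of (p₀, α_Sekler, α_IndoEuropean) ~ U(0,1)³ are accepted only when
  all three samples match, and 1000 accepted draws form an approximate
  posterior for the admixture proportions.

Models A and B are scored over 100 blocks of 100 conditioned simulations
each; the per-block success percentage is averaged and its SD taken across
blocks.

## Worked example

```
$ driftpulse simulate --model B --seed 1 --out runs/modelB
Model B: mean success rate 0.83% (SD 1.04%) over 100 blocks

$ driftpulse fit --seed 1 --out runs/modelC
Model C posterior means: alpha_sekler 43.9% (9.1-92.3), alpha_indo_european
3.6% (0.1-13.1), source final frequency 12.8%
```

The first command says: even after conditioning on the Siberian and Sekler
samples matching, a shared pulse leaves the Indo-European zero essentially
unexplained — fewer than 1% of conditioned simulations also match it, so the
shared-pulse model is rejected more than 95% of the time (pure drift, Model
A, fares far worse at ~0.04%). The second command fits the
independent-pulse model: the Siberian source contributed around 44% of the
Sekler gene pool but only ~3% of the Indo-European one, with the source's
own carrier frequency near 13%. The wide Sekler interval shows how little
power three frequencies carry about α.

Each run directory contains a `manifest.json` (config snapshot, seed,
package version) sufficient to reproduce the outputs exactly, block-level
results as TSV, and JSON summaries. `driftpulse make-fixtures` writes a
deterministic suite of small synthetic count tables with known ground
truth, and the library functions (`read_counts`, `pool`, `to_observed`)
turn any population × haplogroup count table into model inputs.

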