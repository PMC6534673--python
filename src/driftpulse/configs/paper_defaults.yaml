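# Canonical three-pool study configuration: N = 5000 haploid lineages,
# 100 generations (3000 y at 30 y/generation), single admixture pulse 30
# generations before present (Models B/C), 100 blocks x 100 conditioned
# simulations, 1000 accepted rejection-sampling draws (Model C).
model: A
effective_size: 5000
total_generations: 100
admixture_generation: 30
generation_time_years: 30
blocks: 100
sims_per_block: 100
n_accepted: 1000
tolerance_variant: paper
interval: percentile
observed:
  - {role: indo_european, label: IndoEuropean, n: 2677, carriers: 0}
  - {role: sekler, label: HungarianSekler, n: 95, carriers: 4}
  - {role: source, label: UralSiberian, n: 957, carriers: 124}
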