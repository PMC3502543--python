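"""Human-specific sequence alterations in multi-primate alignment blocks.

Simulates 1-kb alignment blocks (human + chimpanzee/gorilla/orangutan/
macaque + Neanderthal/Denisova) at 20 substitutions per kb on the human
branch, counts HSAs, partitions them by archaic allele state, compares
per-kb rates against a low-rate control group, and scans the GATA-1
consensus WGATTAG for gains and losses.
"""

from crosspeak import (
    MotifPattern,
    archaic_fraction,
    compare_groups,
    count_hsas,
    hsa_rates,
    motif_events,
)
from crosspeak.synthetic_data import GeneratorSpec, gen_alignment_blocks, gen_peak_pool

spec = GeneratorSpec(n_peaks=120, n_gain_peaks=0, peak_length_range=(1000, 1000),
                     sub_rate_human=20.0, sub_rate_human_background=8.0,
                     archaic_postsplit=0.033, rng_seed=4)
peaks, _ = gen_peak_pool(spec)
elevated = [p.id for p in peaks[:60]]
blocks, _ = gen_alignment_blocks(peaks, spec, elevated_ids=elevated)

comparison = list(spec.comparison_taxa)
rates = hsa_rates(blocks, comparison)
comp = compare_groups(rates[elevated], rates.drop(elevated), n_sims=10_000, seed=4)
print(f"HSA rate, elevated group: {comp.mean_a:.2f} +/- {comp.sd_a:.2f} per kb")
print(f"HSA rate, control group:  {comp.mean_b:.2f} +/- {comp.sd_b:.2f} per kb")
print(f"Wilcoxon p {comp.wilcoxon_p:.2e}, permutation p {comp.permutation_p:.2e}")

hsas = [h for b in blocks for h in count_hsas(b, comparison, list(spec.archaic_taxa))]
for taxon in spec.archaic_taxa:
    frac = archaic_fraction(hsas, taxon)
    print(f"post-{taxon}-split fraction: {100 * frac:.2f}% of {len(hsas)} HSAs")

motif = MotifPattern("GATA-1", "WGATTAG")
events = [e for b in blocks for e in motif_events(b, motif, comparison)]
gained = sum(e.kind == "gained" for e in events)
print(f"GATA-1 motifs gained {gained}, lost {len(events) - gained}")
print("The elevated group's ~2.5x rate excess with tiny p-values mirrors")
print("an accelerated human branch; the archaic fraction estimates how many")
print("changes postdate the split from each archaic lineage.")
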