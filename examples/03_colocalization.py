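"""Megabase-scale co-localization of a peak subset.

Plants 40 peak pairs spaced under 0.4 Mb inside a 1,500-peak pool and
asks whether the 80 paired peaks sit closer together than random
same-size subsets of the pool, at 1 Mb and 0.5 Mb thresholds.
"""

from crosspeak import enrichment_test
from crosspeak.synthetic_data import GeneratorSpec, gen_peak_pool

spec = GeneratorSpec(n_peaks=1500, n_gain_peaks=0, n_clustered_pairs=40,
                     cluster_max_dist=400_000, rng_seed=3)
peaks, truth = gen_peak_pool(spec)
subset = list(truth.index[truth.cluster_id >= 0])

for d in (1_000_000, 500_000):
    r = enrichment_test(subset, peaks, d=d, n_sims=10_000, seed=3)
    print(f"d < {d / 1e6:.1f} Mb: observed {r.observed:.0f} of {len(subset)} "
          f"peaks paired, expected {r.null_mean:.1f}, "
          f"fold {r.fold_enrichment:.2f}, p {r.p:.1e}")
print("Fold enrichments of ~2-3 with empirical p below 1e-3 mean the")
print("subset clusters on chromosomes far beyond what the pool explains.")
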