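"""Annotation-overlap enrichment of a peak subset against a resampled null.

Builds two annotation tracks (think: sperm DNA-hypomethylated regions of
two species) so a chosen 400-peak subset carries a 22% "target-only"
overlap rate against a ~5.7% pool baseline, then compares the observed
category counts with 10,000 random same-size subsets of the pool.
"""

import numpy as np

from crosspeak import enrichment_test
from crosspeak.synthetic_data import GeneratorSpec, gen_annotations, gen_peak_pool

spec = GeneratorSpec(n_peaks=5000, n_gain_peaks=0, enriched_target_only=0.22,
                     rng_seed=2)
peaks, _ = gen_peak_pool(spec)
rng = np.random.default_rng(2)
subset = [peaks[i].id for i in rng.choice(len(peaks), 400, replace=False)]
target, other, _ = gen_annotations(peaks, spec, enriched_ids=subset)

results = enrichment_test(subset, peaks, annotations=(target, other),
                          n_sims=10_000, seed=2)
for cat, r in results.items():
    print(f"{cat:12s} observed {r.observed:5.0f}  expected {r.null_mean:7.2f}"
          f"  fold {r.fold_enrichment:5.2f}  p {r.p:.2e}")
print("'target_only' well above its expectation with a tiny empirical p")
print("indicates the subset is preferentially marked in the target species.")
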