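"""Classify human-specific H3K4me3 gain peaks on a synthetic cohort.

Generates a 2,000-peak pool with 100 planted fold-4 human gains, an
11-human / 4-chimpanzee / 3-macaque neuronal cohort with overdispersed
tag counts, then runs the gain classifier (length >= 500 bp, >2-fold vs
each comparison species, exact rank-sum + BH FDR) and scores the calls
against the planted truth.
"""

from crosspeak import AnalysisConfig, call_gain, normalize_density
from crosspeak.genomic_io import peak_lengths
from crosspeak.synthetic_data import GeneratorSpec, gen_counts, gen_peak_pool

spec = GeneratorSpec(n_peaks=2000, n_gain_peaks=100, gain_fold=4.0,
                     neuron_restricted_fraction=0.0, rng_seed=1)
peaks, _ = gen_peak_pool(spec)
counts, samples, truth = gen_counts(peaks, spec)
lengths = peak_lengths(peaks)

density = normalize_density(counts, samples, lengths)  # ppm per kb
calls = call_gain(density, samples, "human", ["chimpanzee", "macaque"],
                  lengths, AnalysisConfig())

called = {c.peak_id for c in calls if c.label == "gain"}
planted = set(truth.index[truth.planted_gain])
sens = len(called & planted) / len(planted)
fdp = len(called - planted) / len(called)

print(f"peaks screened:        {len(calls)}")
print(f"human-specific gains:  {len(called)}")
print(f"sensitivity:           {sens:.3f}")
print(f"false-discovery prop.: {fdp:.3f}")
print("A sensitivity near 1 with FDP well under 0.05 means the fold +")
print("exact-rank-sum + FDR screen recovers the planted species effect.")
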