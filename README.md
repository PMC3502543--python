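# crosspeak

Comparative analysis of neuronal histone-methylation landscapes across
primate species. `crosspeak` is a Python library (plus a thin CLI) for
three questions that arise when H3K4me3 ChIP-seq peak atlases from human,
chimpanzee and macaque neurons are compared:

1. **Which peaks are species-specific?** Classify peaks with a
   human-specific gain (or, reciprocally, depletion) of H3K4me3 signal,
   restrict calls to neuronal chromatin (NeuN+ vs NeuN−), re-call under a
   secondary cohort/threshold and intersect call sets, and select
   least-changed control peaks.
2. **Is a peak subset unusual as a set?** Permutation tests that resample
   equally sized subsets from the full peak atlas: co-localization of
   subset peaks within 1 or 0.5 Mb on the same chromosome, and
   overlap-category enrichment against paired annotation tracks (e.g.
   sperm DNA-hypomethylated regions of two species).
3. **Do the called peaks carry an evolutionary footprint?** Count
   human-specific sequence alterations (HSAs) in multi-primate alignment
   blocks, partition them by archaic-hominin (Neanderthal/Denisova)
   allele state, compare per-kb HSA rates between peak groups, and scan
   IUPAC consensus motifs (e.g. GATA-1 `WGATTAG`) for human gains and
   losses.

Every analysis runs end-to-end on synthetic data with planted ground
truth generated by `crosspeak.synthetic_data`, so sensitivity,
false-discovery proportion and parameter recovery are measurable.

## The statistics at the core

**Density.** Raw tag counts are normalized to
`d(p,s) = c(p,s) / (N_s/10^6) / (L_p/10^3)` — tags per million mapped
tags per kb of peak (ppm/kb), with `N_s` the library size and `L_p` the
peak length.

**Species-specific gain.** Peak `p` is a gain for target species `T`
against comparison species `C_1..C_k` iff

- `L_p >= 500` bp,
- `(mean_T + eps) / (mean_Ci + eps) > F` for every `C_i` (default
  `F = 2`, `eps = 0.1` ppm/kb; a pooled-average fold mode is available),
- BH-adjusted `q <= 0.05` from a two-sided exact Mann–Whitney rank-sum
  test of the target samples against the pooled comparison samples,
  with the FDR correction applied over the peaks that survive the
  length+fold screen.

**Resampling null.** For a subset `S` of the atlas `P` and statistic
`T(S)`, `n_sims` subsets of size `|S|` are drawn uniformly without
replacement from `P`, and the add-one empirical p is
`p = (1 + #{T(S*) >= T(S)}) / (1 + n_sims)` (direction reversible).

**HSA.** An alignment column is a substitution HSA iff all comparison
primates carry one identical non-gap base that differs from the human
base; maximal human-gap (deletion) or unanimous comparison-gap
(insertion) runs form one indel event each (`>= 100` bp: long indel).
An HSA postdates the split from an archaic hominin iff the archaic
carries the ancestral (outgroup) allele; rates are HSA events per kb of
ungapped human sequence, compared between groups by exact/asymptotic
Wilcoxon rank-sum and a label-permutation test.

## Worked example

```bash
python examples/01_classify_species_gains.py
```

```
peaks screened:        2000
human-specific gains:  99
sensitivity:           0.990
false-discovery prop.: 0.000
```

2,000 synthetic peaks, 100 of them planted with a 4-fold human-specific
H3K4me3 increase, profiled in 11 humans vs 4 chimpanzees + 3 macaques:
the classifier recovers 99 gains, 99% of the planted effect, with no
false calls. The other examples exercise overlap enrichment
(`02`), megabase co-localization (`03`, folds ~2.1 at 1 Mb and ~3.5 at
0.5 Mb with empirical p = 1e-4), the evolutionary footprint (`04`,
20.6 vs 9.0 HSAs/kb, Wilcoxon p ≈ 7e-20) and the full pipeline (`05`).

The same run is available from the shell:

```bash
crosspeak all --config configs/golden.yaml --outdir run1
```

which writes densities, call tables, permutation results, HSA tables and
a run manifest (config snapshot, per-stage seeds, output digests) under
`run1/`; identical config + seed reproduces every TSV/JSON byte for byte.

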