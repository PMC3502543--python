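# Methods

This note documents the models, defaults and numerical choices behind
`crosspeak`, and what the synthetic-data experiments do and do not show.

## Quantification

Raw per-peak tag counts are converted to densities in ppm per kb:
`d(p,s) = c(p,s) / (library_size_s / 1e6) / (length_p / 1e3)`. The
per-kb term makes peaks of different lengths comparable; raw ppm is
available via `per_kb=False`. Densities are linear in counts, so
library-size rescaling acts multiplicatively per sample. Optional input
correction rescales each peak by `mean(input) / (input_p + pseudo)`;
it is off by default because locus-specific background correction is
only warranted when an input (mononucleosomal) library is part of the
design. Sample-to-sample Pearson correlations are computed on densities
by default (raw counts are accepted); zero-variance samples yield NaN
correlations plus a warning rather than a silent 0.

## Species-specific peak classification

A gain call for target species T against comparison species C1..Ck
requires, per peak:

1. length >= `min_length` (default 500 bp);
2. fold `(mean_T + eps) / (mean_Ci + eps) > F` for **each** Ci
   (`fold_mode="each_species"`, default) or against the pooled
   comparison mean (`"pooled_average"`); defaults `F = 2` primary,
   1.5 for the secondary re-call; `eps = 0.1` ppm/kb keeps folds finite
   on zero-background peaks (results are insensitive to eps well below
   typical peak densities, which have median ~2.7 ppm/kb under the
   generator defaults);
3. BH-adjusted `q <= alpha` (default 0.05) from a two-sided Mann–Whitney
   rank-sum test of the target samples against the pooled comparison
   samples.

**Test.** The per-peak test uses mid-ranks for ties. When the smaller
group has <= 12 samples and the row is tie-free, the p-value is exact:
the null distribution of U is built once per group-size pair from the
Gaussian-binomial recurrence and applied as a table lookup, which makes
exact testing of tens of thousands of peaks cheap. Rows with ties (or
larger groups) use the tie-corrected normal approximation with
continuity correction. The exact path is cross-checked in the test suite
against an independent library implementation.

**Screen-then-correct.** The FDR correction runs over the peaks that
survive the length and fold filters, mirroring a workflow that first
screens an atlas by effect size and then asks which survivors are
significant; peaks outside the screen keep `q = 1`. This matters at
small cohort sizes: with 11 vs 7 samples the smallest attainable exact
p is 2/C(18,7) ≈ 6.3e-5, and correcting over an entire multi-thousand
peak atlas rather than the screened candidates costs real sensitivity.
Under a global null the screened BH still holds the FDR level (checked
empirically over 50 seeded generator runs).

**Depletion calls** mirror gains with roles reversed, restricted to a
candidate universe of peaks with pooled comparison-species mean density
>= `presence_floor` (default 1 ppm/kb) — a stand-in for requiring the
peak to be detected in the comparison species at all.

**Neuronal restriction** keeps calls whose NeuN+ mean exceeds F times
each reference cell type's mean (with eps) and whose NeuN+ vs NeuN−
rank-sum test passes BH at alpha over the call set.

**Control peaks** are the k peaks with the smallest maximum absolute
log-fold across all species-pair group means (with eps), optionally
length-matched to a target set within a window; ties break by atlas
order (stable sort).

**Secondary re-call.** The pipeline re-calls gains at F = 1.5 on the
non-child human samples and intersects with the primary calls. With the
default cohort (4 adults of 11 humans) this re-call is underpowered
relative to a dedicated adult cohort; the intersection is reported as a
robustness readout, not a second discovery set.

## Permutation machinery

The null model resamples peak **identities** from the atlas, preserving
its chromosomal and positional structure — the question is whether a
subset of real peaks is unusual among equally sized subsets of the same
pool, not whether peaks are uniform on the genome. Empirical p-values
use the add-one estimator `(1 + exceedances) / (1 + n_sims)` (never 0,
1 attainable); direction is `greater` or `less`. Detecting p below 1e-4
requires `n_sims > 1e4`, which the CLI permits.

Two statistics have vectorized batch paths:

- **pairing count**: subset peaks with >= 1 other subset member on the
  same chromosome at midpoint distance < d (defaults d = 1 Mb and
  0.5 Mb). Midpoints are robust to unequal peak lengths; edge-to-edge
  distance and pair counting (rather than peak counting) are options.
- **marked-subset count**: subset peaks overlapping an annotation
  category by >= 1 bp (no reciprocal-fraction requirement). Peaks are
  partitioned into both / target-only / other-only / neither by
  membership in two annotation sets.

Interpretation note: the pairing statistic saturates when the subset is
dense relative to the genome (nearly every random subset peak then has a
neighbor within d). Fold enrichment is informative at subset densities
of order 0.1–0.5 peaks per Mb; the packaged reference run (80 subset
peaks over a 240-Mb layout) sits in that regime.

## Evolutionary footprint

**HSA calling.** A column is a substitution HSA iff every comparison
primate carries one identical non-gap, non-N base differing from the
human base — human-specific by parsimony, with outgroup unanimity as
the strictest (default) informativeness rule; columns with comparison
disagreement or N are skipped. Maximal runs of human-gap columns
(deletion) or unanimous comparison-gap columns (insertion) form one
event each; events >= 100 bp are labelled `long_indel`. Archaic rows
never create or destroy events; per event the archaic state is
`derived` (equals the human allele), `ancestral` (equals the outgroup
allele) or `missing`. The post-split fraction for an archaic taxon is
#ancestral / #non-missing. Rates are events per kb of **ungapped human
sequence** (not peak length — alignment and peak coordinates can
disagree after indels).

**Group comparison.** Two-sided Wilcoxon rank-sum (exact when the
smaller group has <= 12 tie-free observations, tie-corrected normal
approximation otherwise) plus a label-permutation test on the absolute
difference of group means with the add-one estimator.

**Motifs.** IUPAC consensus patterns are scanned on both strands
(reverse-strand matches reported at their forward-strand start; a
sequence N matches only the pattern letter N). Orthology is resolved
through alignment columns, not coordinate liftover: a human match whose
column window carries no comparison match is a gain; a match shared by
all comparison taxa with no human match in the window is a loss. The
gain/loss 2x2 table (events over site counts) is reported with both
Pearson and Yates chi-square variants, since the test variant behind
published tallies of this kind is typically unstated.

## Synthetic data

The generator emulates a cross-species neuronal ChIP-seq study at desk
scale. Defaults:

- layout 4 x 60 Mb; 3,000 non-overlapping peaks of 500–5,000 bp
  (pool density ~12.5 peaks/Mb, comparable to a genome-scale atlas);
- cohort 11 human NeuN+ (7 children, 4 adults), 4 human NeuN−,
  4 chimpanzee NeuN+, 3 macaque NeuN+; libraries 10–30 M tags;
- per-peak strengths log-normal (meanlog 1, sdlog 1; median
  ~2.7 ppm/kb); counts negative-binomial with
  `var = mu + 0.2 mu^2` (dispersion 0.2, typical ChIP-seq
  overdispersion); planted gains default fold 4 on human NeuN+ (half
  neuron-restricted);
- annotation categories both/target-only/other-only/neither at
  0.73/0.057/0.005/0.208, enriched target-only 0.22 for a designated
  subset — intervals are carved inside their (non-overlapping) peaks so
  the truth category of every peak is exact by construction;
- alignment blocks simulate a star-with-outgroup history: human branch
  20 substitutions/kb on designated peaks and 8/kb elsewhere (the
  elevated-vs-background contrast), 5/kb per comparison branch, short
  indels at 0.5/kb (geometric lengths, mean 3) and long indels
  (100–300 bp) at 0.01/kb; archaic rows revert each planted human event
  to the ancestral allele with probability `archaic_postsplit`
  (default 0.033) or go missing with probability 0.02.

By default sample effects are i.i.d. given the peak strength, so an
unplanted generator is an exchangeable, all-species-identical null —
the regime in which FDR and permutation calibration are verified. A
correlated-effect mode (`effect_corr=(within, cross)`) adds shared and
species-level log-normal effects for studying correlation structure;
it is not part of the null or power experiments.

Deliberate simplifications: uniform base composition (no GC or repeat
structure), independent peaks (no gene-centric clustering beyond what is
planted), no read-level simulation, star topology rather than the true
primate tree, and comparison-branch events that only break outgroup
unanimity (at the default rates ~2–4% of planted human substitutions
are masked by coincident comparison-branch changes, visible as a small
downward bias in rate recovery). Passing tests therefore demonstrate
correctness and calibration of the statistics under the stated model,
not robustness to the full messiness of real ChIP-seq or real genome
alignments.

## Problem sizes and determinism

The test suite and the acceptance script run at fixed desk-scale sizes
chosen so every stage completes in seconds to a few minutes on one CPU:
pools of 500–5,000 peaks, 10,000 permutations where a p below 1e-3 is
asserted, 500 alignment blocks for rate recovery, and 20–100 seeded
replicates for power/calibration claims. One global seed expands into
per-stage child seeds via `SeedSequence([seed, stage_index])`; identical
config + seed reproduces every TSV/JSON output byte for byte (the
plain-text log, which records wall times, is the only non-reproducible
file). The packaged reference run (`configs/golden.yaml`) and its
committed report serve as an end-to-end regression anchor.

## Known limitations

- The exact rank-sum test is only one defensible reading of a
  "significant after FDR correction" criterion at n = 11 vs 7; any
  distribution-free alternative (e.g. permutation t) would shift call
  boundaries slightly.
- With 4 comparison samples per species, fold thresholds near the noise
  scale (F close to 1) are unstable; the defaults (F = 2, eps = 0.1)
  assume effects well above measurement noise.
- Archaic states are assigned per event from the aligned segment; partial
  matches (e.g. an archaic sharing only part of a long indel) count as
  `missing`.
- The co-localization fold compresses toward 1 for dense subsets (see
  above); the empirical p remains valid.
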