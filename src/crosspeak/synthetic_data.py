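"""Synthetic pipeline inputs with planted ground truth.

The generator emulates the structure of a cross-species neuronal ChIP-seq
study at desk scale: a pool of a few thousand non-overlapping peaks on a
small multi-chromosome layout, overdispersed (negative-binomial) tag
counts with log-normal per-peak strengths and planted species/cell-type
fold effects, annotation tracks carved to hit assigned peaks exactly, and
star-topology alignment blocks with per-branch substitution/indel rates
and archaic rows that carry either the human (derived) or the ancestral
allele at each planted event.

Every generator is deterministic given its seed, and every stage emits a
truth table sufficient to score the downstream analysis (sensitivity and
false-discovery proportion for calls, planted enrichment for the
resampling tests, rate and fraction recovery for the footprint stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from crosspeak.errors import ValidationError
from crosspeak.genomic_io import AlignmentBlock, AnnotationSet, GenomeLayout, Peak, SampleMeta

_BASES = np.frombuffer(b"ACGT", np.uint8)


def default_layout() -> GenomeLayout:
    return GenomeLayout({f"chr{i}": 60_000_000 for i in range(1, 5)}, assembly="synth1")


@dataclass
class GeneratorSpec:
    """All knobs of the synthetic study, with study-scale defaults."""

    layout: GenomeLayout = field(default_factory=default_layout)
    n_peaks: int = 3000
    peak_length_range: tuple[int, int] = (500, 5000)

    # cohort: 11 human NeuN+ (7 children, 4 adults), 4 human NeuN-,
    # 4 chimpanzee NeuN+, 3 macaque NeuN+
    n_human: int = 11
    n_human_children: int = 7
    n_human_nonneuronal: int = 4
    n_chimp: int = 4
    n_macaque: int = 3
    library_size_range: tuple[int, int] = (10_000_000, 30_000_000)

    strength_meanlog: float = 1.0   # log ppm/kb; median ~2.7
    strength_sdlog: float = 1.0
    dispersion: float = 0.2         # NB: var = mu + dispersion * mu^2

    n_gain_peaks: int = 100
    gain_fold: float = 4.0
    gain_species: str = "human"
    gain_cell_type: str = "NeuN+"
    neuron_restricted_fraction: float = 0.5

    # optional correlated per-sample effects: (within-species, cross-species)
    # correlation of log effects; None = exchangeable samples (no species
    # random effects), which is the all-species-identical null when no
    # gains are planted
    effect_corr: tuple[float, float] | None = None
    effect_sdlog: float = 0.5

    annotation_fracs: dict[str, float] = field(default_factory=lambda: {
        "both": 0.73, "target_only": 0.057, "other_only": 0.005, "neither": 0.208,
    })
    enriched_target_only: float = 0.22

    n_clustered_pairs: int = 0
    cluster_max_dist: int = 400_000

    comparison_taxa: tuple[str, ...] = ("chimpanzee", "gorilla", "orangutan", "macaque")
    archaic_taxa: tuple[str, ...] = ("neanderthal", "denisova")
    sub_rate_human: float = 20.0          # substitutions per kb, human branch
    sub_rate_human_background: float = 8.0  # human branch rate off the planted set
    sub_rate_comparison: float = 5.0      # per comparison branch
    indel_rate_human: float = 0.5         # short indel events per kb
    indel_rate_comparison: float = 0.2
    mean_indel_len: float = 3.0
    max_indel_len: int = 30
    long_indel_rate_human: float = 0.01   # events per kb, length >= 100
    long_indel_len_range: tuple[int, int] = (100, 300)
    archaic_postsplit: float = 0.033      # P(archaic carries ancestral allele)
    archaic_missing: float = 0.02

    rng_seed: int = 0

    def __post_init__(self):
        if self.peak_length_range[0] < 1 or self.peak_length_range[0] > self.peak_length_range[1]:
            raise ValidationError("bad peak_length_range")
        for rate in (self.sub_rate_human, self.sub_rate_comparison,
                     self.indel_rate_human, self.indel_rate_comparison,
                     self.long_indel_rate_human):
            if rate < 0:
                raise ValidationError("rates must be >= 0")
        if not 0 <= self.archaic_postsplit <= 1:
            raise ValidationError("archaic_postsplit must be in [0, 1]")
        if self.n_gain_peaks > self.n_peaks:
            raise ValidationError("more planted gains than peaks")
        if abs(sum(self.annotation_fracs.values()) - 1.0) > 1e-9:
            raise ValidationError("annotation fractions must sum to 1")
        if self.library_size_range[0] <= 0:
            raise ValidationError("library sizes must be positive")


def default_cohort(spec: GeneratorSpec, rng: np.random.Generator) -> list[SampleMeta]:
    libs = rng.integers(spec.library_size_range[0], spec.library_size_range[1],
                        size=spec.n_human + spec.n_human_nonneuronal
                        + spec.n_chimp + spec.n_macaque)
    samples = []
    k = 0
    for i in range(spec.n_human):
        age = "child" if i < spec.n_human_children else "adult"
        samples.append(SampleMeta(f"H{i + 1:02d}", "human", "NeuN+", int(libs[k]), age))
        k += 1
    for i in range(spec.n_human_nonneuronal):
        samples.append(SampleMeta(f"HN{i + 1:02d}", "human", "NeuN-", int(libs[k]), "adult"))
        k += 1
    for i in range(spec.n_chimp):
        samples.append(SampleMeta(f"C{i + 1:02d}", "chimpanzee", "NeuN+", int(libs[k]), "adult"))
        k += 1
    for i in range(spec.n_macaque):
        samples.append(SampleMeta(f"M{i + 1:02d}", "macaque", "NeuN+", int(libs[k]), "adult"))
        k += 1
    return samples


# ---------------------------------------------------------------------------
# peak pool


def gen_peak_pool(spec: GeneratorSpec, seed: int | None = None):
    """Place non-overlapping peaks; optionally plant clustered pairs.

    Returns (peaks, truth) where truth records cluster membership
    (cluster_id = -1 for unclustered peaks).
    """
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    chroms = list(spec.layout.chrom_lengths)
    chrom_len = np.array([spec.layout.chrom_lengths[c] for c in chroms], float)
    probs = chrom_len / chrom_len.sum()
    lo, hi = spec.peak_length_range

    trees = {c: IntervalTree() for c in chroms}
    placed: list[tuple[str, int, int]] = []
    cluster_ids: list[int] = []

    def free(c: str, s: int, length: int) -> bool:
        return (0 <= s and s + length <= spec.layout.chrom_lengths[c]
                and not trees[c].overlap(s, s + length))

    def place_uniform(length: int) -> tuple[str, int] | None:
        for _ in range(200):
            c = chroms[int(rng.choice(len(chroms), p=probs))]
            if spec.layout.chrom_lengths[c] <= length:
                continue
            s = int(rng.integers(0, spec.layout.chrom_lengths[c] - length))
            if free(c, s, length):
                trees[c].addi(s, s + length)
                return c, s
        return None

    if 2 * spec.n_clustered_pairs > spec.n_peaks:
        raise ValidationError("clustered pairs exceed n_peaks")

    for pair in range(spec.n_clustered_pairs):
        la = int(rng.integers(lo, hi + 1))
        lb = int(rng.integers(lo, hi + 1))
        min_off = (la + lb) // 2 + 1
        max_off = spec.cluster_max_dist - 1
        if max_off <= min_off:
            raise ValidationError("cluster_max_dist too small for peak lengths")
        for _ in range(200):
            spot = place_uniform(la)
            if spot is None:
                raise ValidationError("infeasible packing for clustered pairs")
            ca, sa = spot
            mid_a = sa + la / 2
            off = int(rng.integers(min_off, max_off + 1))
            if rng.random() < 0.5:
                off = -off
            sb = int(mid_a + off - lb / 2)
            if free(ca, sb, lb):
                trees[ca].addi(sb, sb + lb)
                placed.extend([(ca, sa, la), (ca, sb, lb)])
                cluster_ids.extend([pair, pair])
                break
            trees[ca].removei(sa, sa + la)
        else:
            raise ValidationError("infeasible packing for clustered pairs")

    while len(placed) < spec.n_peaks:
        length = int(rng.integers(lo, hi + 1))
        spot = place_uniform(length)
        if spot is None:
            raise ValidationError("infeasible packing: pool does not fit the layout")
        placed.append((spot[0], spot[1], length))
        cluster_ids.append(-1)

    peaks = [Peak(f"peak_{i + 1}", c, s, s + length)
             for i, (c, s, length) in enumerate(placed)]

    truth = pd.DataFrame({
        "peak_id": [p.id for p in peaks],
        "chrom": [p.chrom for p in peaks],
        "start": [p.start for p in peaks],
        "end": [p.end for p in peaks],
        "length": [p.length for p in peaks],
        "cluster_id": cluster_ids,
    }).set_index("peak_id")
    return peaks, truth


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def gen_counts(peaks: Sequence[Peak], spec: GeneratorSpec,
               seed: int | None = None,
               samples: Sequence[SampleMeta] | None = None):
    """Overdispersed tag counts with planted species/cell-type fold effects.

    Returns (counts, samples, truth); truth records per-peak strength,
    planted-gain membership, neuronal restriction and the planted fold.
    """
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    if samples is None:
        samples = default_cohort(spec, rng)
    n_p, n_s = len(peaks), len(samples)
    ids = [p.id for p in peaks]
    lengths = np.array([p.length for p in peaks], float)
    libs = np.array([s.library_size for s in samples], float)

    strength = rng.lognormal(spec.strength_meanlog, spec.strength_sdlog, n_p)

    planted = np.zeros(n_p, bool)
    restricted = np.zeros(n_p, bool)
    if spec.n_gain_peaks > 0:
        gain_idx = rng.choice(n_p, spec.n_gain_peaks, replace=False)
        planted[gain_idx] = True
        n_restricted = int(round(spec.neuron_restricted_fraction * spec.n_gain_peaks))
        if n_restricted:
            restricted[rng.choice(gain_idx, n_restricted, replace=False)] = True

    fold = np.ones((n_p, n_s))
    for j, s in enumerate(samples):
        if s.species != spec.gain_species:
            continue
        if s.cell_type == spec.gain_cell_type:
            fold[planted, j] = spec.gain_fold
        else:
            # non-restricted gains are present across the species' cell types
            fold[planted & ~restricted, j] = spec.gain_fold

    mult = np.ones((n_p, n_s))
    if spec.effect_corr is not None:
        w, x = spec.effect_corr
        if not (0 <= x <= w <= 1):
            raise ValidationError("effect_corr must satisfy 0 <= cross <= within <= 1")
        s2 = spec.effect_sdlog ** 2
        shared = rng.normal(0, np.sqrt(x * s2), size=(n_p, 1))
        sp_codes = {sp: i for i, sp in enumerate({s.species for s in samples})}
        sp_fx = rng.normal(0, np.sqrt((w - x) * s2), size=(n_p, len(sp_codes)))
        noise = rng.normal(0, np.sqrt((1 - w) * s2), size=(n_p, n_s))
        col_sp = np.array([sp_codes[s.species] for s in samples])
        mult = np.exp(shared + sp_fx[:, col_sp] + noise)

    mean = (strength[:, None] * fold * mult
            * (libs / 1e6)[None, :] * (lengths / 1e3)[:, None])
    counts = _nb_draw(rng, mean, spec.dispersion)

    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="peak_id"),
                             columns=[s.sample_id for s in samples])
    truth = pd.DataFrame({
        "peak_id": ids,
        "strength": strength,
        "planted_gain": planted,
        "neuron_restricted": restricted,
        "fold": np.where(planted, spec.gain_fold, 1.0),
    }).set_index("peak_id")
    return counts_df, list(samples), truth


# ---------------------------------------------------------------------------
# annotations


def gen_annotations(peaks: Sequence[Peak], spec: GeneratorSpec,
                    seed: int | None = None,
                    enriched_ids: Sequence[str] | None = None):
    """Two annotation tracks with controllable per-category overlap fractions.

    Intervals are carved inside their assigned peaks (peaks are
    non-overlapping by construction), so the truth category of every peak
    is exact.  Peaks in ``enriched_ids`` use the enriched target-only
    probability, with the difference absorbed by "neither".
    """
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    cats = ["both", "target_only", "other_only", "neither"]
    base = np.array([spec.annotation_fracs[c] for c in cats])
    enr = base.copy()
    enr[1] = spec.enriched_target_only
    enr[3] = 1.0 - enr[0] - enr[1] - enr[2]
    if enr[3] < 0:
        raise ValidationError("enriched target-only fraction leaves negative 'neither'")
    enriched = set(enriched_ids or ())

    target = AnnotationSet(name="hypomethylated_target")
    other = AnnotationSet(name="hypomethylated_other")
    assigned = []
    for p in peaks:
        probs = enr if p.id in enriched else base
        cat = cats[rng.choice(4, p=probs)]
        assigned.append(cat)
        half = p.length // 2
        if cat in ("both", "target_only"):
            target.intervals.append((p.chrom, p.start, p.start + min(100, half)))
        if cat in ("both", "other_only"):
            other.intervals.append((p.chrom, p.end - min(100, p.length - half), p.end))
    truth = pd.DataFrame({"peak_id": [p.id for p in peaks], "category": assigned}
                         ).set_index("peak_id")
    return target, other, truth


# ---------------------------------------------------------------------------
# alignment blocks


def _sample_indels(rng, L, rate_per_kb, mean_len, max_len):
    n = rng.poisson(rate_per_kb / 1000 * L)
    events = []
    for _ in range(n):
        length = min(int(rng.geometric(1.0 / mean_len)), max_len)
        kind = "deletion" if rng.random() < 0.5 else "insertion"
        if kind == "deletion":
            if L <= length:
                continue
            pos = int(rng.integers(0, L - length))
        else:
            pos = int(rng.integers(0, L + 1))
        events.append((kind, pos, length))
    return events


def gen_alignment_blocks(peaks: Sequence[Peak], spec: GeneratorSpec,
                         seed: int | None = None,
                         elevated_ids: Sequence[str] | None = None,
                         block_length: int | None = None):
    """Star-with-outgroup alignment blocks with planted per-branch events.

    Human-branch substitutions are drawn at ``sub_rate_human`` per kb for
    peaks in ``elevated_ids`` (all peaks when None) and at
    ``sub_rate_human_background`` otherwise.  Comparison-branch changes
    break outgroup unanimity by construction and therefore never create
    spurious human-specific columns.  Archaic rows copy the human allele
    at each planted event with probability 1 - archaic_postsplit, else
    the ancestral allele; truth records the realized state per taxon.

    Returns (blocks, truth) with one truth row per planted human event.
    """
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    elevated = set(elevated_ids) if elevated_ids is not None else None
    blocks: list[AlignmentBlock] = []
    truth_rows: list[dict] = []

    for peak in peaks:
        L = block_length or peak.length
        anc = rng.choice(_BASES, size=L)

        sub_rate = (spec.sub_rate_human if elevated is None or peak.id in elevated
                    else spec.sub_rate_human_background)

        # ---- human branch events in ancestral coordinates
        n_sub = rng.poisson(sub_rate / 1000 * L)
        sub_pos = rng.choice(L, size=min(n_sub, L), replace=False)
        indels = _sample_indels(rng, L, spec.indel_rate_human,
                                spec.mean_indel_len, spec.max_indel_len)
        n_long = rng.poisson(spec.long_indel_rate_human / 1000 * L)
        for _ in range(n_long):
            length = int(rng.integers(*spec.long_indel_len_range))
            kind = "deletion" if rng.random() < 0.5 else "insertion"
            if kind == "deletion":
                if L <= length:
                    continue
                pos = int(rng.integers(0, L - length))
            else:
                pos = int(rng.integers(0, L + 1))
            indels.append((kind, pos, length))

        # resolve human deletion overlaps; drop subs inside deletions
        del_mask = np.zeros(L, bool)
        human_dels = []
        for kind, pos, length in indels:
            if kind != "deletion":
                continue
            if del_mask[pos:pos + length].any():
                continue
            del_mask[pos:pos + length] = True
            human_dels.append((pos, length))
        human_ins = [(pos, length) for kind, pos, length in indels if kind == "insertion"]
        sub_pos = np.array([p for p in sub_pos if not del_mask[p]], int)

        human = anc.copy()
        if sub_pos.size:
            shift = rng.integers(1, 4, size=sub_pos.size).astype(np.uint8)
            base_idx = np.searchsorted(_BASES, human[sub_pos])
            human[sub_pos] = _BASES[(base_idx + shift) % 4]

        # ---- comparison branches
        comp_rows = {}
        comp_del_masks = {}
        comp_ins = []  # (pos, taxon, bases)
        for taxon in spec.comparison_taxa:
            row = anc.copy()
            n_cs = rng.poisson(spec.sub_rate_comparison / 1000 * L)
            cpos = rng.choice(L, size=min(n_cs, L), replace=False)
            if cpos.size:
                shift = rng.integers(1, 4, size=cpos.size).astype(np.uint8)
                bidx = np.searchsorted(_BASES, row[cpos])
                row[cpos] = _BASES[(bidx + shift) % 4]
            dmask = np.zeros(L, bool)
            for kind, pos, length in _sample_indels(
                    rng, L, spec.indel_rate_comparison,
                    spec.mean_indel_len, spec.max_indel_len):
                if kind == "deletion":
                    dmask[pos:pos + length] = True
                else:
                    comp_ins.append((pos, taxon, rng.choice(_BASES, size=length)))
            comp_rows[taxon] = row
            comp_del_masks[taxon] = dmask

        # ---- assemble columns: base columns + insertion chunks
        taxa = ["human", *spec.comparison_taxa]
        base_mat = np.empty((len(taxa), L), np.uint8)
        base_mat[0] = np.where(del_mask, _GAPB, human)
        for i, taxon in enumerate(spec.comparison_taxa, start=1):
            base_mat[i] = np.where(comp_del_masks[taxon], _GAPB, comp_rows[taxon])

        ins_events = ([(pos, "human", rng.choice(_BASES, size=length))
                       for pos, length in human_ins] + comp_ins)
        ins_events.sort(key=lambda e: e[0])

        chunks = []
        col_of = np.zeros(L + 1, int)  # final column index of anc position
        cursor = 0
        offset = 0
        human_ins_cols = []  # (final_start, length) for human insertions
        for pos, taxon, bases in ins_events:
            if pos > cursor:
                chunks.append(base_mat[:, cursor:pos])
                col_of[cursor:pos] = np.arange(cursor, pos) + offset
                cursor = pos
            chunk = np.full((len(taxa), bases.size), _GAPB, np.uint8)
            chunk[taxa.index(taxon)] = bases
            if taxon == "human":
                human_ins_cols.append((pos + offset, bases.size))
            chunks.append(chunk)
            offset += bases.size
        chunks.append(base_mat[:, cursor:])
        col_of[cursor:] = np.arange(cursor, L + 1) + offset
        mat = np.concatenate(chunks, axis=1) if chunks else base_mat

        rows = {t: mat[i].tobytes().decode("ascii") for i, t in enumerate(taxa)}

        # ---- archaic rows: copy human, revert planted events with p=postsplit
        arch_arrays = {t: mat[0].copy() for t in spec.archaic_taxa}

        def archaic_outcome():
            u = rng.random()
            if u < spec.archaic_missing:
                return "missing"
            return "ancestral" if rng.random() < spec.archaic_postsplit else "derived"

        def record(kind, length, states):
            row = {"peak_id": peak.id, "kind": kind, "length": length}
            for t in spec.archaic_taxa:
                row[f"state_{t}"] = states[t]
            truth_rows.append(row)

        for p_ in sub_pos:
            c = col_of[p_]
            states = {}
            for t in spec.archaic_taxa:
                s = archaic_outcome()
                states[t] = s
                if s == "ancestral":
                    arch_arrays[t][c] = anc[p_]
                elif s == "missing":
                    arch_arrays[t][c] = _NB_
            record("substitution", 1, states)
        for pos, length in human_dels:
            cols = col_of[pos:pos + length]
            states = {}
            for t in spec.archaic_taxa:
                s = archaic_outcome()
                states[t] = s
                if s == "ancestral":
                    arch_arrays[t][cols] = anc[pos:pos + length]
                elif s == "missing":
                    arch_arrays[t][cols] = _NB_
            record("long_indel" if length >= 100 else "deletion", length, states)
        for fstart, length in human_ins_cols:
            cols = np.arange(fstart, fstart + length)
            states = {}
            for t in spec.archaic_taxa:
                s = archaic_outcome()
                states[t] = s
                if s == "ancestral":
                    arch_arrays[t][cols] = _GAPB
                elif s == "missing":
                    arch_arrays[t][cols] = _NB_
            record("long_indel" if length >= 100 else "insertion", length, states)

        for t in spec.archaic_taxa:
            rows[t] = arch_arrays[t].tobytes().decode("ascii")

        blocks.append(AlignmentBlock(peak.id, rows))

    columns = ["peak_id", "kind", "length"] + [f"state_{t}" for t in spec.archaic_taxa]
    truth = pd.DataFrame(truth_rows, columns=columns)
    return blocks, truth


_GAPB = ord("-")
_NB_ = ord("N")
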