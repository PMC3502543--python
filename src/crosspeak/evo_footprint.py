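"""Human-specific sequence alterations (HSAs) in multi-taxon alignments.

An alignment column contributes a substitution HSA when every comparison
primate carries one identical non-gap, non-N base that differs from the
human base (human-specific by parsimony: unanimity of the outgroups).
Columns where the comparison taxa disagree, or where any relevant base is
N, are uninformative and skipped.  Maximal runs of human-gap columns
(deletions) or unanimous comparison-gap columns (insertions) form one
indel event each; events of >= 100 bp are labelled ``long_indel``.

Archaic hominin rows (Neanderthal, Denisova) never create or destroy
HSAs; they only annotate each event as carrying the human (derived) or
the outgroup (ancestral) allele.  An HSA whose archaic state is ancestral
postdates the split from that archaic lineage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from crosspeak._stats import exact_mwu_two_sided, permutation_mean_diff_p
from crosspeak.errors import ValidationError
from crosspeak.genomic_io import AlignmentBlock

LONG_INDEL_MIN = 100
_GAP = ord("-")
_N = ord("N")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}
_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
    "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC consensus motif, e.g. GATA-1 = WGATTAG."""

    name: str
    pattern: str

    def __post_init__(self):
        if not self.pattern:
            raise ValidationError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValidationError(f"illegal IUPAC letters {sorted(bad)} in {self.name!r}")

    @property
    def reverse_complement(self) -> str:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(self.pattern.upper()))


@dataclass
class HSARecord:
    peak_id: str
    column: int              # 0-based first alignment column of the event
    kind: str                # substitution | insertion | deletion | long_indel
    human_allele: str
    outgroup_allele: str
    length: int
    archaic_states: dict[str, str]  # taxon -> ancestral | derived | missing


@dataclass
class MotifEvent:
    peak_id: str
    column: int
    strand: str
    kind: str  # gained | lost


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    wilcoxon_p: float
    permutation_p: float
    n_sims: int
    rng_seed: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _rows(block: AlignmentBlock, taxa: Sequence[str]) -> np.ndarray:
    out = []
    for t in taxa:
        if t not in block.sequences:
            raise ValidationError(f"block {block.peak_id!r}: taxon {t!r} absent")
        out.append(np.frombuffer(block.sequences[t].encode("ascii"), np.uint8))
    return np.stack(out) if out else np.empty((0, block.n_columns), np.uint8)


def _runs(mask: np.ndarray):
    """Yield (start, length) of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def _archaic_state(segment_archaic: str, segment_human: str,
                   segment_outgroup: str) -> str:
    if "N" in segment_archaic:
        return "missing"
    if segment_archaic == segment_human:
        return "derived"
    if segment_archaic == segment_outgroup:
        return "ancestral"
    return "missing"


def count_hsas(block: AlignmentBlock, comparison_taxa: Sequence[str],
               archaic_taxa: Sequence[str] = ()) -> list[HSARecord]:
    """Enumerate human-specific alterations in one alignment block."""
    if not comparison_taxa:
        raise ValidationError("need at least one comparison taxon")
    human = _rows(block, ["human"])[0]
    comp = _rows(block, list(comparison_taxa))
    arch = {t: block.sequences[t] for t in archaic_taxa if t in block.sequences}
    for t in archaic_taxa:
        if t not in block.sequences:
            raise ValidationError(f"block {block.peak_id!r}: archaic taxon {t!r} absent")

    agree = np.all(comp == comp[0], axis=0)
    out = comp[0]
    out_base = agree & (out != _GAP) & (out != _N)
    out_gap = agree & (out == _GAP)
    h_base = (human != _GAP) & (human != _N)
    h_gap = human == _GAP

    hseq = block.sequences["human"]
    oseq = out.tobytes().decode("ascii")

    records: list[HSARecord] = []

    def add(col, kind, length):
        h_seg = hseq[col:col + length]
        o_seg = oseq[col:col + length]
        states = {t: _archaic_state(seq[col:col + length], h_seg, o_seg)
                  for t, seq in arch.items()}
        records.append(HSARecord(
            peak_id=block.peak_id, column=int(col), kind=kind,
            human_allele=h_seg, outgroup_allele=o_seg,
            length=int(length), archaic_states=states,
        ))

    for col in np.flatnonzero(out_base & h_base & (human != out)):
        add(int(col), "substitution", 1)
    for start, length in _runs(h_gap & out_base):
        add(start, "long_indel" if length >= LONG_INDEL_MIN else "deletion", length)
    for start, length in _runs(h_base & out_gap):
        add(start, "long_indel" if length >= LONG_INDEL_MIN else "insertion", length)
    records.sort(key=lambda r: r.column)
    return records


def archaic_fraction(hsas: Sequence[HSARecord], taxon: str) -> float:
    """Fraction of informative HSAs that postdate the split from ``taxon``.

    Post-split = the archaic carries the ancestral (outgroup) allele.
    """
    states = [r.archaic_states.get(taxon, "missing") for r in hsas]
    informative = [s for s in states if s != "missing"]
    if not informative:
        raise ValidationError(f"no informative archaic states for {taxon!r}")
    return sum(s == "ancestral" for s in informative) / len(informative)


def hsa_rates(blocks: Sequence[AlignmentBlock], comparison_taxa: Sequence[str],
              kinds: Sequence[str] | None = None) -> pd.Series:
    """HSA events per kb of ungapped human sequence, per peak."""
    rates = {}
    for block in blocks:
        hlen = sum(1 for c in block.sequences["human"] if c != "-")
        if hlen == 0:
            raise ValidationError(f"block {block.peak_id!r}: empty human sequence")
        events = count_hsas(block, comparison_taxa)
        if kinds is not None:
            events = [e for e in events if e.kind in kinds]
        rates[block.peak_id] = len(events) / (hlen / 1000)
    return pd.Series(rates, name="hsa_per_kb")


def compare_groups(rates_a: Sequence[float], rates_b: Sequence[float],
                   n_sims: int = 10_000, seed: int = 0) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum plus label-permutation test on mean diff."""
    a = np.asarray(list(rates_a), float)
    b = np.asarray(list(rates_b), float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if min(a.size, b.size) <= 12 and not ties:
        wp = exact_mwu_two_sided(a, b)
    else:
        wp = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").pvalue)
    rng = np.random.default_rng(seed)
    pp = permutation_mean_diff_p(a, b, n_sims, rng)
    return GroupComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        n_a=a.size,
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)) if b.size > 1 else 0.0,
        n_b=b.size,
        wilcoxon_p=wp, permutation_p=pp, n_sims=n_sims, rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# motifs


def _pattern_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" for c in pattern.upper()))


def scan_motif(sequence: str, pattern: MotifPattern) -> list[tuple[int, str]]:
    """All matches of an IUPAC pattern on both strands of a gap-free sequence.

    Reverse-strand matches are reported at their forward-strand start.
    A sequence N only matches the pattern letter N.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"illegal sequence characters {sorted(bad)}")
    hits: list[tuple[int, str]] = []
    fwd = _pattern_regex(pattern.pattern)
    for m in re.finditer(f"(?=({fwd.pattern}))", seq):
        hits.append((m.start(), "+"))
    rc = pattern.reverse_complement
    rcre = _pattern_regex(rc)
    for m in re.finditer(f"(?=({rcre.pattern}))", seq):
        hits.append((m.start(), "-"))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _ungapped_with_columns(seq: str):
    arr = np.frombuffer(seq.encode("ascii"), np.uint8)
    cols = np.flatnonzero(arr != _GAP)
    return seq.replace("-", ""), cols


def _match_windows(seq: str, pattern: MotifPattern):
    """Matches in the ungapped projection, as (col_start, col_end, strand)."""
    ungapped, cols = _ungapped_with_columns(seq)
    m = len(pattern.pattern)
    out = []
    for pos, strand in scan_motif(ungapped, pattern):
        out.append((int(cols[pos]), int(cols[pos + m - 1]), strand))
    return out


def _overlaps(w, windows) -> bool:
    return any(not (w[1] < o[0] or o[1] < w[0]) for o in windows)


def motif_events(block: AlignmentBlock, pattern: MotifPattern,
                 comparison_taxa: Sequence[str]) -> list[MotifEvent]:
    """Motif gains and losses on the human branch, resolved via alignment columns.

    gained: a human match whose aligned column window carries no match in
    any comparison taxon.  lost: a match present in every comparison taxon
    at overlapping column windows, with no human match there.
    """
    if not comparison_taxa:
        raise ValidationError("need at least one comparison taxon")
    for t in comparison_taxa:
        if t not in block.sequences:
            raise ValidationError(f"block {block.peak_id!r}: taxon {t!r} absent")
    human_w = _match_windows(block.sequences["human"], pattern)
    comp_w = {t: _match_windows(block.sequences[t], pattern)
              for t in comparison_taxa}

    events: list[MotifEvent] = []
    all_comp = [w for ws in comp_w.values() for w in ws]
    for w in human_w:
        if not _overlaps(w, all_comp):
            events.append(MotifEvent(block.peak_id, w[0], w[2], "gained"))

    first = comparison_taxa[0]
    seen: set[tuple[int, int]] = set()
    for w in comp_w[first]:
        if (w[0], w[1]) in seen:
            continue
        shared = all(_overlaps(w, comp_w[t]) for t in comparison_taxa[1:])
        if shared and not _overlaps(w, human_w):
            events.append(MotifEvent(block.peak_id, w[0], w[2], "lost"))
            seen.add((w[0], w[1]))
    events.sort(key=lambda e: (e.column, e.kind, e.strand))
    return events


def motif_site_counts(block: AlignmentBlock, pattern: MotifPattern,
                      comparison_taxa: Sequence[str]) -> tuple[int, int]:
    """(human site count, comparison-shared site count) for one block.

    These are the denominators of the gain/loss 2x2 table: gains are
    scored against human sites, losses against sites shared by all
    comparison taxa.
    """
    human_w = _match_windows(block.sequences["human"], pattern)
    comp_w = {t: _match_windows(block.sequences[t], pattern)
              for t in comparison_taxa}
    first = comparison_taxa[0]
    shared = sum(
        1 for w in comp_w[first]
        if all(_overlaps(w, comp_w[t]) for t in comparison_taxa[1:])
    )
    return len(human_w), shared


def hsas_to_frame(hsas: Sequence[HSARecord]) -> pd.DataFrame:
    rows = []
    for r in hsas:
        row = {"peak_id": r.peak_id, "column": r.column, "kind": r.kind,
               "human_allele": r.human_allele, "outgroup_allele": r.outgroup_allele,
               "length": r.length}
        for t, s in r.archaic_states.items():
            row[f"state_{t}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def motif_gain_loss_table(n_lost: int, n_lost_total: int, n_gained: int,
                          n_gained_total: int) -> dict:
    """2x2 chi-square on motif loss vs gain counts (Pearson and Yates)."""
    table = np.array([[n_lost, n_lost_total - n_lost],
                      [n_gained, n_gained_total - n_gained]], float)
    pearson = stats.chi2_contingency(table, correction=False)
    yates = stats.chi2_contingency(table, correction=True)
    return {
        "lost": n_lost, "lost_total": n_lost_total,
        "gained": n_gained, "gained_total": n_gained_total,
        "chi2_pearson": float(pearson.statistic), "p_pearson": float(pearson.pvalue),
        "chi2_yates": float(yates.statistic), "p_yates": float(yates.pvalue),
    }


def read_motif_patterns(path) -> list[MotifPattern]:
    """Read a 2-column TSV (name, IUPAC string) of motif patterns."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "pattern"],
                     comment="#", dtype=str)
    return [MotifPattern(str(r["name"]), str(r["pattern"]).upper())
            for _, r in df.iterrows()]
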