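"""Readers/writers for the standard genomics formats the pipeline touches.

All genomic intervals are 0-based half-open (BED convention) internally.
Peak ids are the authoritative join keys between the BED atlas, the
count matrix, and alignment blocks; an id mismatch is a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from crosspeak.errors import FormatError, ValidationError

SPECIES = frozenset({"human", "chimpanzee", "macaque"})
# "input" rides the same metadata path so mononucleosomal input libraries
# can be carried through quantification like any other sample.
CELL_TYPES = frozenset({"NeuN+", "NeuN-", "blood", "input"})
AGE_GROUPS = frozenset({"child", "adult", "unknown"})
ALIGNMENT_ALPHABET = frozenset("ACGTN-")


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome name -> length (bp) for one named assembly."""

    chrom_lengths: Mapping[str, int]
    assembly: str = "custom"

    def __post_init__(self):
        for name, length in self.chrom_lengths.items():
            if not isinstance(length, (int,)) or length <= 0:
                raise ValidationError(
                    f"chromosome {name!r}: length must be a positive integer, got {length!r}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r} for assembly {self.assembly!r}")


@dataclass(frozen=True)
class Peak:
    """A genomic interval (0-based half-open) with a unique id."""

    id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"peak {self.id!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    species: str
    cell_type: str
    library_size: int
    age_group: str = "unknown"

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r} (sample {self.sample_id!r})")
        if self.cell_type not in CELL_TYPES:
            raise ValidationError(
                f"unknown cell type {self.cell_type!r} (sample {self.sample_id!r})"
            )
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"unknown age group {self.age_group!r} (sample {self.sample_id!r})"
            )
        if self.library_size <= 0:
            raise ValidationError(
                f"library_size must be positive (sample {self.sample_id!r})"
            )


@dataclass
class AnnotationSet:
    """A named collection of genomic intervals (may overlap each other)."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def validate(self, layout: GenomeLayout) -> None:
        for chrom, start, end in self.intervals:
            if chrom not in layout:
                raise ValidationError(f"annotation {self.name!r}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= layout.length_of(chrom)):
                raise ValidationError(
                    f"annotation {self.name!r}: bad interval {chrom}:{start}-{end}"
                )


@dataclass
class AlignmentBlock:
    """One multi-taxon alignment over a peak; equal-length rows, human required."""

    peak_id: str
    sequences: dict[str, str]

    def __post_init__(self):
        if "human" not in self.sequences:
            raise ValidationError(f"block {self.peak_id!r}: missing human reference row")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValidationError(
                f"block {self.peak_id!r}: unequal row lengths {sorted(lengths)}"
            )
        for taxon, seq in self.sequences.items():
            bad = set(seq) - ALIGNMENT_ALPHABET
            if bad:
                raise ValidationError(
                    f"block {self.peak_id!r}, taxon {taxon!r}: illegal characters {sorted(bad)}"
                )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)


def _norm_cell_type(token: str) -> str:
    # tolerate the unicode minus occasionally found in metadata exports
    return token.replace("−", "-").replace("–", "-")


def read_peaks(path, layout: GenomeLayout) -> list[Peak]:
    """Parse a BED3/BED4 file into validated peaks, preserving file order.

    A missing 4th (name) column yields auto ids ``peak_1..peak_n``.
    """
    peaks: list[Peak] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            if chrom not in layout:
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end):
                raise FormatError(
                    f"{path}:{lineno}: malformed record, need 0 <= start < end "
                    f"(got {start}, {end})"
                )
            if end > layout.length_of(chrom):
                raise ValidationError(
                    f"{path}:{lineno}: interval end {end} beyond {chrom} length "
                    f"{layout.length_of(chrom)}"
                )
            pid = fields[3] if len(fields) >= 4 and fields[3] else f"peak_{len(peaks) + 1}"
            if pid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate peak id {pid!r}")
            seen.add(pid)
            peaks.append(Peak(pid, chrom, start, end))
    return peaks


def write_peaks(peaks: Iterable[Peak], path) -> None:
    """Write peaks as BED4 (round-trips byte-for-byte with read_peaks)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\n")


def read_annotations(path, layout: GenomeLayout, name: str | None = None) -> AnnotationSet:
    """Read a BED3+ file as an annotation set (name defaults to the file stem)."""
    name = name if name is not None else Path(path).stem
    annot = AnnotationSet(name=name)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            annot.intervals.append((chrom, start, end))
    annot.validate(layout)
    return annot


def write_annotations(annot: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in annot.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_sample_table(path) -> list[SampleMeta]:
    """Read a TSV sample table (header row required) into validated metadata.

    Required columns: sample_id, species, cell_type, library_size.
    Optional: age_group (defaults to "unknown").
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "species", "cell_type", "library_size"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    samples: list[SampleMeta] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in seen:
            raise ValidationError(f"{path}: duplicate sample id {sid!r}")
        seen.add(sid)
        try:
            lib = int(row["library_size"])
        except (TypeError, ValueError):
            raise FormatError(f"{path}: non-integer library_size for sample {sid!r}")
        age = row.get("age_group", "unknown")
        if pd.isna(age):
            age = "unknown"
        samples.append(
            SampleMeta(
                sample_id=sid,
                species=str(row["species"]),
                cell_type=_norm_cell_type(str(row["cell_type"])),
                library_size=lib,
                age_group=str(age),
            )
        )
    return samples


def write_sample_table(samples: Sequence[SampleMeta], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "species": [s.species for s in samples],
            "cell_type": [s.cell_type for s in samples],
            "library_size": [s.library_size for s in samples],
            "age_group": [s.age_group for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_count_matrix(path, peaks: Sequence[Peak] | None = None,
                      samples: Sequence[SampleMeta] | None = None) -> pd.DataFrame:
    """Read a peak x sample tag-count TSV (first column = peak id).

    If ``peaks``/``samples`` are given, ids must match exactly (order-free);
    a mismatch is an error, never a silent drop.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{path}: missing entries in count matrix")
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative tag counts")
    if peaks is not None:
        want = [p.id for p in peaks]
        if set(want) != set(df.index):
            raise ValidationError(f"{path}: peak ids do not match the peak set")
        df = df.loc[want]
    if samples is not None:
        want_s = [s.sample_id for s in samples]
        if set(want_s) != set(df.columns):
            raise ValidationError(f"{path}: sample ids do not match the sample table")
        df = df[want_s]
    return df


def write_count_matrix(matrix: pd.DataFrame, path, float_format: str | None = None) -> None:
    matrix.to_csv(path, sep="\t", index_label="peak_id", float_format=float_format)


def read_alignment_blocks(path) -> list[AlignmentBlock]:
    """Read aligned multi-FASTA with headers ``>taxon|peak_id`` into blocks.

    Records sharing one peak_id form a block; sequences are upper-cased and
    validated (equal lengths, restricted alphabet, human row present).
    """
    by_peak: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise FormatError(f"{path}: header {rec.id!r} is not of the form taxon|peak_id")
        taxon, peak_id = rec.id.split("|", 1)
        if peak_id not in by_peak:
            by_peak[peak_id] = {}
            order.append(peak_id)
        if taxon in by_peak[peak_id]:
            raise FormatError(f"{path}: duplicate taxon {taxon!r} in block {peak_id!r}")
        by_peak[peak_id][taxon] = str(rec.seq).upper()
    return [AlignmentBlock(pid, by_peak[pid]) for pid in order]


def write_alignment_blocks(blocks: Iterable[AlignmentBlock], path) -> None:
    records = []
    for block in blocks:
        for taxon, seq in block.sequences.items():
            records.append(SeqRecord(Seq(seq), id=f"{taxon}|{block.peak_id}", description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [p.id for p in peaks],
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "length": [p.length for p in peaks],
        }
    ).set_index("peak_id")


def peak_lengths(peaks: Sequence[Peak]) -> pd.Series:
    return pd.Series({p.id: p.length for p in peaks}, name="length")
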