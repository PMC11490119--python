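"""Sequence and annotation I/O.

Internal coordinates are 0-based half-open on every code path; 1-based
inclusive conventions (RepeatMasker ``.out``, BLAST tabular) are converted at
the format boundary and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence as TypingSequence

from Bio import SeqIO

__all__ = [
    "Sequence",
    "GenomicInterval",
    "AnnotationSet",
    "read_fasta",
    "write_fasta",
    "normalize_single_line",
    "chunk_sequences",
    "read_repeatmasker_out",
    "read_bed",
    "write_bed",
    "revcomp",
]

# IUPAC one-letter DNA codes; ambiguity codes other than N are demoted to N on
# input so downstream scanning only ever sees the 5-letter alphabet.
_CANONICAL = set("ACGTN")
_AMBIGUITY = set("RYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(residues: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence (uppercase A/C/G/T/N)."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware location on a named sequence, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AnnotationSet:
    """A bag of genomic intervals under one label (e.g. ``"SINE"``).

    Overlap between members is permitted; merging is an explicit operation
    (see :func:`merge_intervals`).
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    label: str = "SINE"

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def sorted(self) -> "AnnotationSet":
        return AnnotationSet(sorted(self.intervals), self.label)

    def total_bp(self) -> int:
        """Total bp covered after unioning self-overlaps."""
        return sum(e - s for _, s, e in merge_intervals(self.intervals))


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[tuple[str, int, int]]:
    """Union overlapping/touching intervals, strand-blind.

    Returns (seq_id, start, end) triples sorted by (seq_id, start).
    """
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end))
    out: list[tuple[str, int, int]] = []
    for seq_id in sorted(by_seq):
        spans = sorted(by_seq[seq_id])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((seq_id, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((seq_id, cur_s, cur_e))
    return out


def _clean_residues(seq_id: str, raw: str) -> str:
    residues = raw.upper()
    bad = set(residues) - _CANONICAL
    if not bad:
        return residues
    if bad <= _AMBIGUITY:
        warnings.warn(
            f"sequence {seq_id!r}: IUPAC ambiguity codes "
            f"{sorted(bad)} mapped to N"
        )
        return residues.translate(str.maketrans({c: "N" for c in bad}))
    offender = next(c for c in residues if c not in _CANONICAL | _AMBIGUITY)
    pos = residues.index(offender)
    raise ValueError(
        f"sequence {seq_id!r}: non-IUPAC character {offender!r} at position {pos}"
    )


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a (multi-line) FASTA file into uppercase :class:`Sequence` records.

    Duplicate ids and non-IUPAC characters raise; ambiguity codes other than
    N are mapped to N with a warning; an empty file warns and returns [].
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        warnings.warn(f"{path}: no FASTA records found")
        return []
    seen: set[str] = set()
    out: list[Sequence] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        out.append(Sequence(rec.id, _clean_residues(rec.id, str(rec.seq))))
    return out


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 60) -> int:
    """Write sequences as wrapped FASTA; returns the record count."""
    n = 0
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")
            if not seq.residues:
                fh.write("\n")
            n += 1
    return n


def normalize_single_line(in_path: str | Path, out_path: str | Path) -> int:
    """Rewrite a FASTA file with one sequence line per record.

    Residue bytes are preserved verbatim (no case change); returns the number
    of records written. Structure-sensitive downstream steps assume this
    normalization has been applied.
    """
    n = 0
    with open(in_path) as fin, open(out_path, "w") as fout:
        header: str | None = None
        parts: list[str] = []

        def flush() -> None:
            nonlocal n
            if header is not None:
                fout.write(header + "\n")
                fout.write("".join(parts) + "\n")
                n += 1

        for line in fin:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line
                parts = []
            elif line:
                if header is None:
                    raise ValueError(f"{in_path}: sequence data before header")
                parts.append(line)
        flush()
    return n


def chunk_sequences(
    seqs: Iterable[Sequence], chunk_size: int = 10_000, overlap: int = 2_000
) -> list[tuple[Sequence, int]]:
    """Split sequences into overlapping chunks for windowed scanning.

    Adjacent chunks share exactly ``overlap`` bp; ``origin_offset`` maps chunk
    coordinate 0 back to the parent coordinate. Every parent position appears
    in at least one chunk.
    """
    if overlap < 0 or chunk_size <= overlap:
        raise ValueError("chunk_size must exceed overlap and overlap be >= 0")
    stride = chunk_size - overlap
    out: list[tuple[Sequence, int]] = []
    for seq in seqs:
        offset = 0
        while True:
            chunk = seq.residues[offset : offset + chunk_size]
            out.append((Sequence(seq.id, chunk), offset))
            if offset + chunk_size >= len(seq.residues):
                break
            offset += stride
    return out


def read_repeatmasker_out(
    path: str | Path, class_filter: str | None = "SINE"
) -> AnnotationSet:
    """Parse a classic 15-column RepeatMasker ``.out`` report.

    1-based inclusive begin/end become 0-based half-open; strand ``C`` becomes
    ``-``. Only rows whose repeat class/family starts with ``class_filter``
    are kept (None keeps everything). Malformed rows are skipped with a
    counted warning; a file whose every row is malformed raises.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    rows = 0
    skipped = 0
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            # header lines: "SW perc ..." / "score div ..."
            if not fields[0].replace(".", "").isdigit():
                continue
            if len(fields) < 11:
                skipped += 1
                rows += 1
                continue
            rows += 1
            try:
                seq_id = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
                strand = fields[8]
                rep_class = fields[10]
                if strand not in ("+", "C"):
                    raise ValueError("bad strand")
                iv = GenomicInterval(
                    seq_id, begin - 1, end, "-" if strand == "C" else "+"
                )
            except (ValueError, IndexError):
                skipped += 1
                continue
            if class_filter is None or rep_class.startswith(class_filter):
                intervals.append(iv)
    if rows and skipped == rows:
        raise ValueError(f"{path}: all {rows} rows malformed")
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} malformed row(s)")
    return AnnotationSet(intervals, class_filter or "repeat")


def read_bed(path: str | Path) -> AnnotationSet:
    """Read BED3+ (0-based half-open; column 6 strand honored if present)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
            intervals.append(GenomicInterval(fields[0], start, end, strand))
    return AnnotationSet(intervals)


def write_bed(
    annot: AnnotationSet,
    path: str | Path,
    names: TypingSequence[str] | None = None,
    scores: TypingSequence[int] | None = None,
) -> None:
    """Write BED6 (name defaults to the set label, score to 0)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(annot):
            name = names[i] if names is not None else annot.label
            score = scores[i] if scores is not None else 0
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )
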