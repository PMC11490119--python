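"""PAF ingestion and BLAST tabular-format-6 interchange.

Minimap2 emits PAF (0-based half-open); the copy-number machinery consumes
the 12-column BLAST outfmt-6 layout (1-based inclusive, minus strand
signalled by sstart > send). Conversion is streamed in bounded chunks and
the output is sharded so arbitrarily large alignment sets never have to be
held in memory at once.

outfmt-6 has two columns with no PAF equivalent: evalue is emitted as the
sentinel ``-1`` and bitscore as the matching-base count. Downstream logic
consumes coordinates and identity, never these surrogates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "PafRecord",
    "Tab6Record",
    "ConversionManifest",
    "parse_paf_line",
    "paf_to_tab6",
    "format_tab6",
    "parse_tab6_line",
    "read_tab6",
    "convert_paf_stream",
    "choose_alignment_mode",
]

_CIGAR_RUN = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    blocklen: int
    mapq: int
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(f"bad query span in {self.qname}")
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(f"bad target span in {self.qname}->{self.tname}")
        if self.nmatch > self.blocklen:
            raise ValueError("nmatch exceeds block length")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def tag(self, key: str) -> str | None:
        prefix = key + ":"
        for t in self.tags:
            if t.startswith(prefix):
                return t.split(":", 2)[2]
        return None

    @property
    def is_secondary(self) -> bool:
        return self.tag("tp") == "S"


@dataclass(frozen=True)
class Tab6Record:
    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


def parse_paf_line(line: str) -> PafRecord:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError("PAF line has fewer than 12 columns")
    return PafRecord(
        qname=f[0],
        qlen=int(f[1]),
        qstart=int(f[2]),
        qend=int(f[3]),
        strand=f[4],
        tname=f[5],
        tlen=int(f[6]),
        tstart=int(f[7]),
        tend=int(f[8]),
        nmatch=int(f[9]),
        blocklen=int(f[10]),
        mapq=int(f[11]),
        tags=tuple(f[12:]),
    )


def _gapopen_from_cigar(cigar: str | None) -> int:
    if not cigar:
        return 0
    return sum(1 for _, op in _CIGAR_RUN.findall(cigar) if op in "ID")


def paf_to_tab6(rec: PafRecord) -> Tab6Record:
    """Convert one PAF record to outfmt 6.

    pident = 100·nmatch/blocklen; query coordinates become 1-based
    inclusive; on the minus strand the subject span is reported reversed
    (sstart > send) per BLAST convention. Gap opens are counted from the
    ``cg`` CIGAR tag when present (one per indel run), else 0.
    """
    if rec.blocklen == 0:
        raise ValueError("zero-length alignment block")
    if rec.strand == "+":
        sstart, send = rec.tstart + 1, rec.tend
    else:
        sstart, send = rec.tend, rec.tstart + 1
    return Tab6Record(
        qseqid=rec.qname,
        sseqid=rec.tname,
        pident=100.0 * rec.nmatch / rec.blocklen,
        length=rec.blocklen,
        mismatch=rec.blocklen - rec.nmatch,
        gapopen=_gapopen_from_cigar(rec.tag("cg")),
        qstart=rec.qstart + 1,
        qend=rec.qend,
        sstart=sstart,
        send=send,
        evalue=-1.0,
        bitscore=float(rec.nmatch),
    )


def format_tab6(rec: Tab6Record) -> str:
    evalue = "-1" if rec.evalue == -1 else f"{rec.evalue:g}"
    bits = (
        str(int(rec.bitscore))
        if float(rec.bitscore).is_integer()
        else f"{rec.bitscore:g}"
    )
    return (
        f"{rec.qseqid}\t{rec.sseqid}\t{rec.pident:.3f}\t{rec.length}\t"
        f"{rec.mismatch}\t{rec.gapopen}\t{rec.qstart}\t{rec.qend}\t"
        f"{rec.sstart}\t{rec.send}\t{evalue}\t{bits}"
    )


def parse_tab6_line(line: str) -> Tab6Record:
    f = line.rstrip("\n").split("\t")
    if len(f) != 12:
        raise ValueError("outfmt-6 line must have 12 columns")
    return Tab6Record(
        qseqid=f[0],
        sseqid=f[1],
        pident=float(f[2]),
        length=int(f[3]),
        mismatch=int(f[4]),
        gapopen=int(f[5]),
        qstart=int(f[6]),
        qend=int(f[7]),
        sstart=int(f[8]),
        send=int(f[9]),
        evalue=float(f[10]),
        bitscore=float(f[11]),
    )


def read_tab6(path: str | Path) -> list[Tab6Record]:
    with open(path) as fh:
        return [parse_tab6_line(line) for line in fh if line.strip()]


@dataclass
class ConversionManifest:
    """Bookkeeping for a sharded PAF->tab6 conversion."""

    shards: list[Path] = field(default_factory=list)
    records_per_shard: list[int] = field(default_factory=list)
    converted: int = 0
    skipped: int = 0

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"converted\t{self.converted}\n")
            fh.write(f"skipped\t{self.skipped}\n")
            for shard, n in zip(self.shards, self.records_per_shard):
                fh.write(f"shard\t{shard.name}\t{n}\n")


def _chunked_lines(path: Path, chunk_lines: int) -> Iterator[list[str]]:
    chunk: list[str] = []
    with open(path) as fh:
        for line in fh:
            chunk.append(line)
            if len(chunk) >= chunk_lines:
                yield chunk
                chunk = []
    if chunk:
        yield chunk


def convert_paf_stream(
    in_path: str | Path,
    out_prefix: str | Path,
    chunk_lines: int = 100_000,
    shard_records: int = 100_000_000,
    drop_secondary: bool = False,
) -> ConversionManifest:
    """Stream-convert a PAF file to sharded outfmt-6 files.

    The input is read ``chunk_lines`` lines at a time (bounding resident
    records) and the output rolls over to a new shard every
    ``shard_records`` records. Concatenated shards hold exactly one record
    per valid input line, in input order. Malformed lines are skipped and
    counted in the returned manifest.
    """
    if chunk_lines < 1 or shard_records < 1:
        raise ValueError("chunk_lines and shard_records must be >= 1")
    in_path = Path(in_path)
    out_prefix = Path(out_prefix)
    manifest = ConversionManifest()
    shard_fh = None
    shard_count = 0

    def roll() -> None:
        nonlocal shard_fh, shard_count
        if shard_fh is not None:
            shard_fh.close()
        path = Path(f"{out_prefix}.{len(manifest.shards):05d}.tab6")
        shard_fh = open(path, "w")
        manifest.shards.append(path)
        manifest.records_per_shard.append(0)
        shard_count = 0

    for chunk in _chunked_lines(in_path, chunk_lines):
        rows: list[str] = []
        for line in chunk:
            if not line.strip():
                continue
            try:
                paf = parse_paf_line(line)
                if drop_secondary and paf.is_secondary:
                    continue
                rows.append(format_tab6(paf_to_tab6(paf)))
            except (ValueError, IndexError):
                manifest.skipped += 1
        for row in rows:
            if shard_fh is None or shard_count >= shard_records:
                roll()
            shard_fh.write(row + "\n")
            shard_count += 1
            manifest.records_per_shard[-1] += 1
            manifest.converted += 1
    if shard_fh is not None:
        shard_fh.close()
    manifest.write(Path(f"{out_prefix}.manifest.txt"))
    return manifest


def choose_alignment_mode(
    candidate_fasta_size_bytes: int, threshold_bytes: int = 10_000_000
) -> str:
    """Pick the external-aligner batching mode from candidate-file size.

    Above the threshold (default 10 Mb) the invocation contract adds the
    aligner's ``-K 1M`` batching flag ("low_memory"); at or below it the
    standard invocation is used. The comparison is strictly greater-than.
    """
    if candidate_fasta_size_bytes < 0 or threshold_bytes < 0:
        raise ValueError("sizes must be >= 0")
    return (
        "low_memory"
        if candidate_fasta_size_bytes > threshold_bytes
        else "standard"
    )
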