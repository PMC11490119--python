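"""Hermetic fixture generation: genomes with implanted SINE-like elements.

Every pipeline stage is testable without downloads: this module fabricates
background genomes, implants elements carrying the full structural signature
(left TSD + body + poly-A tail + right TSD, family copies with point
mutations), and writes the companion files external tools would normally
produce — an nhmmer-style hit table and a PAF of candidate-vs-genome
alignments — so fixtures double as format-conformance tests.

Truth intervals record the element body (tail included, TSDs excluded: the
duplication is host sequence, not element), which fixes what a "correct
boundary" means in recovery tests.

What this emulates and what it does not: implants have exact TSDs, clean
poly-A tails and uniform background; real SINEs carry tRNA-derived heads,
CpG decay, truncations and nested insertions, so passing recovery tests
bound the machinery's correctness, not real-genome accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .formats import AnnotationSet, GenomicInterval, Sequence, revcomp, write_fasta
from .homology import ProfileRecord

__all__ = [
    "make_genome",
    "implant_sines",
    "mock_hit_table",
    "mock_paf",
    "mock_profile_manifest",
    "ImplantMeta",
    "Fixture",
    "build_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_genome(length: int, gc: float = 0.4, seed: int = 0) -> Sequence:
    """An i.i.d. background sequence with the requested GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 < gc < 1):
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(_BASES, size=length, p=probs)
    return Sequence("synth1", arr.tobytes().decode("ascii"))


@dataclass(frozen=True)
class ImplantMeta:
    """Ground-truth record for one implanted element."""

    element_id: str
    family_id: str
    seq_id: str
    start: int  # element body start (TSD excluded)
    end: int
    strand: str
    tsd: str
    tail_len: int
    body: str  # oriented as inserted (reverse-complemented on "-")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def implant_sines(
    genome: Sequence,
    n_elements: int = 20,
    body_len_range: tuple[int, int] = (120, 400),
    tsd_len_range: tuple[int, int] = (10, 16),
    tail_len: int = 12,
    mutation_rate: float = 0.02,
    copies_per_family: int = 3,
    seed: int = 0,
    minus_fraction: float = 0.4,
) -> tuple[Sequence, AnnotationSet, list[ImplantMeta]]:
    """Overwrite background segments with TSD-flanked SINE-like elements.

    Family copies share a body and acquire per-copy point mutations in the
    body core at ``mutation_rate``; tails stay pure poly-A so the structural
    anchor is intact. TSDs are exact direct repeats whose first base is
    never A (an A there would fuse with the tail's A-run and blur the
    element end). Implants never overlap; placement failure after bounded
    retries raises.
    """
    if not (0 <= mutation_rate <= 0.3):
        raise ValueError("mutation_rate must lie in [0, 0.3]")
    if n_elements < 0 or copies_per_family < 1:
        raise ValueError("need n_elements >= 0 and copies_per_family >= 1")
    if n_elements == 0:
        return genome, AnnotationSet([], "SINE"), []
    rng = np.random.default_rng(seed)
    margin = 80  # keeps flank searches clear of sequence ends and neighbours
    arr = np.frombuffer(genome.residues.encode(), dtype=np.uint8).copy()
    n = len(arr)

    n_families = int(np.ceil(n_elements / copies_per_family))
    family_core: dict[int, str] = {}
    for fam in range(n_families):
        body_len = int(rng.integers(body_len_range[0], body_len_range[1] + 1))
        family_core[fam] = _random_dna(rng, body_len - tail_len)

    occupied: list[tuple[int, int]] = []
    truth: list[GenomicInterval] = []
    meta: list[ImplantMeta] = []
    for idx in range(n_elements):
        fam = idx % n_families
        core = _mutate(rng, family_core[fam], mutation_rate)
        body = core + "A" * tail_len
        tsd_len = int(rng.integers(tsd_len_range[0], tsd_len_range[1] + 1))
        tsd = rng.choice(np.frombuffer(b"CGT", dtype=np.uint8)).tobytes().decode(
            "ascii"
        ) + _random_dna(rng, tsd_len - 1)
        strand = "-" if rng.random() < minus_fraction else "+"
        element = body if strand == "+" else revcomp(body)
        slot_len = 2 * tsd_len + len(body)
        placed = False
        for _ in range(1000):
            pos = int(rng.integers(margin, n - slot_len - margin))
            if all(
                pos + slot_len + margin <= s or e + margin <= pos
                for s, e in occupied
            ):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place implant {idx} without overlap"
            )
        insert = tsd + element + tsd
        arr[pos : pos + slot_len] = np.frombuffer(
            insert.encode(), dtype=np.uint8
        )
        occupied.append((pos, pos + slot_len))
        start, end = pos + tsd_len, pos + tsd_len + len(body)
        truth.append(GenomicInterval(genome.id, start, end, strand))
        meta.append(
            ImplantMeta(
                element_id=f"el{idx:03d}",
                family_id=f"fam{fam:03d}",
                seq_id=genome.id,
                start=start,
                end=end,
                strand=strand,
                tsd=tsd,
                tail_len=tail_len,
                body=element,
            )
        )
    order = np.argsort([m.start for m in meta])
    truth = [truth[i] for i in order]
    meta = [meta[i] for i in order]
    return (
        Sequence(genome.id, arr.tobytes().decode("ascii")),
        AnnotationSet(truth, "SINE"),
        meta,
    )


def mock_hit_table(
    truth: AnnotationSet,
    metadata: Iterable[ImplantMeta],
    path: str | Path,
    seq_lengths: Mapping[str, int],
    dropout: float = 0.0,
    jitter: int = 0,
    seed: int = 0,
    split: bool = False,
    lineages: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Write an nhmmer-tblout-style hit table for the implanted elements.

    One hit per surviving element (dropped with probability ``dropout``)
    with boundary noise up to ``jitter`` bp; ``split`` emits two overlapping
    fragments per element instead, exercising the merge sweep. Returns the
    model -> lineage map (families alternate plant/animal by default).
    """
    if not (0 <= dropout < 1) or jitter < 0:
        raise ValueError("need dropout in [0,1) and jitter >= 0")
    rng = np.random.default_rng(seed)
    metadata = list(metadata)
    fams = sorted({m.family_id for m in metadata})
    lineage_map = dict(lineages) if lineages else {
        fam: ("animal" if i % 2 else "plant") for i, fam in enumerate(fams)
    }
    rows: list[str] = []

    def emit(m: ImplantMeta, start: int, end: int) -> None:
        # tblout is 1-based inclusive; reversed coordinates mean minus strand
        alifrom, alito = (start + 1, end) if m.strand == "+" else (end, start + 1)
        rows.append(
            f"{m.seq_id} - {m.family_id} - 1 {end - start} "
            f"{alifrom} {alito} {alifrom} {alito} "
            f"{seq_lengths[m.seq_id]} {m.strand} 1e-30 95.0 0.1 synthetic"
        )

    for m in metadata:
        if rng.random() < dropout:
            continue
        lo = m.start + int(rng.integers(-jitter, jitter + 1)) if jitter else m.start
        hi = m.end + int(rng.integers(-jitter, jitter + 1)) if jitter else m.end
        lo = max(0, lo)
        hi = min(seq_lengths[m.seq_id], max(hi, lo + 1))
        if split and hi - lo >= 80:
            mid = (lo + hi) // 2
            emit(m, lo, mid + 20)
            emit(m, mid - 20, hi)
        else:
            emit(m, lo, hi)
    with open(path, "w") as fh:
        fh.write("# synthetic nhmmer-style hit table\n")
        for row in rows:
            fh.write(row + "\n")
    return lineage_map


def mock_paf(
    metadata: Iterable[ImplantMeta],
    path: str | Path,
    seq_lengths: Mapping[str, int],
    divergence: float = 0.02,
    jitter: int = 0,
    seed: int = 0,
) -> None:
    """Write a PAF of each element's sequence aligned to its family copies.

    Queries are named by genomic locus (``seq:start-end``) as the pipeline
    names candidate sequences. The self-hit is exact; hits to sibling
    copies carry ``divergence`` mismatches and up to ``jitter`` bp of
    boundary slack on the query span.
    """
    rng = np.random.default_rng(seed)
    metadata = list(metadata)
    by_family: dict[str, list[ImplantMeta]] = {}
    for m in metadata:
        by_family.setdefault(m.family_id, []).append(m)
    with open(path, "w") as fh:
        for m in metadata:
            qlen = m.end - m.start
            qname = f"{m.seq_id}:{m.start}-{m.end}"
            for other in by_family[m.family_id]:
                tlen = seq_lengths[other.seq_id]
                if other.element_id == m.element_id:
                    q0, q1 = 0, qlen
                    nmatch_frac = 1.0
                else:
                    q0 = int(rng.integers(0, jitter + 1)) if jitter else 0
                    q1 = qlen - (int(rng.integers(0, jitter + 1)) if jitter else 0)
                    nmatch_frac = 1.0 - divergence
                blocklen = q1 - q0
                nmatch = max(1, round(blocklen * nmatch_frac))
                strand = "+" if other.strand == m.strand else "-"
                fh.write(
                    f"{qname}\t{qlen}\t{q0}\t{q1}\t{strand}\t"
                    f"{other.seq_id}\t{tlen}\t{other.start}\t{other.end}\t"
                    f"{nmatch}\t{blocklen}\t60\ttp:A:P\n"
                )


def mock_profile_manifest(
    n_total: int = 139, n_nonsine: int = 21, seed: int = 0
) -> list[ProfileRecord]:
    """A synthetic profile-database manifest for curation bookkeeping.

    ``n_total`` keyword-retrieved entries of which ``n_nonsine`` carry
    annotations with no SINE-related term (mirroring manual flagging of
    mislabelled retrievals).
    """
    if not (0 <= n_nonsine <= n_total):
        raise ValueError("need 0 <= n_nonsine <= n_total")
    rng = np.random.default_rng(seed)
    sine_descs = [
        "SINE tRNA-derived repeat family",
        "Short interspersed element (SINE), 7SL-derived",
        "SINE family consensus profile",
    ]
    nonsine_descs = [
        "LINE retrotransposon fragment",
        "LTR retrotransposon internal region",
        "Satellite repeat of unknown origin",
        "DNA transposon hAT superfamily",
    ]
    flags = np.zeros(n_total, dtype=bool)
    flags[rng.choice(n_total, size=n_nonsine, replace=False)] = True
    records = []
    for i in range(n_total):
        descs = nonsine_descs if flags[i] else sine_descs
        records.append(
            ProfileRecord(
                name=f"DF{i:06d}",
                description=descs[int(rng.integers(len(descs)))],
                classification=(
                    "Interspersed_Repeat;Unknown"
                    if flags[i]
                    else "Interspersed_Repeat;SINE"
                ),
            )
        )
    return records


@dataclass
class Fixture:
    """A complete hermetic test scenario on disk plus in-memory truth."""

    genome: Sequence
    truth: AnnotationSet
    metadata: list[ImplantMeta]
    fasta_path: Path
    hit_path: Path
    paf_path: Path
    lineage_map: dict[str, str]

    @property
    def genome_lengths(self) -> dict[str, int]:
        return {self.genome.id: len(self.genome)}


def build_fixture(
    workdir: str | Path,
    seed: int = 0,
    length: int = 100_000,
    n_elements: int = 20,
    copies_per_family: int = 3,
    mutation_rate: float = 0.02,
    hit_dropout: float = 0.25,
    hit_jitter: int = 0,
    paf_jitter: int = 0,
) -> Fixture:
    """Generate the default end-to-end fixture: genome + truth + mock files."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    background = make_genome(length, gc=0.4, seed=seed)
    genome, truth, meta = implant_sines(
        background,
        n_elements=n_elements,
        copies_per_family=copies_per_family,
        mutation_rate=mutation_rate,
        seed=seed + 1,
    )
    lengths = {genome.id: len(genome)}
    fasta_path = workdir / "genome.fa"
    write_fasta([genome], fasta_path)
    hit_path = workdir / "hits.tbl"
    lineage_map = mock_hit_table(
        truth, meta, hit_path, lengths, dropout=hit_dropout,
        jitter=hit_jitter, seed=seed + 2,
    )
    paf_path = workdir / "copies.paf"
    mock_paf(meta, paf_path, lengths, jitter=paf_jitter, seed=seed + 3)
    return Fixture(
        genome=genome,
        truth=truth,
        metadata=meta,
        fasta_path=fasta_path,
        hit_path=hit_path,
        paf_path=paf_path,
        lineage_map=lineage_map,
    )
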