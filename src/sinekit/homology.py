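"""Homology-based SINE discovery from profile-HMM hit tables.

Consumes nhmmer/HMMER tabular hit records, selects the plant/animal model
set (the ``-a`` flag), and merges overlapping alignments into genomic loci
with a single sorted sweep — replacing the quadratic pairwise-overlap pass
with an O(n log n) sort followed by one linear traversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional

from .formats import GenomicInterval, Sequence
from .structure import SineCandidate, StructureParams, find_tsd, TsdHit

__all__ = [
    "HmmHit",
    "MergedLocus",
    "ProfileRecord",
    "read_hmm_hits",
    "select_library",
    "merge_hits_sorted",
    "merge_hits_sorted_with_stats",
    "loci_to_candidates",
    "is_sine_profile",
    "curate_profiles",
]


@dataclass(frozen=True)
class HmmHit:
    """One profile-HMM alignment record (0-based half-open on the target)."""

    model: str
    target: str
    start: int
    end: int
    strand: str
    bit_score: float
    e_value: float
    lineage: str = "plant"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"hit {self.model}->{self.target}: start >= end")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass
class MergedLocus:
    """A chain of mutually overlapping hits collapsed to one genomic locus."""

    interval: GenomicInterval
    supporting_hits: list[HmmHit]
    best_model: str
    best_score: float


def read_hmm_hits(
    path: str | Path,
    lineage_map: Mapping[str, str] | None = None,
    default_lineage: str = "plant",
) -> list[HmmHit]:
    """Parse a whitespace-delimited nhmmer-style hit table.

    Expects the nhmmer ``--tblout`` column layout (target, t-acc, query,
    q-acc, hmm from/to, ali from/to, env from/to, sqlen, strand, E-value,
    score, bias, ...). Alignment coordinates are 1-based; reversed
    coordinates signal the minus strand. ``#`` comment lines are skipped.
    """
    hits: list[HmmHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 14:
                raise ValueError(f"{path}:{lineno}: expected >= 14 columns")
            try:
                alifrom, alito = int(f[6]), int(f[7])
                e_value, score = float(f[12]), float(f[13])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinate or score"
                ) from exc
            strand = "+" if alifrom <= alito else "-"
            lo, hi = sorted((alifrom, alito))
            model = f[2]
            lineage = (
                lineage_map.get(model, default_lineage)
                if lineage_map
                else default_lineage
            )
            hits.append(
                HmmHit(
                    model=model,
                    target=f[0],
                    start=lo - 1,
                    end=hi,
                    strand=strand,
                    bit_score=score,
                    e_value=e_value,
                    lineage=lineage,
                )
            )
    return hits


def select_library(hits: Iterable[HmmHit], a_flag: int) -> list[HmmHit]:
    """Apply the ``-a`` model-set switch: 0 plant, 1 animal, 2 both."""
    if a_flag not in (0, 1, 2):
        raise ValueError(f"a_flag must be 0, 1 or 2, got {a_flag}")
    if a_flag == 2:
        return list(hits)
    want = "plant" if a_flag == 0 else "animal"
    return [h for h in hits if h.lineage == want]


def _merge(
    hits: Iterable[HmmHit], max_gap: int
) -> tuple[list[MergedLocus], int]:
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_target: dict[str, list[HmmHit]] = {}
    for h in hits:
        by_target.setdefault(h.target, []).append(h)
    loci: list[MergedLocus] = []
    iterations = 0
    for target in sorted(by_target):
        # equal starts ordered larger-end-first so a contained hit never
        # opens a new chain
        ordered = sorted(by_target[target], key=lambda h: (h.start, -h.end))
        chain: list[HmmHit] = []
        chain_end = -1

        def close() -> None:
            best = max(chain, key=lambda h: h.bit_score)
            loci.append(
                MergedLocus(
                    interval=GenomicInterval(
                        target, chain[0].start, chain_end, best.strand
                    ),
                    supporting_hits=list(chain),
                    best_model=best.model,
                    best_score=best.bit_score,
                )
            )

        for h in ordered:
            iterations += 1
            if chain and h.start <= chain_end + max_gap:
                chain.append(h)
                chain_end = max(chain_end, h.end)
            else:
                if chain:
                    close()
                chain = [h]
                chain_end = h.end
        if chain:
            close()
    loci.sort(key=lambda l: (l.interval.seq_id, l.interval.start))
    return loci, iterations


def merge_hits_sorted(
    hits: Iterable[HmmHit], max_gap: int = 0
) -> list[MergedLocus]:
    """Merge overlapping hits per target with one sorted linear sweep.

    Hits whose start lies within ``max_gap`` of the running chain end join
    the chain; each closed chain becomes one :class:`MergedLocus` spanning
    the union of its members. Merging crosses models and strands: the goal
    is a genomic SINE locus, with ``best_model`` recording the dominant
    profile.
    """
    return _merge(hits, max_gap)[0]


def merge_hits_sorted_with_stats(
    hits: Iterable[HmmHit], max_gap: int = 0
) -> tuple[list[MergedLocus], int]:
    """Like :func:`merge_hits_sorted` but also returns the sweep-iteration
    count (linear in the number of hits after sorting)."""
    return _merge(hits, max_gap)


def loci_to_candidates(
    loci: Iterable[MergedLocus],
    genome: Mapping[str, Sequence] | None = None,
    params: StructureParams | None = None,
) -> list[SineCandidate]:
    """One homology candidate per merged locus.

    When the genome is supplied, the locus flanks are checked for a TSD
    (structural corroboration); a qualifying hit is stored on the candidate
    but its absence never drops a homology candidate.
    """
    params = params or StructureParams()
    out: list[SineCandidate] = []
    for locus in loci:
        iv = locus.interval
        tsd: Optional[TsdHit] = None
        if genome is not None and iv.seq_id in genome:
            residues = genome[iv.seq_id].residues
            left = residues[max(0, iv.start - params.flank_window) : iv.start]
            right = residues[iv.end : iv.end + params.flank_window]
            local = find_tsd(left, right, params)
            if local is not None:
                lf_start = max(0, iv.start - params.flank_window)
                tsd = TsdHit(
                    left=GenomicInterval(
                        iv.seq_id,
                        lf_start + local.left.start,
                        lf_start + local.left.end,
                    ),
                    right=GenomicInterval(
                        iv.seq_id,
                        iv.end + local.right.start,
                        iv.end + local.right.end,
                    ),
                    length=local.length,
                    mismatches=local.mismatches,
                    score=local.score,
                )
        out.append(
            SineCandidate(interval=iv, source_mode="homology", tsd=tsd)
        )
    return out


# --- profile-library curation bookkeeping ---------------------------------

#: terms accepted as SINE-related in profile descriptions/classifications
_SINE_TERMS = ("SINE", "TRNA-DERIVED", "7SL-DERIVED", "5S-DERIVED")


@dataclass(frozen=True)
class ProfileRecord:
    """One database profile entry as curated for the homology library."""

    name: str
    description: str = ""
    classification: str = ""


def is_sine_profile(record: ProfileRecord) -> bool:
    """A profile is SINE-related iff its description or classification
    mentions a SINE term; anything else is flagged non-SINE and excluded."""
    text = f"{record.description} {record.classification}".upper()
    return any(term in text for term in _SINE_TERMS)


def curate_profiles(records: Iterable[ProfileRecord]) -> list[ProfileRecord]:
    """Drop keyword-retrieved profiles whose annotations are not SINE-related."""
    return [r for r in records if is_sine_profile(r)]
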