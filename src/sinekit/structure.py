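"""Structure-based (de novo) SINE discovery.

A SINE insertion leaves a structural signature: a short direct repeat of host
sequence (the target site duplication, TSD) flanking the element, and a
poly-A tail at the element's 3' end. The scanner anchors on poly-A tail
terminations, then searches the regions flanking a plausible element body for
the best ungapped TSD pair.

TSD scoring: for an equal-length pair with ``m`` mismatches over length
``L``, score = matches - mismatches = L - 2m. A hit is reported only when the
best score reaches the score cutoff ``s_score`` and its mismatch count is
within the tolerance ``t``. Ties are broken toward greater length, then the
smaller left-flank offset, then the smaller right-flank offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .formats import GenomicInterval, Sequence, revcomp

__all__ = [
    "TsdHit",
    "StructureParams",
    "SineCandidate",
    "find_tsd",
    "find_tail",
    "scan_structure",
    "partition_scan",
]


@dataclass(frozen=True)
class TsdHit:
    """A target-site-duplication pair bracketing a putative element."""

    left: GenomicInterval
    right: GenomicInterval
    length: int
    mismatches: int
    score: int


@dataclass(frozen=True)
class StructureParams:
    """Tunables of the structural scan.

    ``t`` and ``s_score`` are the TSD mismatch tolerance and TSD score
    cutoff; ``flank_window`` is how far beyond the element each flank is
    searched; ``n_parts`` is the partition count for parallel decomposition.
    """

    t: int = 2
    s_score: int = 10
    tsd_min_len: int = 5
    tsd_max_len: int = 20
    flank_window: int = 40
    tail_min_len: int = 8
    tail_max_len: int = 64
    tail_purity: float = 0.9
    body_min_len: int = 80
    body_max_len: int = 800
    n_parts: int = 8

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("mismatch tolerance t must be >= 0")
        if not (0 < self.tsd_min_len <= self.tsd_max_len):
            raise ValueError("need 0 < tsd_min_len <= tsd_max_len")
        if not (0.5 < self.tail_purity <= 1.0):
            raise ValueError("tail_purity must be in (0.5, 1]")
        if self.n_parts < 1:
            raise ValueError("n_parts must be >= 1")
        if not (0 < self.body_min_len <= self.body_max_len):
            raise ValueError("need 0 < body_min_len <= body_max_len")
        if self.tail_min_len < 1 or self.tail_max_len < self.tail_min_len:
            raise ValueError("need 1 <= tail_min_len <= tail_max_len")


@dataclass
class SineCandidate:
    """A putative SINE locus with its supporting evidence.

    ``source_mode`` is fixed at creation ("homology" or "structure"); the
    hybrid pipeline relabels overlap-merged records "both".
    """

    interval: GenomicInterval
    source_mode: str
    tsd: Optional[TsdHit] = None
    tail: Optional[GenomicInterval] = None
    copies: int = 0
    family_id: Optional[str] = None
    original_interval: Optional[GenomicInterval] = None
    boundary_flagged: bool = False

    @property
    def id(self) -> str:
        iv = self.interval
        return f"{iv.seq_id}:{iv.start}-{iv.end}"


def _encode(residues: str) -> np.ndarray:
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8)


def _best_pair(
    left: np.ndarray,
    right: np.ndarray,
    min_len: int,
    max_len: int,
    t: int,
    allowed_left_end: np.ndarray | None = None,
) -> tuple[int, int, int, int, int] | None:
    """Best ungapped equal-length pair between two encoded regions.

    Returns (score, length, left_offset, right_offset, mismatches) or None.
    ``allowed_left_end``, when given, is a boolean mask over left-region end
    positions (length ``len(left)+1``) restricting where a pair may end on
    the left side. Tie order: score desc, length desc, left offset asc,
    right offset asc.
    """
    m, n = len(left), len(right)
    lmax = min(max_len, m, n)
    if lmax < min_len:
        return None
    best: tuple[int, int, int, int, int] | None = None
    cum = np.zeros((m, n), dtype=np.int32)
    for length in range(1, lmax + 1):
        k = length - 1
        diff = left[k:, None] != right[None, k:]
        view = cum[: m - k, : n - k]
        view += diff
        if length < min_len:
            continue
        ok = view <= t
        if allowed_left_end is not None:
            ok = ok & allowed_left_end[length : m - k + length, None]
        if not ok.any():
            continue
        scores = np.where(ok, length - 2 * view, np.iinfo(np.int32).min)
        top = int(scores.max())
        # later (longer) lengths win score ties; within a length, argwhere's
        # row-major order yields the smallest (i, j) pair
        if best is None or top > best[0] or (top == best[0] and length > best[1]):
            i, j = map(int, np.argwhere(scores == top)[0])
            best = (top, length, i, j, int(view[i, j]))
    return best


def find_tsd(
    left_flank: str, right_flank: str, params: StructureParams
) -> Optional[TsdHit]:
    """Best TSD pair between two flanks, or None below the score cutoff.

    Coordinates in the returned hit are local to each flank (seq ids
    ``left_flank`` / ``right_flank``); genomic callers rebase them.
    """
    if not left_flank or not right_flank:
        return None
    best = _best_pair(
        _encode(left_flank.upper()),
        _encode(right_flank.upper()),
        params.tsd_min_len,
        params.tsd_max_len,
        params.t,
    )
    if best is None or best[0] < params.s_score:
        return None
    score, length, i, j, mism = best
    return TsdHit(
        left=GenomicInterval("left_flank", i, i + length),
        right=GenomicInterval("right_flank", j, j + length),
        length=length,
        mismatches=mism,
        score=score,
    )


def find_tail(
    body: str,
    tail_min_len: int = 8,
    tail_purity: float = 0.9,
    strand: str = "+",
    tail_max_len: int | None = None,
) -> Optional[tuple[int, int]]:
    """Longest qualifying homopolymer tail window, as (start, end) in body.

    On "+" the tail is an A-rich suffix (3' poly-A); on "-" a T-rich prefix
    (the reverse-complement image of a poly-A tail). The longest window
    meeting the purity bound is taken and any leading (trailing, on "-")
    non-tail bases are stripped, so the reported tail begins and ends on the
    homopolymer base; the stripped window must still reach ``tail_min_len``.
    """
    if not body:
        return None
    base = "A" if strand == "+" else "T"
    n = len(body)
    cap = n if tail_max_len is None else min(n, tail_max_len)
    is_base = _encode(body.upper()) == ord(base)
    hits = np.concatenate(([0], np.cumsum(is_base)))
    for k in range(cap, tail_min_len - 1, -1):
        if strand == "+":
            count = hits[n] - hits[n - k]
        else:
            count = hits[k]
        if count / k < tail_purity:
            continue
        if strand == "+":
            lo, hi = n - k, n
            while lo < hi and not is_base[lo]:
                lo += 1
        else:
            lo, hi = 0, k
            while hi > lo and not is_base[hi - 1]:
                hi -= 1
        if hi - lo >= tail_min_len:
            return (lo, hi)
        return None
    return None


def _tail_length_at(
    is_a: np.ndarray, prefix_a: np.ndarray, e: int, params: StructureParams
) -> int:
    """Longest qualifying A-tail window ending at e, leading non-A stripped
    (0 if none reaches ``tail_min_len``)."""
    cap = min(params.tail_max_len, e)
    for k in range(cap, params.tail_min_len - 1, -1):
        if (prefix_a[e] - prefix_a[e - k]) / k < params.tail_purity:
            continue
        lo = e - k
        while lo < e and not is_a[lo]:
            lo += 1
        # stripping is monotone in k: if the longest window fails here,
        # every shorter one does too
        return e - lo if e - lo >= params.tail_min_len else 0
    return 0


def _scan_forward(
    residues: str, params: StructureParams
) -> list[tuple[int, int, int, int, int, int, int, int]]:
    """Scan one orientation of a sequence.

    Returns tuples (b, e, tsd_left_start, tsd_right_start, tsd_len,
    mismatches, score, tail_len): element [b, e) whose left TSD copy ends at
    b and whose right TSD copy starts at e + offset within the right flank.
    """
    n = len(residues)
    if n < params.body_min_len:
        return []
    arr = _encode(residues)
    is_a = arr == ord("A")
    prefix_a = np.concatenate(([0], np.cumsum(is_a)))

    # seeds: terminations of maximal A-runs (a poly-A tail ends in A)
    seed_mask = np.zeros(n + 1, dtype=bool)
    seed_mask[1:n] = is_a[:-1] & ~is_a[1:]
    seed_mask[n] = bool(is_a[-1]) if n else False
    seeds = np.flatnonzero(seed_mask)

    out = []
    for e in seeds:
        e = int(e)
        if e < params.body_min_len:
            continue
        tail_len = _tail_length_at(is_a, prefix_a, e, params)
        if tail_len == 0:
            continue
        lo = max(0, e - params.body_max_len - params.tsd_max_len)
        hi = e - params.body_min_len
        if hi - lo < params.tsd_min_len:
            continue
        left_region = arr[lo:hi]
        right_region = arr[e : e + params.flank_window]
        # restrict the left TSD copy to end where the body start lands in
        # the allowed body-length range
        allowed = np.zeros(hi - lo + 1, dtype=bool)
        p_lo = max(0, e - params.body_max_len - lo)
        p_hi = e - params.body_min_len - lo
        allowed[p_lo : p_hi + 1] = True
        best = _best_pair(
            left_region,
            right_region,
            params.tsd_min_len,
            params.tsd_max_len,
            params.t,
            allowed_left_end=allowed,
        )
        if best is None or best[0] < params.s_score:
            continue
        score, length, i, j, mism = best
        b = lo + i + length
        out.append((b, e, lo + i, e + j, length, mism, score, tail_len))
    return out


def _candidates_from_scan(
    seq_id: str, residues: str, params: StructureParams, offset: int = 0
) -> list[SineCandidate]:
    """Run both orientations, mapping local hits to parent coordinates."""
    n = len(residues)
    cands: list[SineCandidate] = []
    for b, e, tl, tr, length, mism, score, tail_len in _scan_forward(
        residues, params
    ):
        tsd = TsdHit(
            left=GenomicInterval(seq_id, offset + tl, offset + tl + length),
            right=GenomicInterval(seq_id, offset + tr, offset + tr + length),
            length=length,
            mismatches=mism,
            score=score,
        )
        cands.append(
            SineCandidate(
                interval=GenomicInterval(seq_id, offset + b, offset + e, "+"),
                source_mode="structure",
                tsd=tsd,
                tail=GenomicInterval(
                    seq_id, offset + max(b, e - tail_len), offset + e, "+"
                ),
            )
        )
    rc = revcomp(residues)
    for b, e, tl, tr, length, mism, score, tail_len in _scan_forward(rc, params):
        # map reverse-complement local coordinates [x, y) -> parent [n-y, n-x)
        def back(x: int, y: int) -> tuple[int, int]:
            return offset + n - y, offset + n - x

        s0, e0 = back(b, e)
        lts, lte = back(tr, tr + length)  # rc right copy is the parent-left one
        rts, rte = back(tl, tl + length)
        tsd = TsdHit(
            left=GenomicInterval(seq_id, lts, lte),
            right=GenomicInterval(seq_id, rts, rte),
            length=length,
            mismatches=mism,
            score=score,
        )
        ts, te = back(e - tail_len if e - tail_len > b else b, e)
        cands.append(
            SineCandidate(
                interval=GenomicInterval(seq_id, s0, e0, "-"),
                source_mode="structure",
                tsd=tsd,
                tail=GenomicInterval(seq_id, ts, te, "-"),
            )
        )
    return cands


def _dedup_sorted(cands: Iterable[SineCandidate]) -> list[SineCandidate]:
    seen: set[tuple[str, int, int, str]] = set()
    out: list[SineCandidate] = []
    for c in sorted(
        cands,
        key=lambda c: (c.interval.seq_id, c.interval.start, c.interval.end,
                       c.interval.strand),
    ):
        key = (c.interval.seq_id, c.interval.start, c.interval.end,
               c.interval.strand)
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


def scan_structure(
    seqs: Iterable[Sequence], params: StructureParams | None = None
) -> list[SineCandidate]:
    """Structure-based candidate scan over both strands of each sequence.

    Emits one candidate per qualifying (tail, TSD pair, body-length) triple,
    deduplicated by exact interval identity and sorted by position.
    """
    params = params or StructureParams()
    cands: list[SineCandidate] = []
    for seq in seqs:
        cands.extend(_candidates_from_scan(seq.id, seq.residues, params))
    return _dedup_sorted(cands)


def partition_scan(
    seqs: Iterable[Sequence],
    params: StructureParams | None = None,
    n_parts: int | None = None,
) -> list[SineCandidate]:
    """Partitioned structural scan; result equals :func:`scan_structure`.

    Each sequence is divided into ``n_parts`` parts whose windows carry
    ``flank_window + tsd_max_len + body_max_len`` bp of overlap on each side,
    guaranteeing every candidate is computed with full context in the part
    that owns its anchor position.
    """
    params = params or StructureParams()
    n_parts = params.n_parts if n_parts is None else n_parts
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    margin = params.flank_window + params.tsd_max_len + params.body_max_len
    cands: list[SineCandidate] = []
    for seq in seqs:
        n = len(seq.residues)
        if n == 0:
            continue
        k = min(n_parts, n)
        bounds = [round(i * n / k) for i in range(k + 1)]
        for p in range(k):
            core_lo, core_hi = bounds[p], bounds[p + 1]
            w0 = max(0, core_lo - margin)
            w1 = min(n, core_hi + margin)
            for c in _candidates_from_scan(
                seq.id, seq.residues[w0:w1], params, offset=w0
            ):
                # the scan anchor is the poly-A tail termination: the element
                # end on "+", the element start on "-"
                anchor = c.interval.end if c.interval.strand == "+" else c.interval.start
                if core_lo <= anchor < core_hi or (
                    anchor == n and core_hi == n
                ):
                    cands.append(c)
    return _dedup_sorted(cands)
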