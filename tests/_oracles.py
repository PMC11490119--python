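"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain exhaustive Python —
no numpy, no sorting tricks — so it shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def tsd_pair_oracle(left: str, right: str, min_len: int, max_len: int, t: int):
    """Exhaustive enumeration of all equal-length ungapped substring pairs.

    Returns (score, length, left_offset, right_offset, mismatches) for the
    best pair (score desc, length desc, left offset asc, right offset asc)
    or None when no pair has mismatches <= t.
    """
    best = None
    best_key = None
    for i in range(len(left)):
        for j in range(len(right)):
            mism = 0
            max_l = min(max_len, len(left) - i, len(right) - j)
            for k in range(max_l):
                if left[i + k] != right[j + k]:
                    mism += 1
                length = k + 1
                if length < min_len or mism > t:
                    continue
                score = length - 2 * mism
                key = (score, length, -i, -j)
                if best_key is None or key > best_key:
                    best_key = key
                    best = (score, length, i, j, mism)
    return best


def fixpoint_merge_oracle(spans, max_gap=0):
    """Quadratic repeated pairwise merging until stable.

    ``spans`` are (target, start, end) triples. Returns (sorted merged
    triples, number of pairwise comparisons performed).
    """
    items = [list(s) for s in spans]
    comparisons = 0
    while True:
        out: list[list] = []
        for item in items:
            merged = False
            for other in out:
                comparisons += 1
                if (
                    other[0] == item[0]
                    and item[1] <= other[2] + max_gap
                    and other[1] <= item[2] + max_gap
                ):
                    other[1] = min(other[1], item[1])
                    other[2] = max(other[2], item[2])
                    merged = True
                    break
            if not merged:
                out.append(item)
        if len(out) == len(items):
            return sorted(tuple(i) for i in out), comparisons
        items = out


def bitmask_eval_oracle(pred, truth, genome_lengths):
    """Confusion counts from explicit per-base boolean vectors."""
    masks_p = {s: np.zeros(n, dtype=bool) for s, n in genome_lengths.items()}
    masks_t = {s: np.zeros(n, dtype=bool) for s, n in genome_lengths.items()}
    for iv in pred:
        masks_p[iv.seq_id][iv.start : iv.end] = True
    for iv in truth:
        masks_t[iv.seq_id][iv.start : iv.end] = True
    tp = fp = fn = tn = 0
    for s in genome_lengths:
        p, t = masks_p[s], masks_t[s]
        tp += int((p & t).sum())
        fp += int((p & ~t).sum())
        fn += int((~p & t).sum())
        tn += int((~p & ~t).sum())
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _scan_forward_oracle(residues: str, params):
    n = len(residues)
    out = []
    for e in range(1, n + 1):
        if residues[e - 1] != "A":
            continue
        if e < n and residues[e] == "A":
            continue
        if e < params.body_min_len:
            continue
        tail = 0
        for k in range(min(params.tail_max_len, e), params.tail_min_len - 1, -1):
            win = residues[e - k : e]
            if win.count("A") / k >= params.tail_purity:
                stripped = len(win.lstrip("CGTN"))
                tail = stripped if stripped >= params.tail_min_len else 0
                break
        if tail == 0:
            continue
        lo = max(0, e - params.body_max_len - params.tsd_max_len)
        best = None
        best_key = None
        for length in range(params.tsd_min_len, params.tsd_max_len + 1):
            for b in range(
                max(lo + length, e - params.body_max_len),
                e - params.body_min_len + 1,
            ):
                i = b - length
                left = residues[i:b]
                for j in range(e, min(n, e + params.flank_window) - length + 1):
                    mism = sum(
                        a != c for a, c in zip(left, residues[j : j + length])
                    )
                    if mism > params.t:
                        continue
                    score = length - 2 * mism
                    key = (score, length, -(i - lo), -(j - e))
                    if best_key is None or key > best_key:
                        best_key = key
                        best = (b, score)
        if best is not None and best[1] >= params.s_score:
            out.append((best[0], e))
    return out


def structure_scan_oracle(seq_id: str, residues: str, params):
    """Brute-force structural scan: set of (seq_id, start, end, strand)."""
    n = len(residues)
    found = set()
    for b, e in _scan_forward_oracle(residues, params):
        found.add((seq_id, b, e, "+"))
    for b, e in _scan_forward_oracle(_revcomp(residues), params):
        found.add((seq_id, n - e, n - b, "-"))
    return found
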