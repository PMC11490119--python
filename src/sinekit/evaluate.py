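"""Base-pair-level benchmarking of predicted vs. reference annotations.

Whole-genome annotation accuracy is scored over bases, not elements: each
genomic base is a trial, and the confusion counts come from interval
arithmetic on the self-overlap-merged prediction and truth sets (so a
double-covered base is never counted twice). Strand is ignored, matching
how repeat-annotation ground truths are compared in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional

import pandas as pd

from .formats import AnnotationSet, merge_intervals

__all__ = ["EvalReport", "compare_annotations", "roc_sweep"]


@dataclass
class EvalReport:
    """bp-level confusion counts and derived rates.

    Undefined ratios (zero denominators) are reported as None rather than
    raising or returning an arbitrary number.
    """

    genome_bp: int
    truth_bp: int
    pred_bp: int
    tp_bp: int
    fp_bp: int
    fn_bp: int
    tn_bp: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    fpr: Optional[float]
    f1: Optional[float]

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _merged_by_seq(annot: AnnotationSet) -> dict[str, list[tuple[int, int]]]:
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for seq_id, start, end in merge_intervals(annot.intervals):
        by_seq.setdefault(seq_id, []).append((start, end))
    return by_seq


def _intersect_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def compare_annotations(
    pred: AnnotationSet,
    truth: AnnotationSet,
    genome_lengths: Mapping[str, int],
) -> EvalReport:
    """Score a predicted annotation against a truth annotation in bp.

    Both sets are unioned internally before comparison; every interval must
    lie within the declared genome lengths. TP bases are covered by both
    sets, FP by prediction only, FN by truth only, TN by neither.
    """
    for name, annot in (("pred", pred), ("truth", truth)):
        for iv in annot:
            if iv.seq_id not in genome_lengths:
                raise ValueError(
                    f"{name} interval on unknown sequence {iv.seq_id!r}"
                )
            if iv.end > genome_lengths[iv.seq_id]:
                raise ValueError(
                    f"{name} interval {iv.seq_id}:{iv.start}-{iv.end} "
                    f"exceeds sequence length {genome_lengths[iv.seq_id]}"
                )
    pred_m = _merged_by_seq(pred)
    truth_m = _merged_by_seq(truth)
    genome_bp = sum(genome_lengths.values())
    pred_bp = sum(e - s for spans in pred_m.values() for s, e in spans)
    truth_bp = sum(e - s for spans in truth_m.values() for s, e in spans)
    tp = sum(
        _intersect_bp(pred_m.get(seq, []), truth_m.get(seq, []))
        for seq in set(pred_m) | set(truth_m)
    )
    fp = pred_bp - tp
    fn = truth_bp - tp
    tn = genome_bp - (pred_bp + truth_bp - tp)
    sens = _ratio(tp, truth_bp)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, pred_bp)
    fpr = _ratio(fp, fp + tn)
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return EvalReport(
        genome_bp=genome_bp,
        truth_bp=truth_bp,
        pred_bp=pred_bp,
        tp_bp=tp,
        fp_bp=fp,
        fn_bp=fn,
        tn_bp=tn,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        fpr=fpr,
        f1=f1,
    )


def roc_sweep(
    truth: AnnotationSet,
    genome_lengths: Mapping[str, int],
    config_grid: Iterable[Mapping[str, object]],
    runner: Callable[[Mapping[str, object]], AnnotationSet],
) -> pd.DataFrame:
    """Run the pipeline across a parameter grid and tabulate (TPR, FPR).

    ``runner`` maps one grid entry (parameter overrides such as ``{"s": 10,
    "minc": 2}``) to the resulting predicted annotation on fixed inputs.
    Each output row carries the full parameter provenance plus ``tpr`` (=
    bp sensitivity) and ``fpr``.
    """
    grid = list(config_grid)
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    for setting in grid:
        pred = runner(setting)
        report = compare_annotations(pred, truth, genome_lengths)
        row = dict(setting)
        row["tpr"] = report.sensitivity
        row["fpr"] = report.fpr
        rows.append(row)
    return pd.DataFrame(rows)
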