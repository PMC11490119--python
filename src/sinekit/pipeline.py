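"""Mode orchestration: homology (1), structure (2), and hybrid (3) runs.

Mode 1 relies on profile-HMM hits and excels where a species' SINE families
are already curated; Mode 2 is fully de novo and carries the load for novel
taxa; Mode 3 unions both candidate sets before filtering, recording per-
candidate provenance so the contribution of each strategy stays visible in
the final annotation.

The pipeline is hermetic by default: it consumes pre-computed hit tables
and alignments. The invocation contract for producing them externally is::

    nhmmer --tblout hits.tbl sine_profiles.hmm genome.fa
    minimap2 -c -N 50 [-K 1M if candidates.fa > 10 Mb] genome.fa candidates.fa > copies.paf

where the low-memory ``-K 1M`` batching is chosen by
:func:`sinekit.alignio.choose_alignment_mode`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

from . import __version__ as _version
from .alignio import Tab6Record, parse_paf_line, paf_to_tab6, read_tab6
from .cleanup import purge_nonsine, remove_nested_redundancy
from .families import adjust_boundaries, count_copies, filter_by_copy_number
from .formats import AnnotationSet, GenomicInterval, Sequence
from .homology import (
    loci_to_candidates,
    merge_hits_sorted,
    read_hmm_hits,
    select_library,
)
from .structure import SineCandidate, StructureParams, partition_scan

logger = logging.getLogger("sinekit")

__all__ = [
    "PipelineConfig",
    "RunResult",
    "ProvenanceReport",
    "run_mode",
    "provenance_report",
    "merge_candidate_sets",
    "make_sweep_runner",
]


@dataclass
class PipelineConfig:
    """All pipeline tunables in one place (mirrors the CLI flags)."""

    structure: StructureParams = field(default_factory=StructureParams)
    a_flag: int = 2  # 0 plant, 1 animal, 2 both
    max_gap: int = 0
    evalue_cutoff: float = 1e-5
    s: int = 10  # max boundary shift for copy support
    minc: int = 2  # min copy number per element
    min_cov: float = 0.8  # min candidate coverage for a copy
    cov: float = 0.95  # nested-redundancy coverage threshold
    miniden: float = 80.0
    minlen: int = 50
    nr: float = 0.8  # max masked fraction before purging
    drop_secondary: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a key=value config file mirroring the CLI flags."""
        cfg = cls()
        struct_fields = {f for f in StructureParams.__dataclass_fields__}
        struct_over: dict[str, object] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if not _:
                    raise ValueError(f"config line without '=': {line!r}")
                target = struct_over if key in struct_fields else cfg.__dict__
                if key in struct_fields or key in cfg.__dict__:
                    current = (
                        getattr(StructureParams(), key)
                        if key in struct_fields
                        else getattr(cfg, key)
                    )
                    caster = type(current)
                    target[key] = (
                        value.lower() in ("1", "true", "yes")
                        if caster is bool
                        else caster(value)
                    )
                else:
                    raise ValueError(f"unknown config key {key!r}")
        if struct_over:
            cfg.structure = replace(cfg.structure, **struct_over)
        return cfg


@dataclass
class ProvenanceReport:
    """Mode-3 source accounting over elements and bp."""

    n_elements: int
    element_fractions: dict[str, float]
    bp_fractions: dict[str, float]
    empty: bool

    def as_dict(self) -> dict:
        return {
            "n_elements": self.n_elements,
            "empty": self.empty,
            **{f"elements_{k}": v for k, v in self.element_fractions.items()},
            **{f"bp_{k}": v for k, v in self.bp_fractions.items()},
        }


@dataclass
class RunResult:
    """Everything one pipeline invocation produced."""

    mode: int
    candidates: list[SineCandidate]
    annotation: AnnotationSet
    sequences: dict[str, str]
    pre_filter_candidates: list[SineCandidate]
    provenance: ProvenanceReport
    warnings: list[str] = field(default_factory=list)


def merge_candidate_sets(
    candidates: Iterable[SineCandidate],
) -> list[SineCandidate]:
    """Union-merge overlapping candidates, combining provenance.

    Any >=1 bp overlap on the same sequence collapses records into one
    spanning interval; a record backed by both discovery modes is labelled
    "both". Structural evidence (TSD/tail) is kept from whichever member
    carries it.
    """
    ordered = sorted(
        candidates, key=lambda c: (c.interval.seq_id, c.interval.start,
                                   c.interval.end)
    )
    out: list[SineCandidate] = []
    for cand in ordered:
        if (
            out
            and out[-1].interval.seq_id == cand.interval.seq_id
            and cand.interval.start < out[-1].interval.end
        ):
            prev = out[-1]
            modes = {prev.source_mode, cand.source_mode} - {"both"}
            if "both" in (prev.source_mode, cand.source_mode) or len(modes) > 1:
                mode = "both"
            else:
                mode = modes.pop()
            out[-1] = replace(
                prev,
                interval=GenomicInterval(
                    prev.interval.seq_id,
                    prev.interval.start,
                    max(prev.interval.end, cand.interval.end),
                    prev.interval.strand,
                ),
                source_mode=mode,
                tsd=prev.tsd or cand.tsd,
                tail=prev.tail or cand.tail,
            )
        else:
            out.append(cand)
    return out


def _read_alignments(
    paf_path: str | Path | None, tab6: list[Tab6Record] | None,
    drop_secondary: bool,
) -> list[Tab6Record] | None:
    if tab6 is not None:
        return list(tab6)
    if paf_path is None:
        return None
    records: list[Tab6Record] = []
    with open(paf_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            try:
                paf = parse_paf_line(line)
            except ValueError:
                continue
            if drop_secondary and paf.is_secondary:
                continue
            records.append(paf_to_tab6(paf))
    return records


def _parse_locus(qseqid: str) -> tuple[str, int, int] | None:
    try:
        seq_id, span = qseqid.rsplit(":", 1)
        lo, hi = span.split("-")
        return seq_id, int(lo), int(hi)
    except ValueError:
        return None


def _assign_alignment_groups(
    candidates: list[SineCandidate], alignments: list[Tab6Record]
) -> dict[int, list[Tab6Record]]:
    """Attach each query's alignment group to the candidate its locus overlaps
    best (queries are named ``seq:start-end``)."""
    groups: dict[str, list[Tab6Record]] = {}
    for rec in alignments:
        groups.setdefault(rec.qseqid, []).append(rec)
    assigned: dict[int, list[Tab6Record]] = {}
    loci = {qid: _parse_locus(qid) for qid in groups}
    for i, cand in enumerate(candidates):
        iv = cand.interval
        best_qid, best_ov = None, 0
        for qid, locus in loci.items():
            if locus is None or locus[0] != iv.seq_id:
                continue
            ov = min(iv.end, locus[2]) - max(iv.start, locus[1])
            if ov > best_ov:
                best_qid, best_ov = qid, ov
        if best_qid is not None:
            assigned[i] = groups[best_qid]
    return assigned


def run_mode(
    genome: list[Sequence],
    mode: int,
    config: PipelineConfig | None = None,
    hit_path: str | Path | None = None,
    paf_path: str | Path | None = None,
    tab6: list[Tab6Record] | None = None,
    lineage_map: Mapping[str, str] | None = None,
    masks: Mapping[str, list[tuple[int, int]]] | None = None,
    library_self_hits: list[Tab6Record] | None = None,
    n_parts: int | None = None,
) -> RunResult:
    """Run one annotation mode end to end.

    Mode 1 needs a hit table; mode 3 without one degrades to mode 2 with a
    warning (the situation of a taxon with no curated profiles). Copy-number
    filtering runs only when candidate-vs-genome alignments (PAF or tab6)
    are supplied; redundancy removal only when library self-hits are.
    """
    config = config or PipelineConfig()
    run_warnings: list[str] = []
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    if mode == 1 and hit_path is None:
        raise ValueError("mode 1 requires a profile-HMM hit table")
    if mode == 3 and hit_path is None:
        msg = "mode 3 without a hit table: degrading to structure-only mode 2"
        warnings.warn(msg)
        run_warnings.append(msg)
        mode = 2
    logger.info(
        "sinekit %s run_mode mode=%d a=%d s=%d minc=%d t=%d s_score=%d",
        _version, mode, config.a_flag, config.s, config.minc,
        config.structure.t, config.structure.s_score,
    )
    seq_index = {s.id: s for s in genome}

    homology_cands: list[SineCandidate] = []
    if mode in (1, 3):
        hits = read_hmm_hits(hit_path, lineage_map=lineage_map)
        hits = select_library(hits, config.a_flag)
        hits = [h for h in hits if h.e_value <= config.evalue_cutoff]
        loci = merge_hits_sorted(hits, config.max_gap)
        homology_cands = loci_to_candidates(loci, seq_index, config.structure)

    structure_cands: list[SineCandidate] = []
    if mode in (2, 3):
        structure_cands = partition_scan(genome, config.structure, n_parts)

    if mode == 3:
        pre_filter = merge_candidate_sets(homology_cands + structure_cands)
    elif mode == 1:
        pre_filter = homology_cands
    else:
        pre_filter = structure_cands

    # copy-number support
    alignments = _read_alignments(paf_path, tab6, config.drop_secondary)
    candidates = list(pre_filter)
    if alignments is not None:
        assigned = _assign_alignment_groups(candidates, alignments)
        filtered: list[SineCandidate] = []
        for i, cand in enumerate(candidates):
            support = count_copies(
                cand, assigned.get(i, []), s=config.s, min_cov=config.min_cov
            )
            if support.copy_count >= config.minc:
                cand = adjust_boundaries(cand, support, s=config.s)
                cand = replace(cand, copies=support.copy_count)
                filtered.append(cand)
        candidates = filtered
    else:
        msg = "no candidate-vs-genome alignments given: copy filter skipped"
        run_warnings.append(msg)

    # library cleanup: purge masked/N-dominated candidates, trim termini
    seqs = [
        Sequence(c.id, seq_index[c.interval.seq_id].residues[
            c.interval.start : c.interval.end
        ])
        for c in candidates
        if c.interval.seq_id in seq_index
    ]
    kept, report = purge_nonsine(
        seqs, masks or {}, nr=config.nr, minlen=config.minlen,
        return_report=True,
    )
    trimmed: list[SineCandidate] = []
    kept_seq = {s.id: s.residues for s in kept}
    for cand in candidates:
        outcome = report.get(cand.id)
        if outcome is None or not outcome.kept:
            continue
        iv = cand.interval
        if outcome.lead_trim or outcome.tail_trim:
            cand = replace(
                cand,
                interval=GenomicInterval(
                    iv.seq_id,
                    iv.start + outcome.lead_trim,
                    iv.end - outcome.tail_trim,
                    iv.strand,
                ),
            )
        trimmed.append(cand)
    candidates = trimmed

    if library_self_hits is not None:
        lib = [Sequence(c.id, kept_seq[c.id]) for c in candidates]
        retained = {
            s.id
            for s in remove_nested_redundancy(
                lib, library_self_hits, cov=config.cov,
                miniden=config.miniden, minlen=config.minlen,
            )
        }
        candidates = [c for c in candidates if c.id in retained]

    candidates.sort(
        key=lambda c: (c.interval.seq_id, c.interval.start, c.interval.end)
    )
    annotation = AnnotationSet([c.interval for c in candidates], "SINE")
    sequences = {
        c.id: seq_index[c.interval.seq_id].residues[
            c.interval.start : c.interval.end
        ]
        for c in candidates
    }
    return RunResult(
        mode=mode,
        candidates=candidates,
        annotation=annotation,
        sequences=sequences,
        pre_filter_candidates=pre_filter,
        provenance=provenance_report(candidates),
        warnings=run_warnings,
    )


def provenance_report(
    candidates: Iterable[SineCandidate],
) -> ProvenanceReport:
    """Fractions of elements (and bp) by discovery source.

    Sums to 1 over {homology-only, structure-only, both}; an empty input
    yields an all-zero, flagged report.
    """
    counts = {"homology": 0, "structure": 0, "both": 0}
    bps = dict(counts)
    total = 0
    total_bp = 0
    for cand in candidates:
        counts[cand.source_mode] += 1
        bps[cand.source_mode] += len(cand.interval)
        total += 1
        total_bp += len(cand.interval)
    if total == 0:
        zero = {k: 0.0 for k in counts}
        return ProvenanceReport(0, dict(zero), dict(zero), empty=True)
    return ProvenanceReport(
        n_elements=total,
        element_fractions={k: v / total for k, v in counts.items()},
        bp_fractions={k: v / total_bp for k, v in bps.items()},
        empty=False,
    )


def make_sweep_runner(
    genome: list[Sequence],
    mode: int,
    base_config: PipelineConfig | None = None,
    **run_kwargs,
):
    """A grid-entry -> AnnotationSet runner for :func:`sinekit.evaluate.roc_sweep`.

    Grid keys matching :class:`StructureParams` fields (t, s_score, ...)
    override the structural scan; the rest (s, minc, a_flag, ...) override
    the pipeline config.
    """
    base = base_config or PipelineConfig()
    struct_fields = set(StructureParams.__dataclass_fields__)

    def runner(setting: Mapping[str, object]) -> AnnotationSet:
        struct_over = {k: v for k, v in setting.items() if k in struct_fields}
        cfg_over = {
            k: v for k, v in setting.items() if k not in struct_fields
        }
        cfg = replace(
            base,
            structure=replace(base.structure, **struct_over),
            **cfg_over,
        )
        return run_mode(genome, mode, cfg, **run_kwargs).annotation

    return runner
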