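from __future__ import annotations

import numpy as np
import pytest

from sinekit import (
    HmmHit,
    Sequence,
    StructureParams,
    curate_profiles,
    loci_to_candidates,
    merge_hits_sorted,
    merge_hits_sorted_with_stats,
    read_hmm_hits,
    select_library,
)
from sinekit.synthgen import mock_profile_manifest

from ._oracles import fixpoint_merge_oracle


def _hit(target="chr1", start=0, end=100, model="m", score=50.0,
         evalue=1e-20, strand="+", lineage="plant"):
    return HmmHit(model=model, target=target, start=start, end=end,
                  strand=strand, bit_score=score, e_value=evalue,
                  lineage=lineage)


TBL_ROW = "{target} - {model} - 1 100 {alifrom} {alito} {alifrom} {alito} 50000 {strand} {evalue} 80.0 0.1 desc\n"


class TestReadHmmHits:
    def test_forward_coordinates_to_half_open(self, tmp_path):
        p = tmp_path / "h.tbl"
        p.write_text(TBL_ROW.format(target="chr1", model="m1", alifrom=101,
                                    alito=200, strand="+", evalue="1e-10"))
        (hit,) = read_hmm_hits(p)
        assert (hit.start, hit.end, hit.strand) == (100, 200, "+")

    def test_reversed_coordinates_mean_minus_strand(self, tmp_path):
        p = tmp_path / "h.tbl"
        p.write_text(TBL_ROW.format(target="chr1", model="m1", alifrom=200,
                                    alito=101, strand="-", evalue="1e-10"))
        (hit,) = read_hmm_hits(p)
        assert (hit.start, hit.end, hit.strand) == (100, 200, "-")

    def test_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "h.tbl"
        p.write_text("# a comment\n" + TBL_ROW.format(
            target="chr1", model="m1", alifrom=1, alito=50, strand="+",
            evalue="1e-10"))
        assert len(read_hmm_hits(p)) == 1

    def test_non_numeric_coordinate_reports_line(self, tmp_path):
        p = tmp_path / "h.tbl"
        p.write_text(TBL_ROW.format(target="chr1", model="m1", alifrom="x",
                                    alito=50, strand="+", evalue="1e-10"))
        with pytest.raises(ValueError, match=":1"):
            read_hmm_hits(p)

    def test_lineage_map_applied(self, tmp_path):
        p = tmp_path / "h.tbl"
        p.write_text(TBL_ROW.format(target="chr1", model="zoo", alifrom=1,
                                    alito=50, strand="+", evalue="1e-10"))
        (hit,) = read_hmm_hits(p, lineage_map={"zoo": "animal"})
        assert hit.lineage == "animal"


class TestSelectLibrary:
    @pytest.fixture()
    def mixed(self):
        return [_hit(model=f"p{i}", lineage="plant") for i in range(3)] + [
            _hit(model=f"a{i}", lineage="animal") for i in range(2)
        ]

    def test_a0_keeps_plant_only(self, mixed):
        assert len(select_library(mixed, 0)) == 3

    def test_a1_keeps_animal_only(self, mixed):
        assert len(select_library(mixed, 1)) == 2

    def test_a2_keeps_both(self, mixed):
        assert len(select_library(mixed, 2)) == 5

    def test_other_flag_rejected(self, mixed):
        with pytest.raises(ValueError):
            select_library(mixed, 3)


def spans(loci):
    return sorted(
        (l.interval.seq_id, l.interval.start, l.interval.end) for l in loci
    )


class TestMergeHitsSorted:
    def test_textbook_interval_union(self):
        hits = [
            _hit(start=100, end=200),
            _hit(start=150, end=250),
            _hit(start=300, end=400),
        ]
        assert spans(merge_hits_sorted(hits)) == [
            ("chr1", 100, 250), ("chr1", 300, 400)
        ]

    def test_targets_never_merge_together(self):
        hits = [_hit(target="chr1"), _hit(target="chr2")]
        assert len(merge_hits_sorted(hits)) == 2

    def test_best_model_is_max_bit_score(self):
        hits = [
            _hit(start=0, end=100, model="weak", score=10),
            _hit(start=50, end=150, model="strong", score=90),
        ]
        (locus,) = merge_hits_sorted(hits)
        assert locus.best_model == "strong" and locus.best_score == 90

    def test_max_gap_bridges_nearby_hits(self):
        hits = [_hit(start=0, end=100), _hit(start=105, end=200)]
        assert len(merge_hits_sorted(hits, max_gap=0)) == 2
        assert len(merge_hits_sorted(hits, max_gap=5)) == 1

    def _random_hits(self, rng, n):
        targets = [f"chr{i}" for i in range(1 + int(rng.integers(0, 3)))]
        hits = []
        for _ in range(n):
            start = int(rng.integers(0, n * 40))
            length = int(rng.integers(30, 400))
            hits.append(
                _hit(
                    target=targets[int(rng.integers(len(targets)))],
                    start=start,
                    end=start + length,
                    score=float(rng.integers(10, 100)),
                )
            )
        return hits

    @pytest.mark.parametrize("max_gap", [0, 25])
    def test_equals_fixpoint_oracle_on_random_instances(self, rng, max_gap):
        for _ in range(40):
            hits = self._random_hits(rng, int(rng.integers(2, 300)))
            got = spans(merge_hits_sorted(hits, max_gap))
            expected, _ = fixpoint_merge_oracle(
                [(h.target, h.start, h.end) for h in hits], max_gap
            )
            assert got == sorted(expected)

    def test_permutation_invariance(self, rng):
        hits = self._random_hits(rng, 200)
        reference = spans(merge_hits_sorted(hits))
        for _ in range(5):
            rng.shuffle(hits)
            assert spans(merge_hits_sorted(hits)) == reference

    def test_idempotence_on_merged_loci(self, rng):
        hits = self._random_hits(rng, 300)
        loci = merge_hits_sorted(hits)
        pseudo = [
            _hit(target=l.interval.seq_id, start=l.interval.start,
                 end=l.interval.end)
            for l in loci
        ]
        assert spans(merge_hits_sorted(pseudo)) == spans(loci)

    def test_every_hit_contained_in_exactly_one_locus(self, rng):
        hits = self._random_hits(rng, 250)
        loci = merge_hits_sorted(hits)
        assert sum(len(l.supporting_hits) for l in loci) == len(hits)
        for locus in loci:
            for h in locus.supporting_hits:
                assert locus.interval.start <= h.start < h.end <= locus.interval.end

    def test_iteration_counter_is_linear(self, rng):
        hits = self._random_hits(rng, 500)
        _, iterations = merge_hits_sorted_with_stats(hits)
        assert iterations == len(hits)


class TestLociToCandidates:
    def test_candidate_mirrors_locus(self):
        (locus,) = merge_hits_sorted([_hit(start=100, end=250)])
        (cand,) = loci_to_candidates([locus])
        assert (cand.interval.start, cand.interval.end) == (100, 250)
        assert cand.source_mode == "homology" and cand.tsd is None

    def test_flanking_repeat_recorded_as_tsd(self, rng):
        tsd = "GATTACAGATTA"
        background = "".join(rng.choice(list("CG"), size=400))
        residues = background[:100] + tsd + "ACGT" * 50 + tsd + background[100:]
        genome = {"chr1": Sequence("chr1", residues)}
        start, end = 112, 312  # element between the two repeat copies
        (locus,) = merge_hits_sorted([_hit(start=start, end=end)])
        (cand,) = loci_to_candidates([locus], genome, StructureParams())
        assert cand.tsd is not None
        assert cand.tsd.length >= len(tsd) and cand.tsd.mismatches <= 2

    def test_empty_loci(self):
        assert loci_to_candidates([]) == []


class TestProfileCuration:
    def test_keyword_retrieval_minus_flagged_nonsine(self):
        manifest = mock_profile_manifest(139, 21, seed=5)
        retained = curate_profiles(manifest)
        assert len(manifest) == 139
        assert len(retained) == 118

    def test_counts_are_exact_for_any_split(self):
        manifest = mock_profile_manifest(30, 12, seed=0)
        assert len(curate_profiles(manifest)) == 18
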