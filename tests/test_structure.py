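from __future__ import annotations

import numpy as np
import pytest

from sinekit import (
    Sequence,
    StructureParams,
    find_tail,
    find_tsd,
    partition_scan,
    revcomp,
    scan_structure,
)
from sinekit.synthgen import implant_sines, make_genome

from ._oracles import structure_scan_oracle, tsd_pair_oracle


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindTsd:
    def test_exact_repeat_scores_its_length(self):
        params = StructureParams(t=0, s_score=10)
        hit = find_tsd("GGGGTTAGCCATAGG", "TTAGCCATAGGCCCC", params)
        assert hit is not None
        assert (hit.length, hit.mismatches, hit.score) == (11, 0, 11)
        assert (hit.left.start, hit.right.start) == (4, 0)

    def test_mismatch_tolerance_recovers_full_length(self):
        left = "GGGGTTAGCCATAGG"
        right = "TTAGCCTTAGGCCCC"  # one substitution inside the repeat
        strict = find_tsd(left, right, StructureParams(t=0, s_score=5))
        assert strict is not None and strict.mismatches == 0 and strict.length < 11
        relaxed = find_tsd(left, right, StructureParams(t=1, s_score=9))
        assert relaxed is not None
        assert (relaxed.length, relaxed.mismatches, relaxed.score) == (11, 1, 9)
        assert find_tsd(left, right, StructureParams(t=1, s_score=10)) is None

    def test_flank_shorter_than_min_length_returns_none(self):
        assert find_tsd("ACG", "ACG", StructureParams(tsd_min_len=5)) is None

    @pytest.mark.parametrize("t", [0, 1, 2])
    def test_equals_exhaustive_oracle_on_random_flanks(self, t, rng):
        params = StructureParams(t=t, s_score=6)
        for _ in range(60):
            n1 = int(rng.integers(5, 41))
            n2 = int(rng.integers(5, 41))
            left, right = random_dna(rng, n1), random_dna(rng, n2)
            if rng.random() < 0.5 and min(n1, n2) > 6:  # plant a repeat
                k = int(rng.integers(6, min(15, n1, n2)))
                core = random_dna(rng, k)
                i = int(rng.integers(0, n1 - k + 1))
                j = int(rng.integers(0, n2 - k + 1))
                left = left[:i] + core + left[i + k :]
                right = right[:j] + core + right[j + k :]
            expected = tsd_pair_oracle(
                left, right, params.tsd_min_len, params.tsd_max_len, t
            )
            got = find_tsd(left, right, params)
            if expected is None or expected[0] < params.s_score:
                assert got is None
            else:
                score, length, i, j, mism = expected
                assert got is not None
                assert (
                    got.score, got.length, got.left.start, got.right.start,
                    got.mismatches,
                ) == (score, length, i, j, mism)


class TestFindTail:
    def test_clean_poly_a_suffix(self):
        assert find_tail("ACGT" * 10 + "A" * 10, 8, 0.9) == (40, 50)

    def test_purity_controls_window_length(self):
        body = "CCGT" * 10 + "AAGAAAAAAA"  # 9 A of the last 10
        assert find_tail(body, 8, 0.9) == (40, 50)
        # at 0.95 the impure window fails; only the trailing 7 A qualify,
        # below the 8 bp minimum -> no tail
        assert find_tail(body, 8, 0.95) is None
        assert find_tail(body, 7, 0.95) == (43, 50)

    def test_non_tail_ending_returns_none(self):
        assert find_tail("AAAAAAACGTACGT", 8, 0.9) is None

    def test_minus_orientation_looks_for_t_prefix(self):
        body = "T" * 9 + "GCGC" * 10
        assert find_tail(body, 8, 0.9, strand="-") == (0, 9)


def _implant_fixture(seed=7, **kw):
    genome = make_genome(20_000, 0.4, seed)
    kw.setdefault("n_elements", 1)
    kw.setdefault("copies_per_family", 1)
    kw.setdefault("mutation_rate", 0.0)
    return implant_sines(genome, seed=seed, **kw)


class TestScanStructure:
    def test_single_implant_recovered_at_truth_coordinates(self):
        genome, truth, _ = _implant_fixture()
        cands = scan_structure([genome])
        assert [c.interval for c in cands] == truth.intervals
        (cand,) = cands
        assert cand.source_mode == "structure"
        assert cand.tsd is not None and cand.tsd.mismatches == 0

    def test_reverse_complement_flips_strand_same_footprint(self):
        genome, truth, _ = _implant_fixture()
        rc = Sequence(genome.id, revcomp(genome.residues))
        fwd = scan_structure([genome])
        rev = scan_structure([rc])
        n = len(genome.residues)
        flipped = {
            (n - c.interval.end, n - c.interval.start,
             "-" if c.interval.strand == "+" else "+")
            for c in rev
        }
        assert {
            (c.interval.start, c.interval.end, c.interval.strand) for c in fwd
        } == flipped

    def test_random_dna_matches_brute_force_oracle(self, rng):
        params = StructureParams()
        for seed in range(3):
            residues = random_dna(np.random.default_rng(seed), 20_000)
            got = {
                (c.interval.seq_id, c.interval.start, c.interval.end,
                 c.interval.strand)
                for c in scan_structure([Sequence("r", residues)], params)
            }
            assert got == structure_scan_oracle("r", residues, params)

    def test_implanted_genome_matches_brute_force_oracle(self):
        genome, _, _ = _implant_fixture(n_elements=4)
        params = StructureParams()
        got = {
            (c.interval.seq_id, c.interval.start, c.interval.end,
             c.interval.strand)
            for c in scan_structure([genome], params)
        }
        assert got == structure_scan_oracle(genome.id, genome.residues, params)

    def test_empty_genome_yields_empty_result(self):
        assert scan_structure([Sequence("e", "ACGT" * 10)]) == []


class TestPartitionScan:
    def test_partition_invariance(self):
        genome, _, _ = _implant_fixture(n_elements=5, copies_per_family=2)
        reference = [
            (c.interval.start, c.interval.end, c.interval.strand)
            for c in scan_structure([genome])
        ]
        for n_parts in (1, 2, 8):
            got = [
                (c.interval.start, c.interval.end, c.interval.strand)
                for c in partition_scan([genome], n_parts=n_parts)
            ]
            assert got == reference

    def test_invalid_part_count_rejected(self):
        with pytest.raises(ValueError):
            partition_scan([Sequence("a", "ACGT" * 50)], n_parts=0)

    def test_empty_input(self):
        assert partition_scan([], n_parts=4) == []


class TestParameterMonotonicity:
    def test_candidate_count_monotone_in_t_and_s_score(self):
        genome, _, _ = _implant_fixture(
            n_elements=8, copies_per_family=2, mutation_rate=0.02, seed=11
        )
        counts_t = [
            len(scan_structure([genome], StructureParams(t=t)))
            for t in (0, 1, 2, 3)
        ]
        assert counts_t == sorted(counts_t)
        counts_s = [
            len(scan_structure([genome], StructureParams(s_score=s)))
            for s in (8, 10, 12, 16)
        ]
        assert counts_s == sorted(counts_s, reverse=True)


def test_recovery_rate_of_clean_implants():
    """>=95% of implants with exact TSDs and pure tails are recovered
    (>=90% reciprocal overlap) under default parameters."""
    recovered = 0
    total = 0
    for seed in (3, 4):
        genome = make_genome(60_000, 0.4, seed)
        genome, truth, _ = implant_sines(
            genome, n_elements=12, copies_per_family=3,
            mutation_rate=0.02, seed=seed + 100,
        )
        cands = scan_structure([genome])
        for iv in truth:
            total += 1
            for c in cands:
                ov = min(iv.end, c.interval.end) - max(iv.start, c.interval.start)
                if ov >= 0.9 * len(iv) and ov >= 0.9 * len(c.interval):
                    recovered += 1
                    break
    assert recovered / total >= 0.95
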