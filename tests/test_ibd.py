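"""Detector correctness: trivial cases, brute-force oracle equivalence,
maximality/monotonicity properties and truth-based recovery on
simulated pedigrees."""

import numpy as np
import pytest

from pedscan.ibd import (
    DetectorParams,
    all_pairs_ibd,
    detection_scores,
    ibd_summary,
    pairwise_ibd,
    segments_to_frame,
)
from pedscan.io import MISSING
from pedscan.simulate import true_pairwise_ibd

from conftest import make_gm

LOOSE = DetectorParams(min_markers=1, min_length_mb=0.0, max_mismatch_fraction=0.0)


def oracle_zero_mismatch(status, positions, params):
    """Enumerate-all-runs oracle for the zero-mismatch-tolerance regime.

    A candidate run [i, j] has concordant endpoints, no discordant marker
    inside, and no stretch of more than ``max_missing_gap_markers``
    consecutive missing comparisons inside.  Kept runs are the maximal
    ones passing the reporting thresholds.
    """
    n = len(status)
    candidates = []
    for i in range(n):
        if status[i] != 0:
            continue
        for j in range(i, n):
            if status[j] != 0:
                continue
            inside = status[i : j + 1]
            if (inside == 1).any():
                continue
            # longest missing stretch inside
            gap, worst = 0, 0
            for code in inside:
                gap = gap + 1 if code == -1 else 0
                worst = max(worst, gap)
            if worst > params.max_missing_gap_markers:
                continue
            candidates.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in candidates
        if not any((a <= i and j <= b and (a, b) != (i, j)) for a, b in candidates)
    ]
    kept = []
    for i, j in maximal:
        n_cmp = int((status[i : j + 1] >= 0).sum())
        length_mb = (positions[j] - positions[i]) / 1e6
        if n_cmp >= params.min_markers and length_mb >= params.min_length_mb:
            kept.append((int(positions[i]), int(positions[j])))
    return sorted(kept)


class TestTrivialCases:
    def test_identical_lines_one_segment_per_chromosome(self, sim_result):
        gm = sim_result.genotypes
        line = "Tapidor"
        calls = np.stack([gm.row(line), gm.row(line)])
        gm2 = make_gm(calls[:, : 400], sample_ids=["x", "y"], spacing=27_500)
        segs = pairwise_ibd(gm2, "x", "y", DetectorParams(min_markers=1, min_length_mb=0))
        assert len(segs) == 1
        assert segs[0].n_markers == 400

    def test_fully_discordant_lines_give_nothing(self):
        gm = make_gm([[0] * 50, [1] * 50])
        assert pairwise_ibd(gm, "s0", "s1", LOOSE) == []

    def test_symmetry(self, sim_result):
        gm = sim_result.genotypes
        ab = pairwise_ibd(gm, "Regent", "Tapidor")
        ba = pairwise_ibd(gm, "Tapidor", "Regent")
        assert [(s.chromosome, s.start_bp, s.end_bp, s.n_markers) for s in ab] == [
            (s.chromosome, s.start_bp, s.end_bp, s.n_markers) for s in ba
        ]

    def test_unknown_line_is_hard_error(self, sim_result):
        with pytest.raises(KeyError, match="nobody"):
            pairwise_ibd(sim_result.genotypes, "nobody", "Tapidor")

    def test_all_missing_chromosome_skipped(self, sim_result):
        # Chengduai (diploid A) has an all-missing C subgenome
        segs = pairwise_ibd(sim_result.genotypes, "Chengduai", "Chuanyou2", LOOSE)
        assert all(s.chromosome.startswith("A") for s in segs)

    def test_empty_pair_list(self, sim_result):
        assert all_pairs_ibd(sim_result.genotypes, []) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle(self, seed):
        """On <=200-marker instances with missing data, the detector equals
        the O(n^2) enumerate-all-runs oracle (zero mismatch tolerance)."""
        rng = np.random.default_rng(seed)
        n_markers = 200
        base = rng.integers(0, 2, n_markers).astype(np.int8)
        other = base.copy()
        flip = rng.random(n_markers) < 0.1
        other[flip] = 1 - other[flip]
        calls = np.stack([base, other])
        calls[rng.random(calls.shape) < 0.15] = MISSING
        params = DetectorParams(
            min_markers=5, min_length_mb=0.2, max_mismatch_fraction=0.0,
            max_missing_gap_markers=3,
        )
        gm = make_gm(calls, spacing=100_000)
        detected = pairwise_ibd(gm, "s0", "s1", params)
        usable = (calls[0] != MISSING) & (calls[1] != MISSING)
        status = np.where(usable, (calls[0] != calls[1]).astype(np.int8), np.int8(-1))
        expected = oracle_zero_mismatch(status, gm.markers.positions("A01"), params)
        assert [(s.start_bp, s.end_bp) for s in detected] == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_reported_segments_not_extendable(self, seed):
        """With mismatch absorption, every reported segment has concordant
        endpoints, interior mismatch fraction within the cap, and no
        same-pair overlap."""
        rng = np.random.default_rng(100 + seed)
        n_markers = 300
        base = rng.integers(0, 2, n_markers).astype(np.int8)
        other = base.copy()
        flip = rng.random(n_markers) < 0.05
        other[flip] = 1 - other[flip]
        calls = np.stack([base, other])
        params = DetectorParams(
            min_markers=5, min_length_mb=0.0, max_mismatch_fraction=0.05
        )
        gm = make_gm(calls, spacing=10_000)
        segs = pairwise_ibd(gm, "s0", "s1", params)
        assert segs, "expected at least one segment"
        positions = list(gm.markers.positions("A01"))
        prev_end = None
        for s in segs:
            i, j = positions.index(s.start_bp), positions.index(s.end_bp)
            assert calls[0, i] == calls[1, i] and calls[0, j] == calls[1, j]
            inside_mismatch = int((calls[0, i : j + 1] != calls[1, i : j + 1]).sum())
            assert inside_mismatch == s.n_mismatch
            assert s.n_mismatch <= params.max_mismatch_fraction * s.n_markers
            if prev_end is not None:
                assert s.start_bp > prev_end
            prev_end = s.end_bp


class TestProperties:
    def test_min_length_monotonicity(self, sim_result):
        gm = sim_result.genotypes
        prev_count, prev_len = None, None
        for min_len in (0.0, 0.5, 1.0, 2.0, 4.0):
            params = DetectorParams(min_markers=10, min_length_mb=min_len)
            segs = pairwise_ibd(gm, "Ningyou1", "Ningyou7", params)
            count = len(segs)
            total = sum(s.length_mb for s in segs)
            if prev_count is not None:
                assert count <= prev_count
                assert total <= prev_len + 1e-12
            prev_count, prev_len = count, total

    def test_determinism(self, sim_result):
        gm = sim_result.genotypes
        a = segments_to_frame(pairwise_ibd(gm, "Chuanyou2", "Ningyou7"))
        b = segments_to_frame(pairwise_ibd(gm, "Chuanyou2", "Ningyou7"))
        assert a.equals(b)


class TestSummary:
    def test_single_segment_subgenome_assignment(self):
        from pedscan.ibd import IBDSegment

        seg = IBDSegment("a", "b", "A03", 1_000_000, 3_500_000, 30, 0)
        summary = ibd_summary([seg])
        row = summary[summary["sample_a"] == "a"].iloc[0]
        assert row["count_A"] == 1
        assert row["length_A_mb"] == pytest.approx(2.5)
        assert row["count_C"] == 0
        assert row["count_total"] == 1

    def test_totals_are_additive_and_match_recount(self, sim_result):
        gm = sim_result.genotypes
        pairs = [("Regent", "Tapidor"), ("Chuanyou2", "Ningyou7")]
        segs = all_pairs_ibd(gm, pairs)
        summary = ibd_summary(segs)
        pooled = summary[summary["sample_a"] == "(all)"].iloc[0]
        # brute-force recount from the segment list itself
        assert pooled["count_total"] == len(segs)
        assert pooled["length_total_mb"] == pytest.approx(
            sum(s.length_mb for s in segs)
        )
        assert pooled["count_A"] + pooled["count_C"] == pooled["count_total"]
        per_pair = summary[summary["sample_a"] != "(all)"]
        assert per_pair["count_total"].sum() == pooled["count_total"]


class TestTruthRecovery:
    def test_parent_offspring_precision_recall(self, sim_result):
        """Error-free simulation: detected segments recover pairwise truth
        with high precision/recall and tight boundaries."""
        gm = sim_result.genotypes
        params = DetectorParams()
        pairs = [
            ("Regent", "Tapidor"), ("Bienvenu", "Tapidor"),
            ("Chuanyou2", "Ningyou7"), ("Ningyou1", "Ningyou7"),
        ]
        for a, b in pairs:
            detected = pairwise_ibd(gm, a, b, params)
            truth = true_pairwise_ibd(sim_result, a, b)
            scores = detection_scores(detected, truth, sim_result.marker_map, params)
            if scores["n_truth_segments"] == 0:
                continue
            assert scores["precision"] >= 0.95, (a, b, scores)
            assert scores["recall"] >= 0.95, (a, b, scores)
            assert scores["median_boundary_error_intervals"] <= 1.0, (a, b, scores)
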