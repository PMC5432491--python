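"""Window statistics against brute-force pair-enumeration oracles, the
quadrant truth table, and histogram recounts."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedscan.io import MISSING
from pedscan.scan import (
    classify_selection,
    d_histogram,
    gene_diversity,
    genome_mean_d,
    pic,
    site_stats,
    sliding_scan,
    tajima_d,
)

from conftest import make_gm


def oracle_tajima(window):
    """Independent Tajima's D: enumerate all line pairs and compute every
    normalising constant straight from its definition."""
    n, k = window.shape
    S = 0
    for j in range(k):
        obs = [int(v) for v in window[:, j] if v != MISSING]
        if len(obs) >= 2 and 0 < sum(obs) < len(obs):
            S += 1
    diffs = []
    for i, j in combinations(range(n), 2):
        d = 0
        for c in range(k):
            x, y = window[i, c], window[j, c]
            if x != MISSING and y != MISSING and x != y:
                d += 1
        diffs.append(d)
    pi = sum(diffs) / len(diffs)
    if S == 0:
        return S, pi, float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return S, pi, float("nan")
    return S, pi, (pi - S / a1) / math.sqrt(var)


class TestSiteStats:
    def test_monomorphic(self):
        q, seg, usable = site_stats(np.array([0, 0, 0, 0, 0], dtype=np.int8))
        assert (q, seg, usable) == (0.0, False, True)

    def test_segregating_frequency(self):
        q, seg, usable = site_stats(np.array([0, 1, 1, 0, 1], dtype=np.int8))
        assert q == pytest.approx(0.6)
        assert seg and usable

    def test_missing_excluded_from_count(self):
        q, seg, usable = site_stats(np.array([0, 1, 1, 0, MISSING], dtype=np.int8))
        assert q == pytest.approx(0.5)  # over the 4 remaining calls
        assert seg and usable

    def test_too_few_calls_unusable(self):
        q, seg, usable = site_stats(np.array([0, MISSING, MISSING], dtype=np.int8))
        assert not usable and not seg


class TestTajimaD:
    def test_monomorphic_window_undefined(self):
        window = np.zeros((5, 15), dtype=np.int8)
        S, pi, D = tajima_d(window)
        assert (S, pi) == (0, 0.0)
        assert math.isnan(D)

    def test_fewer_than_three_lines_is_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            tajima_d(np.zeros((2, 15), dtype=np.int8))

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        window = rng.integers(0, 2, size=(n, 15)).astype(np.int8)
        if seed % 3 == 0:  # a third of the windows carry missing calls
            window[rng.random(window.shape) < 0.1] = MISSING
        S, pi, D = tajima_d(window)
        S_o, pi_o, D_o = oracle_tajima(window)
        assert S == S_o
        assert pi == pytest.approx(pi_o, abs=1e-12)
        if math.isnan(D_o):
            assert math.isnan(D)
        else:
            assert D == pytest.approx(D_o, abs=1e-12)

    def test_duplicating_lines_rescales_pi_exactly(self):
        """Duplicating every line changes the pair average by the exact
        combinatorial factor 2(n-1)/(2n-1) (identical copies contribute
        zero-difference pairs)."""
        rng = np.random.default_rng(17)
        window = rng.integers(0, 2, size=(5, 15)).astype(np.int8)
        _, pi, _ = tajima_d(window)
        _, pi_dup, _ = tajima_d(np.vstack([window, window]))
        n = 5
        assert pi_dup == pytest.approx(pi * 2 * (n - 1) / (2 * n - 1), abs=1e-12)
        # and both equal the pair-enumeration oracle
        assert pi_dup == pytest.approx(oracle_tajima(np.vstack([window, window]))[1])


class TestDiversity:
    @pytest.mark.parametrize(
        "q,expected",
        [(0.5, 0.5), (0.0, 0.0), (1.0, 0.0), (0.2, 0.32)],
    )
    def test_single_locus_values(self, q, expected):
        hs, per_locus = gene_diversity([q])
        assert hs == pytest.approx(expected)
        assert per_locus[0] == pytest.approx(expected)

    def test_three_locus_mean(self):
        hs, _ = gene_diversity([0.2, 0.5, 1.0])
        assert hs == pytest.approx((0.32 + 0.5 + 0.0) / 3)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            gene_diversity([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_equals_mean_2q_one_minus_q(self, qs):
        hs, _ = gene_diversity(qs)
        assert hs == pytest.approx(float(np.mean([2 * q * (1 - q) for q in qs])), abs=1e-12)


class TestPIC:
    @pytest.mark.parametrize(
        "q,expected",
        [(0.5, 0.375), (0.0, 0.0), (0.2, 1 - (0.64 + 0.04) - 2 * 0.04 * 0.64)],
    )
    def test_single_locus_values(self, q, expected):
        assert pic([q]) == pytest.approx(expected)

    def test_bounded_by_biallelic_maximum(self):
        qs = np.linspace(0, 1, 101)
        assert max(pic([q]) for q in qs) == pytest.approx(0.375)


class TestSlidingScan:
    def test_window_count_is_m_minus_14(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 2, size=(5, 100)).astype(np.int8)
        scan = sliding_scan(make_gm(calls), [f"s{i}" for i in range(5)])
        assert len(scan) == 100 - 14

    def test_midpoint_is_eighth_locus(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 2, size=(5, 20)).astype(np.int8)
        gm = make_gm(calls)
        scan = sliding_scan(gm, gm.sample_ids)
        positions = gm.markers.positions("A01")
        assert scan.iloc[0]["midpoint_bp"] == positions[7]
        assert scan.iloc[1]["midpoint_bp"] == positions[8]

    def test_no_cross_chromosome_windows(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 2, size=(5, 40)).astype(np.int8)
        df = pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(40)],
                "chromosome": ["A01"] * 20 + ["C01"] * 20,
                "position": list(range(1, 21)) * 2,
            }
        )
        df["position"] = df["position"] * 100_000
        from pedscan.io import GenotypeMatrix, MarkerMap

        gm = GenotypeMatrix([f"s{i}" for i in range(5)], MarkerMap(df), calls)
        scan = sliding_scan(gm, gm.sample_ids)
        assert set(scan["chromosome"]) == {"A01", "C01"}
        assert (scan.groupby("chromosome").size() == 6).all()  # 20 - 14 each

    def test_short_chromosome_skipped(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 2, size=(5, 10)).astype(np.int8)
        gm = make_gm(calls)
        assert sliding_scan(gm, gm.sample_ids).empty


class TestQuadrants:
    @pytest.mark.parametrize(
        "D,Hs,expected",
        [
            (-0.5, 0.2, "early_breeding"),
            (-0.5, 0.4, "late_breeding"),
            (0.5, 0.2, "pre_pedigree"),
            (0.5, 0.4, "no_selection"),
        ],
    )
    def test_main_text_convention(self, D, Hs, expected):
        quadrant, boundary = classify_selection(D, Hs)
        assert quadrant == expected and not boundary

    @pytest.mark.parametrize(
        "D,Hs,expected",
        [
            (-0.5, 0.2, "late_breeding"),
            (-0.5, 0.4, "early_breeding"),
            (0.5, 0.2, "pre_pedigree"),
            (0.5, 0.4, "no_selection"),
        ],
    )
    def test_figure_legend_convention_swaps_early_late(self, D, Hs, expected):
        quadrant, _ = classify_selection(D, Hs, convention="figure_legend")
        assert quadrant == expected

    @pytest.mark.parametrize("D,Hs", [(0.0, 0.3), (0.0, 0.5), (1.0, 0.3)])
    def test_boundary_values_flagged(self, D, Hs):
        quadrant, boundary = classify_selection(D, Hs)
        assert quadrant == "no_selection" and boundary

    def test_undefined_d_suppressed(self):
        with pytest.raises(ValueError, match="undefined"):
            classify_selection(float("nan"), 0.2)


class TestHistogram:
    def test_all_in_one_class(self):
        hist = d_histogram([0.5] * 10)
        assert hist["[0,1)"] == 1.0
        assert hist["out_of_range"] == 0.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            d_histogram([float("nan")])

    def test_recount_oracle(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(-2.5, 2.5, 500)
        hist = d_histogram(d)
        # brute-force recount
        assert hist["[-2,-1)"] == np.mean((d >= -2) & (d < -1))
        assert hist["[-1,0)"] == np.mean((d >= -1) & (d < 0))
        assert hist["[0,1)"] == np.mean((d >= 0) & (d < 1))
        assert hist["[1,2]"] == np.mean((d >= 1) & (d <= 2))
        assert hist["out_of_range"] == pytest.approx(
            1 - sum(v for k, v in hist.items() if k != "out_of_range")
        )

    def test_genome_mean_over_defined_windows(self):
        scan = pd.DataFrame({"D": [0.5, float("nan"), 1.5]})
        assert genome_mean_d(scan) == pytest.approx(1.0)
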