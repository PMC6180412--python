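"""LD blocks: gametic tables, Fisher test, segmentation, block variance."""

import numpy as np
import pandas as pd
import pytest

from crossboa import simdata
from crossboa.ldblocks import (
    GameticTable,
    LDBlock,
    block_variance_explained,
    fisher_exact_2x2,
    gametic_table,
    match_top_regions,
    segment_ld_blocks,
    top_blocks,
)
from crossboa.simdata import MarkerMap, OriginMatrix, PhasedGenotypes

from conftest import tiny_phased, tiny_origins

S, LR, LW = 0, 1, 2
MISS = simdata.ORIGIN_MISSING


class TestGameticTable:
    def test_balanced_table_has_zero_d(self):
        t = GameticTable(np.array([[2, 2], [2, 2]]))
        assert t.D == pytest.approx(0.0)

    def test_perfect_association_d_quarter(self):
        t = GameticTable(np.array([[5, 0], [0, 5]]))
        assert t.D == pytest.approx(0.25)

    def test_counts_only_same_origin_gametes(self):
        codes = [[[1, 1], [1, 0]], [[0, 1], [0, 0]]]
        lab = [[[S, LR], [S, MISS]], [[S, LR], [S, LR]]]
        haps = tiny_phased(codes, "c")
        orig = tiny_origins(lab, haps.animals)
        # animal 0's maternal gamete has missing origin at locus 1: excluded
        t = gametic_table(haps, orig, "S", 0, 1)
        assert t.n == 2  # the two paternal gametes
        t2 = gametic_table(haps, orig, "LR", 0, 1)
        assert t2.n == 1  # only animal 1's maternal gamete has LR at both

    def test_d_bounded_for_biallelic_loci(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = rng.integers(0, 30, (2, 2))
            assert abs(GameticTable(c).D) <= 0.25 + 1e-12


class TestFisher:
    def test_perfect_table_enumeration_value(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_modal_table_p_one(self):
        assert fisher_exact_2x2([[2, 2], [2, 2]]) == 1.0

    def test_zero_margin_degenerate_support(self):
        assert fisher_exact_2x2([[3, 0], [4, 0]]) == 1.0
        assert fisher_exact_2x2([[0, 0], [0, 0]]) == 1.0

    def test_agrees_with_scipy_on_large_tables(self):
        from scipy import stats

        t = [[150, 80], [60, 140]]
        assert fisher_exact_2x2(t) == pytest.approx(
            float(stats.fisher_exact(t)[1]), rel=1e-9
        )


class TestSegmentation:
    @staticmethod
    def _cb_from_gametes(g1, g2=None):
        """Crossbred objects whose paternal gametes are rows of g1 (origin S)."""
        g1 = np.asarray(g1, dtype=np.int8)
        n, m = g1.shape
        codes = np.zeros((n, m, 2), dtype=np.int8)
        codes[:, :, 0] = g1
        lab = np.full((n, m, 2), MISS, dtype=np.int8)
        lab[:, :, 0] = S
        animals = [f"c{i}" for i in range(n)]
        return PhasedGenotypes(codes, animals), OriginMatrix(lab, animals)

    def test_complete_ld_gives_single_block(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 2, 40)
        g = np.tile(col[:, None], (1, 10))  # identical columns: complete LD
        haps, orig = self._cb_from_gametes(g)
        mm = MarkerMap.uniform(1, 10)
        blocks, summary = segment_ld_blocks(haps, orig, mm, "S")
        assert summary.n_blocks == 1
        assert blocks[0].n_snps == 10

    def test_independent_loci_give_mostly_singletons(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 2, (300, 30))
        haps, orig = self._cb_from_gametes(g)
        mm = MarkerMap.uniform(1, 30)
        blocks, summary = segment_ld_blocks(haps, orig, mm, "S", alpha=0.01)
        assert summary.n_blocks >= 25  # ~1% false joins expected

    def test_blocks_partition_kept_snps(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 2, (100, 25))
        haps, orig = self._cb_from_gametes(g)
        mm = MarkerMap.uniform(1, 25)
        blocks, _ = segment_ld_blocks(haps, orig, mm, "S")
        covered = np.concatenate([b.snp_indices for b in blocks])
        assert sorted(covered.tolist()) == list(range(25))
        assert len(set(covered.tolist())) == 25

    def test_single_snp_chromosome_allowed(self):
        haps, orig = self._cb_from_gametes(np.ones((10, 1)))
        mm = MarkerMap.uniform(1, 1)
        blocks, summary = segment_ld_blocks(haps, orig, mm, "S")
        assert summary.n_blocks == 1 and blocks[0].n_snps == 1


class TestBlockVariance:
    def test_zero_effects_explain_nothing(self):
        Z = np.random.default_rng(4).integers(0, 3, (10, 6)).astype(float)
        blocks = [LDBlock("1", 0, 2, 1, 3, "S"), LDBlock("1", 3, 5, 4, 6, "S")]
        tab = block_variance_explained(blocks, Z, np.zeros(6), sigma2_a=1.0)
        assert (tab["percent"] == 0).all()

    def test_single_block_self_normalizes_to_100(self):
        rng = np.random.default_rng(5)
        Z = rng.integers(0, 3, (12, 5)).astype(float)
        alpha = rng.normal(size=5)
        blocks = [LDBlock("1", 0, 4, 1, 5, "S")]
        tab = block_variance_explained(blocks, Z, alpha)
        assert tab["percent"].iloc[0] == pytest.approx(100.0)

    def test_size_scaling_against_hand_computed_toy(self):
        # 5 individuals, 6 SNPs in blocks of sizes 2 and 4: x_n/n_i = 1.5, 0.75
        Z = np.array(
            [
                [0, 1, 2, 0, 1, 2],
                [1, 1, 0, 2, 0, 1],
                [2, 0, 1, 1, 2, 0],
                [0, 2, 2, 1, 1, 1],
                [1, 0, 1, 0, 2, 2],
            ],
            dtype=float,
        )
        alpha = np.array([0.5, -0.2, 0.1, 0.3, -0.4, 0.2])
        sigma2_a = 0.9
        blocks = [LDBlock("1", 0, 1, 1, 2, "S"), LDBlock("1", 2, 5, 3, 6, "S")]
        tab = block_variance_explained(blocks, Z, alpha, sigma2_a=sigma2_a)
        # independent hand evaluation with explicit loops
        for row, (first, last, scale) in zip(
            tab.itertuples(index=False), [(0, 1, 1.5), (2, 5, 0.75)]
        ):
            vals = []
            for i in range(5):
                vals.append(sum(Z[i, j] * alpha[j] for j in range(first, last + 1)))
            mean = sum(vals) / 5
            var = sum((v - mean) ** 2 for v in vals) / 5
            assert row.percent == pytest.approx(var / sigma2_a * scale * 100.0)

    def test_scaled_statistic_identity(self):
        # mean over blocks of percent * n_i / x_n * sigma2_a / 100 equals
        # sum Var(a_i) / n_blocks (algebraic identity of the size correction)
        rng = np.random.default_rng(6)
        Z = rng.integers(0, 3, (20, 12)).astype(float)
        alpha = rng.normal(size=12)
        blocks = [
            LDBlock("1", 0, 3, 1, 4, "S"),
            LDBlock("1", 4, 5, 5, 6, "S"),
            LDBlock("1", 6, 11, 7, 12, "S"),
        ]
        sigma2_a = 2.0
        tab = block_variance_explained(blocks, Z, alpha, sigma2_a=sigma2_a)
        x_n = np.mean([b.n_snps for b in blocks])
        lhs = np.mean(tab["percent"] * tab["n_snps"] / x_n * sigma2_a / 100.0)
        rhs = tab["var"].sum() / len(blocks)
        assert lhs == pytest.approx(rhs)


class TestRegionMatching:
    @staticmethod
    def _table(rows):
        df = pd.DataFrame(
            rows, columns=["chrom", "start_bp", "stop_bp", "percent"]
        )
        df["first"] = 0
        df["last"] = 0
        df["n_snps"] = 1
        df["breed"] = "S"
        df["var"] = 0.0
        return df

    def test_published_style_overlap_matches(self):
        # blocks 7.6-9.9 Mb and 7.6-9.4 Mb on the same chromosome overlap
        a = self._table([("SSC11", 7_600_000, 9_900_000, 1.18)])
        b = self._table([("SSC11", 7_600_000, 9_400_000, 0.58)])
        matches = match_top_regions(a, b, k=10)
        assert len(matches) == 1 and matches[0].gap_bp == 0

    def test_gap_arithmetic(self):
        a = self._table([("1", 9_000_000, 10_000_000, 1.0)])
        far = self._table([("1", 11_200_000, 12_000_000, 1.0)])
        near = self._table([("1", 10_800_000, 12_000_000, 1.0)])
        assert match_top_regions(a, far, k=5) == []
        m = match_top_regions(a, near, k=5)
        assert len(m) == 1 and m[0].gap_bp == 800_000

    def test_identical_lists_include_self_matches(self):
        rows = [("1", i * 10_000_000, i * 10_000_000 + 500_000, float(10 - i)) for i in range(5)]
        t = self._table(rows)
        matches = match_top_regions(t, t, k=5)
        self_pairs = [m for m in matches if m.a_start_bp == m.b_start_bp]
        assert len(self_pairs) == 5

    def test_different_chromosomes_never_match(self):
        a = self._table([("1", 0, 1_000_000, 1.0)])
        b = self._table([("2", 0, 1_000_000, 1.0)])
        assert match_top_regions(a, b) == []

    def test_top_k_ranked_by_percent_with_positional_ties(self):
        rows = [
            ("1", 5_000_000, 6_000_000, 2.0),
            ("1", 1_000_000, 2_000_000, 2.0),
            ("2", 3_000_000, 4_000_000, 5.0),
        ]
        t = self._table(rows)
        top = top_blocks(t, 2)
        assert top.iloc[0]["percent"] == 5.0
        assert top.iloc[1]["start_bp"] == 1_000_000  # tie broken by position


class TestFisherProperties:
    """Property checks of the exact-enumeration Fisher implementation."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25)
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_agrees_with_scipy_and_stays_in_unit_interval(self, a, b, c, d):
        from scipy import stats

        p = fisher_exact_2x2([[a, b], [c, d]])
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(float(stats.fisher_exact([[a, b], [c, d]])[1]), abs=1e-9)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_transpose_invariance(self, a, b, c, d):
        assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
            fisher_exact_2x2([[a, c], [b, d]]), abs=1e-12
        )
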