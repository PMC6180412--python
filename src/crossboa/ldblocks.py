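"""LD-block segmentation and per-block percentage of genetic variance.

Nonrandom association between two loci is tested within one breed-of-origin
of the crossbred population: the four gametic types are counted over the
crossbred gametes whose alleles carry that origin at both loci, and
Fisher's exact test decides whether the disequilibrium coefficient
D = p_AB - p_A p_B differs from zero. Breakpoints between LD blocks fall
where D between two consecutive SNPs is not significant (P >= alpha), so
blocks partition the kept SNPs of every chromosome.

The percentage of genetic variance explained by block i is
Var(a_i) / sigma2_a * (x_n / n_i) * 100 with a_i = Z alpha-hat over the
block's SNPs, n_i the block size and x_n the mean block size — a
size-corrected share of the total genetic variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from crossboa.simdata import MarkerMap, OriginMatrix, PhasedGenotypes, breed_code


@dataclass
class GameticTable:
    """2x2 gamete counts: rows allele at locus i, columns allele at locus j."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 2x2 table")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def D(self) -> float:
        n = self.n
        if n == 0:
            return 0.0
        p11 = self.counts[1, 1] / n
        pa = self.counts[1, :].sum() / n
        pb = self.counts[:, 1].sum() / n
        return float(p11 - pa * pb)

    @property
    def pvalue(self) -> float:
        return fisher_exact_2x2(self.counts)


_EXACT_FISHER_MAX_N = 200


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sum of hypergeometric probabilities (same margins) of all tables whose
    point probability does not exceed the observed one; a zero margin gives
    a degenerate support and p = 1. Tables with up to 200 observations are
    evaluated in exact integer arithmetic (the point probabilities share
    one denominator, so the two-sided tie comparison is exact); larger
    tables fall back to scipy's floating-point implementation.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 array")
    n = int(t.sum())
    if n == 0:
        return 1.0
    if n <= _EXACT_FISHER_MAX_N:
        from math import comb

        r1, r2 = int(t[0].sum()), int(t[1].sum())
        c1 = int(t[:, 0].sum())
        lo, hi = max(0, c1 - r2), min(r1, c1)
        # numerators of the hypergeometric pmf over the common denominator
        nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
        obs = comb(r1, int(t[0, 0])) * comb(r2, c1 - int(t[0, 0]))
        return float(sum(v for v in nums if v <= obs) / comb(n, c1))
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def gametic_table(
    haps: PhasedGenotypes,
    origins: OriginMatrix,
    breed: str,
    locus_i: int,
    locus_j: int,
) -> GameticTable:
    """Gamete counts at two loci among same-origin crossbred gametes.

    A gamete contributes only when both its alleles carry the requested
    breed-of-origin; gametes with a missing origin at either locus are
    excluded.
    """
    code = breed_code(breed)
    mask = (origins.labels[:, locus_i, :] == code) & (origins.labels[:, locus_j, :] == code)
    ai = haps.codes[:, locus_i, :][mask]
    aj = haps.codes[:, locus_j, :][mask]
    counts = np.zeros((2, 2), dtype=np.int64)
    for a in (0, 1):
        for b in (0, 1):
            counts[a, b] = int(np.sum((ai == a) & (aj == b)))
    return GameticTable(counts)


@dataclass(frozen=True)
class LDBlock:
    chrom: str
    first: int  # inclusive index into the kept SNP set
    last: int  # inclusive
    start_bp: int
    stop_bp: int
    breed: str

    @property
    def n_snps(self) -> int:
        return self.last - self.first + 1

    @property
    def snp_indices(self) -> np.ndarray:
        return np.arange(self.first, self.last + 1)


@dataclass
class BlockSummary:
    breed: str
    n_blocks: int
    mean_len: float
    min_len: int
    max_len: int


def segment_ld_blocks(
    haps: PhasedGenotypes,
    origins: OriginMatrix,
    marker_map: MarkerMap,
    breed: str,
    alpha: float = 0.01,
) -> tuple[list[LDBlock], BlockSummary]:
    """Partition each chromosome's SNPs into LD blocks for one origin.

    Consecutive SNPs stay in the same block while the Fisher exact test on
    their gametic counts rejects D = 0 at ``alpha``; otherwise a breakpoint
    is placed. Chromosomes with a single SNP yield a singleton block.
    """
    if haps.n_snps != len(marker_map):
        raise ValueError("marker map does not match genotypes")
    blocks: list[LDBlock] = []
    for c in marker_map.chromosomes:
        idx = marker_map.chrom_indices(c)
        start = int(idx[0])
        for k in range(len(idx) - 1):
            i, j = int(idx[k]), int(idx[k + 1])
            p = gametic_table(haps, origins, breed, i, j).pvalue
            if p >= alpha:
                blocks.append(
                    LDBlock(c, start, i, int(marker_map.pos[start]), int(marker_map.pos[i]), breed)
                )
                start = j
        last = int(idx[-1])
        blocks.append(
            LDBlock(c, start, last, int(marker_map.pos[start]), int(marker_map.pos[last]), breed)
        )
    lens = [b.n_snps for b in blocks]
    summary = BlockSummary(breed, len(blocks), float(np.mean(lens)), min(lens), max(lens))
    return blocks, summary


def block_variance_explained(
    blocks: list[LDBlock],
    Z: np.ndarray,
    effects: np.ndarray,
    sigma2_a: float | None = None,
    x_n: float | None = None,
) -> pd.DataFrame:
    """Percentage of genetic variance explained by each LD block.

    ``Z`` holds the genotypes of all purebred individuals of the block's
    breed (rows individuals, columns the same kept SNP set the blocks index
    into) and ``effects`` the back-solved per-SNP allele effects. Variances
    are taken across individuals (population variance). ``sigma2_a``
    defaults to Var(Z @ effects) — the variance of the total genomic value —
    and ``x_n`` to the mean block size.
    """
    Z = np.asarray(Z, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if Z.shape[1] != len(effects):
        raise ValueError("Z and effects disagree on SNP count")
    if sigma2_a is None:
        sigma2_a = float(np.var(Z @ effects))
    if sigma2_a <= 0:
        raise ValueError("total genetic variance must be > 0")
    if x_n is None:
        x_n = float(np.mean([b.n_snps for b in blocks]))
    rows = []
    for b in blocks:
        a_i = Z[:, b.first : b.last + 1] @ effects[b.first : b.last + 1]
        var_i = float(np.var(a_i))
        pct = var_i / sigma2_a * (x_n / b.n_snps) * 100.0
        rows.append(
            {
                "chrom": b.chrom,
                "first": b.first,
                "last": b.last,
                "start_bp": b.start_bp,
                "stop_bp": b.stop_bp,
                "n_snps": b.n_snps,
                "breed": b.breed,
                "var": var_i,
                "percent": pct,
            }
        )
    out = pd.DataFrame(rows)
    order = np.lexsort((out["start_bp"], out["chrom"], -out["percent"]))
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    return out


@dataclass(frozen=True)
class RegionMatch:
    chrom: str
    a_start_bp: int
    a_stop_bp: int
    b_start_bp: int
    b_stop_bp: int
    gap_bp: int
    percent_a: float
    percent_b: float


def top_blocks(table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k blocks by percentage, ties broken by genomic position."""
    return table.sort_values(
        ["percent", "chrom", "start_bp"], ascending=[False, True, True], kind="stable"
    ).head(k)


def match_top_regions(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    k: int = 10,
    max_gap_bp: int = 1_000_000,
) -> list[RegionMatch]:
    """Cross-scenario matches among the two top-k block lists.

    Two blocks match when they sit on the same chromosome and their bp
    intervals overlap or are separated by less than ``max_gap_bp``.
    """
    ta = top_blocks(table_a, k)
    tb = top_blocks(table_b, k)
    out: list[RegionMatch] = []
    for a in ta.itertuples(index=False):
        for b in tb.itertuples(index=False):
            if a.chrom != b.chrom:
                continue
            gap = max(b.start_bp - a.stop_bp, a.start_bp - b.stop_bp, 0)
            if gap < max_gap_bp:
                out.append(
                    RegionMatch(
                        a.chrom,
                        int(a.start_bp),
                        int(a.stop_bp),
                        int(b.start_bp),
                        int(b.stop_bp),
                        int(gap),
                        float(a.percent),
                        float(b.percent),
                    )
                )
    return out
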