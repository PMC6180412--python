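"""Haplotype and allele-substitution analysis around a focal causal SNP.

For a known large-effect mutation (the motivating case is a missense
mutation in MC4R affecting growth and fatness in pigs) the module

1. builds, per breed-of-origin, the set of panel SNPs whose alleles are in
   significant gametic LD with the focal SNP on its chromosome (breakpoints
   are defined against the focal SNP, not between consecutive SNPs);
2. enumerates the distinct haplotypes of the cross-origin intersection
   block, records which focal allele (mutant m = code 1, wild type w =
   code 0) each co-segregates with, and excludes rare inconsistent copies
   as presumed genotyping errors;
3. scores each haplotype with the centered sum of its back-solved block-SNP
   effects and averages the m- and w-class effects weighted by haplotype
   frequency — the difference approximates the allele-substitution effect;
4. estimates the origin-specific substitution effects directly by a
   fixed-regression mixed model on pre-corrected phenotypes with a
   pedigree-based additive effect (variance fixed from the BOA fit) and a
   common-litter effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from crossboa.ldblocks import gametic_table
from crossboa.mixedmodel import reml_linear_cov
from crossboa.simdata import (
    BREEDS,
    ORIGIN_MISSING,
    MarkerMap,
    OriginMatrix,
    PhasedGenotypes,
    breed_code,
)


@dataclass
class FocalBlock:
    """Per-origin LD blocks around the focal SNP and their intersection."""

    focal_index: int
    per_origin: dict[str, np.ndarray]
    intersection: np.ndarray


def focal_ld_block(
    focal_snp: int,
    haps: PhasedGenotypes,
    origins: OriginMatrix,
    marker_map: MarkerMap,
    alpha: float = 0.01,
) -> FocalBlock:
    """SNPs in significant LD with the focal SNP, per breed-of-origin.

    Every other SNP on the focal chromosome is tested against the focal SNP
    with Fisher's exact test on same-origin gametic counts; the block
    collects those with p < alpha plus the focal SNP itself. The
    cross-origin intersection is returned for comparisons across origins.
    """
    chrom = marker_map.chrom[focal_snp]
    candidates = marker_map.chrom_indices(chrom)
    per_origin: dict[str, np.ndarray] = {}
    for b in BREEDS:
        hits = [focal_snp]
        for j in candidates:
            j = int(j)
            if j == focal_snp:
                continue
            if gametic_table(haps, origins, b, focal_snp, j).pvalue < alpha:
                hits.append(j)
        per_origin[b] = np.array(sorted(hits), dtype=np.int64)
    inter = per_origin[BREEDS[0]]
    for b in BREEDS[1:]:
        inter = np.intersect1d(inter, per_origin[b])
    return FocalBlock(focal_snp, per_origin, inter)


@dataclass
class HaplotypeRecord:
    """One distinct block haplotype with its carried focal allele."""

    codes: np.ndarray  # alleles over the block SNPs (excluding the focal SNP)
    focal_allele: str  # "m" (code 1) or "w" (code 0)
    counts: np.ndarray  # copies per origin (3,)
    n_excluded: int  # minority-focal-allele copies dropped as inconsistent
    effects: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def string(self) -> str:
        return "".join(str(int(c)) for c in self.codes)


def enumerate_block_haplotypes(
    block_snps: np.ndarray,
    haps: PhasedGenotypes,
    origins: OriginMatrix,
    focal_index: int,
) -> list[HaplotypeRecord]:
    """Distinct block haplotypes with per-origin counts and focal allele.

    A gamete copy is attributed to the breed-of-origin of its focal allele;
    copies with missing origin there are skipped. A haplotype string seen
    with both focal alleles keeps the majority allele and its minority
    copies are flagged and excluded (presumed genotyping errors).
    """
    block_snps = np.asarray(
        [j for j in np.asarray(block_snps, dtype=np.int64) if j != focal_index]
    )
    tally: dict[bytes, np.ndarray] = {}  # hap -> (3 origins x 2 focal alleles)
    for a in range(haps.n_animals):
        for g in range(2):
            org = int(origins.labels[a, focal_index, g])
            if org == ORIGIN_MISSING:
                continue
            key = haps.codes[a, block_snps, g].tobytes()
            if key not in tally:
                tally[key] = np.zeros((3, 2), dtype=np.int64)
            tally[key][org, int(haps.codes[a, focal_index, g])] += 1
    records: list[HaplotypeRecord] = []
    for key, counts in sorted(tally.items()):
        by_allele = counts.sum(axis=0)
        major = int(np.argmax(by_allele))  # majority focal allele for this string
        n_excl = int(by_allele[1 - major])
        records.append(
            HaplotypeRecord(
                codes=np.frombuffer(key, dtype=np.int8).copy(),
                focal_allele="m" if major == 1 else "w",
                counts=counts[:, major].copy(),
                n_excluded=n_excl,
            )
        )
    return records


def haplotype_effect(
    record: HaplotypeRecord,
    effects: np.ndarray,
    p: np.ndarray,
    block_snps: np.ndarray,
    focal_index: int,
    centered: bool = True,
) -> float:
    """Summed back-solved effect of the haplotype for one breed-of-origin.

    ``effects`` and ``p`` are the full-length per-SNP crossbred-performance
    effect and counted-allele frequency vectors of the origin. The default
    centered sum subtracts p_j from each allele code (so the
    frequency-weighted mean effect within an origin stays near zero); the
    raw sum is available with ``centered=False``.
    """
    block_snps = np.asarray(
        [j for j in np.asarray(block_snps, dtype=np.int64) if j != focal_index]
    )
    codes = record.codes.astype(float)
    if len(codes) != len(block_snps):
        raise ValueError("haplotype length does not match block SNP count")
    alpha = np.asarray(effects, dtype=float)[block_snps]
    if centered:
        return float(np.sum((codes - np.asarray(p, dtype=float)[block_snps]) * alpha))
    return float(np.sum(codes * alpha))


@dataclass
class AlleleMeans:
    """Frequency-weighted mean effects of the m- and w-haplotype classes."""

    mean_m: float | None
    mean_w: float | None
    n_m: int
    n_w: int

    @property
    def substitution_w_for_m(self) -> float | None:
        """Effect of substituting an m allele by a w allele."""
        if self.mean_m is None or self.mean_w is None:
            return None
        return self.mean_w - self.mean_m


def weighted_allele_means(records: list[HaplotypeRecord], origin: str) -> AlleleMeans:
    """Per-origin weighted means of m- and w-class haplotype effects.

    Weights are the haplotype copy counts within the origin, normalized
    within each focal-allele class.
    """
    code = breed_code(origin)
    sums = {"m": 0.0, "w": 0.0}
    ns = {"m": 0, "w": 0}
    for r in records:
        c = int(r.counts[code])
        if c == 0:
            continue
        if origin not in r.effects:
            raise ValueError("haplotype effects for this origin not yet computed")
        sums[r.focal_allele] += c * r.effects[origin]
        ns[r.focal_allele] += c
    mean_m = sums["m"] / ns["m"] if ns["m"] else None
    mean_w = sums["w"] / ns["w"] if ns["w"] else None
    return AlleleMeans(mean_m, mean_w, ns["m"], ns["w"])


@dataclass
class SubstitutionEstimate:
    """Fixed-regression substitution effects per origin, with their SEs."""

    estimates: dict[str, float | None]
    se: dict[str, float | None]
    sigma2_u: float
    sigma2_c: float
    sigma2_e: float

    def ci(self, breed: str, z: float = 1.96) -> tuple[float, float] | None:
        b, s = self.estimates.get(breed), self.se.get(breed)
        if b is None or s is None:
            return None
        return (b - z * s, b + z * s)


def fit_focal_snp_model(
    y: np.ndarray,
    allele_content: dict[str, np.ndarray],
    A: np.ndarray,
    litter: np.ndarray,
    sigma2_u: float,
    sigma2_c: float | None = None,
    sigma2_e: float | None = None,
) -> SubstitutionEstimate:
    """Mixed-model fixed regression of the focal-SNP origin contents.

    ``y`` holds pre-corrected crossbred phenotypes, ``allele_content`` the
    0/1 focal-allele count per breed-of-origin (entered centered), ``A`` the
    pedigree relationship matrix over the same animals and ``litter`` their
    litter labels. The additive genetic variance ``sigma2_u`` is fixed (it
    comes from the BOA fit); litter and residual variances are estimated by
    REML here unless supplied. Origins whose content never varies are
    reported as inestimable (None).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if A.shape != (n, n):
        raise ValueError("A does not match the number of records")
    cols = [np.ones(n)]
    names: list[str] = []
    for b in BREEDS:
        if b not in allele_content:
            continue
        x = np.asarray(allele_content[b], dtype=float)
        if np.std(x) < 1e-12:
            continue
        cols.append(x - x.mean())
        names.append(b)
    X = np.column_stack(cols)

    labels = pd.Series(np.asarray(litter, dtype=object))
    keep = labels != "0"
    uniq = labels[keep].unique()
    Zl = np.zeros((n, len(uniq)))
    for j, l in enumerate(uniq):
        Zl[:, j] = (labels == l).to_numpy(dtype=float)
    C_lit = Zl @ Zl.T

    V0 = sigma2_u * A
    if sigma2_c is None or sigma2_e is None:
        info = reml_linear_cov(
            y, X, [C_lit, np.eye(n)], ["c", "e"], V_offset=V0, tol=1e-8, max_iter=100
        )
        est_c, est_e = float(info.theta[0]), float(info.theta[1])
        sigma2_c = est_c if sigma2_c is None else sigma2_c
        sigma2_e = est_e if sigma2_e is None else sigma2_e
    V = V0 + sigma2_c * C_lit + sigma2_e * np.eye(n)
    cf = linalg.cho_factor(V, lower=True)
    VX = linalg.cho_solve(cf, X)
    XtVX = X.T @ VX
    cov_b = np.linalg.inv(XtVX)
    b_hat = cov_b @ (VX.T @ y)
    se_all = np.sqrt(np.diag(cov_b))
    estimates: dict[str, float | None] = {b: None for b in BREEDS}
    se: dict[str, float | None] = {b: None for b in BREEDS}
    for k, b in enumerate(names, start=1):
        estimates[b] = float(b_hat[k])
        se[b] = float(se_all[k])
    return SubstitutionEstimate(estimates, se, sigma2_u, sigma2_c, sigma2_e)
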