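"""Breed-specific partial genomic relationship matrices and pedigree A.

For each breed-of-origin b the partial relationship blocks follow VanRaden's
first method, with the crossbred rows built from the b-origin allele content
only:

    G_bb     = W_b  W_b'  / F_b        (purebred x purebred)
    G_b,CB   = W_b  W_cb' / F_b        (purebred x crossbred)
    G_CB,CB  = W_cb W_cb' / F_b        (crossbred x crossbred)

where W_b centers purebred dosages by 2 p_b, W_cb centers the crossbred
b-origin allele content (0/1) by p_b — the haploid centering is kept exactly
as the asymmetry it is — and alleles without an assigned origin contribute a
zero entry. p_b is the frequency of the counted allele among all breed-b
alleles (purebred plus crossbred b-origin), and F_b = sum_j 2 p_j (1 - p_j).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from crossboa.simdata import (
    BREEDS,
    OriginMatrix,
    PhasedGenotypes,
    breed_code,
    validate_pedigree,
)


@dataclass
class AlleleFreqEntry:
    """Counted-allele frequencies and scaling factor for one breed-of-origin."""

    breed: str
    p: np.ndarray
    F: float

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError(f"scaling factor F for breed {self.breed} must be > 0")


def breed_allele_frequencies(
    pb_haps: PhasedGenotypes,
    cb_haps: PhasedGenotypes,
    cb_origins: OriginMatrix,
    breed: str,
) -> AlleleFreqEntry:
    """Counted-allele frequency per SNP among all breed-b-origin alleles.

    Numerator: allele-1 copies among the breed's purebred animals plus the
    crossbred alleles assigned to that origin; denominator: the total number
    of breed-b alleles at the locus. Crossbred alleles with missing origin
    enter neither. SNPs with a zero denominator are rejected (they must have
    been filtered upstream).
    """
    code = breed_code(breed)
    mask = cb_origins.labels == code
    num = pb_haps.codes.sum(axis=(0, 2)).astype(np.int64)
    num += (cb_haps.codes * mask).sum(axis=(0, 2))
    den = np.full(pb_haps.n_snps, 2 * pb_haps.n_animals, dtype=np.int64)
    den += mask.sum(axis=(0, 2))
    if np.any(den == 0):
        bad = int(np.flatnonzero(den == 0)[0])
        raise ValueError(f"SNP {bad}: no breed-{breed} alleles observed")
    p = num / den
    F = float(np.sum(2.0 * p * (1.0 - p)))
    return AlleleFreqEntry(breed, p, F)


@dataclass
class PartialGRM:
    """Assembled partial relationship matrix for one breed-of-origin."""

    breed: str
    ids_pb: list[str]
    ids_cb: list[str]
    W_pb: np.ndarray  # (n_pb, m) purebred centered dosages
    W_cb: np.ndarray  # (n_cb, m) crossbred centered b-origin content
    freqs: AlleleFreqEntry

    @property
    def G_bb(self) -> np.ndarray:
        return (self.W_pb @ self.W_pb.T) / self.freqs.F

    @property
    def G_bcb(self) -> np.ndarray:
        return (self.W_pb @ self.W_cb.T) / self.freqs.F

    @property
    def G_cbcb(self) -> np.ndarray:
        return (self.W_cb @ self.W_cb.T) / self.freqs.F

    @property
    def ids(self) -> list[str]:
        return self.ids_pb + self.ids_cb

    def assembled(self) -> np.ndarray:
        """One matrix over (purebred-b, crossbred) animals."""
        top = np.hstack([self.G_bb, self.G_bcb])
        bot = np.hstack([self.G_bcb.T, self.G_cbcb])
        return np.vstack([top, bot])


@dataclass
class PartialGRMSet:
    """The three breed-specific partial relationship matrices."""

    grms: dict[str, PartialGRM]

    def __getitem__(self, breed: str) -> PartialGRM:
        return self.grms[breed]

    def __iter__(self):
        return iter(self.grms.values())

    @property
    def breeds(self) -> list[str]:
        return list(self.grms)


def crossbred_origin_content(
    cb_haps: PhasedGenotypes, cb_origins: OriginMatrix, breed: str, p: np.ndarray
) -> np.ndarray:
    """Centered b-origin allele content of crossbreds; missing origin -> 0."""
    code = breed_code(breed)
    mask = (cb_origins.labels == code).astype(np.float64)
    centered = (cb_haps.codes.astype(np.float64) - p[None, :, None]) * mask
    return centered.sum(axis=2)


def build_partial_grm_set(
    pb_haps: Mapping[str, PhasedGenotypes],
    cb_haps: PhasedGenotypes,
    cb_origins: OriginMatrix,
    freqs: Mapping[str, AlleleFreqEntry] | None = None,
) -> PartialGRMSet:
    """Partial GRMs for every breed with purebred data.

    ``freqs`` may carry precomputed allele frequencies (they must come from
    the same kept SNP set); by default they are computed here.
    """
    grms: dict[str, PartialGRM] = {}
    for b in BREEDS:
        if b not in pb_haps:
            continue
        fq = (
            freqs[b]
            if freqs is not None and b in freqs
            else breed_allele_frequencies(pb_haps[b], cb_haps, cb_origins, b)
        )
        if len(fq.p) != cb_haps.n_snps:
            raise ValueError("allele frequencies and genotypes disagree on SNP count")
        W_pb = pb_haps[b].dosage().astype(np.float64) - 2.0 * fq.p[None, :]
        W_cb = crossbred_origin_content(cb_haps, cb_origins, b, fq.p)
        grms[b] = PartialGRM(b, list(pb_haps[b].animals), list(cb_haps.animals), W_pb, W_cb, fq)
    if not grms:
        raise ValueError("no purebred populations supplied")
    return PartialGRMSet(grms)


def regularize_psd(G: np.ndarray, ridge: float) -> np.ndarray:
    """Blend towards the identity on the matrix's own diagonal scale.

    ``G' = (1 - ridge) G + ridge * mean(diag(G)) * I``; ridge 0 returns the
    matrix unchanged, and any matrix proportional to I is a fixed point.
    """
    if ridge < 0 or ridge > 1:
        raise ValueError("ridge must be in [0, 1]")
    if ridge == 0:
        return G
    d = float(np.mean(np.diag(G)))
    if d <= 0:
        d = 1.0
    return (1.0 - ridge) * G + ridge * d * np.eye(G.shape[0])


@dataclass
class PedigreeA:
    """Pedigree numerator relationship matrix with inbreeding coefficients."""

    A: np.ndarray
    ids: list[str]

    @property
    def inbreeding(self) -> np.ndarray:
        return np.diag(self.A) - 1.0

    def submatrix(self, animals: Sequence[str]) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.ids)}
        rows = [index[a] for a in animals]
        return self.A[np.ix_(rows, rows)]


def pedigree_numerator_matrix(ped: pd.DataFrame) -> PedigreeA:
    """Numerator relationship matrix by the tabular (recursive) method.

    Rows must be ordered parents-before-offspring; unknown parents are "0".
    Founders get a diagonal of 1; the diagonal is 1 plus the inbreeding
    coefficient (half the parents' relationship).
    """
    validate_pedigree(ped)
    ids = list(ped["id"])
    index = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = [index.get(s, -1) if s != "0" else -1 for s in ped["sire"]]
    dams = [index.get(d, -1) if d != "0" else -1 for d in ped["dam"]]
    for i in range(n):
        s, d = sires[i], dams[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return PedigreeA(A, ids)


def most_related_purebreds(grm: PartialGRM, k: int) -> list[str]:
    """The k purebreds most related (on average) to the crossbred block.

    Mirrors the practice of reducing a purebred population to its members
    closest to the crossbreds before variance-component estimation.
    """
    if grm.W_cb.shape[0] == 0:
        raise ValueError("no crossbred animals in this partial GRM")
    mean_rel = grm.G_bcb.mean(axis=1)
    order = np.argsort(-mean_rel, kind="stable")[: min(k, len(grm.ids_pb))]
    return [grm.ids_pb[i] for i in sorted(order)]
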