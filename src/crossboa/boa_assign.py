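"""Breed-of-origin assignment of crossbred alleles from a haplotype library.

Purebred haplotypes are catalogued window by window (multiple core lengths,
each tiled twice: once from the chromosome start and once shifted by half a
core, giving up to ``2 x n_lengths`` views of every allele). A window
haplotype is assigned to a breed when at least a ``purity`` share of its
copies is observed in that breed. Crossbred alleles then collect one vote
per view from the assigned window haplotypes they sit on; votes that are
incompatible with the cross design (e.g. a dam-line origin on the paternal
gamete of a terminal cross) are discarded and the majority of the remaining
votes decides, with ties left missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from crossboa.simdata import (
    BREEDS,
    ORIGIN_MISSING,
    MarkerMap,
    OriginMatrix,
    PhasedGenotypes,
    breed_code,
)

#: nine core lengths (SNP counts) spanning 25-400 on a geometric grid
DEFAULT_CORE_LENGTHS: tuple[int, ...] = (25, 35, 50, 71, 100, 141, 200, 283, 400)


@dataclass(frozen=True)
class WindowSpec:
    """Core lengths and offset modes defining the window views."""

    core_lengths: tuple[int, ...] = DEFAULT_CORE_LENGTHS
    offset_modes: tuple[str, ...] = ("not_offset", "offset")

    def __post_init__(self) -> None:
        if any(l < 2 for l in self.core_lengths):
            raise ValueError("core lengths must be >= 2")
        for m in self.offset_modes:
            if m not in ("not_offset", "offset"):
                raise ValueError(f"unknown offset mode {m!r}")

    @property
    def views_per_allele(self) -> int:
        return len(self.core_lengths) * len(self.offset_modes)

    def windows(self, n_snps: int) -> list[tuple[int, int]]:
        """(start, stop) index pairs tiling a chromosome of ``n_snps`` SNPs.

        Core lengths larger than the chromosome are skipped (they cannot
        tile it); if none fits, an error is raised. Trailing partial windows
        of at least 2 SNPs are kept.
        """
        fitting = [l for l in self.core_lengths if l <= n_snps]
        if not fitting:
            raise ValueError(
                f"all core lengths {self.core_lengths} exceed chromosome size {n_snps}"
            )
        out: list[tuple[int, int]] = []
        for length in fitting:
            for mode in self.offset_modes:
                start = length // 2 if mode == "offset" else 0
                while start < n_snps:
                    stop = min(start + length, n_snps)
                    if stop - start >= 2:
                        out.append((start, stop))
                    start += length
        return out


@dataclass
class HaplotypeLibrary:
    """Window haplotypes with per-breed copy counts and breed assignment."""

    windows: dict[tuple[str, int, int], dict[bytes, np.ndarray]]
    assigned: dict[tuple[str, int, int], dict[bytes, int]]
    purity: float
    spec: WindowSpec

    def breed_of(self, window: tuple[str, int, int], hap: bytes) -> int:
        """Assigned breed code for a window haplotype, -1 if unassigned."""
        return self.assigned.get(window, {}).get(hap, ORIGIN_MISSING)

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def _assign_hap(counts: np.ndarray, purity: float) -> int:
    total = counts.sum()
    if total == 0:
        return ORIGIN_MISSING
    b = int(np.argmax(counts))
    return b if counts[b] / total >= purity else ORIGIN_MISSING


def build_haplotype_library(
    purebred_haps: Mapping[str, PhasedGenotypes],
    marker_map: MarkerMap,
    windows: WindowSpec | None = None,
    purity: float = 0.80,
) -> HaplotypeLibrary:
    """Catalogue purebred window haplotypes and assign each to a breed.

    Every distinct haplotype string within a window gets per-breed copy
    counts over all purebred gametes; it is assigned to a breed when that
    breed holds at least ``purity`` of the copies, otherwise it stays
    unassigned.
    """
    spec = windows or WindowSpec()
    lib: dict[tuple[str, int, int], dict[bytes, np.ndarray]] = {}
    assigned: dict[tuple[str, int, int], dict[bytes, int]] = {}
    for c in marker_map.chromosomes:
        idx = marker_map.chrom_indices(c)
        lo = int(idx[0])
        for start, stop in spec.windows(len(idx)):
            key = (c, lo + start, lo + stop)
            table = lib.setdefault(key, {})
            for b in BREEDS:
                if b not in purebred_haps:
                    continue
                code = breed_code(b)
                haps = purebred_haps[b].codes[:, lo + start : lo + stop, :]
                for a in range(haps.shape[0]):
                    for g in range(2):
                        h = haps[a, :, g].tobytes()
                        if h not in table:
                            table[h] = np.zeros(3, dtype=np.int64)
                        table[h][code] += 1
            assigned[key] = {h: _assign_hap(cnt, purity) for h, cnt in table.items()}
    return HaplotypeLibrary(lib, assigned, purity, spec)


@dataclass(frozen=True)
class CrossDesign:
    """Breeds admissible on each gamete of the crossbred animals."""

    paternal: tuple[str, ...] = ("S",)
    maternal: tuple[str, ...] = ("LR", "LW")


def assign_breed_of_origin(
    cb_haps: PhasedGenotypes,
    library: HaplotypeLibrary,
    marker_map: MarkerMap,
    cross_design: CrossDesign | None = None,
) -> OriginMatrix:
    """Vote-based breed-of-origin assignment of every crossbred allele.

    Each allele collects one vote per window view from the library; votes
    for breeds excluded by the cross design on that gamete side are
    discarded; a strict majority of the remaining votes assigns the origin,
    and ties or vote-less alleles are left missing.
    """
    design = cross_design or CrossDesign()
    n, m = cb_haps.n_animals, cb_haps.n_snps
    votes = np.zeros((n, m, 2, 3), dtype=np.int16)
    for (c, start, stop), table in library.assigned.items():
        block = cb_haps.codes[:, start:stop, :]
        for a in range(n):
            for g in range(2):
                b = table.get(block[a, :, g].tobytes(), ORIGIN_MISSING)
                if b != ORIGIN_MISSING:
                    votes[a, start:stop, g, b] += 1
    allowed = np.zeros((2, 3), dtype=bool)
    for lbl in design.paternal:
        allowed[0, breed_code(lbl)] = True
    for lbl in design.maternal:
        allowed[1, breed_code(lbl)] = True
    votes = votes * allowed[None, None, :, :]
    order = np.sort(votes, axis=-1)
    top, second = order[..., -1], order[..., -2]
    winner = np.argmax(votes, axis=-1).astype(np.int8)
    labels = np.where((top > 0) & (top > second), winner, ORIGIN_MISSING).astype(np.int8)
    return OriginMatrix(labels, cb_haps.animals)


@dataclass
class AssignmentQC:
    """Per-SNP assignment rates, per-animal genome fractions, allele counts."""

    snp_rate_paternal: np.ndarray
    snp_rate_maternal: np.ndarray
    animal_rate: np.ndarray
    allele_counts: np.ndarray  # (n_snps, 3 origins, 2 alleles)


def compute_assignment_qc(origins: OriginMatrix, cb_haps: PhasedGenotypes) -> AssignmentQC:
    lab = origins.labels
    snp_pat = (lab[:, :, 0] != ORIGIN_MISSING).mean(axis=0)
    snp_mat = (lab[:, :, 1] != ORIGIN_MISSING).mean(axis=0)
    animal = (lab != ORIGIN_MISSING).reshape(lab.shape[0], -1).mean(axis=1)
    counts = np.zeros((lab.shape[1], 3, 2), dtype=np.int64)
    for b in range(3):
        mask = lab == b
        for allele in (0, 1):
            counts[:, b, allele] = ((cb_haps.codes == allele) & mask).sum(axis=(0, 2))
    return AssignmentQC(snp_pat, snp_mat, animal, counts)


@dataclass
class FilterResult:
    origins: OriginMatrix
    kept_snps: np.ndarray
    kept_animals: list[str]
    removed_snps_rate: int
    removed_animals: int
    removed_snps_copies: int
    qc: AssignmentQC


def apply_assignment_filters(
    origins: OriginMatrix,
    cb_haps: PhasedGenotypes,
    snp_rate: float = 0.90,
    animal_rate: float = 0.90,
    min_copies: int = 5,
    min_copies_allele: str = "both",
) -> FilterResult:
    """The three post-assignment filters, applied in order.

    1. SNPs whose paternal or maternal allele was assigned in less than
       ``snp_rate`` of the crossbreds are removed.
    2. Crossbreds with less than ``animal_rate`` of their genome (allele
       slots over the kept SNPs) assigned are removed.
    3. SNPs where an allele is observed fewer than ``min_copies`` times
       within any breed-of-origin are removed. ``min_copies_allele`` counts
       either ``"both"`` alleles (default) or only the ``"counted"`` code-1
       allele.

    One common SNP set results for all downstream populations.
    """
    if min_copies_allele not in ("both", "counted"):
        raise ValueError("min_copies_allele must be 'both' or 'counted'")
    qc = compute_assignment_qc(origins, cb_haps)
    keep_snp = (qc.snp_rate_paternal >= snp_rate) & (qc.snp_rate_maternal >= snp_rate)
    removed_rate = int((~keep_snp).sum())

    lab1 = origins.labels[:, keep_snp, :]
    animal_frac = (lab1 != ORIGIN_MISSING).reshape(lab1.shape[0], -1).mean(axis=1)
    keep_animal = animal_frac >= animal_rate
    removed_animals = int((~keep_animal).sum())
    kept_animals = [a for a, k in zip(origins.animals, keep_animal) if k]
    if not kept_animals:
        raise ValueError("all crossbred animals removed by the genome-assigned filter")

    sub_orig = origins.labels[keep_animal][:, keep_snp, :]
    sub_codes = cb_haps.codes[keep_animal][:, keep_snp, :]
    counts = np.zeros((sub_orig.shape[1], 3, 2), dtype=np.int64)
    for b in range(3):
        mask = sub_orig == b
        for allele in (0, 1):
            counts[:, b, allele] = ((sub_codes == allele) & mask).sum(axis=(0, 2))
    if min_copies_allele == "both":
        ok = (counts >= min_copies).all(axis=2)
    else:
        ok = counts[:, :, 1] >= min_copies
    # the rule applies to every breed-of-origin present in the data; an
    # origin observed nowhere (e.g. in a two-way design) is not demanded
    present = counts.sum(axis=(0, 2)) > 0  # (3,)
    keep_copies = (ok | ~present[None, :]).all(axis=1)
    removed_copies = int((~keep_copies).sum())

    kept_snps = np.flatnonzero(keep_snp)[keep_copies]
    if len(kept_snps) == 0:
        raise ValueError("all SNPs removed by assignment filters; check configuration")
    out = OriginMatrix(origins.labels[keep_animal][:, kept_snps, :], kept_animals)
    return FilterResult(
        out, kept_snps, kept_animals, removed_rate, removed_animals, removed_copies, qc
    )


@dataclass
class AccuracySummary:
    assigned_fraction: float
    accuracy: float | None
    per_origin: dict[str, dict[str, float | None]]


def assignment_accuracy(origins: OriginMatrix, truth: OriginMatrix) -> AccuracySummary:
    """Assignment completeness and correctness against simulation truth."""
    if origins.labels.shape != truth.labels.shape:
        raise ValueError("origin and truth matrices have different shapes")
    assigned = origins.labels != ORIGIN_MISSING
    frac = float(assigned.mean()) if assigned.size else 0.0
    if assigned.any():
        acc = float((origins.labels[assigned] == truth.labels[assigned]).mean())
    else:
        acc = None
    per: dict[str, dict[str, float | None]] = {}
    for b in BREEDS:
        code = breed_code(b)
        truth_b = truth.labels == code
        n_b = int(truth_b.sum())
        a_b = assigned & truth_b
        per[b] = {
            "assigned_fraction": float(a_b.sum() / n_b) if n_b else None,
            "accuracy": float((origins.labels[a_b] == code).mean()) if a_b.any() else None,
        }
    return AccuracySummary(frac, acc, per)
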