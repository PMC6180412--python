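"""Synthetic purebred and three-way crossbred populations with truth labels.

The generator emulates the structure of a commercial pig breeding program:
three diverged purebred lines (a synthetic sire line S and two dam lines LR
and LW), a terminal cross S x (LR x LW), breed-of-origin-specific additive
QTL effects (so that the purebred-crossbred genetic correlation r_pc can be
below one), common-litter environmental effects, and the usual growth /
feed-intake trait panel (BF, ADG, ADFI and derived RFI).

Founder divergence follows a Balding-Nichols style model: a common ancestral
allele frequency per SNP, and per-breed frequencies drawn from a Beta
distribution whose variance is chosen so that realized pairwise
Weir-Cockerham F_ST approaches the requested targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BREEDS: tuple[str, str, str] = ("S", "LR", "LW")
ORIGIN_MISSING: int = -1

_BREED_CODE = {b: i for i, b in enumerate(BREEDS)}

#: default pairwise F_ST targets between the three lines
DEFAULT_FST = {("S", "LR"): 0.17, ("S", "LW"): 0.12, ("LR", "LW"): 0.14}

#: default genetic-parameter targets per trait: per-breed purebred
#: heritability, crossbred heritability, per-breed r_pc, litter-variance
#: ratio c2, phenotypic mean and SD on the trait's own scale.
#: LR values for RFI are not estimable in the source populations; the
#: simulator uses plausible mid-range stand-ins.
DEFAULT_TRAIT_TARGETS: dict[str, "TraitTargets"]


def breed_code(label: str) -> int:
    return _BREED_CODE[label]


def breed_label(code: int) -> str:
    if code == ORIGIN_MISSING:
        return "missing"
    return BREEDS[code]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreedSpec:
    """Founder specification of one purebred line.

    ``target_fst`` maps the other breed ids to the pairwise Weir-Cockerham
    F_ST targets; ``base_freq_model`` gives the (low, high) bounds of the
    uniform ancestral allele-frequency distribution.
    """

    breed_id: str
    n_founders: int
    target_fst: Mapping[str, float] = field(default_factory=dict)
    base_freq_model: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError(f"breed {self.breed_id}: n_founders must be >= 2")
        for other, t in self.target_fst.items():
            if not (0.0 <= t < 1.0):
                raise ValueError(f"target_fst[{other}]={t} outside [0, 1)")
        lo, hi = self.base_freq_model
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("base_freq_model bounds must satisfy 0 < lo <= hi < 1")


class MarkerMap:
    """Marker map: chromosome, 1-based bp position, focal/panel flags."""

    def __init__(
        self,
        chrom: Sequence[str],
        pos: Sequence[int],
        ids: Sequence[str] | None = None,
        is_focal: Sequence[bool] | None = None,
        on_panel: Sequence[bool] | None = None,
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        n = len(self.pos)
        if len(self.chrom) != n:
            raise ValueError("chrom and pos length mismatch")
        self.ids = (
            np.asarray(ids, dtype=object)
            if ids is not None
            else np.array([f"snp{i}" for i in range(n)], dtype=object)
        )
        self.is_focal = (
            np.asarray(is_focal, dtype=bool) if is_focal is not None else np.zeros(n, bool)
        )
        self.on_panel = (
            np.asarray(on_panel, dtype=bool) if on_panel is not None else np.ones(n, bool)
        )
        if self.is_focal.sum() > 1:
            raise ValueError("at most one focal SNP allowed")
        if np.any(self.pos < 1):
            raise ValueError("positions are 1-based and must be >= 1")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_indices(self, c: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == c)

    @property
    def focal_index(self) -> int | None:
        idx = np.flatnonzero(self.is_focal)
        return int(idx[0]) if len(idx) else None

    @property
    def panel_indices(self) -> np.ndarray:
        return np.flatnonzero(self.on_panel)

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        indices = np.asarray(indices)
        return MarkerMap(
            self.chrom[indices],
            self.pos[indices],
            self.ids[indices],
            self.is_focal[indices],
            self.on_panel[indices],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "id": self.ids,
                "is_focal": self.is_focal,
                "on_panel": self.on_panel,
            }
        )

    @classmethod
    def uniform(
        cls,
        n_chrom: int = 1,
        n_snps_per_chrom: int = 100,
        chrom_length_bp: int = 100_000_000,
        chrom_names: Sequence[str] | None = None,
    ) -> "MarkerMap":
        """Evenly spaced markers on equally sized chromosomes."""
        chroms: list[str] = []
        pos: list[int] = []
        names = chrom_names or [str(i + 1) for i in range(n_chrom)]
        spacing = chrom_length_bp // (n_snps_per_chrom + 1)
        for c in names:
            for j in range(n_snps_per_chrom):
                chroms.append(c)
                pos.append((j + 1) * spacing)
        return cls(chroms, pos)


class PhasedGenotypes:
    """Phased biallelic allele codes: (n_animals, n_snps, 2) in {0, 1}.

    Gamete 0 is paternal, gamete 1 maternal.
    """

    def __init__(self, codes: np.ndarray, animals: Sequence[str]) -> None:
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 3 or codes.shape[2] != 2:
            raise ValueError("codes must have shape (n_animals, n_snps, 2)")
        if codes.size and (codes.min() < 0 or codes.max() > 1):
            raise ValueError("allele codes must be 0/1")
        if len(animals) != codes.shape[0]:
            raise ValueError("animal id count does not match codes")
        self.codes = codes
        self.animals = list(animals)
        self._index = {a: i for i, a in enumerate(self.animals)}

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def dosage(self) -> np.ndarray:
        """Allele-1 dosage (n_animals, n_snps) in {0, 1, 2}."""
        return self.codes.sum(axis=2).astype(np.int16)

    def row(self, animal: str) -> np.ndarray:
        return self.codes[self._index[animal]]

    def subset_animals(self, animals: Sequence[str]) -> "PhasedGenotypes":
        rows = [self._index[a] for a in animals]
        return PhasedGenotypes(self.codes[rows], list(animals))

    def subset_snps(self, indices: np.ndarray) -> "PhasedGenotypes":
        return PhasedGenotypes(self.codes[:, np.asarray(indices)], self.animals)


class OriginMatrix:
    """Breed-of-origin labels per animal x SNP x gamete.

    Codes 0/1/2 for S/LR/LW, -1 for missing/unassigned. Used both for the
    simulation truth and for the output of the assignment stage.
    """

    def __init__(self, labels: np.ndarray, animals: Sequence[str]) -> None:
        labels = np.asarray(labels, dtype=np.int8)
        if labels.ndim != 3 or labels.shape[2] != 2:
            raise ValueError("labels must have shape (n_animals, n_snps, 2)")
        if labels.size and (labels.min() < -1 or labels.max() > 2):
            raise ValueError("origin codes must be in {-1, 0, 1, 2}")
        if len(animals) != labels.shape[0]:
            raise ValueError("animal id count does not match labels")
        self.labels = labels
        self.animals = list(animals)
        self._index = {a: i for i, a in enumerate(self.animals)}

    @property
    def n_animals(self) -> int:
        return self.labels.shape[0]

    @property
    def n_snps(self) -> int:
        return self.labels.shape[1]

    def subset_animals(self, animals: Sequence[str]) -> "OriginMatrix":
        rows = [self._index[a] for a in animals]
        return OriginMatrix(self.labels[rows], list(animals))

    def subset_snps(self, indices: np.ndarray) -> "OriginMatrix":
        return OriginMatrix(self.labels[:, np.asarray(indices)], self.animals)


@dataclass(frozen=True)
class TraitTargets:
    """Generator targets for one trait (variance ratios of phenotypic var)."""

    name: str
    h2_pb: Mapping[str, float]
    h2_cb: float
    r_pc: Mapping[str, float]
    c2: float = 0.10
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        for b, h in self.h2_pb.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"h2_pb[{b}] outside [0, 1]")
        if not 0.0 <= self.h2_cb <= 1.0:
            raise ValueError("h2_cb outside [0, 1]")
        if not 0.0 <= self.c2 <= 1.0:
            raise ValueError("c2 outside [0, 1]")
        for b, r in self.r_pc.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"r_pc[{b}] outside [-1, 1]")


DEFAULT_TRAIT_TARGETS = {
    "BF": TraitTargets(
        "BF",
        h2_pb={"S": 0.31, "LR": 0.33, "LW": 0.34},
        h2_cb=0.41,
        r_pc={"S": 0.80, "LR": 0.71, "LW": 0.89},
        mean=12.0,
        sd=2.5,
    ),
    "ADG": TraitTargets(
        "ADG",
        h2_pb={"S": 0.09, "LR": 0.22, "LW": 0.20},
        h2_cb=0.29,
        r_pc={"S": 0.69, "LR": 0.60, "LW": 0.68},
        mean=900.0,
        sd=90.0,
    ),
    "RFI": TraitTargets(
        "RFI",
        h2_pb={"S": 0.15, "LR": 0.15, "LW": 0.61},
        h2_cb=0.40,
        r_pc={"S": 0.37, "LR": 0.50, "LW": 0.60},
        mean=0.0,
        sd=120.0,
    ),
}


@dataclass
class QTLModel:
    """Additive QTL with breed-of-origin-specific effects per trait.

    ``alpha_pb[trait][breed]`` and ``alpha_cb[trait][breed]`` hold unit-scale
    effect vectors over ``qtl_index``; the per-breed correlation between the
    purebred- and crossbred-performance vectors controls r_pc. Effects are
    rescaled against the realized genetic variance inside
    :func:`simulate_phenotypes`.
    """

    qtl_index: np.ndarray
    alpha_pb: dict[str, dict[str, np.ndarray]]
    alpha_cb: dict[str, dict[str, np.ndarray]]

    @classmethod
    def sample(
        cls,
        n_snps: int,
        targets: Mapping[str, TraitTargets],
        seed: int | np.random.Generator,
        n_qtl: int | None = None,
    ) -> "QTLModel":
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        if n_qtl is None or n_qtl >= n_snps:
            qtl_index = np.arange(n_snps)
        else:
            qtl_index = np.sort(rng.choice(n_snps, size=n_qtl, replace=False))
        q = len(qtl_index)
        alpha_pb: dict[str, dict[str, np.ndarray]] = {}
        alpha_cb: dict[str, dict[str, np.ndarray]] = {}
        for trait, tt in targets.items():
            alpha_pb[trait] = {}
            alpha_cb[trait] = {}
            for b in BREEDS:
                a_pb = rng.standard_normal(q)
                r = float(tt.r_pc.get(b, 0.0))
                a_cb = r * a_pb + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(q)
                alpha_pb[trait][b] = a_pb
                alpha_cb[trait][b] = a_cb
        return cls(qtl_index=qtl_index, alpha_pb=alpha_pb, alpha_cb=alpha_cb)


# ---------------------------------------------------------------------------
# founder simulation
# ---------------------------------------------------------------------------


def _solve_breed_drift(specs: Sequence[BreedSpec]) -> dict[str, float]:
    """Per-breed drift parameters F_b such that (F_a + F_b)/2 matches the
    pairwise targets (least squares for >3 breeds, exact for <=3)."""
    ids = [s.breed_id for s in specs]
    pairs: dict[frozenset, float] = {}
    for s in specs:
        for other, t in s.target_fst.items():
            key = frozenset((s.breed_id, other))
            if key in pairs and abs(pairs[key] - t) > 1e-12:
                raise ValueError(f"inconsistent pairwise F_ST targets for {set(key)}")
            pairs[key] = t
    if not pairs:
        return {b: 0.0 for b in ids}
    rows, rhs = [], []
    for key, t in pairs.items():
        row = np.zeros(len(ids))
        for b in key:
            row[ids.index(b)] = 0.5
        rows.append(row)
        rhs.append(t)
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    return {b: float(max(f, 0.0)) for b, f in zip(ids, sol)}


def simulate_founder_breeds(
    specs: Sequence[BreedSpec],
    marker_map: MarkerMap,
    seed: int,
) -> dict[str, PhasedGenotypes]:
    """Draw founder haplotypes for each breed from diverged allele frequencies.

    Ancestral frequencies are uniform on ``base_freq_model``; breed
    frequencies follow a Balding-Nichols Beta model with per-breed drift F_b
    solved from the pairwise F_ST targets (F_ST(a,b) ~ (F_a + F_b)/2).
    """
    ids = [s.breed_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate breed ids")
    if len(marker_map) == 0:
        raise ValueError("empty marker map")
    lo, hi = specs[0].base_freq_model
    if hi - lo < 1e-12 and (lo <= 0.0 or lo >= 1.0):
        raise ValueError("degenerate frequency model: all SNPs monomorphic")
    rng = np.random.default_rng(seed)
    m = len(marker_map)
    drift = _solve_breed_drift(specs)
    p_anc = rng.uniform(lo, hi, size=m)
    out: dict[str, PhasedGenotypes] = {}
    for s in specs:
        F = drift[s.breed_id]
        if F <= 1e-12:
            p_b = p_anc.copy()
        else:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            p_b = rng.beta(a, b)
        p_b = np.clip(p_b, 1e-6, 1.0 - 1e-6)
        haps = (rng.random((s.n_founders, m, 2)) < p_b[None, :, None]).astype(np.int8)
        out[s.breed_id] = PhasedGenotypes(
            haps, [f"{s.breed_id}_f{i}" for i in range(s.n_founders)]
        )
    return out


def default_breed_specs(n_founders: int = 50) -> list[BreedSpec]:
    """S/LR/LW specs with the default pairwise differentiation targets."""
    specs = []
    for b in BREEDS:
        tf = {}
        for (x, y), t in DEFAULT_FST.items():
            if b == x:
                tf[y] = t
            elif b == y:
                tf[x] = t
        specs.append(BreedSpec(b, n_founders, tf))
    return specs


def weir_cockerham_fst(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Multi-locus Weir-Cockerham F_ST between two sets of haplotypes.

    Inputs are (n_animals, n_snps, 2) phased codes (every gamete is treated
    as one sampled allele). Returns the ratio-of-sums estimator from the
    two-level (allele within population) analysis of variance.
    """
    ha = codes_a.transpose(0, 2, 1).reshape(-1, codes_a.shape[1])
    hb = codes_b.transpose(0, 2, 1).reshape(-1, codes_b.shape[1])
    n1, n2 = ha.shape[0], hb.shape[0]
    p1 = ha.mean(axis=0)
    p2 = hb.mean(axis=0)
    n = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n
    r = 2
    msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
    # within-population mean squares (unbiased per-population allele variance)
    msg = (n1 * p1 * (1 - p1) * n1 / (n1 - 1) + n2 * p2 * (1 - p2) * n2 / (n2 - 1)) / (n - r)
    nc = (n - (n1 * n1 + n2 * n2) / n) / (r - 1)
    a = (msp - msg) / nc
    denom = a + msg
    keep = denom > 0
    if not np.any(keep):
        return float("nan")
    return float(a[keep].sum() / denom[keep].sum())


# ---------------------------------------------------------------------------
# pedigree and gene dropping
# ---------------------------------------------------------------------------

PED_COLUMNS = ["id", "sire", "dam", "group", "litter"]


def make_three_way_pedigree(
    n_founders: int = 50,
    n_purebred: int = 60,
    n_f1: int = 40,
    n_crossbred: int = 120,
    litter_size: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Pedigree for a terminal three-way cross.

    Generation 0: ``n_founders`` founders per purebred line. Generation 1:
    ``n_purebred`` phenotyped purebreds per line (full-sib litters of
    ``litter_size``). Generation 2: ``n_f1`` F1 dams from gen-1 LR sires x
    gen-1 LW dams. Generation 3: ``n_crossbred`` crossbreds (gen-1 S sire x
    F1 dam, litters of ``litter_size``). Phenotyped purebreds are thus the
    parents and maternal grandparents of the crossbreds, mirroring a
    combined crossbred-purebred selection scheme.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    founders: dict[str, list[str]] = {}
    for b in BREEDS:
        founders[b] = [f"{b}_f{i}" for i in range(n_founders)]
        for a in founders[b]:
            rows.append((a, "0", "0", b, "0"))

    def add_litters(prefix, group, sires, dams, count, litter_size):
        n_litters = int(np.ceil(count / litter_size))
        k = 0
        for li in range(n_litters):
            sire = sires[rng.integers(len(sires))]
            dam = dams[rng.integers(len(dams))]
            for _ in range(litter_size):
                if k >= count:
                    break
                rows.append((f"{prefix}{k}", sire, dam, group, f"{prefix}L{li}"))
                k += 1

    for b in BREEDS:
        males = founders[b][: n_founders // 2]
        females = founders[b][n_founders // 2 :]
        add_litters(f"{b}_p", b, males, females, n_purebred, litter_size)
    # F1 dams: gen-1 LR sires x gen-1 LW dams (phenotyped purebreds)
    lr_m = [f"LR_p{i}" for i in range(max(1, n_purebred // 2))]
    lw_f = [f"LW_p{i}" for i in range(max(1, n_purebred // 2), n_purebred)] or ["LW_p0"]
    f1 = [f"F1_{i}" for i in range(n_f1)]
    for i, a in enumerate(f1):
        rows.append((a, lr_m[rng.integers(len(lr_m))], lw_f[rng.integers(len(lw_f))], "F1", "0"))
    s_males = [f"S_p{i}" for i in range(max(1, n_purebred // 2))]
    add_litters("CB_", "CB", s_males, f1, n_crossbred, litter_size)
    ped = pd.DataFrame(rows, columns=PED_COLUMNS)
    validate_pedigree(ped)
    return ped


def validate_pedigree(ped: pd.DataFrame) -> None:
    seen: set[str] = set()
    for row in ped.itertuples(index=False):
        for parent in (row.sire, row.dam):
            if parent != "0" and parent not in seen:
                raise ValueError(f"parent {parent} of {row.id} does not precede it")
        if row.id in seen:
            raise ValueError(f"duplicate animal id {row.id}")
        seen.add(row.id)


def _meiosis(
    parent_codes: np.ndarray,
    parent_orig: np.ndarray,
    marker_map: MarkerMap,
    rng: np.random.Generator,
    cm_per_mb: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: recombinant mosaic of the parent's two gametes.

    Crossover counts per chromosome are Poisson with rate given by the map
    length (Haldane, no interference); crossover positions are uniform.
    """
    m = parent_codes.shape[0]
    gam = np.empty(m, dtype=np.int8)
    org = np.empty(m, dtype=np.int8)
    for c in marker_map.chromosomes:
        idx = marker_map.chrom_indices(c)
        pos = marker_map.pos[idx].astype(float)
        length_m = pos[-1] * cm_per_mb * 1e-8  # bp -> Morgan
        phase = int(rng.integers(2))
        if cm_per_mb > 0 and length_m > 0:
            n_x = rng.poisson(length_m)
        else:
            n_x = 0
        if n_x > 0:
            xpos = np.sort(rng.uniform(0.0, pos[-1], size=n_x))
            seg = phase + np.searchsorted(xpos, pos, side="right")
            which = (seg % 2).astype(np.intp)
        else:
            which = np.full(len(idx), phase, dtype=np.intp)
        gam[idx] = parent_codes[idx, which]
        org[idx] = parent_orig[idx, which]
    return gam, org


def gene_drop_pedigree(
    founders: Mapping[str, PhasedGenotypes],
    ped: pd.DataFrame,
    marker_map: MarkerMap,
    seed: int,
    cm_per_mb: float = 1.0,
) -> tuple[PhasedGenotypes, OriginMatrix]:
    """Drop founder haplotypes through the pedigree.

    Founders consume haplotype pairs from their breed's founder pool (in
    pedigree order); every transmitted allele keeps the breed label of the
    founder gamete it descends from, giving the truth breed-of-origin matrix.
    """
    validate_pedigree(ped)
    rng = np.random.default_rng(seed)
    m = len(marker_map)
    animals = list(ped["id"])
    codes = np.zeros((len(animals), m, 2), dtype=np.int8)
    orig = np.zeros((len(animals), m, 2), dtype=np.int8)
    index = {a: i for i, a in enumerate(animals)}
    next_founder = {b: 0 for b in founders}
    for row in ped.itertuples(index=False):
        i = index[row.id]
        if row.sire == "0" and row.dam == "0":
            if row.group not in founders:
                raise ValueError(f"no founder pool for group {row.group} ({row.id})")
            pool = founders[row.group]
            k = next_founder[row.group]
            if k >= pool.n_animals:
                raise ValueError(f"founder pool for {row.group} exhausted")
            codes[i] = pool.codes[k]
            orig[i] = breed_code(row.group)
            next_founder[row.group] = k + 1
        elif row.sire != "0" and row.dam != "0":
            si, di = index[row.sire], index[row.dam]
            codes[i, :, 0], orig[i, :, 0] = _meiosis(
                codes[si], orig[si], marker_map, rng, cm_per_mb
            )
            codes[i, :, 1], orig[i, :, 1] = _meiosis(
                codes[di], orig[di], marker_map, rng, cm_per_mb
            )
        else:
            raise ValueError(f"animal {row.id} has exactly one known parent")
    return PhasedGenotypes(codes, animals), OriginMatrix(orig, animals)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

#: Table-2-style covariate used per trait and population class
_TRAIT_COVARIATE = {
    ("BF", "PB"): "bw_off",
    ("BF", "CB"): "hcw",
    ("ADG", "PB"): "birth_weight",
    ("ADG", "CB"): "birth_weight",
    ("RFI", "PB"): "bw_on",
    ("RFI", "CB"): "bw_on",
}

#: genome share of each breed-of-origin in the three-way cross
CB_GENOME_SHARE = {"S": 0.5, "LR": 0.25, "LW": 0.25}


def _scale_to_variance(g: np.ndarray, target_var: float) -> np.ndarray:
    v = float(np.var(g))
    if v <= 0:
        return np.zeros_like(g)
    return g * np.sqrt(target_var / v)


def simulate_phenotypes(
    geno: PhasedGenotypes,
    origins: OriginMatrix,
    ped: pd.DataFrame,
    qtl: QTLModel,
    targets: Mapping[str, TraitTargets],
    seed: int,
    n_farms_pb: int = 3,
    n_farms_cb: int = 2,
    n_trials: int = 2,
    extra_genetic: Mapping[str, np.ndarray] | None = None,
    phenotyped: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Phenotypes for purebred gen-1 and crossbred animals.

    Each phenotype is fixed part + breed-of-origin-specific QTL sum + litter
    effect + residual. QTL effect vectors are rescaled so the realized
    genetic variance among the phenotyped animals matches the targets (h2_pb
    per breed, h2_cb split by genome share across origins), which makes
    realized heritabilities converge to the targets by construction.

    ``extra_genetic`` maps a trait name to a per-phenotyped-animal genetic
    contribution added after scaling (used for the focal-mutation scenario).
    """
    rng = np.random.default_rng(seed)
    ped = ped.set_index("id", drop=False)
    if phenotyped is None:
        phen = [
            r.id
            for r in ped.itertuples(index=False)
            if (r.group in BREEDS and r.sire != "0") or r.group == "CB"
        ]
    else:
        phen = list(phenotyped)
    groups = ped.loc[phen, "group"].to_numpy()
    litters = ped.loc[phen, "litter"].to_numpy()
    n = len(phen)
    is_cb = groups == "CB"

    rec = pd.DataFrame({"animal": phen, "group": groups, "litter": litters})
    rec["sex"] = rng.choice(["M", "F"], size=n)
    farm = np.empty(n, dtype=object)
    farm[~is_cb] = np.char.add("pf", rng.integers(n_farms_pb, size=(~is_cb).sum()).astype(str))
    farm[is_cb] = np.char.add("cf", rng.integers(n_farms_cb, size=is_cb.sum()).astype(str))
    rec["farm"] = farm
    trial = np.array(["0"] * n, dtype=object)
    trial[is_cb] = rng.integers(n_trials, size=is_cb.sum()).astype(str)
    rec["trial"] = trial
    rec["bw_on"] = np.round(rng.normal(30.0, 3.0, size=n), 3)
    rec["bw_off"] = np.round(rng.normal(100.0, 8.0, size=n), 3)
    rec["birth_weight"] = np.round(rng.normal(1.4, 0.2, size=n), 4)
    rec["hcw"] = np.round(rng.normal(95.0, 6.0, size=n), 3)

    sub_codes = geno.subset_animals(phen).codes
    sub_orig = origins.subset_animals(phen).labels
    qidx = qtl.qtl_index
    dos = sub_codes[:, qidx, :].sum(axis=2).astype(float)  # (n, q)

    # per-origin centered allele content among crossbreds (truth labels):
    # (x - p_b) for alleles of origin b, 0 otherwise, with p_b the counted-
    # allele frequency among all breed-b alleles (purebred + crossbred) —
    # origin-specific breeding values are deviations from the origin's own
    # allele-frequency mean, matching the partial-GRM convention.
    content: dict[str, np.ndarray] = {}
    for b in BREEDS:
        bc = breed_code(b)
        mask = sub_orig[:, qidx, :] == bc
        pb_sel = groups == b
        num = sub_codes[pb_sel][:, qidx, :].sum(axis=(0, 2)).astype(float)
        den = np.full(len(qidx), 2.0 * pb_sel.sum())
        cb_mask = mask & is_cb[:, None, None]
        num += (sub_codes[:, qidx, :] * cb_mask).sum(axis=(0, 2))
        den += cb_mask.sum(axis=(0, 2))
        p_b = np.divide(num, den, out=np.full(len(qidx), 0.5), where=den > 0)
        content[b] = (
            (sub_codes[:, qidx, :].astype(float) - p_b[None, :, None]) * mask
        ).sum(axis=2)

    litter_ids = pd.unique(litters)
    litter_map = {l: i for i, l in enumerate(litter_ids)}
    litter_idx = np.array([litter_map[l] for l in litters])

    for trait, tt in targets.items():
        sd2 = tt.sd**2
        g = np.zeros(n)
        for b in BREEDS:
            sel = groups == b
            if sel.any():
                X = dos[sel]
                Xc = X - X.mean(axis=0, keepdims=True)
                raw = Xc @ qtl.alpha_pb[trait][b]
                g[sel] = _scale_to_variance(raw, tt.h2_pb.get(b, 0.0) * sd2)
        if is_cb.any():
            for b in BREEDS:
                W = content[b][is_cb]
                Wc = W - W.mean(axis=0, keepdims=True)
                raw = Wc @ qtl.alpha_cb[trait][b]
                g[is_cb] += _scale_to_variance(raw, CB_GENOME_SHARE[b] * tt.h2_cb * sd2)
        if extra_genetic is not None and trait in extra_genetic:
            g = g + np.asarray(extra_genetic[trait], dtype=float)

        lit_eff = rng.normal(0.0, np.sqrt(tt.c2 * sd2), size=len(litter_ids))
        lit_eff[np.array([l == "0" for l in litter_ids])] = 0.0
        h2_rec = np.where(
            is_cb, tt.h2_cb, [tt.h2_pb.get(gr, 0.0) for gr in groups]
        ).astype(float)
        e_sd = np.sqrt(np.maximum(1.0 - h2_rec - tt.c2, 1e-6) * sd2)
        resid = rng.normal(0.0, 1.0, size=n) * e_sd

        fixed = np.full(n, tt.mean)
        for col in ("farm", "sex", "trial"):
            levels = pd.unique(rec[col])
            eff = rng.normal(0.0, 0.25 * tt.sd, size=len(levels))
            lm = {l: e for l, e in zip(levels, eff)}
            fixed += np.array([lm[v] for v in rec[col]])
        for pc, colname in (("PB", None), ("CB", None)):
            cov = _TRAIT_COVARIATE.get((trait, pc))
            if cov is None:
                continue
            sel = is_cb if pc == "CB" else ~is_cb
            x = rec[cov].to_numpy(dtype=float)
            slope = 0.2 * tt.sd / max(x[sel].std(), 1e-9)
            fixed[sel] += slope * (x[sel] - x[sel].mean())

        rec[trait] = fixed + g + lit_eff[litter_idx] + resid

    if "RFI" in targets:
        tt = targets["RFI"]
        rfi_latent = rec["RFI"].to_numpy()
        b1, b2, b3, b4 = 18.0, 14.0, 25.0, 1.1
        rec["ADFI"] = (
            2300.0
            + b1 * rec["bw_on"]
            + b2 * rec["bw_off"]
            + (b3 * rec["BF"] if "BF" in rec else 0.0)
            + (b4 * rec["ADG"] if "ADG" in rec else 0.0)
            + rfi_latent
        )
        rec = rec.drop(columns=["RFI"])
    return rec


def derive_rfi(records: pd.DataFrame) -> pd.DataFrame:
    """Residual feed intake: residual of ADFI on BW_on, BW_off, BF and ADG.

    The regression is fitted by least squares separately within the purebred
    and the crossbred population (their feed-intake recording differs), so
    within each population the residuals are exactly orthogonal to all four
    covariates and sum to zero.
    """
    required = ["ADFI", "bw_on", "bw_off", "BF", "ADG"]
    for c in required:
        if c not in records.columns:
            raise ValueError(f"derive_rfi requires column {c}")
    out = records.copy()
    out["RFI"] = np.nan
    is_cb = (records["group"] == "CB").to_numpy()
    for sel in (~is_cb, is_cb):
        if not sel.any():
            continue
        X = np.column_stack(
            [
                np.ones(sel.sum()),
                records.loc[sel, "bw_on"],
                records.loc[sel, "bw_off"],
                records.loc[sel, "BF"],
                records.loc[sel, "ADG"],
            ]
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient covariate matrix in RFI regression")
        y = records.loc[sel, "ADFI"].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out.loc[sel, "RFI"] = y - X @ beta
    return out


# ---------------------------------------------------------------------------
# focal-mutation scenario
# ---------------------------------------------------------------------------


@dataclass
class FocalConfig:
    """Configuration of the focal-mutation (MC4R-style) scenario.

    The focal SNP is biallelic with the mutant allele m coded 1; the default
    breed frequencies of m and the equal-across-origins substitution effect
    on ADG mirror a large-effect missense mutation segregating at very
    different frequencies in the three lines. ``on_panel=False`` keeps the
    mutation itself out of the analysis panel so the panel tags it only
    through LD.
    """

    focal_freq: Mapping[str, float] = field(
        default_factory=lambda: {"S": 0.85, "LR": 0.06, "LW": 0.39}
    )
    beta_adg: float = 20.0  # effect of one m allele on ADG, g/d
    n_founders: int = 300
    n_purebred: int = 400
    n_f1: int = 300
    n_crossbred: int = 1200
    litter_size: int = 4
    # a dense panel keeps the per-region polygenic share small relative to
    # the focal mutation (as with a genome-wide chip), and chromosomes of
    # realistic genetic length (2.5 Morgan) let family linkage decay before
    # it masquerades as population LD in the gametic tests
    n_chrom: int = 4
    n_snps_per_chrom: int = 400
    chrom_length_bp: int = 250_000_000
    ld_span_bp: int = 12_000_000
    eps_near: float = 0.03
    eps_far: float = 0.35
    on_panel: bool = False


@dataclass
class FocalScenario:
    geno: PhasedGenotypes
    origins: OriginMatrix
    records: pd.DataFrame
    marker_map: MarkerMap
    ped: pd.DataFrame
    qtl: QTLModel
    config: FocalConfig


def build_focal_scenario(config: FocalConfig | None = None, seed: int = 0) -> FocalScenario:
    """Simulate a population carrying one large-effect focal mutation.

    The focal SNP sits mid-way on chromosome 1 with breed-specific allele
    frequencies; flanking panel SNPs within ``ld_span_bp`` are generated by
    copying the focal allele with a distance-increasing flip probability, so
    they are in strong breed-specific LD with the mutation. The mutation adds
    ``beta_adg`` g/d per m allele to ADG identically for every
    breed-of-origin, on top of the polygenic background.
    """
    cfg = config or FocalConfig()
    freqs = dict(cfg.focal_freq)
    if all(f <= 0.0 or f >= 1.0 for f in freqs.values()):
        raise ValueError("focal mutation must segregate in at least one breed")
    base = MarkerMap.uniform(cfg.n_chrom, cfg.n_snps_per_chrom, cfg.chrom_length_bp)
    # insert the focal SNP mid-chromosome 1
    c1 = base.chrom_indices("1")
    focal_pos = int(cfg.chrom_length_bp // 2 + 1)
    chrom = list(base.chrom)
    pos = list(base.pos)
    insert_at = int(np.searchsorted(base.pos[c1], focal_pos))
    chrom.insert(insert_at, "1")
    pos.insert(insert_at, focal_pos)
    is_focal = [False] * len(pos)
    is_focal[insert_at] = True
    on_panel = [True] * len(pos)
    on_panel[insert_at] = bool(cfg.on_panel)
    ids = [f"snp{i}" for i in range(len(pos))]
    ids[insert_at] = "focal"
    mmap = MarkerMap(chrom, pos, ids, is_focal, on_panel)

    specs = default_breed_specs(cfg.n_founders)
    founders = simulate_founder_breeds(specs, mmap, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))

    fi = mmap.focal_index
    near = np.flatnonzero(
        (mmap.chrom == "1") & (np.abs(mmap.pos - focal_pos) <= cfg.ld_span_bp)
    )
    dist = np.abs(mmap.pos[near] - focal_pos) / cfg.ld_span_bp
    eps = cfg.eps_near + (cfg.eps_far - cfg.eps_near) * dist
    for b in BREEDS:
        haps = founders[b].codes
        f = rng.random(haps.shape[0] * 2).reshape(haps.shape[0], 2) < freqs[b]
        focal_alleles = f.astype(np.int8)
        haps[:, fi, :] = focal_alleles
        flips = rng.random((haps.shape[0], len(near), 2)) < eps[None, :, None]
        haps[:, near, :] = np.where(flips, 1 - focal_alleles[:, None, :], focal_alleles[:, None, :])
        haps[:, fi, :] = focal_alleles

    ped = make_three_way_pedigree(
        cfg.n_founders,
        cfg.n_purebred,
        cfg.n_f1,
        cfg.n_crossbred,
        cfg.litter_size,
        seed=seed + 1,
    )
    geno, origins = gene_drop_pedigree(founders, ped, mmap, seed + 2)

    targets = {"ADG": DEFAULT_TRAIT_TARGETS["ADG"], "BF": DEFAULT_TRAIT_TARGETS["BF"]}
    qtl = QTLModel.sample(len(mmap), targets, np.random.default_rng(seed + 3))
    # keep the focal SNP out of the polygenic background
    keep = qtl.qtl_index != fi
    qtl = QTLModel(
        qtl_index=qtl.qtl_index[keep],
        alpha_pb={t: {b: v[keep] for b, v in d.items()} for t, d in qtl.alpha_pb.items()},
        alpha_cb={t: {b: v[keep] for b, v in d.items()} for t, d in qtl.alpha_cb.items()},
    )
    pedi = ped.set_index("id", drop=False)
    phen = [
        r.id
        for r in ped.itertuples(index=False)
        if (r.group in BREEDS and r.sire != "0") or r.group == "CB"
    ]
    m_dosage = geno.subset_animals(phen).codes[:, fi, :].sum(axis=1).astype(float)
    extra = {"ADG": cfg.beta_adg * (m_dosage - m_dosage.mean())}
    records = simulate_phenotypes(
        geno, origins, ped, qtl, targets, seed + 4, extra_genetic=extra, phenotyped=phen
    )
    return FocalScenario(geno, origins, records, mmap, ped, qtl, cfg)
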