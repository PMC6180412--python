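"""Breed-of-origin assignment: library purity, voting, filters, accuracy."""

import numpy as np
import pytest

from crossboa import boa_assign, simdata
from crossboa.boa_assign import (
    CrossDesign,
    HaplotypeLibrary,
    WindowSpec,
    apply_assignment_filters,
    assign_breed_of_origin,
    assignment_accuracy,
    build_haplotype_library,
)
from crossboa.simdata import MarkerMap, OriginMatrix, PhasedGenotypes

from conftest import tiny_phased, tiny_origins


def _library_from_counts(counts_by_hap, window=("1", 0, 4), purity=0.8):
    """HaplotypeLibrary with one window and prescribed per-breed counts."""
    table = {h: np.asarray(c, dtype=np.int64) for h, c in counts_by_hap.items()}
    assigned = {h: boa_assign._assign_hap(c, purity) for h, c in table.items()}
    return HaplotypeLibrary({window: table}, {window: assigned}, purity, WindowSpec((4,)))


class TestHaplotypeLibrary:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((0, 9, 1), "LR"),  # 90% of copies in LR: assigned
            ((10, 0, 0), "S"),  # private haplotype
            ((3, 1, 1), None),  # 60% < 80%: unassigned
            ((4, 1, 0), "S"),  # exactly at the 80% threshold: assigned
        ],
    )
    def test_purity_threshold(self, counts, expected):
        code = boa_assign._assign_hap(np.asarray(counts), 0.8)
        if expected is None:
            assert code == simdata.ORIGIN_MISSING
        else:
            assert code == simdata.breed_code(expected)

    def test_library_counts_all_purebred_gametes(self):
        # two S animals share one haplotype; LR contributes two copies of its own
        s = tiny_phased([[[1, 1], [0, 0], [1, 1]]] * 2, "s")
        lr = tiny_phased([[[0, 0], [1, 1], [0, 0]]], "lr")
        mm = MarkerMap.uniform(1, 3)
        lib = build_haplotype_library({"S": s, "LR": lr}, mm, WindowSpec((3,), ("not_offset",)))
        key = ("1", 0, 3)
        s_hap = np.array([1, 0, 1], dtype=np.int8).tobytes()
        assert lib.windows[key][s_hap].tolist() == [4, 0, 0]
        assert lib.breed_of(key, s_hap) == simdata.breed_code("S")

    def test_window_longer_than_chromosome_rejected(self):
        s = tiny_phased([[[1, 1], [0, 0]]], "s")
        mm = MarkerMap.uniform(1, 2)
        with pytest.raises(ValueError, match="exceed chromosome"):
            build_haplotype_library({"S": s}, mm, WindowSpec((5,)))

    def test_default_spec_gives_up_to_18_views(self):
        assert WindowSpec().views_per_allele == 18


class TestVoting:
    def test_unanimous_votes_assign(self):
        lib = _library_from_counts({np.array([1, 1, 1, 1], dtype=np.int8).tobytes(): (10, 0, 0)})
        cb = tiny_phased([[[1, 0], [1, 0], [1, 0], [1, 0]]], "cb")
        mm = MarkerMap.uniform(1, 4)
        origins = assign_breed_of_origin(cb, lib, mm)
        assert (origins.labels[0, :, 0] == simdata.breed_code("S")).all()

    def test_majority_of_cast_votes_assigns_maternal_origin(self):
        # three window views of SNPs 0-1: two vote LR, one votes LW -> LR
        lib_windows = {}
        lib_assigned = {}
        for stop, code in zip((2, 3, 4), ("LR", "LR", "LW")):
            h = np.ones(stop, dtype=np.int8).tobytes()
            lib_windows[("1", 0, stop)] = {h: np.zeros(3, dtype=np.int64)}
            lib_assigned[("1", 0, stop)] = {h: simdata.breed_code(code)}
        lib = HaplotypeLibrary(lib_windows, lib_assigned, 0.8, WindowSpec((2,)))
        cb = tiny_phased([[[0, 1]] * 4], "cb")
        origins = assign_breed_of_origin(cb, lib, MarkerMap.uniform(1, 4))
        # SNPs 0-1 covered by all three views: 2 LR vs 1 LW -> LR
        assert origins.labels[0, 0, 1] == simdata.breed_code("LR")
        assert origins.labels[0, 1, 1] == simdata.breed_code("LR")

    def test_tied_votes_leave_origin_missing(self):
        lib_windows = {}
        lib_assigned = {}
        for stop, code in zip((2, 4), ("LR", "LW")):
            h = np.ones(stop, dtype=np.int8).tobytes()
            lib_windows[("1", 0, stop)] = {h: np.zeros(3, dtype=np.int64)}
            lib_assigned[("1", 0, stop)] = {h: simdata.breed_code(code)}
        lib = HaplotypeLibrary(lib_windows, lib_assigned, 0.8, WindowSpec((2,)))
        cb = tiny_phased([[[0, 1]] * 4], "cb")
        origins = assign_breed_of_origin(cb, lib, MarkerMap.uniform(1, 4))
        assert origins.labels[0, 0, 1] == simdata.ORIGIN_MISSING

    def test_cross_design_discards_incompatible_votes(self):
        # a library voting LR is useless on the paternal side of an S-sired cross
        hap = np.ones(4, dtype=np.int8).tobytes()
        lib = _library_from_counts({hap: (0, 10, 0)})
        cb = tiny_phased([[[1, 1]] * 4], "cb")
        origins = assign_breed_of_origin(cb, lib, MarkerMap.uniform(1, 4))
        assert (origins.labels[0, :, 0] == simdata.ORIGIN_MISSING).all()
        assert (origins.labels[0, :, 1] == simdata.breed_code("LR")).all()

    def test_origin_labels_respect_cross_design_on_simulation(self, default_assignment):
        labels = default_assignment["assigned"].labels
        pat = labels[:, :, 0]
        mat = labels[:, :, 1]
        assert np.isin(pat, [simdata.ORIGIN_MISSING, simdata.breed_code("S")]).all()
        assert np.isin(
            mat,
            [simdata.ORIGIN_MISSING, simdata.breed_code("LR"), simdata.breed_code("LW")],
        ).all()


class TestFilters:
    @staticmethod
    def _origins_with_rates(n_animals, rates_pat):
        """Origin matrix where SNP j's paternal assignment rate is rates_pat[j]."""
        m = len(rates_pat)
        lab = np.full((n_animals, m, 2), simdata.breed_code("S"), dtype=np.int8)
        lab[:, :, 1] = simdata.breed_code("LR")
        for j, r in enumerate(rates_pat):
            k = int(round((1 - r) * n_animals))
            lab[:k, j, 0] = simdata.ORIGIN_MISSING
        codes = np.zeros((n_animals, m, 2), dtype=np.int8)
        codes[: n_animals // 2] = 1  # both alleles well represented
        animals = [f"c{i}" for i in range(n_animals)]
        return OriginMatrix(lab, animals), PhasedGenotypes(codes, animals)

    def test_snp_rate_boundary_089_removed_091_kept(self):
        origins, cb = self._origins_with_rates(100, [0.89, 0.91, 1.0])
        res = apply_assignment_filters(origins, cb, snp_rate=0.90, animal_rate=0.0, min_copies=0)
        assert res.kept_snps.tolist() == [1, 2]

    def test_animal_rate_boundary(self):
        lab = np.full((10, 20, 2), simdata.breed_code("S"), dtype=np.int8)
        lab[:, :, 1] = simdata.breed_code("LW")
        # animal 0: 91% of slots assigned -> kept; animal 1: 85% -> removed
        lab[0, :2, 0] = simdata.ORIGIN_MISSING  # 38/40 = 0.95
        lab[1, :6, :] = simdata.ORIGIN_MISSING  # 28/40 = 0.70
        codes = np.zeros((10, 20, 2), dtype=np.int8)
        codes[5:] = 1
        animals = [f"c{i}" for i in range(10)]
        res = apply_assignment_filters(
            OriginMatrix(lab, animals),
            PhasedGenotypes(codes, animals),
            snp_rate=0.0,
            animal_rate=0.90,
            min_copies=0,
        )
        assert "c0" in res.kept_animals and "c1" not in res.kept_animals

    def test_allele_seen_four_times_in_an_origin_removes_snp(self):
        n = 50
        lab = np.full((n, 2, 2), simdata.breed_code("S"), dtype=np.int8)
        lab[:, :, 1] = simdata.breed_code("LR")
        codes = np.zeros((n, 2, 2), dtype=np.int8)
        codes[:25, :, :] = 1
        codes[:, 1, 1] = 0
        codes[:4, 1, 1] = 1  # allele 1 seen only 4x among LR-origin alleles at SNP 1
        animals = [f"c{i}" for i in range(n)]
        res = apply_assignment_filters(
            OriginMatrix(lab, animals),
            PhasedGenotypes(codes, animals),
            snp_rate=0.0,
            animal_rate=0.0,
            min_copies=5,
        )
        assert res.kept_snps.tolist() == [0]

    def test_filters_monotone_in_thresholds(self, default_assignment):
        assigned, cb = default_assignment["assigned"], default_assignment["cb"]
        prev_snps, prev_animals = None, None
        for rate in (0.5, 0.7, 0.9, 0.95):
            res = apply_assignment_filters(assigned, cb, snp_rate=rate, animal_rate=0.5, min_copies=1)
            snps = set(res.kept_snps.tolist())
            if prev_snps is not None:
                assert snps <= prev_snps
            prev_snps = snps
        for mc in (1, 3, 5, 8):
            res = apply_assignment_filters(assigned, cb, snp_rate=0.9, animal_rate=0.9, min_copies=mc)
            snps = set(res.kept_snps.tolist())
            if prev_animals is not None:
                assert snps <= prev_animals
            prev_animals = snps

    def test_all_snps_removed_raises(self):
        origins, cb = self._origins_with_rates(50, [0.1, 0.2])
        with pytest.raises(ValueError, match="all SNPs removed|genome-assigned"):
            apply_assignment_filters(origins, cb, snp_rate=0.99, animal_rate=0.0, min_copies=0)


class TestAccuracy:
    def test_identical_to_truth_gives_unit_accuracy(self, default_sim):
        ped = default_sim["ped"]
        cb = [r.id for r in ped.itertuples(index=False) if r.group == "CB"]
        truth = default_sim["origins"].subset_animals(cb)
        acc = assignment_accuracy(truth, truth)
        assert acc.assigned_fraction == 1.0
        assert acc.accuracy == 1.0

    def test_all_missing_reports_null_accuracy(self):
        lab = np.full((3, 4, 2), simdata.ORIGIN_MISSING, dtype=np.int8)
        o = OriginMatrix(lab, ["a", "b", "c"])
        t = OriginMatrix(np.zeros((3, 4, 2), dtype=np.int8), ["a", "b", "c"])
        acc = assignment_accuracy(o, t)
        assert acc.assigned_fraction == 0.0
        assert acc.accuracy is None

    def test_zero_recombination_private_haplotypes_fully_assigned(self):
        # fully breed-informative founders, no crossovers anywhere
        rng = np.random.default_rng(12)
        mm = MarkerMap.uniform(1, 40, 100_000_000)
        founders = {}
        base = {"S": 0.9, "LR": 0.5, "LW": 0.1}
        for b, p in base.items():
            codes = (rng.random((10, 40, 2)) < p).astype(np.int8)
            codes[:, 0, :] = {"S": 1, "LR": 0, "LW": 1}[b]
            codes[:, 1, :] = {"S": 1, "LR": 1, "LW": 0}[b]
            founders[b] = PhasedGenotypes(codes, [f"{b}_f{i}" for i in range(10)])
        ped = simdata.make_three_way_pedigree(10, 10, 8, 20, 4, seed=13)
        geno, truth = simdata.gene_drop_pedigree(founders, ped, mm, 14, cm_per_mb=0.0)
        pb = {
            b: geno.subset_animals([r.id for r in ped.itertuples(index=False) if r.group == b])
            for b in simdata.BREEDS
        }
        cb_ids = [r.id for r in ped.itertuples(index=False) if r.group == "CB"]
        lib = build_haplotype_library(pb, mm, WindowSpec((40,), ("not_offset",)))
        origins = assign_breed_of_origin(geno.subset_animals(cb_ids), lib, mm)
        acc = assignment_accuracy(origins, truth.subset_animals(cb_ids))
        assert acc.assigned_fraction == 1.0
        assert acc.accuracy == 1.0


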