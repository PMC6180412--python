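"""Shared fixtures: a desk-scale three-way-cross dataset used across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crossboa import boa_assign, relationship, simdata


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale simulated cross with truth labels (seeded)."""
    mm = simdata.MarkerMap.uniform(2, 150, 100_000_000)
    specs = simdata.default_breed_specs(60)
    founders = simdata.simulate_founder_breeds(specs, mm, 1)
    ped = simdata.make_three_way_pedigree(60, 80, 50, 200, 4, seed=2)
    geno, origins = simdata.gene_drop_pedigree(founders, ped, mm, 3)
    return {
        "marker_map": mm,
        "founders": founders,
        "ped": ped,
        "geno": geno,
        "origins": origins,
    }


@pytest.fixture(scope="session")
def default_assignment(default_sim):
    """Haplotype-library assignment of the default simulation's crossbreds."""
    sim = default_sim
    ped = sim["ped"]
    pb = {
        b: sim["geno"].subset_animals(
            [r.id for r in ped.itertuples(index=False) if r.group == b]
        )
        for b in simdata.BREEDS
    }
    cb_ids = [r.id for r in ped.itertuples(index=False) if r.group == "CB"]
    cb = sim["geno"].subset_animals(cb_ids)
    truth = sim["origins"].subset_animals(cb_ids)
    library = boa_assign.build_haplotype_library(pb, sim["marker_map"])
    assigned = boa_assign.assign_breed_of_origin(cb, library, sim["marker_map"])
    return {"pb": pb, "cb": cb, "truth": truth, "library": library, "assigned": assigned}


@pytest.fixture(scope="session")
def phenotyped_sim(default_sim):
    """Default simulation with BF phenotypes and partial GRMs (truth origins)."""
    sim = default_sim
    targets = {"BF": simdata.DEFAULT_TRAIT_TARGETS["BF"]}
    qtl = simdata.QTLModel.sample(len(sim["marker_map"]), targets, 4)
    records = simdata.simulate_phenotypes(
        sim["geno"], sim["origins"], sim["ped"], qtl, targets, 5
    )
    pb = {
        b: sim["geno"].subset_animals(list(records.animal[records.group == b]))
        for b in simdata.BREEDS
    }
    cb_ids = list(records.animal[records.group == "CB"])
    grms = relationship.build_partial_grm_set(
        pb,
        sim["geno"].subset_animals(cb_ids),
        sim["origins"].subset_animals(cb_ids),
    )
    return {"records": records, "grms": grms, "qtl": qtl, **sim}


def tiny_phased(codes, prefix="a"):
    """PhasedGenotypes from a nested list (n_animals, n_snps, 2)."""
    arr = np.asarray(codes, dtype=np.int8)
    return simdata.PhasedGenotypes(arr, [f"{prefix}{i}" for i in range(arr.shape[0])])


def tiny_origins(labels, animals):
    return simdata.OriginMatrix(np.asarray(labels, dtype=np.int8), animals)
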