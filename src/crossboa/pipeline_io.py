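"""File formats, configuration and end-to-end pipeline orchestration.

Stages: simulate -> assign breed-of-origin -> filter -> partial GRMs ->
BOA-model fit -> back-solve SNP effects -> LD blocks / variance mapping ->
focal-locus analysis. Every stage logs the counts it removed; the final
report is machine-readable JSON carrying the configuration and seed, so a
run is reproducible bit for bit.

Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from crossboa import backsolve as bs
from crossboa import boa_assign, focal_locus, ldblocks, relationship, simdata
from crossboa.mixedmodel import BOAModel, genetic_parameters
from crossboa.simdata import BREEDS, MarkerMap, OriginMatrix, PhasedGenotypes

log = logging.getLogger("crossboa")


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def write_phased_vcf(path, geno: PhasedGenotypes, marker_map: MarkerMap) -> None:
    """Minimal phased VCF (GT with '|'); REF/ALT are placeholder A/B."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in marker_map.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.animals)
            + "\n"
        )
        for j in range(len(marker_map)):
            gts = "\t".join(
                f"{geno.codes[i, j, 0]}|{geno.codes[i, j, 1]}" for i in range(geno.n_animals)
            )
            fh.write(
                f"{marker_map.chrom[j]}\t{marker_map.pos[j]}\t{marker_map.ids[j]}"
                f"\tA\tB\t.\t.\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path) -> tuple[PhasedGenotypes, MarkerMap]:
    """Read a phased VCF: biallelic SNPs only, unphased genotypes rejected.

    Multiallelic sites are skipped (the count is logged); positions stay
    1-based.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    chroms: list[str] = []
    pos: list[int] = []
    ids: list[str] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        g = np.asarray(v.genotypes)
        if g.shape[1] < 3 or not np.all(g[:, 2]):
            raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS} ({v.ID})")
        if g[:, :2].min() < 0:
            raise ValueError(f"missing genotype at {v.CHROM}:{v.POS} ({v.ID})")
        rows.append(g[:, :2].astype(np.int8))
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
    if n_multi:
        log.info("read_phased_vcf: skipped %d multiallelic sites", n_multi)
    codes = np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0, 2), np.int8)
    return PhasedGenotypes(codes, samples), MarkerMap(chroms, pos, ids)


def write_pedigree_csv(path, ped: pd.DataFrame) -> None:
    ped[simdata.PED_COLUMNS].to_csv(path, index=False)


def read_pedigree_csv(path) -> pd.DataFrame:
    ped = pd.read_csv(path, dtype=str).fillna("0")
    simdata.validate_pedigree(ped)
    return ped


def write_origin_tsv(path, origins: OriginMatrix, marker_map: MarkerMap) -> None:
    """Long-format origin table: animal, snp, gamete, origin."""
    with Path(path).open("w") as fh:
        fh.write("animal\tsnp\tgamete\torigin\n")
        for i, a in enumerate(origins.animals):
            for j in range(origins.n_snps):
                for g, side in enumerate(("paternal", "maternal")):
                    fh.write(
                        f"{a}\t{marker_map.ids[j]}\t{side}\t"
                        f"{simdata.breed_label(int(origins.labels[i, j, g]))}\n"
                    )


def write_marker_map_tsv(path, marker_map: MarkerMap) -> None:
    marker_map.to_frame().to_csv(path, sep="\t", index=False)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def write_report(results: dict, path) -> dict:
    """JSON report with stable key order and fixed float precision."""
    clean = _round_floats(results)
    with Path(path).open("w") as fh:
        json.dump(clean, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return clean


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Thresholds default to the pipeline's standard settings: 80% library
    purity, 90% per-SNP and per-animal assignment, 5 minimum allele copies
    per origin, P < 0.01 for LD, top-10 blocks, 1-Mb region matching."""

    seed: int = 1
    out_dir: str = "crossboa_out"
    # simulation scale
    n_founders: int = 60
    n_purebred: int = 80
    n_f1: int = 50
    n_crossbred: int = 200
    litter_size: int = 4
    n_chrom: int = 2
    n_snps_per_chrom: int = 150
    chrom_length_bp: int = 100_000_000
    # thresholds
    purity: float = 0.80
    snp_rate: float = 0.90
    animal_rate: float = 0.90
    min_copies: int = 5
    alpha: float = 0.01
    top_k: int = 10
    max_gap_bp: int = 1_000_000
    ridge: float = 1e-6
    # model
    traits: tuple[str, ...] = ("BF",)
    vc_source: str = "reml"  # "reml" | "fixed"
    run_focal: bool = False

    def __post_init__(self) -> None:
        for name, v, lo, hi in (
            ("purity", self.purity, 0.5, 1.0),
            ("snp_rate", self.snp_rate, 0.0, 1.0),
            ("animal_rate", self.animal_rate, 0.0, 1.0),
            ("alpha", self.alpha, 0.0, 1.0),
        ):
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_copies < 0 or self.top_k < 1:
            raise ValueError("min_copies must be >= 0 and top_k >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if "traits" in raw:
            raw["traits"] = tuple(raw["traits"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["traits"] = list(self.traits)
        return d


@dataclass
class SimDataset:
    ped: pd.DataFrame
    geno: PhasedGenotypes
    origins: OriginMatrix
    records: pd.DataFrame
    marker_map: MarkerMap
    qtl: simdata.QTLModel


def simulate_dataset(cfg: RunConfig, targets=None) -> SimDataset:
    """Default three-line cross simulation at the configured scale."""
    mmap = MarkerMap.uniform(cfg.n_chrom, cfg.n_snps_per_chrom, cfg.chrom_length_bp)
    specs = simdata.default_breed_specs(cfg.n_founders)
    founders = simdata.simulate_founder_breeds(specs, mmap, cfg.seed)
    ped = simdata.make_three_way_pedigree(
        cfg.n_founders, cfg.n_purebred, cfg.n_f1, cfg.n_crossbred, cfg.litter_size, cfg.seed + 1
    )
    geno, origins = simdata.gene_drop_pedigree(founders, ped, mmap, cfg.seed + 2)
    if targets is None:
        targets = {t: simdata.DEFAULT_TRAIT_TARGETS[t] for t in cfg.traits}
        if "RFI" in cfg.traits:
            # ADFI construction needs the component traits
            for t in ("BF", "ADG"):
                targets.setdefault(t, simdata.DEFAULT_TRAIT_TARGETS[t])
    qtl = simdata.QTLModel.sample(len(mmap), targets, cfg.seed + 3)
    records = simdata.simulate_phenotypes(geno, origins, ped, qtl, targets, cfg.seed + 4)
    if "RFI" in cfg.traits:
        records = simdata.derive_rfi(records)
    return SimDataset(ped, geno, origins, records, mmap, qtl)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig, write_files: bool = True) -> dict:
    """simulate -> assign -> filter -> GRM -> fit -> back-solve -> blocks.

    Returns the report dict; with ``write_files`` the stage outputs (VCF,
    pedigree/phenotype CSV, origin and effect TSVs, report JSON) land in
    ``cfg.out_dir``.
    """
    report: dict = {"config": cfg.to_dict(), "stages": {}}
    ds = simulate_dataset(cfg)
    log.info("simulated %d animals, %d SNPs", ds.geno.n_animals, len(ds.marker_map))

    pb_ids = {b: [r.id for r in ds.ped.itertuples(index=False) if r.group == b] for b in BREEDS}
    cb_ids = [r.id for r in ds.ped.itertuples(index=False) if r.group == "CB"]
    pb_haps = {b: ds.geno.subset_animals(ids) for b, ids in pb_ids.items()}
    cb_haps = ds.geno.subset_animals(cb_ids)
    cb_truth = ds.origins.subset_animals(cb_ids)

    library = boa_assign.build_haplotype_library(
        pb_haps, ds.marker_map, purity=cfg.purity
    )
    assigned = boa_assign.assign_breed_of_origin(cb_haps, library, ds.marker_map)
    acc = boa_assign.assignment_accuracy(assigned, cb_truth)
    filt = boa_assign.apply_assignment_filters(
        assigned, cb_haps, cfg.snp_rate, cfg.animal_rate, cfg.min_copies
    )
    log.info(
        "assignment: %.3f assigned (accuracy %.3f); filters removed %d+%d SNPs, %d animals",
        acc.assigned_fraction,
        -1.0 if acc.accuracy is None else acc.accuracy,
        filt.removed_snps_rate,
        filt.removed_snps_copies,
        filt.removed_animals,
    )
    report["stages"]["assignment"] = {
        "assigned_fraction": acc.assigned_fraction,
        "accuracy": acc.accuracy,
        "per_origin": acc.per_origin,
        "n_windows": library.n_windows,
        "removed_snps_rate": filt.removed_snps_rate,
        "removed_snps_copies": filt.removed_snps_copies,
        "removed_animals": filt.removed_animals,
        "kept_snps": len(filt.kept_snps),
        "kept_animals": len(filt.kept_animals),
    }

    kept = filt.kept_snps
    kept_map = ds.marker_map.subset(kept)
    phen_pb = {
        b: [a for a in pd.unique(ds.records["animal"]) if a in set(pb_ids[b])] for b in BREEDS
    }
    pb_sub = {b: ds.geno.subset_animals(phen_pb[b]).subset_snps(kept) for b in BREEDS}
    cb_sub = cb_haps.subset_animals(filt.kept_animals).subset_snps(kept)
    orig_sub = filt.origins
    grms = relationship.build_partial_grm_set(pb_sub, cb_sub, orig_sub)
    report["stages"]["grm"] = {
        b: {
            "F": grms[b].freqs.F,
            "mean_diag_pb": float(np.mean(np.diag(grms[b].G_bb))),
            "mean_diag_cb": float(np.mean(np.diag(grms[b].G_cbcb))),
        }
        for b in BREEDS
    }

    records = ds.records[ds.records["animal"].isin(set(sum(phen_pb.values(), [])) | set(filt.kept_animals))]
    report["stages"]["traits"] = {}
    for trait in cfg.traits:
        model = BOAModel(records, trait, grms)
        res = model.fit(method="reml" if cfg.vc_source == "reml" else "blup", ridge=cfg.ridge)
        gp = res.genetic_parameters()
        effects = bs.backsolve_all(grms, res.gebv.pb, res.gebv.cb_partial, ridge=0.0)
        trait_rep: dict = {
            "h2_pb": gp.h2_pb,
            "h2_cb": gp.h2_cb,
            "r_pc": gp.r_pc,
            "reml_converged": res.converged,
            "blocks": {},
            "top_block_matches": {},
        }
        sigma2_a_cb = sum(gp.cb_contributions.values())
        tables: dict[str, pd.DataFrame] = {}
        for b in BREEDS:
            blocks, summary = ldblocks.segment_ld_blocks(
                cb_sub, orig_sub, kept_map, b, cfg.alpha
            )
            Z = pb_sub[b].dosage().astype(float)
            tab = ldblocks.block_variance_explained(
                blocks, Z, effects.effects(b, "crossbred"), sigma2_a=sigma2_a_cb
            )
            tables[b] = tab
            top = ldblocks.top_blocks(tab, cfg.top_k)
            trait_rep["blocks"][b] = {
                "n_blocks": summary.n_blocks,
                "mean_len": summary.mean_len,
                "min_len": summary.min_len,
                "max_len": summary.max_len,
                "top_percent_sum": float(top["percent"].sum()),
            }
        for a, b in (("S", "LR"), ("S", "LW"), ("LR", "LW")):
            matches = ldblocks.match_top_regions(
                tables[a], tables[b], cfg.top_k, cfg.max_gap_bp
            )
            trait_rep["top_block_matches"][f"{a}-{b}"] = len(matches)
        report["stages"]["traits"][trait] = trait_rep

    if cfg.run_focal:
        scenario = simdata.build_focal_scenario(seed=cfg.seed + 100)
        report["stages"]["focal"] = run_focal_analysis(scenario, alpha=cfg.alpha)

    if write_files:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_phased_vcf(out / "genotypes.vcf", ds.geno, ds.marker_map)
        write_pedigree_csv(out / "pedigree.csv", ds.ped)
        ds.records.to_csv(out / "phenotypes.csv", index=False)
        write_marker_map_tsv(out / "marker_map.tsv", ds.marker_map)
        write_origin_tsv(out / "origins_assigned.tsv", filt.origins, kept_map)
        write_report(report, out / "report.json")
    return report


# ---------------------------------------------------------------------------
# focal-locus driver
# ---------------------------------------------------------------------------


def _targets_vc(
    targets: simdata.TraitTargets, grms: relationship.PartialGRMSet
) -> "VarianceComponents":
    """Variance components implied by the generator targets.

    Per-breed crossbred parameters are rescaled by the mean diagonal of the
    breed's crossbred partial relationship block so that the implied genetic
    variance contributions equal genome share x h2_cb x phenotypic variance.
    """
    from crossboa.mixedmodel import POPS, VarianceComponents

    sd2 = targets.sd**2
    genetic: dict[str, np.ndarray] = {}
    for b in BREEDS:
        w_pb = float(np.mean(np.diag(grms[b].G_bb)))
        w_cb = float(np.mean(np.diag(grms[b].G_cbcb)))
        v_pb = targets.h2_pb.get(b, 0.0) * sd2 / max(w_pb, 1e-9)
        v_cb = simdata.CB_GENOME_SHARE[b] * targets.h2_cb * sd2 / max(w_cb, 1e-9)
        r = targets.r_pc.get(b, 0.0)
        genetic[b] = np.array(
            [[v_pb, r * np.sqrt(v_pb * v_cb)], [r * np.sqrt(v_pb * v_cb), v_cb]]
        )
    litter = {p: targets.c2 * sd2 for p in POPS}
    residual = {
        p: max(1.0 - (targets.h2_cb if p == "CB" else targets.h2_pb.get(p, 0.0)) - targets.c2, 0.05)
        * sd2
        for p in POPS
    }
    return VarianceComponents(genetic, litter, residual)


def run_focal_analysis(
    scenario: simdata.FocalScenario,
    alpha: float = 0.01,
    min_copies: int = 5,
    ridge: float = 1e-6,
    vc_source: str = "targets",
) -> dict:
    """Full focal-mutation analysis on a simulated scenario.

    Uses the simulation-truth origin labels, solves the BOA model for ADG,
    back-solves crossbred SNP effects per origin, builds the focal LD
    block, scores haplotypes, and estimates the origin-specific substitution
    effects with the pedigree fixed-regression model.

    ``vc_source="targets"`` (default) solves the mixed model at the variance
    components implied by the generator targets — the substitution analysis
    conditions on variance components obtained elsewhere, as when BLUP runs
    with parameters from a separate estimation step; ``"reml"`` re-estimates
    them from the scenario itself.
    """
    mmap = scenario.marker_map
    focal = mmap.focal_index
    ped = scenario.ped
    pb_ids = {
        b: [r.id for r in ped.itertuples(index=False) if r.group == b and r.sire != "0"]
        for b in BREEDS
    }
    cb_ids = [r.id for r in ped.itertuples(index=False) if r.group == "CB"]

    # analysis SNP set: panel SNPs passing the min-copies rule (truth labels
    # are complete, so the assignment-rate filters cannot remove anything)
    panel = mmap.panel_indices
    cb_haps_panel = scenario.geno.subset_animals(cb_ids).subset_snps(panel)
    cb_orig_panel = scenario.origins.subset_animals(cb_ids).subset_snps(panel)
    filt = boa_assign.apply_assignment_filters(
        cb_orig_panel, cb_haps_panel, snp_rate=0.0, animal_rate=0.0, min_copies=min_copies
    )
    kept_global = panel[filt.kept_snps]

    pb_sub = {b: scenario.geno.subset_animals(pb_ids[b]).subset_snps(kept_global) for b in BREEDS}
    cb_sub = scenario.geno.subset_animals(cb_ids).subset_snps(kept_global)
    orig_sub = scenario.origins.subset_animals(cb_ids).subset_snps(kept_global)
    grms = relationship.build_partial_grm_set(pb_sub, cb_sub, orig_sub)

    model = BOAModel(scenario.records, "ADG", grms)
    if vc_source == "reml":
        res = model.fit(method="reml", ridge=ridge)
    else:
        targets = simdata.DEFAULT_TRAIT_TARGETS["ADG"]
        res = model.fit(vc=_targets_vc(targets, grms), ridge=ridge)
    gp = res.genetic_parameters()
    effects = bs.backsolve_all(grms, res.gebv.pb, res.gebv.cb_partial, ridge=0.0)
    sigma2_a_cb = sum(gp.cb_contributions.values())

    # focal block on kept SNPs + the (off-panel) focal SNP itself
    ana = np.sort(np.unique(np.append(kept_global, focal)))
    sub_map = mmap.subset(ana)
    geno_ana = scenario.geno.subset_animals(cb_ids).subset_snps(ana)
    orig_ana = scenario.origins.subset_animals(cb_ids).subset_snps(ana)
    focal_ana = int(np.flatnonzero(ana == focal)[0])
    block = focal_locus.focal_ld_block(focal_ana, geno_ana, orig_ana, sub_map, alpha)

    # expand kept-coordinate vectors to analysis coordinates
    kept_pos_in_ana = np.flatnonzero(ana != focal)
    eff_ana: dict[str, np.ndarray] = {}
    p_ana: dict[str, np.ndarray] = {}
    for b in BREEDS:
        e = np.zeros(len(ana))
        e[kept_pos_in_ana] = effects.effects(b, "crossbred")
        eff_ana[b] = e
        p = np.full(len(ana), 0.5)
        p[kept_pos_in_ana] = grms[b].freqs.p
        p_ana[b] = p

    records = focal_locus.enumerate_block_haplotypes(
        block.intersection, geno_ana, orig_ana, focal_ana
    )
    for r in records:
        for b in BREEDS:
            r.effects[b] = focal_locus.haplotype_effect(
                r, eff_ana[b], p_ana[b], block.intersection, focal_ana
            )
    hap_sub: dict[str, float | None] = {}
    spread: dict[str, float | None] = {}
    for b in BREEDS:
        means = focal_locus.weighted_allele_means(records, b)
        hap_sub[b] = means.substitution_w_for_m
        effs = [r.effects[b] for r in records if r.counts[simdata.breed_code(b)] > 0]
        spread[b] = float(max(effs) - min(effs)) if effs else None

    # percent of CB genetic variance in the focal region, per origin (one
    # region common to all origins, so the size correction is identical)
    region = np.intersect1d(block.intersection, kept_global)
    kmap = {g: k for k, g in enumerate(kept_global)}
    region_kept = np.array([kmap[g] for g in region])
    region_pct: dict[str, float | None] = {}
    if len(region_kept):
        blk = ldblocks.LDBlock(
            str(mmap.chrom[focal]),
            int(region_kept.min()),
            int(region_kept.max()),
            int(mmap.pos[region.min()]),
            int(mmap.pos[region.max()]),
            "all",
        )
        for b in BREEDS:
            Z = pb_sub[b].dosage().astype(float)
            tab = ldblocks.block_variance_explained(
                [blk], Z, effects.effects(b, "crossbred"),
                sigma2_a=sigma2_a_cb, x_n=float(blk.n_snps),
            )
            region_pct[b] = float(tab["percent"].iloc[0])
    else:
        region_pct = {b: None for b in BREEDS}

    # fixed-regression substitution model on pre-corrected phenotypes
    rec = model.records
    is_cb = (rec["group"] == "CB").to_numpy()
    resid = model.y - model.X @ res.fixed_effects.to_numpy()
    cb_rec = rec.loc[is_cb]
    cb_animals = cb_rec["animal"].tolist()
    gsub = scenario.geno.subset_animals(cb_animals)
    osub = scenario.origins.subset_animals(cb_animals)
    content = {
        b: (
            (gsub.codes[:, focal, :] == 1)
            & (osub.labels[:, focal, :] == simdata.breed_code(b))
        ).sum(axis=1).astype(float)
        for b in BREEDS
    }
    A = relationship.pedigree_numerator_matrix(ped).submatrix(cb_animals)
    sub = focal_locus.fit_focal_snp_model(
        resid[is_cb], content, A, cb_rec["litter"].to_numpy(), sigma2_u=sigma2_a_cb
    )

    def _blockinfo(b):
        snps = block.per_origin[b]
        return {
            "n_snps": int(len(snps)),
            "start_bp": int(sub_map.pos[snps.min()]) if len(snps) else None,
            "stop_bp": int(sub_map.pos[snps.max()]) if len(snps) else None,
        }

    return {
        "focal_snp": str(mmap.ids[focal]),
        "focal_bp": int(mmap.pos[focal]),
        "beta_true": scenario.config.beta_adg,
        "block_per_origin": {b: _blockinfo(b) for b in BREEDS},
        "intersection_n_snps": int(len(block.intersection)),
        "n_haplotypes": len(records),
        "n_excluded_copies": int(sum(r.n_excluded for r in records)),
        "haplotype_substitution_w_for_m": hap_sub,
        "haplotype_effect_spread": spread,
        "region_percent_variance": region_pct,
        "fixed_substitution_m": sub.estimates,
        "fixed_substitution_se": sub.se,
        "h2_cb": gp.h2_cb,
        "reml_converged": res.converged,
    }


def focal_replicate_summary(base_seed: int, n_rep: int = 3, **kwargs) -> dict:
    """Average the focal-analysis quantities over seeded replicates.

    A single scenario realization carries family-structure noise of the same
    order as the origin-frequency mechanism for the weaker origins; the
    averaged quantities expose the mechanism itself. Replicate seeds are
    ``base_seed + 0 .. n_rep-1``.
    """
    per_origin_keys = (
        "haplotype_substitution_w_for_m",
        "haplotype_effect_spread",
        "region_percent_variance",
        "fixed_substitution_m",
        "fixed_substitution_se",
    )
    acc: dict[str, dict[str, list[float]]] = {k: {b: [] for b in BREEDS} for k in per_origin_keys}
    reps = []
    for r in range(n_rep):
        scenario = simdata.build_focal_scenario(seed=base_seed + r)
        rep = run_focal_analysis(scenario, **kwargs)
        reps.append(rep)
        for k in per_origin_keys:
            for b in BREEDS:
                v = rep[k].get(b)
                if v is not None:
                    acc[k][b].append(float(v))
    out = {
        k: {b: (float(np.mean(v)) if v else None) for b, v in d.items()}
        for k, d in acc.items()
    }
    out["n_replicates"] = n_rep
    out["replicates"] = reps
    return out
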