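"""The 4-trait breed-of-origin GBLUP animal model (BOA model).

One phenotype (e.g. back fat) is modelled as four traits — the purebred
performance of each line S, LR, LW, and crossbred performance — in a single
animal model. For each breed b the purebred-trait effect and the b-origin
partial crossbred effect of the animals covary as

    [[sigma2_PB(b), sigma_PB,CB(b)], [sigma_PB,CB(b), sigma2_CB(b)]] (x) G^(b)

with G^(b) the breed-b partial genomic relationship matrix; effects of
different breeds are independent (the model carries no cross-breed genetic
covariance). Common-litter effects are i.i.d. within population and
residual variances are population-specific; residual covariances between
populations are not estimable (the animal sets are disjoint) and fixed at 0.

``BOAModel.fit`` estimates the variance components by average-information
REML (with an EM-flavoured fallback and PSD projection at the boundary) and
then solves Henderson's mixed-model equations for GEBVs; a fitted
``BOAResults`` carries the estimates, their standard errors, the derived
genetic parameters (h2 per population, r_pc per breed) and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from crossboa.relationship import PartialGRMSet, regularize_psd

POPS: tuple[str, ...] = ("S", "LR", "LW", "CB")


# ---------------------------------------------------------------------------
# fixed effects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedEffectSpec:
    """Categorical interactions and covariates per population class.

    Keys are "PB" and "CB"; interactions are tuples of record columns whose
    cross-classification enters as one factor, covariates enter as linear
    regressions (centered within population block).
    """

    categorical: Mapping[str, tuple[tuple[str, ...], ...]] = field(default_factory=dict)
    covariates: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


DEFAULT_FIXED_SPECS: dict[str, FixedEffectSpec] = {
    "BF": FixedEffectSpec(
        categorical={"PB": (("farm", "sex"),), "CB": (("trial",), ("farm", "sex"))},
        covariates={"PB": ("bw_off",), "CB": ("hcw",)},
    ),
    "ADG": FixedEffectSpec(
        categorical={"PB": (("farm", "sex"),), "CB": (("trial",), ("farm", "sex"))},
        covariates={"PB": ("birth_weight",), "CB": ("birth_weight",)},
    ),
    "RFI": FixedEffectSpec(
        categorical={"PB": (("farm", "sex"),), "CB": (("trial",), ("farm", "sex"))},
        covariates={"PB": ("bw_on",), "CB": ("bw_on",)},
    ),
}


def default_fixed_spec(trait: str) -> FixedEffectSpec:
    return DEFAULT_FIXED_SPECS.get(trait, FixedEffectSpec())


@dataclass
class DesignInfo:
    X: np.ndarray
    names: list[str]
    dropped: list[str]


def build_design_matrices(records: pd.DataFrame, spec: FixedEffectSpec) -> DesignInfo:
    """Full-rank fixed-effect design with per-population blocks.

    Each population (S/LR/LW/CB) gets its own intercept, reference-level
    dummies for every categorical interaction of its class, and centered
    covariates. Constant covariates are flagged inestimable and dropped;
    remaining collinear columns are removed by pivoted QR, with the dropped
    names recorded.
    """
    n = len(records)
    pops = records["group"].to_numpy()
    cols: list[np.ndarray] = []
    names: list[str] = []
    dropped: list[str] = []
    for pop in POPS:
        sel = pops == pop
        if not sel.any():
            continue
        pc = "CB" if pop == "CB" else "PB"
        col = np.zeros(n)
        col[sel] = 1.0
        cols.append(col)
        names.append(f"{pop}:intercept")
        for inter in spec.categorical.get(pc, ()):
            missing = [c for c in inter if c not in records.columns]
            if missing:
                dropped.append(f"{pop}:{'*'.join(inter)} (columns absent)")
                continue
            levels = records.loc[sel, list(inter)].astype(str).agg("|".join, axis=1)
            uniq = sorted(levels.unique())
            for lev in uniq[1:]:  # reference = first level
                col = np.zeros(n)
                col[sel] = (levels == lev).to_numpy(dtype=float)
                cols.append(col)
                names.append(f"{pop}:{'*'.join(inter)}={lev}")
        for cov in spec.covariates.get(pc, ()):
            if cov not in records.columns:
                dropped.append(f"{pop}:{cov} (column absent)")
                continue
            x = records.loc[sel, cov].to_numpy(dtype=float)
            if np.std(x) < 1e-12:
                dropped.append(f"{pop}:{cov} (constant)")
                continue
            col = np.zeros(n)
            col[sel] = x - x.mean()
            cols.append(col)
            names.append(f"{pop}:b_{cov}")
    X = np.column_stack(cols) if cols else np.ones((n, 1))
    if not cols:
        names = ["intercept"]
    # pivoted QR to drop numerically dependent columns
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped += [names[j] for j in piv[rank:]]
    return DesignInfo(X[:, keep], [names[j] for j in keep], dropped)


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """Genetic 2x2 per breed, litter and residual variances per population."""

    genetic: dict[str, np.ndarray]
    litter: dict[str, float]
    residual: dict[str, float]
    se: dict[str, float] | None = None
    cov_params: pd.DataFrame | None = None

    def r_pc(self, breed: str) -> float:
        K = self.genetic[breed]
        den = np.sqrt(K[0, 0] * K[1, 1])
        return float(K[0, 1] / den) if den > 0 else float("nan")

    def validate(self) -> None:
        for b, K in self.genetic.items():
            if np.min(np.linalg.eigvalsh(K)) < -1e-8 * max(np.trace(K), 1.0):
                raise ValueError(f"genetic covariance for breed {b} is not PSD")
        for d in (self.litter, self.residual):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"negative variance for {k}")


@dataclass
class GeneticParameters:
    h2_pb: dict[str, float]
    h2_cb: float
    r_pc: dict[str, float]
    cb_contributions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.h2_pb:
            rows.append(
                {
                    "breed": b,
                    "h2_pb": self.h2_pb[b],
                    "h2_cb": self.h2_cb,
                    "r_pc": self.r_pc.get(b, np.nan),
                }
            )
        return pd.DataFrame(rows)


def genetic_parameters(
    vc: VarianceComponents, grms: PartialGRMSet | None = None
) -> GeneticParameters:
    """Heritabilities and purebred-crossbred correlations from the components.

    Crossbred genetic-variance contributions are weighted by the mean
    diagonal of each breed's crossbred partial relationship block (the
    breed's realized genome share); without matrices the weights default
    to 1, i.e. the parameters are read as variance contributions directly.
    """
    h2_pb: dict[str, float] = {}
    r_pc: dict[str, float] = {}
    contributions: dict[str, float] = {}
    for b, K in vc.genetic.items():
        w_pb = float(np.mean(np.diag(grms[b].G_bb))) if grms is not None else 1.0
        w_cb = float(np.mean(np.diag(grms[b].G_cbcb))) if grms is not None else 1.0
        gv = w_pb * K[0, 0]
        den = gv + vc.litter.get(b, 0.0) + vc.residual.get(b, 0.0)
        h2_pb[b] = gv / den if den > 0 else float("nan")
        r_pc[b] = vc.r_pc(b)
        contributions[b] = w_cb * K[1, 1]
    cb_gv = sum(contributions.values())
    den = cb_gv + vc.litter.get("CB", 0.0) + vc.residual.get("CB", 0.0)
    h2_cb = cb_gv / den if den > 0 else float("nan")
    return GeneticParameters(h2_pb, h2_cb, r_pc, contributions)


# ---------------------------------------------------------------------------
# generic AI-REML for linear covariance structures
# ---------------------------------------------------------------------------


@dataclass
class REMLInfo:
    theta: np.ndarray
    names: list[str]
    se: np.ndarray
    cov_params: np.ndarray
    logL: float
    converged: bool
    n_iter: int


def _reml_state(theta, y, X, comps, V_offset=None):
    """Cheap REML state: log-likelihood and factorizations, no full inverse.

    Returns ``(logL, cf, VinvX, cfx, Py)`` or None if V (or X'V^{-1}X) is
    not positive definite. The projection matrix P is only materialized by
    :func:`_reml_projection` for the accepted iterate.
    """
    n = len(y)
    V = np.zeros((n, n)) if V_offset is None else V_offset.copy()
    for t, C in zip(theta, comps):
        if t != 0.0:
            V += t * C
    try:
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vy = linalg.cho_solve(cf, y, check_finite=False)
    VinvX = linalg.cho_solve(cf, X, check_finite=False)
    XtVX = X.T @ VinvX
    try:
        cfx = linalg.cho_factor(XtVX, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    logdetX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
    b = linalg.cho_solve(cfx, X.T @ Vy, check_finite=False)
    Py = Vy - VinvX @ b
    logL = -0.5 * (logdetV + logdetX + float(y @ Py))
    return logL, cf, VinvX, cfx, Py


def _reml_projection(state, n):
    """Materialize P = V^{-1} - V^{-1}X (X'V^{-1}X)^{-1} X'V^{-1}."""
    _, cf, VinvX, cfx, _ = state
    Vinv = linalg.cho_solve(cf, np.eye(n), check_finite=False)
    B = linalg.cho_solve(cfx, VinvX.T, check_finite=False)
    return Vinv - VinvX @ B


def _project_theta(theta, names, genetic_groups, floor):
    """Floor the pure variances and keep each 2x2 genetic block PSD.

    Variances are floored slightly above zero; covariances are clipped so
    the implied correlation stays within +-0.999, which keeps the blocks
    invertible without fighting the Newton step at the boundary.
    """
    th = theta.copy()
    cov_idx = {g[1] for g in genetic_groups}
    for k in range(len(th)):
        if k not in cov_idx:
            th[k] = max(th[k], floor)
    for (i_pb, i_cov, i_cb) in genetic_groups:
        bound = 0.999 * np.sqrt(th[i_pb] * th[i_cb])
        th[i_cov] = float(np.clip(th[i_cov], -bound, bound))
    return th


def reml_linear_cov(
    y: np.ndarray,
    X: np.ndarray,
    comps: Sequence[np.ndarray],
    names: Sequence[str],
    genetic_groups: Sequence[tuple[int, int, int]] = (),
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    V_offset: np.ndarray | None = None,
    disp: bool = False,
) -> REMLInfo:
    """AI-REML for V = V_offset + sum_k theta_k C_k with symmetric C_k.

    ``V_offset`` is a fixed covariance contribution (coefficient 1, not
    estimated), used e.g. to hold a genetic variance at a value taken from
    another model.

    Newton steps use the average-information matrix with step halving
    against the REML log-likelihood; when no AI step improves, variance
    parameters fall back to a damped EM-style multiplicative update.
    Boundary handling projects each breed's 2x2 genetic block to PSD and
    floors pure variances slightly above zero.
    """
    y = np.asarray(y, dtype=float)
    vary = float(np.var(y))
    floor = 1e-8 * max(vary, 1e-12)
    K = len(comps)
    if init is None:
        init = np.full(K, vary / max(K, 1))
        for (i_pb, i_cov, i_cb) in genetic_groups:
            init[i_cov] = 0.0
    theta = _project_theta(np.asarray(init, dtype=float), names, genetic_groups, floor)
    state = _reml_state(theta, y, X, comps, V_offset)
    if state is None:
        raise ValueError("initial variance components give a singular covariance")
    logL = state[0]
    converged = False
    it = 0
    stall = 0
    AI = np.eye(K)
    n = len(y)
    for it in range(1, max_iter + 1):
        Py = state[4]
        P = _reml_projection(state, n)
        W = np.column_stack([C @ Py for C in comps])
        PW = P @ W
        AI = 0.5 * (W.T @ PW)
        score = np.empty(K)
        yPCPy = W.T @ Py  # = Py' C_k Py
        for k, C in enumerate(comps):
            score[k] = -0.5 * (np.sum(P * C) - yPCPy[k])
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(K) * np.trace(AI), score)
        except np.linalg.LinAlgError:
            delta = score / max(np.trace(AI) / K, 1.0)
        accepted = False
        step = 1.0
        for _ in range(10):
            cand = _project_theta(theta + step * delta, names, genetic_groups, floor)
            st = _reml_state(cand, y, X, comps, V_offset)
            if st is not None and st[0] >= logL - 1e-10:
                accepted, theta_new, state_new = True, cand, st
                break
            step *= 0.5
        if not accepted:
            # EM-flavoured multiplicative fallback on the pure variances
            cand = theta.copy()
            cov_idx = {g[1] for g in genetic_groups}
            for k, C in enumerate(comps):
                if k in cov_idx:
                    continue
                tr = np.sum(P * C)
                if tr > 0 and yPCPy[k] > 0:
                    cand[k] = theta[k] * float(np.clip(yPCPy[k] / tr, 0.1, 10.0))
            cand = _project_theta(cand, names, genetic_groups, floor)
            st = _reml_state(cand, y, X, comps, V_offset)
            if st is None or st[0] < logL - 1e-6 * abs(logL):
                break  # no direction improves: stop at current estimates
            theta_new, state_new = cand, st
        change = np.max(np.abs(theta_new - theta) / (np.abs(theta) + 1e-3 * vary))
        dlogL = abs(state_new[0] - logL)
        theta, state, logL = theta_new, state_new, state_new[0]
        if disp:
            print(
                f"iter {it:3d} logL {logL:.4f} change {change:.2e} "
                f"step {step:g} ai={accepted}"
            )
        if change < tol:
            converged = True
            break
        # likelihood stalled (typically a boundary estimate): accept as
        # converged after three consecutive negligible improvements
        if dlogL < 1e-7 * (1.0 + abs(logL)):
            stall += 1
            if stall >= 3:
                converged = True
                break
        else:
            stall = 0
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(AI)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return REMLInfo(theta, list(names), se, cov, logL, converged, it)


# ---------------------------------------------------------------------------
# the BOA model
# ---------------------------------------------------------------------------


@dataclass
class GEBVSet:
    """GEBVs per performance type: purebred own-trait and crossbred partials."""

    pb: dict[str, pd.Series]
    cb_partial: dict[str, pd.Series]

    @property
    def cb_total(self) -> pd.Series:
        total = None
        for s in self.cb_partial.values():
            total = s if total is None else total.add(s)
        return total


class BOAModel:
    """4-trait GBLUP with three breed-specific partial relationship matrices.

    Parameters
    ----------
    records
        One row per phenotyped animal with columns ``animal``, ``group``
        (S/LR/LW/CB), ``litter`` ("0" = no litter) and the trait column,
        plus whatever the fixed-effect spec references.
    trait
        Name of the trait column.
    grms
        :class:`~crossboa.relationship.PartialGRMSet` whose purebred index
        covers the phenotyped purebreds and whose crossbred index covers
        the phenotyped crossbreds.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        trait: str,
        grms: PartialGRMSet,
        fixed_spec: FixedEffectSpec | None = None,
        litter_col: str = "litter",
    ) -> None:
        if trait not in records.columns:
            raise ValueError(f"trait column {trait!r} missing")
        rec = records.loc[records[trait].notna()].reset_index(drop=True)
        if rec.empty:
            raise ValueError("no phenotyped records")
        self.trait = trait
        self.grms = grms
        self.records = rec
        self.y = rec[trait].to_numpy(dtype=float)
        self.n = len(rec)
        self.fixed_spec = fixed_spec or default_fixed_spec(trait)
        self.design = build_design_matrices(rec, self.fixed_spec)
        self.X = self.design.X

        pops = rec["group"].to_numpy()
        self.pops = pops
        animals = rec["animal"].to_numpy()
        self._G_cache: dict[str, np.ndarray] = {}
        self.breed_pos: dict[str, np.ndarray] = {}
        self.breed_slot: dict[str, np.ndarray] = {}
        for b in grms.breeds:
            g = grms[b]
            pb_index = {a: i for i, a in enumerate(g.ids_pb)}
            cb_index = {a: i for i, a in enumerate(g.ids_cb)}
            pos = np.full(self.n, -1, dtype=np.int64)
            slot = np.full(self.n, -1, dtype=np.int8)
            for i, (a, p) in enumerate(zip(animals, pops)):
                if p == b:
                    if a not in pb_index:
                        raise ValueError(f"purebred {a} not in the {b} partial GRM")
                    pos[i] = pb_index[a]
                    slot[i] = 0
                elif p == "CB":
                    if a not in cb_index:
                        raise ValueError(f"crossbred {a} not in the {b} partial GRM")
                    pos[i] = len(g.ids_pb) + cb_index[a]
                    slot[i] = 1
            self.breed_pos[b] = pos
            self.breed_slot[b] = slot

        lit = rec[litter_col].astype(str).to_numpy() if litter_col in rec else np.full(self.n, "0")
        self.litter_labels = np.array(
            [f"{p}|{l}" if l != "0" else "0" for p, l in zip(pops, lit)], dtype=object
        )
        uniq = [l for l in pd.unique(self.litter_labels) if l != "0"]
        self.litters = uniq
        self.litter_index = {l: i for i, l in enumerate(uniq)}
        self.litter_pop = [l.split("|")[0] for l in uniq]
        self.Zl = np.zeros((self.n, len(uniq)))
        for i, l in enumerate(self.litter_labels):
            if l != "0":
                self.Zl[i, self.litter_index[l]] = 1.0

        self.active_pops = [p for p in POPS if (pops == p).any()]
        # breeds participating in the genetic part (need purebred or CB links)
        self.active_breeds = [
            b for b in grms.breeds if (self.breed_slot[b] >= 0).any()
        ]

    @classmethod
    def from_dataframe(
        cls, records: pd.DataFrame, trait: str, grms: PartialGRMSet, **kwargs
    ) -> "BOAModel":
        return cls(records, trait, grms, **kwargs)

    # -- internals ---------------------------------------------------------

    def _assembled(self, b: str) -> np.ndarray:
        if b not in self._G_cache:
            self._G_cache[b] = self.grms[b].assembled()
        return self._G_cache[b]

    def _litter_pops_with_replication(self) -> list[str]:
        out = []
        for p in self.active_pops:
            sizes = pd.Series(self.litter_labels[self.pops == p])
            sizes = sizes[sizes != "0"].value_counts()
            if len(sizes) > 1 and (sizes >= 2).any():
                out.append(p)
        return out

    def reml_components(self) -> tuple[list[np.ndarray], list[str], list[tuple[int, int, int]]]:
        """Dense covariance patterns C_k with V = sum_k theta_k C_k."""
        comps: list[np.ndarray] = []
        names: list[str] = []
        groups: list[tuple[int, int, int]] = []
        n = self.n
        for b in self.active_breeds:
            G = self._assembled(b)
            pos, slot = self.breed_pos[b], self.breed_slot[b]
            rows_pb = np.flatnonzero(slot == 0)
            rows_cb = np.flatnonzero(slot == 1)
            if len(rows_pb) == 0 and len(rows_cb) == 0:
                continue
            C_pb = np.zeros((n, n))
            if len(rows_pb):
                C_pb[np.ix_(rows_pb, rows_pb)] = G[np.ix_(pos[rows_pb], pos[rows_pb])]
            C_cb = np.zeros((n, n))
            if len(rows_cb):
                C_cb[np.ix_(rows_cb, rows_cb)] = G[np.ix_(pos[rows_cb], pos[rows_cb])]
            if len(rows_pb) and len(rows_cb):
                C_cov = np.zeros((n, n))
                blk = G[np.ix_(pos[rows_pb], pos[rows_cb])]
                C_cov[np.ix_(rows_pb, rows_cb)] = blk
                C_cov[np.ix_(rows_cb, rows_pb)] = blk.T
                i0 = len(comps)
                comps += [C_pb, C_cov, C_cb]
                names += [f"g:{b}:pb", f"g:{b}:cov", f"g:{b}:cb"]
                groups.append((i0, i0 + 1, i0 + 2))
            elif len(rows_pb):
                comps.append(C_pb)
                names.append(f"g:{b}:pb")
            else:
                comps.append(C_cb)
                names.append(f"g:{b}:cb")
        for p in self._litter_pops_with_replication():
            sel = (self.pops == p)[:, None] * (self.pops == p)[None, :]
            C = (self.Zl @ self.Zl.T) * sel
            comps.append(C)
            names.append(f"c:{p}")
        for p in self.active_pops:
            C = np.diag((self.pops == p).astype(float))
            comps.append(C)
            names.append(f"e:{p}")
        return comps, names, groups

    # -- estimation --------------------------------------------------------

    def fit(
        self,
        vc: VarianceComponents | None = None,
        method: str | None = None,
        ridge: float = 1e-6,
        compute_gebv: bool = True,
        tol: float = 1e-8,
        max_iter: int = 200,
        init: VarianceComponents | None = None,
    ) -> "BOAResults":
        """Estimate variance components (AI-REML) and/or solve the MME."""
        if method is None:
            method = "blup" if vc is not None else "reml"
        reml_info = None
        if method == "reml":
            vc, reml_info = reml_estimate(self, tol=tol, max_iter=max_iter, init=init)
        elif method != "blup":
            raise ValueError("method must be 'reml' or 'blup'")
        if vc is None:
            raise ValueError("method='blup' requires variance components")
        vc.validate()
        gebv = beta = litter_sol = None
        if compute_gebv:
            gebv, beta, litter_sol = solve_boa_mme(self, vc, ridge=ridge)
        return BOAResults(self, vc, gebv, beta, litter_sol, reml_info)


def reml_estimate(
    model: BOAModel,
    init: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[VarianceComponents, REMLInfo]:
    """AI-REML variance components for a BOA model."""
    comps, names, groups = model.reml_components()
    init_vec = None
    if init is not None:
        init_vec = np.zeros(len(names))
        for k, nm in enumerate(names):
            kind, *rest = nm.split(":")
            if kind == "g":
                b, part = rest
                K = init.genetic[b]
                init_vec[k] = {"pb": K[0, 0], "cov": K[0, 1], "cb": K[1, 1]}[part]
            elif kind == "c":
                init_vec[k] = init.litter.get(rest[0], 0.01 * np.var(model.y))
            else:
                init_vec[k] = init.residual.get(rest[0], 0.5 * np.var(model.y))
    info = reml_linear_cov(
        model.y, model.X, comps, names, groups, init=init_vec, tol=tol, max_iter=max_iter
    )
    genetic: dict[str, np.ndarray] = {}
    litter: dict[str, float] = {}
    residual: dict[str, float] = {}
    se: dict[str, float] = {}
    val = dict(zip(info.names, info.theta))
    se_map = dict(zip(info.names, info.se))
    for b in model.active_breeds:
        K = np.array(
            [
                [val.get(f"g:{b}:pb", 0.0), val.get(f"g:{b}:cov", 0.0)],
                [val.get(f"g:{b}:cov", 0.0), val.get(f"g:{b}:cb", 0.0)],
            ]
        )
        genetic[b] = K
    for p in model.active_pops:
        litter[p] = float(val.get(f"c:{p}", 0.0))
        residual[p] = float(val[f"e:{p}"])
    se.update({k: float(v) for k, v in se_map.items()})
    cov = pd.DataFrame(info.cov_params, index=info.names, columns=info.names)
    return VarianceComponents(genetic, litter, residual, se, cov), info


def solve_boa_mme(
    model: BOAModel, vc: VarianceComponents, ridge: float = 1e-6
) -> tuple[GEBVSet, pd.Series, pd.Series]:
    """Henderson's mixed-model equations for the BOA model.

    Builds the full coefficient matrix (fixed effects, per-breed bivariate
    genetic effects over each partial GRM's animal index, litter effects)
    and solves it densely. Genetic inverses use Kronecker structure
    ``K_b^{-1} (x) G_b^{-1}`` with ``G_b`` blended towards the identity by
    ``ridge`` before inversion.
    """
    n, X = model.n, model.X
    rinv = np.empty(n)
    for p in model.active_pops:
        sigma_e = vc.residual.get(p)
        if sigma_e is None or sigma_e <= 0:
            raise ValueError(f"residual variance for population {p} must be > 0")
        rinv[model.pops == p] = 1.0 / sigma_e

    Zg_parts: list[np.ndarray] = []
    ginv_parts: list[np.ndarray] = []
    breed_offsets: dict[str, tuple[int, int]] = {}
    offset = 0
    for b in model.active_breeds:
        G = regularize_psd(model._assembled(b), ridge)
        N = G.shape[0]
        K = vc.genetic[b].copy()
        jitter = 1e-8 * max(np.trace(K) / 2.0, 1e-12)
        while np.linalg.det(K) <= 0:
            K = K + jitter * np.eye(2)
            jitter *= 10
        Kinv = np.linalg.inv(K)
        try:
            Ginv = linalg.cho_solve(linalg.cho_factor(G, lower=True), np.eye(N))
        except linalg.LinAlgError:
            Ginv = np.linalg.pinv(G)
        ginv_parts.append(np.kron(Kinv, Ginv))
        Z = np.zeros((n, 2 * N))
        pos, slot = model.breed_pos[b], model.breed_slot[b]
        for i in range(n):
            if slot[i] == 0:
                Z[i, pos[i]] = 1.0
            elif slot[i] == 1:
                Z[i, N + pos[i]] = 1.0
        Zg_parts.append(Z)
        breed_offsets[b] = (offset, N)
        offset += 2 * N

    q = len(model.litters)
    dinv = np.zeros(q)
    use_litter = np.zeros(q, dtype=bool)
    for j, p in enumerate(model.litter_pop):
        s = vc.litter.get(p, 0.0)
        if s > 0:
            dinv[j] = 1.0 / s
            use_litter[j] = True
    Zl = model.Zl[:, use_litter]
    ql = int(use_litter.sum())

    W = np.hstack([X] + Zg_parts + ([Zl] if ql else []))
    WR = W * rinv[:, None]
    lhs = W.T @ WR
    p_fixed = X.shape[1]
    at = p_fixed
    for part in ginv_parts:
        sz = part.shape[0]
        lhs[at : at + sz, at : at + sz] += part
        at += sz
    if ql:
        lhs[at : at + ql, at : at + ql] += np.diag(dinv[use_litter])
    rhs = WR.T @ model.y
    try:
        sol = linalg.cho_solve(linalg.cho_factor(lhs, lower=True), rhs)
    except linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)

    beta = pd.Series(sol[:p_fixed], index=model.design.names, name="fixed")
    pb: dict[str, pd.Series] = {}
    cb_partial: dict[str, pd.Series] = {}
    for b in model.active_breeds:
        off, N = breed_offsets[b]
        u = sol[p_fixed + off : p_fixed + off + 2 * N]
        g = model.grms[b]
        n_pb = len(g.ids_pb)
        pb[b] = pd.Series(u[:n_pb], index=g.ids_pb, name=f"gebv_pb_{b}")
        cb_partial[b] = pd.Series(u[N + n_pb : 2 * N], index=g.ids_cb, name=f"gebv_cb_{b}")
    lit_index = [l for l, use in zip(model.litters, use_litter) if use]
    litter_sol = pd.Series(
        sol[p_fixed + offset : p_fixed + offset + ql], index=lit_index, name="litter"
    )
    return GEBVSet(pb, cb_partial), beta, litter_sol


class BOAResults:
    """Fitted BOA model: variance components, GEBVs and derived parameters."""

    def __init__(
        self,
        model: BOAModel,
        vc: VarianceComponents,
        gebv: GEBVSet | None,
        fixed_effects: pd.Series | None,
        litter_effects: pd.Series | None,
        reml_info: REMLInfo | None,
    ) -> None:
        self.model = model
        self.vc = vc
        self.gebv = gebv
        self.fixed_effects = fixed_effects
        self.litter_effects = litter_effects
        self.reml_info = reml_info

    @property
    def converged(self) -> bool | None:
        return self.reml_info.converged if self.reml_info else None

    @property
    def logL(self) -> float | None:
        return self.reml_info.logL if self.reml_info else None

    def genetic_parameters(self, use_grm_scale: bool = True) -> GeneticParameters:
        return genetic_parameters(self.vc, self.model.grms if use_grm_scale else None)

    def vc_table(self) -> pd.DataFrame:
        rows = []
        se = self.vc.se or {}
        for b, K in self.vc.genetic.items():
            rows.append({"component": f"g:{b}:pb", "estimate": K[0, 0], "se": se.get(f"g:{b}:pb")})
            rows.append({"component": f"g:{b}:cov", "estimate": K[0, 1], "se": se.get(f"g:{b}:cov")})
            rows.append({"component": f"g:{b}:cb", "estimate": K[1, 1], "se": se.get(f"g:{b}:cb")})
        for p, v in self.vc.litter.items():
            rows.append({"component": f"c:{p}", "estimate": v, "se": se.get(f"c:{p}")})
        for p, v in self.vc.residual.items():
            rows.append({"component": f"e:{p}", "estimate": v, "se": se.get(f"e:{p}")})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "BOA model (4-trait GBLUP with breed-of-origin partial GRMs)",
            f"trait: {self.model.trait}   records: {self.model.n}   "
            f"fixed effects: {self.model.X.shape[1]}",
        ]
        if self.reml_info is not None:
            lines.append(
                f"REML: logL={self.reml_info.logL:.3f}  iterations={self.reml_info.n_iter}  "
                f"converged={self.reml_info.converged}"
            )
        lines.append("")
        lines.append(self.vc_table().to_string(index=False, float_format=lambda x: f"{x:.4f}"))
        gp = self.genetic_parameters()
        lines.append("")
        lines.append(
            gp.to_frame().to_string(index=False, float_format=lambda x: f"{x:.3f}")
        )
        return "\n".join(lines)
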