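"""Back-solve per-SNP allele effects from GEBVs.

With the VanRaden-style relationship matrix G = W W' / F built from the
centered genotype matrix W, the GEBVs a-hat of the animals in G convert to
SNP-allele effects as

    alpha-hat = F^{-1} W' G^{-1} a-hat

which satisfies W alpha-hat = a-hat exactly whenever G has full rank. For
crossbred performance W is the origin-specific crossbred allele-content
matrix (missing origins contribute zero) and a-hat the origin's partial
GEBVs; for purebred performance W is the purebred dosage matrix of the
breed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from crossboa.relationship import PartialGRM, PartialGRMSet


@dataclass
class SNPEffects:
    """Back-solved allele effects for one breed-of-origin and performance."""

    breed: str
    performance: str  # "purebred" | "crossbred"
    effects: np.ndarray
    used_pseudo_inverse: bool
    reconstruction_residual: float


@dataclass
class SNPEffectSet:
    """Effects per (breed-of-origin, performance type)."""

    entries: dict[tuple[str, str], SNPEffects]

    def __getitem__(self, key: tuple[str, str]) -> SNPEffects:
        return self.entries[key]

    def effects(self, breed: str, performance: str) -> np.ndarray:
        return self.entries[(breed, performance)].effects

    def to_frame(self, marker_ids=None) -> pd.DataFrame:
        frames = []
        for (b, perf), e in self.entries.items():
            df = pd.DataFrame(
                {
                    "snp": marker_ids if marker_ids is not None else np.arange(len(e.effects)),
                    "origin": b,
                    "performance": perf,
                    "effect": e.effects,
                }
            )
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def backsolve_snp_effects(
    W: np.ndarray,
    G: np.ndarray,
    F: float,
    gebv: np.ndarray,
    allow_pseudo_inverse: bool = True,
) -> SNPEffects:
    """alpha-hat = F^{-1} W' G^{-1} a-hat for one genotype matrix.

    Falls back to the Moore-Penrose pseudo-inverse when G is singular (the
    reconstruction residual then reports how much of the GEBV vector the
    marker space failed to span); with ``allow_pseudo_inverse=False`` a
    singular G raises instead.
    """
    W = np.asarray(W, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if W.shape[0] != G.shape[0] or G.shape[0] != G.shape[1] or len(gebv) != W.shape[0]:
        raise ValueError("W, G and gebv dimensions are inconsistent")
    if F <= 0:
        raise ValueError("scaling factor F must be > 0")
    used_pinv = False
    try:
        cf = linalg.cho_factor(G, lower=True)
        Ginv_a = linalg.cho_solve(cf, gebv)
    except linalg.LinAlgError:
        if not allow_pseudo_inverse:
            raise ValueError("G is singular; enable the pseudo-inverse fallback")
        Ginv_a = np.linalg.pinv(G) @ gebv
        used_pinv = True
    alpha = (W.T @ Ginv_a) / F
    resid = float(np.max(np.abs(W @ alpha - gebv))) if len(gebv) else 0.0
    return SNPEffects("", "", alpha, used_pinv, resid)


def reconstruct_gebv(W: np.ndarray, effects: np.ndarray, gebv: np.ndarray):
    """W alpha-hat and its max absolute deviation from the input GEBVs."""
    check = np.asarray(W, dtype=float) @ np.asarray(effects, dtype=float)
    dev = float(np.max(np.abs(check - np.asarray(gebv, dtype=float)))) if len(check) else 0.0
    return check, dev


def backsolve_all(
    grms: PartialGRMSet,
    gebv_pb: dict[str, pd.Series],
    gebv_cb: dict[str, pd.Series],
    ridge: float = 0.0,
    use_full_matrix: bool = False,
) -> SNPEffectSet:
    """Back-solve purebred and crossbred effects for every breed-of-origin.

    By default the purebred conversion inverts the purebred block G_bb and
    the crossbred conversion the crossbred block G_CB,CB(b), matching the
    matrices whose rows generated each GEBV vector; ``use_full_matrix``
    switches both to the assembled (purebred + crossbred) matrix.
    """
    from crossboa.relationship import regularize_psd

    entries: dict[tuple[str, str], SNPEffects] = {}
    for b in grms.breeds:
        g: PartialGRM = grms[b]
        if use_full_matrix:
            W_full = np.vstack([g.W_pb, g.W_cb])
            G = regularize_psd(g.assembled(), ridge)
            if b in gebv_pb and b in gebv_cb:
                a_full = np.concatenate(
                    [
                        gebv_pb[b].reindex(g.ids_pb).to_numpy(),
                        gebv_cb[b].reindex(g.ids_cb).to_numpy(),
                    ]
                )
                e = backsolve_snp_effects(W_full, G, g.freqs.F, a_full)
                entries[(b, "purebred")] = SNPEffects(
                    b, "purebred", e.effects, e.used_pseudo_inverse, e.reconstruction_residual
                )
                entries[(b, "crossbred")] = entries[(b, "purebred")]
            continue
        if b in gebv_pb:
            a = gebv_pb[b].reindex(g.ids_pb).to_numpy()
            G = regularize_psd(g.G_bb, ridge)
            e = backsolve_snp_effects(g.W_pb, G, g.freqs.F, a)
            entries[(b, "purebred")] = SNPEffects(
                b, "purebred", e.effects, e.used_pseudo_inverse, e.reconstruction_residual
            )
        if b in gebv_cb:
            a = gebv_cb[b].reindex(g.ids_cb).to_numpy()
            G = regularize_psd(g.G_cbcb, ridge)
            e = backsolve_snp_effects(g.W_cb, G, g.freqs.F, a)
            entries[(b, "crossbred")] = SNPEffects(
                b, "crossbred", e.effects, e.used_pseudo_inverse, e.reconstruction_residual
            )
    return SNPEffectSet(entries)
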