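"""BOA mixed model: designs, MME vs conditioning, REML, genetic parameters."""

import numpy as np
import pandas as pd
import pytest

from crossboa import relationship as rel
from crossboa import simdata
from crossboa.mixedmodel import (
    BOAModel,
    FixedEffectSpec,
    GeneticParameters,
    VarianceComponents,
    build_design_matrices,
    genetic_parameters,
    reml_linear_cov,
    solve_boa_mme,
)
from crossboa.simdata import BREEDS, OriginMatrix, PhasedGenotypes


def _toy_model(n_pb=5, n_cb=4, m=40, seed=0, litter=True):
    """Small BOA model instance with invertible partial GRMs."""
    rng = np.random.default_rng(seed)
    pb_codes = {b: rng.integers(0, 2, (n_pb, m, 2)).astype(np.int8) for b in BREEDS}
    cb_codes = rng.integers(0, 2, (n_cb, m, 2)).astype(np.int8)
    lab = np.empty((n_cb, m, 2), dtype=np.int8)
    lab[:, :, 0] = simdata.breed_code("S")
    lab[:, :, 1] = rng.choice(
        [simdata.breed_code("LR"), simdata.breed_code("LW")], size=(n_cb, m)
    )
    pb = {b: PhasedGenotypes(pb_codes[b], [f"{b}p{i}" for i in range(n_pb)]) for b in BREEDS}
    cb = PhasedGenotypes(cb_codes, [f"c{i}" for i in range(n_cb)])
    orig = OriginMatrix(lab, cb.animals)
    # external frequencies keep the assembled G nonsingular (data-derived
    # frequencies put the all-ones vector in its null space)
    freqs = {
        b: rel.AlleleFreqEntry(b, np.full(m, 0.5), float(m) * 0.5) for b in BREEDS
    }
    grms = rel.build_partial_grm_set(pb, cb, orig, freqs)
    rows = []
    k = 0
    for b in BREEDS:
        for i in range(n_pb):
            rows.append((f"{b}p{i}", b, f"L{k % 3}" if litter else "0", rng.normal(10, 3)))
            k += 1
    for i in range(n_cb):
        rows.append((f"c{i}", "CB", f"LC{i % 2}" if litter else "0", rng.normal(10, 3)))
    records = pd.DataFrame(rows, columns=["animal", "group", "litter", "BF"])
    vc = VarianceComponents(
        genetic={b: np.array([[1.5, 0.6], [0.6, 1.2]]) for b in BREEDS},
        litter={p: (0.4 if litter else 0.0) for p in ("S", "LR", "LW", "CB")},
        residual={p: 2.0 for p in ("S", "LR", "LW", "CB")},
    )
    return BOAModel(records, "BF", grms, fixed_spec=FixedEffectSpec()), vc


def _direct_conditioning(model, vc):
    """Oracle: GLS fixed effects and E[u | y] from the full joint covariance."""
    n = model.n
    comps, names, _ = model.reml_components()
    theta = []
    for nm in names:
        kind, *rest = nm.split(":")
        if kind == "g":
            b, part = rest
            K = vc.genetic[b]
            theta.append({"pb": K[0, 0], "cov": K[0, 1], "cb": K[1, 1]}[part])
        elif kind == "c":
            theta.append(vc.litter[rest[0]])
        else:
            theta.append(vc.residual[rest[0]])
    V = sum(t * C for t, C in zip(theta, comps))
    Vinv = np.linalg.inv(V)
    X = model.X
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ model.y)
    resid = model.y - X @ beta
    gebv = {}
    for b in model.active_breeds:
        G = model._assembled(b)
        K = vc.genetic[b]
        pos, slot = model.breed_pos[b], model.breed_slot[b]
        N = G.shape[0]
        # Cov(u_b, y) for the full 2N-vector of breed-b effects
        C_uy = np.zeros((2 * N, n))
        for i in range(n):
            if slot[i] == 0:
                C_uy[:N, i] += K[0, 0] * G[:, pos[i]]
                C_uy[N:, i] += K[0, 1] * G[:, pos[i]]
            elif slot[i] == 1:
                C_uy[:N, i] += K[0, 1] * G[:, pos[i]]
                C_uy[N:, i] += K[1, 1] * G[:, pos[i]]
        gebv[b] = C_uy @ Vinv @ resid
    return beta, gebv


class TestDesignMatrices:
    def test_single_level_factors_reduce_to_intercept_and_covariate(self):
        rec = pd.DataFrame(
            {
                "animal": ["a", "b", "c"],
                "group": ["S", "S", "S"],
                "farm": ["f0", "f0", "f0"],
                "sex": ["M", "M", "M"],
                "bw_off": [100.0, 101.0, 99.0],
            }
        )
        spec = FixedEffectSpec(
            categorical={"PB": (("farm", "sex"),)}, covariates={"PB": ("bw_off",)}
        )
        d = build_design_matrices(rec, spec)
        assert d.names == ["S:intercept", "S:b_bw_off"]

    def test_crossed_factors_lose_one_level_to_the_constraint(self):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame(
            {
                "animal": [f"a{i}" for i in range(60)],
                "group": ["S"] * 60,
                "farm": rng.choice(["f0", "f1", "f2"], 60),
                "sex": rng.choice(["M", "F"], 60),
            }
        )
        spec = FixedEffectSpec(categorical={"PB": (("farm", "sex"),)})
        d = build_design_matrices(rec, spec)
        # 6 interaction levels -> 5 dummies after the reference constraint
        assert d.X.shape[1] == 6  # intercept + 5

    def test_constant_covariate_flagged_inestimable(self):
        rec = pd.DataFrame(
            {
                "animal": ["a", "b"],
                "group": ["S", "S"],
                "bw_off": [100.0, 100.0],
            }
        )
        spec = FixedEffectSpec(covariates={"PB": ("bw_off",)})
        d = build_design_matrices(rec, spec)
        assert any("constant" in x for x in d.dropped)


class TestMME:
    def test_matches_direct_conditioning_on_toys(self):
        for seed in (0, 1):
            model, vc = _toy_model(seed=seed)
            gebv, beta, _ = solve_boa_mme(model, vc, ridge=0.0)
            beta_o, gebv_o = _direct_conditioning(model, vc)
            np.testing.assert_allclose(beta.to_numpy(), beta_o, atol=1e-8)
            for b in BREEDS:
                g = model.grms[b]
                N = len(g.ids)
                np.testing.assert_allclose(
                    gebv.pb[b].to_numpy(), gebv_o[b][: len(g.ids_pb)], atol=1e-8
                )
                np.testing.assert_allclose(
                    gebv.cb_partial[b].to_numpy(),
                    gebv_o[b][N + len(g.ids_pb) : 2 * N],
                    atol=1e-8,
                )

    def test_vanishing_variances_shrink_gebvs_to_zero(self):
        model, vc = _toy_model(litter=False)
        tiny = VarianceComponents(
            genetic={b: np.array([[1e-10, 0.0], [0.0, 1e-10]]) for b in BREEDS},
            litter={p: 0.0 for p in ("S", "LR", "LW", "CB")},
            residual={p: 2.0 for p in ("S", "LR", "LW", "CB")},
        )
        gebv, beta, _ = solve_boa_mme(model, tiny, ridge=0.0)
        for b in BREEDS:
            assert np.max(np.abs(gebv.pb[b])) < 1e-6
        # fixed solutions reduce to OLS on the residual covariance
        X = model.X
        ols = np.linalg.lstsq(X, model.y, rcond=None)[0]
        np.testing.assert_allclose(beta.to_numpy(), ols, atol=1e-6)

    def test_crossbred_total_gebv_is_sum_of_partials(self):
        model, vc = _toy_model(seed=3)
        gebv, _, _ = solve_boa_mme(model, vc)
        total = gebv.cb_total
        summed = sum(gebv.cb_partial[b] for b in BREEDS)
        np.testing.assert_array_equal(total.to_numpy(), summed.to_numpy())

    def test_record_order_invariance(self):
        model, vc = _toy_model(seed=4)
        gebv1, _, _ = solve_boa_mme(model, vc)
        shuffled = model.records.sample(frac=1.0, random_state=7).reset_index(drop=True)
        model2 = BOAModel(shuffled, "BF", model.grms, fixed_spec=FixedEffectSpec())
        gebv2, _, _ = solve_boa_mme(model2, vc)
        for b in BREEDS:
            np.testing.assert_allclose(
                gebv1.pb[b].to_numpy(), gebv2.pb[b].to_numpy(), atol=1e-8
            )


class TestREML:
    def test_single_variance_equals_unbiased_sample_variance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(3.0, 2.0, 200)
        info = reml_linear_cov(y, np.ones((200, 1)), [np.eye(200)], ["e"])
        assert info.theta[0] == pytest.approx(np.var(y, ddof=1), rel=1e-6)
        assert info.converged

    def test_zero_genetic_signal_drives_variance_to_boundary(self):
        # strong family structure in G, but phenotypes are pure noise:
        # the genetic variance should land at (numerically) zero
        rng = np.random.default_rng(2)
        fam = np.repeat(np.arange(30), 4)
        G = 0.5 * (fam[:, None] == fam[None, :]) + 0.5 * np.eye(120)
        y = rng.normal(0.0, 1.0, 120)
        info = reml_linear_cov(y, np.ones((120, 1)), [G, np.eye(120)], ["g", "e"])
        assert info.theta[0] < 0.05 * np.var(y)

    def test_two_component_recovery_on_structured_data(self):
        rng = np.random.default_rng(3)
        n = 300
        W = rng.normal(size=(n, 500))
        G = W @ W.T / 500
        L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
        y = L @ rng.normal(size=n) * np.sqrt(0.5) + rng.normal(0, np.sqrt(0.5), n)
        info = reml_linear_cov(y, np.ones((n, 1)), [G, np.eye(n)], ["g", "e"])
        assert info.theta[0] == pytest.approx(0.5, abs=3 * info.se[0])

    def test_fixed_offset_component_is_respected(self):
        rng = np.random.default_rng(4)
        n = 150
        A = np.eye(n)
        y = rng.normal(0, np.sqrt(2.0), n)
        info = reml_linear_cov(
            y, np.ones((n, 1)), [np.eye(n)], ["e"], V_offset=0.5 * A
        )
        # total variance ~2.0, of which 0.5 is held fixed
        assert info.theta[0] == pytest.approx(np.var(y, ddof=1) - 0.5, rel=0.05)


class TestGeneticParameters:
    def test_ratio_arithmetic(self):
        vc = VarianceComponents(
            genetic={"S": np.array([[0.0, 0.0], [0.0, 0.4]])},
            litter={"CB": 0.1},
            residual={"CB": 0.5},
        )
        gp = genetic_parameters(vc)
        assert gp.h2_cb == pytest.approx(0.40)

    def test_perfect_covariance_gives_unit_correlation(self):
        K = np.array([[0.3, np.sqrt(0.3 * 0.6)], [np.sqrt(0.3 * 0.6), 0.6]])
        vc = VarianceComponents(genetic={"S": K}, litter={}, residual={})
        assert vc.r_pc("S") == pytest.approx(1.0)

    def test_printed_component_example(self):
        K = np.array([[0.2, 0.147], [0.147, 0.3]])
        vc = VarianceComponents(genetic={"S": K}, litter={}, residual={})
        assert vc.r_pc("S") == pytest.approx(0.147 / np.sqrt(0.06), abs=1e-6)

    def test_non_psd_genetic_block_rejected(self):
        vc = VarianceComponents(
            genetic={"S": np.array([[0.1, 0.5], [0.5, 0.1]])},
            litter={},
            residual={},
        )
        with pytest.raises(ValueError, match="PSD"):
            vc.validate()


def test_results_summary_mentions_trait_and_parameters(phenotyped_sim):
    model = BOAModel(phenotyped_sim["records"], "BF", phenotyped_sim["grms"])
    vc = VarianceComponents(
        genetic={b: np.array([[2.0, 1.0], [1.0, 2.0]]) for b in BREEDS},
        litter={p: 0.5 for p in ("S", "LR", "LW", "CB")},
        residual={p: 3.0 for p in ("S", "LR", "LW", "CB")},
    )
    res = model.fit(vc=vc)
    text = res.summary()
    assert "BF" in text and "r_pc" in text and "g:S:pb" in text
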