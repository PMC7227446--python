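"""Kernel construction, Gibbs sampler correctness and derived summaries.

The central correctness check compares Gibbs posterior means, with all
variances held fixed, against the direct generalized-least-squares /
mixed-model-equations solution computed by dense linear algebra.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gxeblup as gx
from gxeblup.model import KernelTerm, build_kernels, fit_gibbs, _psd_factor


def _records(n_lines, envs, seed=0, line_sparsity=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_lines):
        for company, year, loc in envs:
            if rng.random() < line_sparsity:
                continue
            rows.append({"line_id": f"L{i:03d}", "company": company,
                         "year": year, "location": loc,
                         "env_id": gx.make_env_id(company, year, loc),
                         "protein": float(rng.normal(10, 1))})
    return pd.DataFrame(rows)


def _random_G(lines, seed=0):
    rng = np.random.default_rng(seed)
    B = rng.normal(size=(len(lines), len(lines) + 5))
    G = B @ B.T / B.shape[1]
    return gx.RelationshipMatrix(lines, G, kind="genomic")


class TestModelSpec:
    def test_named_term_sets(self):
        assert gx.MODEL_TERMS["ELG"] == ("E", "L", "g")
        assert gx.MODEL_TERMS["ELGA-GxE-AxE"] == ("E", "L", "g", "a", "gE", "aE")

    def test_interaction_requires_main(self):
        with pytest.raises(ValueError, match="gE requires g"):
            gx.ModelSpec("custom", terms=("E", "L", "gE"))

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            gx.ModelSpec("ELX")


class TestKernels:
    def test_interaction_entries(self):
        """gE record kernel: G(j,k) within an environment, 0 across."""
        df = _records(3, [("NS", 2015, 1), ("NS", 2016, 1)], seed=1)
        lines = sorted(df["line_id"].unique())
        G = _random_G(lines, seed=2)
        spec = gx.ModelSpec("ELG-GxE")
        kt = {k.name: k for k in build_kernels(df, spec, G=G)}
        K = kt["gE"].record_kernel()
        for i in range(len(df)):
            for j in range(len(df)):
                li, lj = df["line_id"].iloc[i], df["line_id"].iloc[j]
                same_env = df["env_id"].iloc[i] == df["env_id"].iloc[j]
                expected = G.submatrix([li], [lj])[0, 0] if same_env else 0.0
                assert K[i, j] == pytest.approx(expected, abs=1e-9)

    def test_main_kernel_is_zkz(self):
        df = _records(4, [("NS", 2015, 1), ("SJ", 2015, 1)], seed=3)
        lines = list(dict.fromkeys(df["line_id"]))
        G = _random_G(lines, seed=4)
        kt = {k.name: k for k in build_kernels(df, gx.ModelSpec("ELG"), G=G)}
        Z = pd.get_dummies(df["line_id"]).reindex(columns=lines).to_numpy(float)
        assert np.allclose(kt["g"].record_kernel(), Z @ G.values @ Z.T, atol=1e-8)
        # incidence-style kernels: E record kernel is the env indicator product
        E = (df["env_id"].to_numpy()[:, None] == df["env_id"].to_numpy()[None, :])
        assert np.allclose(kt["E"].record_kernel(), E.astype(float), atol=1e-9)

    def test_missing_line_raises(self):
        df = _records(3, [("NS", 2015, 1)])
        G = _random_G(["L000", "L001"])  # L002 absent
        with pytest.raises(KeyError, match="L002"):
            build_kernels(df, gx.ModelSpec("ELG"), G=G)

    def test_missing_matrix_raises(self):
        df = _records(3, [("NS", 2015, 1)])
        with pytest.raises(ValueError, match="genomic"):
            build_kernels(df, gx.ModelSpec("ELG"), G=None)

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_hadamard_psd_property(self, seed):
        """Schur product of PSD record kernels stays PSD."""
        df = _records(5, [("NS", 2015, 1), ("NS", 2015, 2), ("SJ", 2016, 1)],
                      seed=seed, line_sparsity=0.3)
        if df["line_id"].nunique() < 2 or df["env_id"].nunique() < 2:
            return
        lines = list(dict.fromkeys(df["line_id"]))
        G = _random_G(lines, seed=seed + 1)
        kt = {k.name: k for k in build_kernels(df, gx.ModelSpec("ELG-GxE"), G=G)}
        K = kt["gE"].record_kernel()
        w = np.linalg.eigvalsh((K + K.T) / 2)
        assert w.min() >= -1e-8 * max(w.max(), 1e-12)


class TestGibbsOracle:
    def test_effects_match_gls(self):
        """Fixed variances: posterior-mean effects equal the GLS/MME solution.

        Tolerance: per-effect batch-means Monte-Carlo SEs; >=90% of effects
        within 2 SEs and all within 5 SEs (max over ~200 effects of a
        standard normal exceeds 2 routinely).
        """
        df = _records(18, [("NS", 2015, 1), ("NS", 2016, 1), ("SJ", 2015, 1)],
                      seed=7, line_sparsity=0.15)
        lines = list(dict.fromkeys(df["line_id"]))
        G = _random_G(lines, seed=8)
        A = _random_G(lines, seed=9)
        A.kind = "pedigree"
        spec = gx.ModelSpec("ELGA-GxE-AxE", n_iter=8000, burn_in=1000, thin=2, seed=10)
        kern = build_kernels(df, spec, G=G, A=A)
        fixv = {"sigma2_E": 0.5, "sigma2_L": 0.05, "sigma2_g": 0.05,
                "sigma2_a": 0.05, "sigma2_gE": 0.02, "sigma2_aE": 0.02,
                "sigma2_R": 0.1}
        fit = fit_gibbs(df, "protein", spec, kern, fix_variances=fixv,
                        collect_effects=True)

        y = df["protein"].to_numpy()
        n = len(y)
        V = fixv["sigma2_R"] * np.eye(n)
        Ks = {k.name: k.record_kernel() for k in kern}
        for k in kern:
            V += fixv[k.var_symbol] * Ks[k.name]
        Vi = np.linalg.inv(V)
        one = np.ones((n, 1))
        beta = float(((one.T @ Vi @ y) / (one.T @ Vi @ one)).item())
        r = y - beta

        z_all = []
        for k in kern:
            u_gls = fixv[k.var_symbol] * Ks[k.name] @ Vi @ r
            S = fit.effect_samples[k.name]
            nb = 25
            bs = len(S) // nb
            bm = S[: nb * bs].reshape(nb, bs, -1).mean(axis=1)
            mcse = bm.std(axis=0, ddof=1) / np.sqrt(nb)
            z = np.abs(fit.record_effects[k.name] - u_gls) / np.maximum(mcse, 1e-12)
            z_all.append(z)
        z_all = np.concatenate(z_all)
        assert np.mean(z_all < 2.0) >= 0.90
        assert z_all.max() < 5.0
        assert fit.mu == pytest.approx(beta, abs=0.05)

    def test_chain_determinism(self, small_dataset):
        ds = small_dataset
        spec = gx.ModelSpec("ELG", n_iter=400, burn_in=100, thin=2, seed=21)
        f1 = gx.fit_model(ds.phenotypes, "protein", spec, G=ds.G)
        f2 = gx.fit_model(ds.phenotypes, "protein", spec, G=ds.G)
        assert f1.varcomp == f2.varcomp
        assert np.array_equal(f1.beta_mean, f2.beta_mean)

    def test_retained_sample_count(self, small_fit):
        spec = small_fit.spec
        assert small_fit.n_retained == (spec.n_iter - spec.burn_in) // spec.thin
        assert all(v > 0 for v in small_fit.varcomp.values())

    def test_null_genetic_variances(self):
        """Pure-noise phenotypes: genetic posteriors collapse toward zero."""
        truth = dict(sigma2_E=0.5, sigma2_L=0.0, sigma2_g=0.0, sigma2_a=0.0,
                     sigma2_gE=0.0, sigma2_aE=0.0, sigma2_R=0.3)
        cfg = gx.SimulationConfig(
            n_founders=20, n_families=20, n_singleton_crosses=4, n_markers=300,
            n_chromosomes=3, companies={"NS": {2015: 2, 2016: 2}},
            missing_design_fraction=0.2, truth=truth, seed=31)
        ds = gx.simulate_dataset(cfg)
        spec = gx.ModelSpec("ELGA", n_iter=2500, burn_in=600, thin=2, seed=32)
        fit = gx.fit_model(ds.phenotypes, "protein", spec, G=ds.G, A=ds.A)
        assert fit.records.shape[0] >= 250
        assert fit.varcomp["sigma2_g"] < 0.15 * fit.varcomp["sigma2_R"]
        assert fit.varcomp["sigma2_a"] < 0.15 * fit.varcomp["sigma2_R"]

    def test_gxe_term_reduces_residual(self):
        """With true GxE, adding the interaction term lowers sigma2_R."""
        truth = dict(sigma2_E=0.4, sigma2_L=0.02, sigma2_g=0.08, sigma2_a=0.0,
                     sigma2_gE=0.06, sigma2_aE=0.0, sigma2_R=0.10)
        for rep in range(3):
            cfg = gx.SimulationConfig(
                n_founders=20, n_families=24, n_singleton_crosses=4,
                n_markers=300, n_chromosomes=3,
                companies={"NS": {2015: 2, 2016: 2}},
                missing_design_fraction=0.25, truth=truth, seed=40 + rep)
            ds = gx.simulate_dataset(cfg)
            r_main = gx.fit_model(
                ds.phenotypes, "protein",
                gx.ModelSpec("ELG", n_iter=1500, burn_in=400, thin=2, seed=50 + rep),
                G=ds.G).varcomp["sigma2_R"]
            r_int = gx.fit_model(
                ds.phenotypes, "protein",
                gx.ModelSpec("ELG-GxE", n_iter=1500, burn_in=400, thin=2, seed=60 + rep),
                G=ds.G).varcomp["sigma2_R"]
            assert r_int < r_main


class TestPrediction:
    def _fit(self, with_holdout_zero=False):
        df = _records(16, [("NS", 2015, 1), ("NS", 2016, 1)], seed=70)
        lines = list(dict.fromkeys(df["line_id"]))
        extra = ["NEW0", "NEW1"]
        all_lines = lines + extra
        rng = np.random.default_rng(71)
        B = rng.normal(size=(len(all_lines), len(all_lines) + 5))
        Gv = B @ B.T / B.shape[1]
        gi = len(lines)
        Gv[gi, :] = 0.0
        Gv[:, gi] = 0.0
        Gv[gi, gi] = 1.0          # NEW0: unrelated to everything
        Gv[gi + 1, :] = Gv[0, :]  # NEW1: duplicate of L000
        Gv[:, gi + 1] = Gv[:, 0]
        Gv[gi + 1, gi + 1] = Gv[0, 0]
        G = gx.RelationshipMatrix(all_lines, Gv, kind="genomic")
        spec = gx.ModelSpec("ELG", n_iter=2000, burn_in=500, thin=2, seed=72)
        fit = gx.fit_model(df, "protein", spec, G=G)
        fit.G = G
        return fit

    def test_unrelated_new_line_predicts_zero(self):
        fit = self._fit()
        pred = gx.predict_values(fit, [("NEW0", "NS15_1")])
        assert pred[0] == pytest.approx(0.0, abs=1e-8)

    def test_duplicate_line_interpolates(self):
        fit = self._fit()
        pred_new = gx.predict_values(fit, [("NEW1", "NS15_1")])[0]
        ghat = fit.level_effects("g")["L000"]
        assert pred_new == pytest.approx(ghat, abs=1e-6)

    def test_unknown_line_raises(self):
        fit = self._fit()
        with pytest.raises(KeyError):
            gx.predict_values(fit, [("GHOST", "NS15_1")])

    def test_full_mode_adds_environment(self):
        fit = self._fit()
        bv = gx.predict_values(fit, [("NEW1", "NS15_1")], mode="breeding_value")[0]
        full = gx.predict_values(fit, [("NEW1", "NS15_1")], mode="full")[0]
        Ehat = fit.level_effects("E")["NS15_1"]
        assert full == pytest.approx(bv + Ehat, abs=1e-6)

    def test_holdout_blup_oracle(self):
        """Held-out-line predictions match the BLUP from the MME directly."""
        df = _records(17, [("NS", 2015, 1), ("NS", 2016, 1)], seed=80)
        lines = list(dict.fromkeys(df["line_id"]))
        G = _random_G(lines, seed=81)
        train = df[df["line_id"] != "L000"].reset_index(drop=True)
        spec = gx.ModelSpec("ELG", n_iter=12_000, burn_in=2000, thin=2, seed=82)
        kern = build_kernels(train, spec, G=G)
        fixv = {"sigma2_E": 0.4, "sigma2_L": 0.05, "sigma2_g": 0.3, "sigma2_R": 0.1}
        fit = fit_gibbs(train, "protein", spec, kern, fix_variances=fixv)
        fit.G = G
        pred = gx.predict_values(fit, [("L000", "NS15_1")])[0]

        y = train["protein"].to_numpy()
        n = len(y)
        Ks = {k.name: k.record_kernel() for k in kern}
        V = fixv["sigma2_R"] * np.eye(n)
        for k in kern:
            V += fixv[k.var_symbol] * Ks[k.name]
        Vi = np.linalg.inv(V)
        one = np.ones((n, 1))
        beta = float(((one.T @ Vi @ y) / (one.T @ Vi @ one)).item())
        train_lines = list(dict.fromkeys(train["line_id"]))
        Z = pd.get_dummies(train["line_id"]).reindex(columns=train_lines).to_numpy(float)
        cov_new = fixv["sigma2_g"] * G.submatrix(["L000"], train_lines) @ Z.T
        blup = float((cov_new @ Vi @ (y - beta)).item())
        assert pred == pytest.approx(blup, abs=0.05)


class TestDerivedSummaries:
    def test_variance_partition_printed_components(self):
        """Rounded printed components give the printed within-env percents
        to about one percentage point."""
        fit = _FakeFit({"sigma2_E": 0.59, "sigma2_L": 0.03, "sigma2_g": 0.06,
                        "sigma2_R": 0.12})
        pct = gx.variance_partition(fit)
        assert pct["sigma2_L"] == pytest.approx(14.82, abs=1.0)
        assert pct["sigma2_g"] == pytest.approx(28.49, abs=1.0)
        assert pct["sigma2_R"] == pytest.approx(56.69, abs=1.0)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_variance_partition_hand_cases(self):
        pct = gx.variance_partition(_FakeFit(
            {"sigma2_E": 9.9, "sigma2_L": 1.0, "sigma2_g": 1.0, "sigma2_R": 2.0}))
        assert (pct["sigma2_L"], pct["sigma2_g"], pct["sigma2_R"]) == (25, 25, 50)
        only_r = gx.variance_partition(_FakeFit({"sigma2_E": 3.0, "sigma2_R": 0.4}))
        assert only_r["sigma2_R"] == 100.0

    def test_partition_additive(self):
        vr_g, vr_a = gx.partition_additive(0.044, 0.035)
        assert round(vr_g, 3) == 0.557 and round(vr_a, 3) == 0.443
        assert round(gx.partition_additive(1.510, 0.734)[0], 3) == 0.673
        assert gx.partition_additive(0.3, 0.3) == (0.5, 0.5)
        with pytest.raises(ValueError):
            gx.partition_additive(0.0, 0.0)

    def test_partition_sums_to_100_property(self, small_fit):
        assert sum(gx.variance_partition(small_fit).values()) == pytest.approx(100.0, abs=1e-9)


class TestHeritability:
    def _table(self, layout):
        rows = []
        for line, envs in layout.items():
            for k in range(envs):
                rows.append({"line_id": line, "company": "NS", "year": 2015,
                             "location": k + 1, "protein": 10.0})
        return gx.PhenotypeTable(pd.DataFrame(rows))

    def test_balanced_reduces_to_closed_form(self):
        vc = {"sigma2_L": 0.02, "sigma2_g": 0.05, "sigma2_a": 0.03,
              "sigma2_gE": 0.04, "sigma2_aE": 0.02, "sigma2_R": 0.10}
        table = self._table({f"L{i}": 4 for i in range(6)})  # every line in 4 envs
        h = gx.estimate_heritability(_FakeFit(vc), table)
        assert h.mh == pytest.approx(4.0)
        assert h.ph == pytest.approx(4.0)
        sy = 0.02 + 0.05 + 0.03 + 0.04 / 4 + 0.02 / 4 + 0.10 / 4
        assert h.sigma2_y == pytest.approx(sy)
        assert h.h2 == pytest.approx(0.08 / sy)
        assert h.H2 == pytest.approx(0.10 / sy)

    def test_harmonic_mean_unbalanced(self):
        table = self._table({"A": 1, "B": 2, "C": 4})
        h = gx.estimate_heritability(_FakeFit({"sigma2_g": 0.1, "sigma2_R": 0.1}), table)
        assert h.mh == pytest.approx(12 / 7)

    def test_zero_additive(self):
        table = self._table({"A": 2, "B": 2})
        h = gx.estimate_heritability(
            _FakeFit({"sigma2_L": 0.3, "sigma2_R": 0.1}), table)
        assert h.h2 == 0.0 and h.H2 > 0.0

    def test_bounds_on_real_fit(self, small_fit, small_dataset):
        h = gx.estimate_heritability(small_fit, small_dataset.phenotypes)
        assert 0.0 <= h.h2 <= h.H2 <= 1.0
        assert h.mh >= 1.0 and h.ph >= 1.0


class _FakeFit(gx.FitResult):
    """Minimal stand-in carrying only variance components (synthetic)."""

    def __init__(self, varcomp):
        self.varcomp = dict(varcomp)
        self.varcomp_sd = {k: 0.0 for k in varcomp}
        self.records = None
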