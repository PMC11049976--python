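import numpy as np
import pandas as pd
import pytest

from famet.famm import (
    FAStructure,
    FitOptions,
    ModelSpec,
    VarianceComponents,
    fit,
    fitted_site_covariance,
    model_from_name,
    predict_genetic_values,
    reml_loglik,
)
from famet.kernels import GenomicKernel, additive_kernel, identity_kernel, stabilize
from famet.markers import MarkerMatrix
from famet.phenotypes import PhenotypeTable
from famet.simdata import SimConfig, simulate_genetic_values, simulate_markers, simulate_trial

LOG2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# independent oracles


def dense_reml_neg2(y, X, V):
    """Brute-force dense evaluation of -2 l_R (Harville form)."""
    n, p = X.shape
    Vi = np.linalg.inv(V)
    W = X.T @ Vi @ X
    b = np.linalg.solve(W, X.T @ Vi @ y)
    r = y - X @ b
    return (
        (n - p) * LOG2PI
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(W)[1]
        + float(r @ Vi @ r)
    )


def balanced_oneway_reml_neg2(y_groups, sigma_g, sigma_e):
    """Closed-form REML for balanced one-way random effects (textbook sums of squares)."""
    n, r = y_groups.shape
    lam = r * sigma_g + sigma_e
    gm = y_groups.mean()
    ssb = r * np.sum((y_groups.mean(axis=1) - gm) ** 2)
    ssw = np.sum((y_groups - y_groups.mean(axis=1, keepdims=True)) ** 2)
    return (
        (n * r - 1) * LOG2PI
        + n * np.log(lam)
        + n * (r - 1) * np.log(sigma_e)
        + np.log(n * r / lam)
        + ssw / sigma_e
        + ssb / lam
    )


def oneway_table(y_groups, site="S1"):
    n, r = y_groups.shape
    rows = [
        {"genotype": f"g{i}", "site": site, "rep": str(k + 1), "yield": y_groups[i, k]}
        for i in range(n)
        for k in range(r)
    ]
    return PhenotypeTable(pd.DataFrame(rows))


def sim_pheno(n=30, s=3, seed=0, **kw):
    cfg = SimConfig(n_genotypes=n, n_markers=kw.pop("n_markers", 200), n_sites=s,
                    seed=seed, **kw)
    markers = simulate_markers(cfg)
    truth = simulate_genetic_values(markers, cfg)
    return cfg, markers, truth, simulate_trial(truth, cfg)


# ---------------------------------------------------------------------------
# reml_loglik


class TestRemlLoglik:
    def test_balanced_oneway_matches_closed_form(self, rng):
        y = 5.0 + rng.standard_normal((25, 3))
        table = oneway_table(y)
        spec = ModelSpec([identity_kernel([f"g{i}" for i in range(25)])],
                         fa_order=1, include_reps=False)
        for sg, se in [(0.3, 0.8), (1.2, 0.5), (0.01, 2.0)]:
            fa = FAStructure(np.array([[np.sqrt(sg)]]), np.array([0.0]))
            vc = VarianceComponents(np.zeros(1), np.array([se]))
            got = reml_loglik(fa, vc, table, spec)
            want = -0.5 * balanced_oneway_reml_neg2(y, sg, se)
            assert got == pytest.approx(want, abs=1e-8)

    def test_matches_dense_brute_force(self, rng):
        # dense V built element by element from the covariance rules
        _, markers, _, pheno = sim_pheno(n=12, s=3, seed=3, n_markers=120)
        g_a = stabilize(additive_kernel(markers))
        spec = ModelSpec([g_a], fa_order=1, include_reps=True)
        fa = FAStructure(np.array([[0.4], [0.3], [0.5]]), np.array([0.05, 0.1, 0.02]))
        vc = VarianceComponents(np.array([0.02, 0.03, 0.01]), np.array([0.2, 0.15, 0.25]))
        df = pheno.data
        sites = pheno.sites
        gpos = {g: i for i, g in enumerate(g_a.genotype_ids)}
        spos = {s: j for j, s in enumerate(sites)}
        N = len(df)
        sig = fa.site_covariance()
        V = np.zeros((N, N))
        for a in range(N):
            for b in range(N):
                ga_, gb = gpos[df.genotype[a]], gpos[df.genotype[b]]
                sa, sb = spos[df.site[a]], spos[df.site[b]]
                V[a, b] = sig[sa, sb] * g_a.matrix[ga_, gb]
                if sa == sb and df.rep[a] == df.rep[b]:
                    V[a, b] += vc.rep_vars[sa]
                if a == b:
                    V[a, b] += vc.res_vars[sa]
        X = np.zeros((N, len(sites)))
        for a in range(N):
            X[a, spos[df.site[a]]] = 1.0
        want = -0.5 * dense_reml_neg2(df["yield"].to_numpy(), X, V)
        got = reml_loglik(fa, vc, pheno, spec)
        assert got == pytest.approx(want, abs=1e-7)

    def test_scale_equivariance(self):
        _, _, _, pheno = sim_pheno(n=15, s=2, seed=5, n_markers=100)
        ids = pheno.genotypes
        spec = ModelSpec([identity_kernel(ids)], fa_order=1, include_reps=True)
        fa = FAStructure(np.array([[0.4], [0.3]]), np.array([0.05, 0.1]))
        vc = VarianceComponents(np.array([0.02, 0.03]), np.array([0.2, 0.15]))
        base = reml_loglik(fa, vc, pheno, spec)
        c = 3.7
        scaled = PhenotypeTable(pheno.data.assign(**{"yield": pheno.data["yield"] * c}))
        fa_c = FAStructure(fa.loadings * c, fa.specific_vars * c**2)
        vc_c = VarianceComponents(vc.rep_vars * c**2, vc.res_vars * c**2)
        got = reml_loglik(fa_c, vc_c, scaled, spec)
        n_adj = pheno.n_records - 2  # N - rank(X)
        assert -2 * got == pytest.approx(-2 * base + n_adj * np.log(c**2), abs=1e-6)

    def test_degenerate_independence(self, rng):
        _, _, _, pheno = sim_pheno(n=10, s=2, seed=7, n_markers=100)
        ids = pheno.genotypes
        spec = ModelSpec([identity_kernel(ids)], fa_order=1, include_reps=False)
        fa = FAStructure(np.zeros((2, 1)), np.zeros(2))
        res = np.array([0.3, 0.5])
        vc = VarianceComponents(np.zeros(2), res)
        got = reml_loglik(fa, vc, pheno, spec)
        # independent Normal(site mean, sigma2_ej) records, REML form
        df = pheno.data
        sites = pheno.sites
        sj = df["site"].map({s: j for j, s in enumerate(sites)}).to_numpy()
        y = df["yield"].to_numpy()
        N = len(y)
        neg2 = (N - 2) * LOG2PI
        for j in range(2):
            yj = y[sj == j]
            neg2 += len(yj) * np.log(res[j]) + np.log(len(yj) / res[j])
            neg2 += np.sum((yj - yj.mean()) ** 2) / res[j]
        assert got == pytest.approx(-0.5 * neg2, abs=1e-6)

    def test_q_exceeding_sites_rejected(self):
        _, _, _, pheno = sim_pheno(n=10, s=2, seed=1, n_markers=100)
        spec = ModelSpec([identity_kernel(pheno.genotypes)], fa_order=3)
        fa = FAStructure(np.zeros((2, 3)), np.zeros(2))
        vc = VarianceComponents(np.zeros(2), np.array([0.1, 0.1]))
        with pytest.raises(ValueError, match="fa_order"):
            reml_loglik(fa, vc, pheno, spec)


# ---------------------------------------------------------------------------
# fit


class TestFit:
    def test_grid_search_oracle(self, rng):
        # the optimizer must beat a coarse grid over (loading, D, sigma_e)
        _, _, _, pheno = sim_pheno(n=30, s=2, seed=13, n_markers=100)
        ids = pheno.genotypes
        spec = ModelSpec([identity_kernel(ids)], fa_order=1, include_reps=False)
        best_grid = -np.inf
        v = float(pheno.data["yield"].var())
        for l in np.linspace(0.0, np.sqrt(v), 10):
            fa_l = np.full((2, 1), l)
            for d in np.linspace(0.0, v, 10):
                fa = FAStructure(fa_l, np.full(2, d))
                for se in np.linspace(0.05 * v, 1.5 * v, 10):
                    vc = VarianceComponents(np.zeros(2), np.full(2, se))
                    best_grid = max(best_grid, reml_loglik(fa, vc, pheno, spec))
        f = fit(pheno, spec, FitOptions(n_restarts=2))
        assert f.reml_loglik >= best_grid - 1e-6

    def test_single_site_blups_match_henderson_gblup(self, rng):
        # direct mixed-model-equations oracle at the fitted variances
        cfg = SimConfig(n_genotypes=40, n_markers=300, n_sites=1, seed=17,
                        loadings=np.array([[0.35]]), psi=np.array([0.0]))
        markers = simulate_markers(cfg)
        truth = simulate_genetic_values(markers, cfg)
        pheno = simulate_trial(truth, cfg)
        g_a = stabilize(additive_kernel(markers))
        spec = ModelSpec([g_a], fa_order=1, include_reps=False)
        f = fit(pheno, spec, FitOptions(n_restarts=1))
        assert f.converged
        sigma_g = fitted_site_covariance(f)[0, 0]
        sigma_e = f.varcomp.res_vars[0]
        df = pheno.data
        gpos = {g: i for i, g in enumerate(g_a.genotype_ids)}
        N, n = len(df), len(gpos)
        Z = np.zeros((N, n))
        for a, g in enumerate(df["genotype"]):
            Z[a, gpos[g]] = 1.0
        X = np.ones((N, 1))
        Ginv = np.linalg.inv(sigma_g * g_a.matrix + 1e-10 * np.eye(n))
        lhs = np.block([
            [X.T @ X / sigma_e, X.T @ Z / sigma_e],
            [Z.T @ X / sigma_e, Z.T @ Z / sigma_e + Ginv],
        ])
        rhs = np.concatenate([X.T @ df["yield"] / sigma_e, Z.T @ df["yield"] / sigma_e])
        sol = np.linalg.solve(lhs, rhs)
        u_mme = sol[1:]
        u_fit = f.blup_values["total"].to_numpy()[:, 0]
        np.testing.assert_allclose(u_fit, u_mme, rtol=1e-6, atol=1e-8)

    def test_null_signal_recovers_near_zero_covariance(self):
        # zero genetic signal: estimated Sigma should be tiny vs residual
        ratios = []
        for seed in range(10):
            cfg = SimConfig(n_genotypes=150, n_markers=120, n_sites=3, seed=100 + seed,
                            loadings=np.zeros((3, 1)), psi=np.zeros(3), res_var=0.2)
            markers = simulate_markers(cfg)
            truth = simulate_genetic_values(markers, cfg)
            pheno = simulate_trial(truth, cfg)
            spec = model_from_name("FA", genotype_ids=markers.genotype_ids)
            f = fit(pheno, spec, FitOptions(n_restarts=1))
            ratios.append(np.max(np.abs(fitted_site_covariance(f))) / 0.2)
        assert np.mean(ratios) < 0.1

    def test_blup_shrinkage_with_identity_kernel(self, rng):
        y = 4.0 + rng.standard_normal((20, 4)) * 0.5
        table = oneway_table(y)
        spec = ModelSpec([identity_kernel([f"g{i}" for i in range(20)])],
                         fa_order=1, include_reps=False)
        f = fit(table, spec, FitOptions(n_restarts=1))
        b = f.fixed_site_effects.iloc[0]
        centered = y.mean(axis=1) - b
        blup = f.blup_values["total"].to_numpy()[:, 0]
        big = np.abs(centered) > 1e-3
        frac = blup[big] / centered[big]
        assert np.all(frac > -1e-8) and np.all(frac < 1 + 1e-8)

    def test_permutation_equivariance(self, rng):
        _, markers, _, pheno = sim_pheno(n=24, s=2, seed=19, n_markers=150)
        g_a = stabilize(additive_kernel(markers))
        spec = ModelSpec([g_a], fa_order=1)
        f1 = fit(pheno, spec, FitOptions(n_restarts=1))
        # permute genotype labels consistently in phenotypes and kernel
        perm = rng.permutation(len(g_a.genotype_ids))
        relabel = {g_a.genotype_ids[i]: g_a.genotype_ids[perm[i]] for i in range(len(perm))}
        pheno2 = PhenotypeTable(pheno.data.assign(genotype=pheno.data["genotype"].map(relabel)))
        inv = np.argsort(perm)
        k2 = GenomicKernel(g_a.matrix[np.ix_(inv, inv)][np.ix_(perm, perm)],
                           g_a.genotype_ids, kind="additive")
        # relabeled kernel: entry for (relabel[a], relabel[b]) equals original (a, b)
        mat = np.empty_like(g_a.matrix)
        for i in range(len(perm)):
            for j in range(len(perm)):
                mat[perm[i], perm[j]] = g_a.matrix[i, j]
        k2 = GenomicKernel(mat, g_a.genotype_ids, kind="additive")
        f2 = fit(pheno2, ModelSpec([k2], fa_order=1), FitOptions(n_restarts=1))
        assert f2.reml_loglik == pytest.approx(f1.reml_loglik, abs=1e-4)
        b1 = f1.blup_values["total"]
        b2 = f2.blup_values["total"].rename(index={v: k for k, v in relabel.items()})
        np.testing.assert_allclose(
            b2.loc[b1.index].to_numpy(), b1.to_numpy(), atol=2e-3)

    def test_unobserved_cells_get_predictions(self, small_dataset, small_kernels):
        _, _, _, pheno = small_dataset
        g_a, _ = small_kernels
        # drop one genotype entirely from training
        victim = pheno.genotypes[0]
        train = PhenotypeTable(pheno.data[pheno.data["genotype"] != victim].reset_index(drop=True))
        f = fit(train, ModelSpec([g_a], fa_order=1), FitOptions(n_restarts=1))
        pred = predict_genetic_values(f, [victim])
        assert np.all(np.isfinite(pred.to_numpy()))
        assert np.any(pred.to_numpy() != 0)


class TestPredict:
    def test_zero_kernel_row_predicts_zero(self, rng):
        # an unphenotyped genotype with zero covariance to everyone
        n = 15
        a = rng.standard_normal((n, 30))
        mat = np.zeros((n + 1, n + 1))
        mat[:n, :n] = a @ a.T / 30
        mat[n, n] = 1.0  # own diagonal, but zero covariance with observed
        ids = [f"g{i}" for i in range(n)] + ["orphan"]
        k = GenomicKernel(mat, ids, kind="additive")
        rows = [{"genotype": f"g{i}", "site": s, "rep": r, "yield": float(rng.normal(5, 1))}
                for i in range(n) for s in ("S1", "S2") for r in ("1", "2")]
        pheno = PhenotypeTable(pd.DataFrame(rows))
        f = fit(pheno, ModelSpec([k], fa_order=1), FitOptions(n_restarts=1))
        pred = predict_genetic_values(f, ["orphan"])
        np.testing.assert_allclose(pred.to_numpy(), 0.0, atol=1e-10)

    def test_identical_kernel_rows_identical_predictions(self, rng):
        n = 12
        a = rng.standard_normal((n, 40))
        base = a @ a.T / 40
        mat = np.zeros((n + 2, n + 2))
        mat[:n, :n] = base
        # two unphenotyped genotypes with identical covariances to everyone
        cov = base[:, 0] * 0.5
        for extra in (n, n + 1):
            mat[extra, :n] = cov
            mat[:n, extra] = cov
        mat[n:, n:] = np.array([[base[0, 0], base[0, 0] * 0.9],
                                [base[0, 0] * 0.9, base[0, 0]]])
        mat += np.eye(n + 2) * 1.0  # keep PSD
        ids = [f"g{i}" for i in range(n)] + ["twin1", "twin2"]
        k = GenomicKernel(mat, ids, kind="additive")
        rows = [{"genotype": f"g{i}", "site": s, "rep": r, "yield": float(rng.normal(5, 1))}
                for i in range(n) for s in ("S1", "S2") for r in ("1", "2")]
        pheno = PhenotypeTable(pd.DataFrame(rows))
        f = fit(pheno, ModelSpec([k], fa_order=1), FitOptions(n_restarts=1))
        pred = predict_genetic_values(f, ["twin1", "twin2"])
        np.testing.assert_allclose(pred.iloc[0].to_numpy(), pred.iloc[1].to_numpy(), atol=1e-10)

    def test_requested_observed_cells_equal_stored_blups(self, small_dataset, small_kernels):
        _, _, _, pheno = small_dataset
        g_a, _ = small_kernels
        f = fit(pheno, ModelSpec([g_a], fa_order=1), FitOptions(n_restarts=1))
        sub = predict_genetic_values(f, pheno.genotypes[:5], pheno.sites[:2])
        pd.testing.assert_frame_equal(sub, f.blup_values["total"].loc[pheno.genotypes[:5], pheno.sites[:2]])

    def test_unknown_genotype_raises(self, small_dataset, small_kernels):
        _, _, _, pheno = small_dataset
        g_a, _ = small_kernels
        f = fit(pheno, ModelSpec([g_a], fa_order=1), FitOptions(n_restarts=1))
        with pytest.raises(KeyError):
            predict_genetic_values(f, ["not-a-genotype"])


class TestFAStructure:
    def test_site_covariance_arithmetic(self):
        fa = FAStructure(np.array([[1.0], [0.8]]), np.array([0.2, 0.2]))
        np.testing.assert_allclose(fa.site_covariance(), [[1.2, 0.8], [0.8, 0.84]])

    def test_fitted_site_covariance_psd(self, small_dataset, small_kernels):
        _, _, _, pheno = small_dataset
        g_a, _ = small_kernels
        f = fit(pheno, ModelSpec([g_a], fa_order=1), FitOptions(n_restarts=1))
        sig = fitted_site_covariance(f)
        np.testing.assert_allclose(sig, sig.T)
        assert np.linalg.eigvalsh(sig)[0] >= -1e-8

    def test_canonicalization_preserves_covariance(self, rng):
        lam = rng.standard_normal((5, 2))
        fa = FAStructure(lam, rng.uniform(0.01, 0.3, 5))
        canon = fa.canonicalized()
        np.testing.assert_allclose(canon.site_covariance(), fa.site_covariance(), atol=1e-10)
        assert canon.loadings[0, 1] == pytest.approx(0.0, abs=1e-12)
        for k in range(2):
            col = canon.loadings[:, k]
            nz = col[np.abs(col) > 1e-12]
            if nz.size:
                assert nz[0] >= 0
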