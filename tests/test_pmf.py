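import numpy as np
import pandas as pd
import pytest

from soilrisk.core import ValidationError
from soilrisk import pmf
from soilrisk import synthetic


def cosine(a, b):
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def match_factors(F_hat: pd.DataFrame, F_true: pd.DataFrame) -> dict:
    """Greedy cosine matching of recovered factor profiles to truth."""
    out = {}
    used = set()
    for name, truth in F_true.iterrows():
        best, best_cos = None, -1.0
        for k in F_hat.index:
            if k in used:
                continue
            c = cosine(F_hat.loc[k].to_numpy(), truth.to_numpy())
            if c > best_cos:
                best, best_cos = k, c
        used.add(best)
        out[name] = best_cos
    return out


class TestUncertainty:
    def test_below_detection_rule(self):
        df = pd.DataFrame({"Cd": [0.0005], "Pb": [1.0]}, index=["S1"])
        u = pmf.build_uncertainty(df, mdl=0.001, error_fraction=0.1)
        assert u.values.loc["S1", "Cd"] == pytest.approx(5 / 6 * 0.001, rel=1e-12)
        assert u.values.loc["S1", "Cd"] == pytest.approx(8.333e-4, abs=1e-6)

    def test_above_detection_rule(self):
        df = pd.DataFrame({"Cd": [1.0]}, index=["S1"])
        u = pmf.build_uncertainty(df, mdl=0.001, error_fraction=0.1)
        assert u.values.loc["S1", "Cd"] == pytest.approx(
            np.sqrt(0.01 + 1e-6), rel=1e-12)
        assert u.values.loc["S1", "Cd"] == pytest.approx(0.100005, abs=1e-6)

    def test_small_mdl_limit_is_relative_error(self):
        df = pd.DataFrame({"Cd": [2.0]}, index=["S1"])
        u = pmf.build_uncertainty(df, mdl=1e-12, error_fraction=0.1)
        assert u.values.loc["S1", "Cd"] == pytest.approx(0.2, rel=1e-6)

    def test_nonpositive_mdl_rejected(self):
        df = pd.DataFrame({"Cd": [1.0]})
        with pytest.raises(ValidationError, match="MDL"):
            pmf.build_uncertainty(df, mdl=0.0)
        with pytest.raises(ValidationError, match="error_fraction"):
            pmf.build_uncertainty(df, mdl=0.001, error_fraction=1.5)


class TestQValue:
    def test_exact_reconstruction_zero(self):
        rng = np.random.default_rng(0)
        G = rng.uniform(0, 1, (5, 2))
        F = rng.uniform(0, 1, (2, 4))
        X = G @ F
        assert pmf.q_value(X, np.ones_like(X), G, F) == 0.0

    def test_one_by_one_closed_form(self):
        assert pmf.q_value([[2.0]], [[1.0]], [[1.0]], [[1.0]]) == pytest.approx(1.0)

    def test_matches_cell_loop_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.1, 5, (6, 4))
        U = rng.uniform(0.1, 1, (6, 4))
        G = rng.uniform(0, 1, (6, 3))
        F = rng.uniform(0, 1, (3, 4))
        oracle = 0.0
        for i in range(6):
            for j in range(4):
                gf = sum(G[i, k] * F[k, j] for k in range(3))
                oracle += ((X[i, j] - gf) / U[i, j]) ** 2
        assert pmf.q_value(X, U, G, F) == pytest.approx(oracle, rel=1e-12)

    def test_zero_uncertainty_rejected(self):
        with pytest.raises(ValidationError):
            pmf.q_value([[1.0]], [[0.0]], [[1.0]], [[1.0]])


class TestFit:
    def test_noise_free_rank3_recovery(self, lowrank_dataset):
        """Best of 20 restarts on exact rank-3 data: Q/dof < 1e-6 and
        factor profiles recovered to cosine > 0.99."""
        X = lowrank_dataset.table.df
        U = pd.DataFrame(1e-3 * np.maximum(X.to_numpy(), 1.0),
                         index=X.index, columns=X.columns)
        sol = pmf.fit(X, U, n_factors=3, n_runs=20, seed=42)
        assert sol.q_per_dof() < 1e-6
        cosines = match_factors(sol.F, lowrank_dataset.true_F)
        assert all(c > 0.99 for c in cosines.values()), cosines

    def test_q_monotone_descent(self, lowrank_dataset):
        X = lowrank_dataset.table.df
        U = pmf.build_uncertainty(X, mdl=0.001, error_fraction=0.1)
        sol = pmf.fit(X, U, n_factors=3, n_runs=3, seed=1)
        q = np.array(sol.q_history)
        assert (np.diff(q) <= 1e-9 * np.maximum(q[:-1], 1)).all()

    def test_rank1_identifiable_up_to_scale(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(0.5, 2, 8)
        f = rng.uniform(0.5, 2, 5)
        X = np.outer(g, f)
        sol = pmf.fit(X, np.full_like(X, 0.01), n_factors=1, n_runs=5, seed=3)
        assert cosine(sol.F.to_numpy().ravel(), f) > 0.9999
        assert cosine(sol.G.to_numpy().ravel(), g) > 0.9999

    def test_noisy_recovery_r2(self):
        """5 % multiplicative noise: every per-metal r2 >= 0.75."""
        ds = synthetic.generate(n_sites=30, seed=17, noise_cv=0.05,
                                background=None,
                                sources=synthetic.default_sources(30, None))
        U = pmf.build_uncertainty(ds.table, mdl=0.001, error_fraction=0.05)
        sol = pmf.fit(ds.table, U, n_factors=3, n_runs=10, seed=4)
        diag = pmf.diagnostics(sol, ds.table)
        assert (diag["r2"] >= 0.75).all(), diag["r2"].round(3).to_dict()

    def test_factor_scan_elbow_at_three(self, lowrank_dataset):
        """Q(p) is non-increasing in p and collapses at the true rank 3."""
        X = lowrank_dataset.table.df
        U = pd.DataFrame(1e-3 * np.maximum(X.to_numpy(), 1.0),
                         index=X.index, columns=X.columns)
        qs = {p: pmf.fit(X, U, n_factors=p, n_runs=5, seed=5).Q
              for p in (1, 2, 3, 4)}
        assert qs[1] >= qs[2] >= qs[3] * 0.999
        assert qs[4] <= qs[3] * 1.001 + 1e-9  # both numerically zero
        assert qs[3] < 1e-3 * qs[2]  # elbow: rank-3 fits exactly

    def test_permutation_invariance(self, lowrank_dataset):
        X = lowrank_dataset.table.df
        U = pd.DataFrame(0.05 * np.maximum(X.to_numpy(), 0.1),
                         index=X.index, columns=X.columns)
        sol = pmf.fit(X, U, n_factors=3, n_runs=8, seed=6)
        perm_rows = X.sample(frac=1.0, random_state=0)
        perm = perm_rows[list(X.columns[::-1])]
        U2 = U.loc[perm.index, perm.columns]
        sol2 = pmf.fit(perm, U2, n_factors=3, n_runs=8, seed=6)
        assert sol2.Q == pytest.approx(sol.Q, rel=1e-4)

    def test_shape_contracts(self):
        X = np.ones((4, 3))
        with pytest.raises(ValidationError):
            pmf.fit(X, np.ones((4, 3)), n_factors=3)  # p must be < min(n, m)
        with pytest.raises(ValidationError):
            pmf.fit(-X, np.ones((4, 3)), n_factors=2)

    def test_matches_unweighted_nmf_oracle(self, lowrank_dataset):
        """With uniform uncertainties the objective reduces to a plain
        Frobenius NMF; an independent solver should not beat our Q
        meaningfully."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = lowrank_dataset.table.df.to_numpy()
        U = np.ones_like(X)
        sol = pmf.fit(X, U, n_factors=3, n_runs=10, seed=7)
        nmf = sklearn.NMF(n_components=3, init="random", random_state=0,
                          max_iter=2000, tol=1e-10)
        W = nmf.fit_transform(X)
        H = nmf.components_
        q_sklearn = float(((X - W @ H) ** 2).sum())
        assert sol.Q <= q_sklearn + 1e-6 + 0.05 * max(q_sklearn, 1e-12)


class TestDiagnostics:
    def test_perfect_reconstruction(self, lowrank_dataset):
        X = lowrank_dataset.table.df
        U = pd.DataFrame(1e-3 * np.maximum(X.to_numpy(), 1.0),
                         index=X.index, columns=X.columns)
        sol = pmf.fit(X, U, n_factors=3, n_runs=10, seed=8)
        diag = pmf.diagnostics(sol, X)
        assert np.allclose(diag["r2"].to_numpy(), 1.0, atol=1e-6)
        assert diag["frac_abs_resid_le_3"] == 1.0

    def test_percent_contributions_sum_to_100(self, lowrank_dataset):
        X = lowrank_dataset.table.df
        U = pmf.build_uncertainty(X, mdl=0.001, error_fraction=0.1)
        sol = pmf.fit(X, U, n_factors=3, n_runs=5, seed=9)
        pc = pmf.diagnostics(sol, X)["percent_contribution"]
        assert np.allclose(pc.sum(axis=0).to_numpy(), 100.0)

    def test_landfill_factor_carries_cd_and_pb(self, lowrank_dataset):
        """The factor matching the landfill truth is dominated by the
        landfill metals Cd/Pb/As (ground-truth concordance)."""
        X = lowrank_dataset.table.df
        U = pd.DataFrame(1e-3 * np.maximum(X.to_numpy(), 1.0),
                         index=X.index, columns=X.columns)
        sol = pmf.fit(X, U, n_factors=3, n_runs=20, seed=10)
        pc = pmf.diagnostics(sol, X)["percent_contribution"]
        best = {name: max(sol.F.index,
                          key=lambda k: cosine(sol.F.loc[k].to_numpy(),
                                               truth.to_numpy()))
                for name, truth in lowrank_dataset.true_F.iterrows()}
        landfill = best["landfill"]
        assert pc.loc[landfill, "Cd"] > 50.0
        assert pc.loc[landfill, "Pb"] > 50.0
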