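"""MEM spatial eigenfunctions, VIF screening, forward selection, RDA and
the environment/geography variance partition."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import landgen as lg


def line_coords(n=10):
    return pd.DataFrame({"population": [f"p{i}" for i in range(n)],
                         "lon": np.arange(n, dtype=float), "lat": np.zeros(n)})


@pytest.fixture(scope="module")
def line_mem():
    return lg.mem_basis(line_coords(), n_perm=199, seed=0)


class TestMem:
    def test_orthonormal(self, line_mem):
        v = line_mem.eigenvectors
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-10)

    def test_mem1_matches_pcnm_reference(self, line_mem):
        """Frozen oracle: vegan::pcnm(dist(cbind(0:9, 0)))$vectors[, 1].

        The first eigenfunction of a regular transect is the broadest-scale
        sinusoid — antisymmetric about the centre with flattened ends; its
        rank correlation with the coordinate is 0.830 under the standard
        construction.
        """
        reference = np.array([
            -0.2305300191, -0.3878683861, -0.4220612809, -0.3222527013,
            -0.1201311659, 0.1201311659, 0.3222527013, 0.4220612809,
            0.3878683861, 0.2305300191])
        v1 = line_mem.eigenvectors[:, 0]
        sign = np.sign(v1 @ reference)
        np.testing.assert_allclose(sign * v1, reference, atol=1e-9)
        rho = stats.spearmanr(v1, np.arange(10)).statistic
        assert abs(rho) == pytest.approx(0.830303, abs=1e-6)

    def test_morans_i_ordered_with_eigenvalue(self, line_mem):
        assert line_mem.morans_i[0] > line_mem.morans_i[-1]

    def test_eigenvalues_descending_positive(self, line_mem):
        assert np.all(np.diff(line_mem.eigenvalues) <= 1e-12)
        assert np.all(line_mem.eigenvalues > 0)

    def test_significant_functions_positive_autocorrelation(self, line_mem):
        sig = line_mem.significant()
        n = 10
        assert all(line_mem.morans_i[i] > -1 / (n - 1) for i in sig)

    def test_coincident_sites_rejected(self):
        c = line_coords(5)
        c.loc[1, "lon"] = c.loc[0, "lon"]
        with pytest.raises(ValueError, match="jitter"):
            lg.mem_basis(c)


class TestVif:
    def test_orthogonal_columns_all_kept(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(50, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))   # centered orthogonal set
        x = pd.DataFrame(q, columns=["a", "b", "c"])
        kept, table = lg.vif_screen(x)
        assert kept == ["a", "b", "c"]
        np.testing.assert_allclose(table["vif"], 1.0, atol=1e-8)

    def test_duplicated_column_later_dropped(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=40)
        x = pd.DataFrame({"first": v, "other": rng.normal(size=40),
                          "copy": v})
        kept, _ = lg.vif_screen(x)
        assert kept == ["first", "other"]

    def test_matches_leave_one_out_regression_oracle(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
        x["c"] = 0.7 * x["a"] + 0.3 * x["b"] + 0.4 * rng.normal(size=60)
        _, table = lg.vif_screen(x, vif_max=1e9)
        import statsmodels.api as sm
        for j, name in enumerate(["a", "b", "c"]):
            others = [c for c in ["a", "b", "c"] if c != name]
            fit = sm.OLS(x[name], sm.add_constant(x[others])).fit()
            oracle = 1.0 / (1.0 - fit.rsquared)
            assert table.set_index("variable").loc[name, "vif"] == \
                pytest.approx(oracle, abs=1e-10)


class TestRda:
    def _noise_response(self, rng, n=20, m=30):
        return rng.normal(size=(n, m))

    def test_exact_linear_response_r2_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 2))
        y = x @ rng.normal(size=(2, 10))
        res = lg.rda(y, x, n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0)
        assert res.adj_r2 == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_condition_equals_predictors_leaves_nothing(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 2))
        y = x @ rng.normal(size=(2, 10)) + 0.1 * rng.normal(size=(20, 10))
        res = lg.rda(y, x, condition=x, n_perm=0)
        assert res.r2 == pytest.approx(0.0, abs=1e-10)

    def test_adjusted_r2_unbiased_under_null(self):
        rng = np.random.default_rng(2)
        vals = [lg.rda(self._noise_response(rng), rng.normal(size=(20, 3)),
                       n_perm=0).adj_r2 for _ in range(200)]
        assert abs(np.mean(vals)) < 0.015

    def test_adjusted_never_exceeds_r2(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            res = lg.rda(self._noise_response(rng), rng.normal(size=(20, 4)),
                         n_perm=0)
            assert res.adj_r2 <= res.r2 + 1e-12

    def test_permutation_p_uniform_under_null(self):
        rng = np.random.default_rng(4)
        ps = [lg.rda(self._noise_response(rng, n=15, m=10),
                     rng.normal(size=(15, 2)), n_perm=49,
                     seed=int(rng.integers(2**31))).p_value
              for _ in range(200)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_insufficient_dof_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="degrees of freedom"):
            lg.rda(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)), n_perm=0)

    def test_matches_vegan_oracle(self, tmp_path):
        """R vegan as independent oracle for R^2 and adjusted R^2."""
        rng = np.random.default_rng(6)
        y = rng.normal(size=(15, 8))
        x = rng.normal(size=(15, 3))
        y[:, 0] += x[:, 0]
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        np.savetxt(tmp_path / "x.csv", x, delimiter=",")
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            y <- as.matrix(read.csv("{tmp_path}/y.csv", header=FALSE))
            x <- as.matrix(read.csv("{tmp_path}/x.csv", header=FALSE))
            m <- rda(y ~ x)
            r <- RsquareAdj(m)
            cat(r$r.squared, r$adj.r.squared, sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        r2_v, adj_v = map(float, out.stdout.strip().split())
        res = lg.rda(y, x, n_perm=0)
        assert res.r2 == pytest.approx(r2_v, abs=1e-6)    # R prints 7 digits
        assert res.adj_r2 == pytest.approx(adj_v, abs=1e-6)


class TestForwardSelect:
    def test_true_predictor_selected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cand = pd.DataFrame(rng.normal(size=(20, 4)),
                                columns=["X1", "X2", "X3", "X4"])
            y = np.outer(cand["X1"], rng.normal(size=8)) \
                + 0.05 * rng.normal(size=(20, 8))
            sel = lg.forward_select(y, cand, alpha=0.05, n_perm=199, seed=seed)
            hits += sel[:1] == ["X1"]
        assert hits >= 9

    def test_noise_candidates_rarely_selected(self):
        any_selected = 0
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            cand = pd.DataFrame(rng.normal(size=(15, 3)),
                                columns=["a", "b", "c"])
            y = rng.normal(size=(15, 6))
            sel = lg.forward_select(y, cand, alpha=0.05, n_perm=99, seed=seed)
            any_selected += len(sel) > 0
        # type-I error per dataset <= ~alpha (selection tests the best of 3,
        # so allow alpha plus 2 binomial SE around 0.1)
        assert any_selected / 60 < 0.25

    def test_duplicate_candidate_selected_once(self):
        rng = np.random.default_rng(7)
        x1 = rng.normal(size=20)
        cand = pd.DataFrame({"X1": x1, "X1copy": x1.copy(),
                             "Z": rng.normal(size=20)})
        y = np.outer(x1, rng.normal(size=6)) + 0.05 * rng.normal(size=(20, 6))
        sel = lg.forward_select(y, cand, alpha=0.05, n_perm=199, seed=0)
        assert len({"X1", "X1copy"} & set(sel)) == 1


class TestPartition:
    def test_recovers_constructed_fractions(self):
        rng = np.random.default_rng(0)
        n, m = 60, 40
        e = rng.normal(size=(n, 1))
        g = rng.normal(size=(n, 1))
        y = e @ rng.normal(size=(1, m)) + g @ rng.normal(size=(1, m)) \
            + 1.0 * rng.normal(size=(n, m))
        part = lg.variance_partition(y, pd.DataFrame({"E": e[:, 0]}),
                                     pd.DataFrame({"G": g[:, 0]}),
                                     n_perm=99, seed=1)
        # E and G are independent: confounded ~ 0, individual fractions equal
        # the marginal adjusted R^2
        assert abs(part.confounded) < 0.05
        assert part.env_given_geo == pytest.approx(part.env_total, abs=0.05)
        assert part.geo_given_env == pytest.approx(part.geo_total, abs=0.05)

    def test_collinear_sets_load_confounded(self):
        rng = np.random.default_rng(1)
        n, m = 50, 30
        shared = rng.normal(size=(n, 1))
        y = shared @ rng.normal(size=(1, m)) + 0.5 * rng.normal(size=(n, m))
        e = pd.DataFrame({"E": shared[:, 0] + 1e-6 * rng.normal(size=n)})
        g = pd.DataFrame({"G": shared[:, 0] + 1e-6 * rng.normal(size=n)})
        part = lg.variance_partition(y, e, g, n_perm=0, seed=0)
        assert part.env_given_geo == pytest.approx(0.0, abs=0.02)
        assert part.geo_given_env == pytest.approx(0.0, abs=0.02)
        assert part.confounded > 0.2

    def test_ledger_identity(self, bench_freqs, bench_data):
        mem = lg.mem_basis(bench_data["coords"], n_perm=49, seed=0)
        y = np.nan_to_num(bench_freqs.freq - np.nanmean(bench_freqs.freq, axis=0))
        env = bench_data["env"][["E1", "N1", "N2"]]
        part = lg.variance_partition(y, env, mem.frame(3), n_perm=49, seed=0)
        assert part.env_given_geo + part.geo_given_env + part.confounded == \
            pytest.approx(part.total_explained, abs=1e-10)
        assert part.total_explained + part.total_unexplained == \
            pytest.approx(1.0, abs=1e-12)

    def test_table_structure_confounded_untested(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(30, 10))
        part = lg.variance_partition(y, pd.DataFrame({"E": rng.normal(size=30)}),
                                     pd.DataFrame({"G": rng.normal(size=30)}),
                                     n_perm=49, seed=0)
        frame = part.to_frame()
        assert len(frame) == 7
        conf = frame.set_index("fraction").loc["Confounded (env. + geo.)"]
        assert pd.isna(conf["p_value"])

    def test_overlapping_names_rejected(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(20, 5))
        df = pd.DataFrame({"E": rng.normal(size=20)})
        with pytest.raises(ValueError, match="shared"):
            lg.variance_partition(y, df, df, n_perm=0)
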