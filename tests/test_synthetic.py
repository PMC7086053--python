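"""Synthetic landscape generator: construction, determinism, signal content."""

import numpy as np
import pytest
from scipy import stats

import landgen as lg


def simple_config(seed=0, **kw):
    defaults = dict(n_lon=8, n_lat=4,
                    variables=(lg.EnvVariable("E1", kind="linear", axis="lon"),),
                    n_pops=6, samples_per_pop=8, seed=seed)
    defaults.update(kw)
    return lg.LandscapeConfig(**defaults)


class TestLandscape:
    def test_linear_gradient_tracks_longitude(self):
        grid, _, _ = lg.generate_landscape(simple_config())
        r = np.corrcoef(grid.table["E1"], grid.table["lon"])[0, 1]
        assert r == pytest.approx(1.0)

    def test_zero_amplitude_noise_is_constant(self):
        cfg = simple_config(variables=(
            lg.EnvVariable("N", kind="noise", amplitude=0.0, offset=3.0),))
        grid, _, _ = lg.generate_landscape(cfg)
        assert np.all(grid.table["N"] == 3.0)

    def test_same_seed_identical_grids(self):
        cfg = simple_config(seed=5, variables=(
            lg.EnvVariable("N", kind="noise", amplitude=1.0, length_scale=2.0),))
        g1, c1, e1 = lg.generate_landscape(cfg)
        g2, c2, e2 = lg.generate_landscape(cfg)
        assert g1.table.equals(g2.table)
        assert e1.equals(e2)

    def test_population_env_equals_grid_values(self):
        grid, coords, env = lg.generate_landscape(simple_config())
        at_cells = grid.table.set_index("cell").loc[coords["cell"], "E1"].to_numpy()
        np.testing.assert_array_equal(env["E1"].to_numpy(), at_cells)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            lg.LandscapeConfig(n_lon=1, n_lat=4)
        with pytest.raises(ValueError):
            lg.LandscapeConfig(n_pops=2, pop_cells=(3, 3))


class TestAlleleFrequencies:
    def test_strong_cline_is_monotone_in_driver(self):
        cfg = simple_config(n_pops=8)
        _, coords, env = lg.generate_landscape(cfg)
        arch = lg.GeneticArchitecture(n_neutral=0, n_adaptive=5, beta=3.0,
                                      drivers="E1", missing_rate=0.0)
        truth = lg.simulate_allele_frequencies(arch, env, coords, seed=1)
        for col in truth.columns[1:]:
            rho = stats.spearmanr(truth[col], env["E1"]).statistic
            assert abs(rho) > 0.9

    def test_null_beta_makes_adaptive_and_neutral_exchangeable(self):
        """beta=0: per-locus frequency-environment correlations for 'adaptive'
        and neutral loci come from the same distribution (KS over 20 seeds)."""
        cfg = simple_config(n_pops=10)
        _, coords, env = lg.generate_landscape(cfg)
        arch = lg.GeneticArchitecture(n_neutral=30, n_adaptive=30, beta=0.0,
                                      neutral_sd=0.5, neutral_length=0.0,
                                      missing_rate=0.0)
        r_neu, r_ada = [], []
        for seed in range(20):
            truth = lg.simulate_allele_frequencies(arch, env, coords, seed=seed)
            p = truth.drop(columns="population").to_numpy()
            e = env["E1"].to_numpy()
            r = [stats.spearmanr(p[:, l], e).statistic for l in range(p.shape[1])]
            r_neu.extend(r[:30])
            r_ada.extend(r[30:])
        assert stats.ks_2samp(r_neu, r_ada).pvalue > 0.01

    def test_zero_autocorrelation_gives_independent_drift(self):
        """length -> 0: between-population correlation of centered frequency
        deviations matches the independent-field expectation -1/(k-1)."""
        cfg = simple_config(n_pops=8)
        _, coords, env = lg.generate_landscape(cfg)
        arch = lg.GeneticArchitecture(n_neutral=2000, n_adaptive=0,
                                      neutral_sd=0.8, neutral_length=0.0,
                                      missing_rate=0.0)
        truth = lg.simulate_allele_frequencies(arch, env, coords, seed=2)
        p = truth.drop(columns="population").to_numpy()
        dev = p - p.mean(axis=0)          # remove shared per-locus intercept
        corr = np.corrcoef(dev)
        k = p.shape[0]
        off = corr[np.triu_indices(k, 1)]
        assert abs(off.mean() - (-1.0 / (k - 1))) < 0.05

    def test_frequencies_strictly_inside_unit_interval(self):
        cfg = simple_config(n_pops=6)
        _, coords, env = lg.generate_landscape(cfg)
        arch = lg.GeneticArchitecture(n_neutral=50, n_adaptive=50, beta=4.0)
        truth = lg.simulate_allele_frequencies(arch, env, coords, seed=0)
        p = truth.drop(columns="population").to_numpy()
        assert np.all((p > 0) & (p < 1))

    def test_unknown_driver_rejected(self):
        cfg = simple_config()
        _, coords, env = lg.generate_landscape(cfg)
        arch = lg.GeneticArchitecture(n_adaptive=2, drivers="NOPE")
        with pytest.raises(KeyError):
            lg.simulate_allele_frequencies(arch, env, coords)


class TestGenotypes:
    def _truth(self, cfg, arch, p_override=None, seed=0):
        _, coords, env = lg.generate_landscape(cfg)
        truth = lg.simulate_allele_frequencies(arch, env, coords, seed=seed)
        if p_override is not None:
            truth.iloc[:, 1:] = p_override
        return truth

    def test_degenerate_p_zero_gives_all_reference(self):
        cfg = simple_config()
        arch = lg.GeneticArchitecture(n_neutral=5, n_adaptive=0, missing_rate=0.0)
        truth = self._truth(cfg, arch, p_override=0.0)
        g = lg.sample_genotypes(truth, cfg, arch)
        assert np.all(g.genotypes == 0)

    def test_missing_rate_one_masks_everything(self):
        cfg = simple_config()
        arch = lg.GeneticArchitecture(n_neutral=5, n_adaptive=0, missing_rate=1.0)
        g = lg.sample_genotypes(self._truth(cfg, arch), cfg, arch)
        assert np.all(g.genotypes == -1)

    def test_sample_frequency_within_binomial_error(self):
        cfg = simple_config(n_pops=2, samples_per_pop=2500)  # 10^4 allele draws
        arch = lg.GeneticArchitecture(n_neutral=1, n_adaptive=0, missing_rate=0.0)
        truth = self._truth(cfg, arch, p_override=0.3)
        g = lg.sample_genotypes(truth, cfg, arch)
        n_draws = g.genotypes.size * 2
        phat = g.genotypes.mean() / 2
        se = np.sqrt(0.3 * 0.7 / n_draws)
        assert abs(phat - 0.3) < 3 * se

    def test_frequency_recovery_improves_with_sample_size(self):
        arch = lg.GeneticArchitecture(n_neutral=80, n_adaptive=0,
                                      missing_rate=0.0, neutral_sd=0.8)
        rmse = []
        for n in (10, 100, 1000):
            cfg = simple_config(n_pops=4, samples_per_pop=n, seed=7)
            truth = self._truth(cfg, arch, seed=7)
            g = lg.sample_genotypes(truth, cfg, arch)
            freqs = lg.population_frequencies(g)
            err = freqs.freq - truth.drop(columns="population").to_numpy()
            rmse.append(np.sqrt(np.nanmean(err ** 2)))
        assert rmse[0] > rmse[1] > rmse[2]

    def test_same_seed_identical_vcf_bytes(self, tmp_path):
        cfg = simple_config(seed=9)
        arch = lg.GeneticArchitecture(n_neutral=20, n_adaptive=5, missing_rate=0.1)
        paths = []
        for tag in ("a", "b"):
            out = tmp_path / tag
            lg.generate_dataset(cfg, arch, out_dir=out)
            paths.append((out / "genotypes.vcf").read_bytes())
        assert paths[0] == paths[1]

    def test_vcf_roundtrip_is_lossless(self, tmp_path):
        cfg = simple_config(seed=3)
        arch = lg.GeneticArchitecture(n_neutral=12, n_adaptive=3,
                                      snps_per_fragment=3, missing_rate=0.2)
        data = lg.generate_dataset(cfg, arch, out_dir=tmp_path)
        back = lg.read_genotypes(tmp_path / "genotypes.vcf", tmp_path / "popmap.tsv")
        g = data["genotypes"]
        np.testing.assert_array_equal(back.genotypes, g.genotypes)
        np.testing.assert_array_equal(back.samples, g.samples)
        np.testing.assert_array_equal(back.fragments, g.fragments)
        np.testing.assert_array_equal(back.positions, g.positions)


class TestScenario:
    def test_zero_shift_returns_grid_unchanged(self):
        grid, _, _ = lg.generate_landscape(simple_config())
        out = lg.apply_scenario(grid, lg.ScenarioShift(epoch="null"))
        assert out.table[grid.variables].equals(grid.table[grid.variables])
        assert out.epoch == "null"

    def test_additive_and_multiplicative_shift(self):
        grid, _, _ = lg.generate_landscape(simple_config())
        out = lg.apply_scenario(grid, lg.ScenarioShift(
            add={"E1": 2.0}, mult={"E1": 3.0}, epoch="x"))
        np.testing.assert_allclose(out.table["E1"], grid.table["E1"] * 3.0 + 2.0)
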