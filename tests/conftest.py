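import numpy as np
import pytest

import landgen as lg
from landgen.qc import GenotypeMatrix


def make_gm(genotypes, populations=None, fragments=None, positions=None,
            snp_ids=None, n_alleles=None):
    """Build a GenotypeMatrix directly from arrays (tests' construction path)."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_snp = geno.shape
    if populations is None:
        populations = ["p1"] * (n_ind // 2) + ["p2"] * (n_ind - n_ind // 2)
    samples = [f"s{i}" for i in range(n_ind)]
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(n_snp)]
    if fragments is None:
        fragments = [f"frag{j}" for j in range(n_snp)]
    if positions is None:
        positions = [1] * n_snp
    if n_alleles is None:
        n_alleles = [2] * n_snp
    return GenotypeMatrix(
        genotypes=geno, samples=np.array(samples),
        populations=np.array(populations), snp_ids=np.array(snp_ids),
        fragments=np.array(fragments),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(["A"] * n_snp), alt=np.array(["T"] * n_snp),
        n_alleles=np.array(n_alleles, dtype=np.int64))


@pytest.fixture(scope="session")
def bench_data():
    """One benchmark synthetic dataset shared across tests (seed 11)."""
    cfg = lg.benchmark_config(seed=11)
    arch = lg.benchmark_architecture()
    return lg.generate_dataset(cfg, arch, scenarios=[
        lg.ScenarioShift(add={"E1": 2.0}, epoch="rcp45"),
        lg.ScenarioShift(add={"E1": 4.0}, epoch="rcp85")])


@pytest.fixture(scope="session")
def bench_filtered(bench_data):
    g, _ = lg.filter_variants(bench_data["genotypes"])
    return g


@pytest.fixture(scope="session")
def bench_freqs(bench_filtered):
    return lg.population_frequencies(bench_filtered, min_poly_pops=5)
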