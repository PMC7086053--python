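"""Synthetic landscape-genomic data generator.

Produces the inputs the analysis chain consumes: a gridded climate layer,
population coordinates and site-level environments, true population allele
frequencies with controllable isolation-by-distance (spatially autocorrelated
neutral drift) and isolation-by-environment (adaptive clines), individual
diploid genotypes with missing calls, and shifted future-climate scenarios.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning, in a fixed order: (1) landscape
noise fields, (2) baseline allele-frequency intercepts, (3) neutral drift
fields, (4) genotype draws, (5) missingness mask.  Identical seeds therefore
give bit-identical outputs, including written VCFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnvVariable",
    "LandscapeConfig",
    "GeneticArchitecture",
    "ScenarioShift",
    "ClimateGrid",
    "generate_landscape",
    "simulate_allele_frequencies",
    "sample_genotypes",
    "apply_scenario",
    "write_vcf",
    "write_popmap",
    "generate_dataset",
    "benchmark_config",
    "benchmark_architecture",
]


@dataclass(frozen=True)
class EnvVariable:
    """One environmental layer on the grid.

    kind:
        ``linear``   — gradient along ``axis`` ("lon" or "lat"), range = amplitude.
        ``sinusoid`` — ``amplitude * sin(2*pi*coord/period)`` along ``axis``.
        ``noise``    — Gaussian random field, exponential covariance with
                       correlation length ``length_scale`` (grid coordinate
                       units) and marginal sd ``amplitude``.
    """

    name: str
    kind: str = "noise"
    axis: str = "lon"
    amplitude: float = 1.0
    offset: float = 0.0
    period: float = 1.0
    length_scale: float = 1.0

    def __post_init__(self):
        if self.kind not in ("linear", "sinusoid", "noise"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.axis not in ("lon", "lat"):
            raise ValueError(f"axis must be 'lon' or 'lat', got {self.axis!r}")


@dataclass(frozen=True)
class LandscapeConfig:
    """Grid geometry, environmental layers, and the sampling design."""

    n_lon: int = 20
    n_lat: int = 10
    lon_range: tuple[float, float] = (95.0, 115.0)
    lat_range: tuple[float, float] = (30.0, 40.0)
    variables: tuple[EnvVariable, ...] = (EnvVariable("E1", kind="linear"),)
    n_pops: int = 17
    pop_cells: tuple[int, ...] | None = None  # flat cell indices; None = spread
    samples_per_pop: int | tuple[int, ...] = 12
    seed: int = 0

    def __post_init__(self):
        if self.n_lon < 2 or self.n_lat < 2:
            raise ValueError("grid dimensions must be at least 2x2")
        if self.pop_cells is not None:
            if len(self.pop_cells) != self.n_pops:
                raise ValueError("pop_cells length must equal n_pops")
            if len(set(self.pop_cells)) != self.n_pops:
                raise ValueError("population placements must be distinct cells")
        if self.n_pops > self.n_lon * self.n_lat:
            raise ValueError("more populations than grid cells")

    def sample_sizes(self) -> np.ndarray:
        if np.isscalar(self.samples_per_pop):
            return np.full(self.n_pops, int(self.samples_per_pop))
        sizes = np.asarray(self.samples_per_pop, dtype=int)
        if sizes.size != self.n_pops:
            raise ValueError("samples_per_pop length must equal n_pops")
        return sizes


@dataclass(frozen=True)
class GeneticArchitecture:
    """Locus counts, fragment grouping, and the strength of IBD/IBE signals.

    ``beta`` is the logistic slope of adaptive allele frequency on the
    standardized driver variable; ``drivers`` names one environmental variable
    per adaptive locus (a single name is broadcast).  Neutral loci are logistic
    transforms of Gaussian fields over population coordinates with exponential
    covariance: sd ``neutral_sd`` and correlation length ``neutral_length``
    (degrees); length 0 gives independent drift per population.
    """

    n_neutral: int = 450
    n_adaptive: int = 50
    snps_per_fragment: int = 1
    beta: float | tuple[float, ...] = 2.0
    drivers: str | tuple[str, ...] = "E1"
    neutral_sd: float = 0.5
    neutral_length: float = 0.0
    base_freq_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.snps_per_fragment < 1:
            raise ValueError("snps_per_fragment must be >= 1")
        betas = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not np.all(np.isfinite(betas)):
            raise ValueError("beta must be finite")

    @property
    def n_loci(self) -> int:
        return self.n_neutral + self.n_adaptive

    def adaptive_betas(self) -> np.ndarray:
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if b.size == 1:
            return np.full(self.n_adaptive, b[0])
        if b.size != self.n_adaptive:
            raise ValueError("beta length must equal n_adaptive")
        return b

    def adaptive_drivers(self) -> list[str]:
        d = [self.drivers] if isinstance(self.drivers, str) else list(self.drivers)
        if len(d) == 1:
            return d * self.n_adaptive
        if len(d) != self.n_adaptive:
            raise ValueError("drivers length must equal n_adaptive")
        return d


@dataclass(frozen=True)
class ScenarioShift:
    """Per-variable additive shift and/or multiplicative scaling of a grid."""

    add: dict[str, float] = field(default_factory=dict)
    mult: dict[str, float] = field(default_factory=dict)
    epoch: str = "future"


@dataclass
class ClimateGrid:
    """Grid cells x environmental variables for one epoch."""

    table: pd.DataFrame  # columns: cell, lon, lat, then variables
    epoch: str = "current"

    @property
    def variables(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("cell", "lon", "lat")]

    def values(self, variables: Sequence[str] | None = None) -> np.ndarray:
        return self.table[list(variables or self.variables)].to_numpy(float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, epoch: str = "current") -> "ClimateGrid":
        return cls(pd.read_csv(path), epoch=epoch)


def _exp_field(coords: np.ndarray, sd: float, length: float,
               rng: np.random.Generator) -> np.ndarray:
    """Draw a Gaussian field with covariance sd^2 * exp(-d/length)."""
    n = coords.shape[0]
    if sd == 0.0:
        return np.zeros(n)
    if length <= 0.0:
        return rng.normal(0.0, sd, n)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    cov = sd ** 2 * np.exp(-d / length)
    # tiny jitter keeps Cholesky stable for coincident/near rows
    chol = np.linalg.cholesky(cov + 1e-10 * sd ** 2 * np.eye(n))
    return chol @ rng.normal(0.0, 1.0, n)


def generate_landscape(config: LandscapeConfig):
    """Build the current-epoch grid, population coordinates and environments.

    Returns ``(grid, coords, env)``: a :class:`ClimateGrid`, a DataFrame
    (population, lon, lat, cell), and a DataFrame (population + one column per
    variable) whose rows equal the grid values at the population cells.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_land = np.random.Generator(np.random.PCG64(ss.spawn(5)[0]))

    lons = np.linspace(*config.lon_range, config.n_lon)
    lats = np.linspace(*config.lat_range, config.n_lat)
    glon, glat = np.meshgrid(lons, lats, indexing="ij")
    glon, glat = glon.ravel(), glat.ravel()
    n_cells = glon.size
    coords_xy = np.column_stack([glon, glat])

    cols = {"cell": np.arange(n_cells), "lon": glon, "lat": glat}
    for var in config.variables:
        coord = glon if var.axis == "lon" else glat
        if var.kind == "linear":
            span = coord.max() - coord.min()
            vals = var.offset + var.amplitude * (coord - coord.min()) / span
        elif var.kind == "sinusoid":
            vals = var.offset + var.amplitude * np.sin(2 * np.pi * coord / var.period)
        else:
            vals = var.offset + _exp_field(coords_xy, var.amplitude,
                                           var.length_scale, rng_land)
        cols[var.name] = vals
    grid = ClimateGrid(pd.DataFrame(cols), epoch="current")

    if config.pop_cells is not None:
        cells = np.asarray(config.pop_cells)
    else:  # evenly spread over the flat cell index — deterministic placement
        cells = np.unique(np.round(
            np.linspace(0, n_cells - 1, config.n_pops)).astype(int))
        if cells.size < config.n_pops:
            raise ValueError("grid too small to place distinct populations")
    pops = [f"pop{i + 1:02d}" for i in range(config.n_pops)]
    coords = pd.DataFrame({"population": pops,
                           "lon": glon[cells], "lat": glat[cells],
                           "cell": cells})
    env = pd.DataFrame({"population": pops})
    for var in config.variables:
        env[var.name] = grid.table[var.name].to_numpy()[cells]
    return grid, coords, env


def simulate_allele_frequencies(arch: GeneticArchitecture, env: pd.DataFrame,
                                coords: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """True per-population alternate-allele frequencies.

    Every locus receives a spatially autocorrelated Gaussian drift field *g*
    over population coordinates; adaptive locus *l* with driver *v* adds the
    selection term: ``p = logistic(a_l + g + beta_l * z_v)`` where ``z_v``
    is the driver standardized across populations.  Drift on adaptive loci
    keeps them exchangeable with neutral loci when beta = 0 (selection acts
    on top of drift, not instead of it).  Returns a DataFrame
    (populations x loci) with locus columns ``snp0001`` ...; all values in
    (0, 1).
    """
    ss = np.random.SeedSequence(seed)
    _, s_base, s_drift = ss.spawn(5)[:3]
    rng_base = np.random.Generator(np.random.PCG64(s_base))
    rng_drift = np.random.Generator(np.random.PCG64(s_drift))

    pops = env["population"].tolist()
    n_pops = len(pops)
    var_names = [c for c in env.columns if c != "population"]
    for drv in set(arch.adaptive_drivers()) if arch.n_adaptive else set():
        if drv not in var_names:
            raise KeyError(f"unknown driver variable {drv!r}")

    lo, hi = arch.base_freq_range
    base = rng_base.uniform(lo, hi, arch.n_loci)
    intercepts = np.log(base / (1 - base))

    xy = coords.set_index("population").loc[pops, ["lon", "lat"]].to_numpy(float)
    freqs = np.empty((n_pops, arch.n_loci))
    betas = arch.adaptive_betas()
    drivers = arch.adaptive_drivers()
    z = {}
    for v in var_names:
        col = env[v].to_numpy(float)
        sd = col.std(ddof=1)
        z[v] = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)

    for l in range(arch.n_loci):
        g = _exp_field(xy, arch.neutral_sd, arch.neutral_length, rng_drift)
        eta = intercepts[l] + g
        if l >= arch.n_neutral:
            k = l - arch.n_neutral
            eta = eta + betas[k] * z[drivers[k]]
        freqs[:, l] = 1.0 / (1.0 + np.exp(-eta))

    names = [f"snp{l + 1:05d}" for l in range(arch.n_loci)]
    out = pd.DataFrame(freqs, columns=names)
    out.insert(0, "population", pops)
    return out


def _fragment_layout(arch: GeneticArchitecture) -> tuple[list[str], list[int]]:
    """Assign consecutive SNPs to fragments; positions 1-based within fragment."""
    frags, positions = [], []
    for l in range(arch.n_loci):
        f = l // arch.snps_per_fragment
        frags.append(f"frag{f + 1:05d}")
        positions.append((l % arch.snps_per_fragment) * 50 + 1)
    return frags, positions


def sample_genotypes(freqs: pd.DataFrame, config: LandscapeConfig,
                     arch: GeneticArchitecture):
    """Draw diploid genotypes (alt-allele counts 0/1/2, -1 = missing).

    Each individual draws two allele copies at its population's true
    frequency; missing entries are inserted completely at random at
    ``arch.missing_rate``.  Returns a :class:`landgen.qc.GenotypeMatrix`.
    """
    from .qc import GenotypeMatrix

    p = freqs.drop(columns="population").to_numpy(float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    pops = freqs["population"].tolist()
    sizes = config.sample_sizes()
    if np.any(sizes < 1):
        raise ValueError("sample sizes must be >= 1")
    if len(pops) != sizes.size:
        raise ValueError("frequency table and config disagree on populations")

    ss = np.random.SeedSequence(config.seed)
    _, _, _, s_geno, s_miss = ss.spawn(5)
    rng_g = np.random.Generator(np.random.PCG64(s_geno))
    rng_m = np.random.Generator(np.random.PCG64(s_miss))

    n_ind = int(sizes.sum())
    n_snp = p.shape[1]
    geno = np.empty((n_ind, n_snp), dtype=np.int8)
    samples, sample_pops = [], []
    row = 0
    for k, pop in enumerate(pops):
        for j in range(sizes[k]):
            geno[row] = rng_g.binomial(2, p[k])
            samples.append(f"{pop}_ind{j + 1:02d}")
            sample_pops.append(pop)
            row += 1
    if arch.missing_rate > 0:
        mask = rng_m.random((n_ind, n_snp)) < arch.missing_rate
        geno[mask] = -1

    frags, positions = _fragment_layout(arch)
    snp_ids = [c for c in freqs.columns if c != "population"]
    return GenotypeMatrix(
        genotypes=geno,
        samples=np.array(samples),
        populations=np.array(sample_pops),
        snp_ids=np.array(snp_ids),
        fragments=np.array(frags),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(["A"] * n_snp),
        alt=np.array(["T"] * n_snp),
        n_alleles=np.full(n_snp, 2, dtype=np.int64),
    )


def apply_scenario(grid: ClimateGrid, shift: ScenarioShift) -> ClimateGrid:
    """Shifted copy of a grid; a zero shift returns values unchanged."""
    table = grid.table.copy()
    for v, m in shift.mult.items():
        table[v] = table[v] * m
    for v, a in shift.add.items():
        table[v] = table[v] + a
    return ClimateGrid(table, epoch=shift.epoch)


_GT = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(g, path) -> None:
    """Write a minimal GT-only VCF 4.2.

    CHROM is the fragment ID (one GBS fragment = one contig-like unit), POS
    the 1-based within-fragment position, and INFO carries ``FRAG=`` so the
    grouping round-trips regardless of how a reader treats CHROM.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=FRAG,Number=1,Type=String,Description="GBS fragment ID">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for frag in dict.fromkeys(g.fragments):
            fh.write(f"##contig=<ID={frag}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for j in range(g.n_snps):
            gts = "\t".join(_GT[int(v)] for v in g.genotypes[:, j])
            fh.write(f"{g.fragments[j]}\t{g.positions[j]}\t{g.snp_ids[j]}\t"
                     f"{g.ref[j]}\t{g.alt[j]}\t.\tPASS\tFRAG={g.fragments[j]}"
                     f"\tGT\t{gts}\n")


def write_popmap(g, path) -> None:
    pd.DataFrame({"sample": g.samples, "population": g.populations}).to_csv(
        path, sep="\t", index=False, header=False)


def generate_dataset(config: LandscapeConfig, arch: GeneticArchitecture,
                     out_dir=None, scenarios: Sequence[ScenarioShift] = ()):
    """One-call generator: landscape + truth + genotypes (+ files).

    Returns a dict with keys ``grid``, ``coords``, ``env``, ``true_freqs``,
    ``genotypes`` and, per scenario, ``grid_<epoch>``.  When ``out_dir`` is
    given, also writes VCF, popmap TSV, coordinates/environment CSVs and one
    grid CSV per epoch.
    """
    grid, coords, env = generate_landscape(config)
    truth = simulate_allele_frequencies(arch, env, coords, seed=config.seed)
    g = sample_genotypes(truth, config, arch)
    out = {"grid": grid, "coords": coords, "env": env,
           "true_freqs": truth, "genotypes": g}
    for sc in scenarios:
        out[f"grid_{sc.epoch}"] = apply_scenario(grid, sc)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_vcf(g, out_dir / "genotypes.vcf")
        write_popmap(g, out_dir / "popmap.tsv")
        coords.to_csv(out_dir / "coords.csv", index=False)
        env.to_csv(out_dir / "env.csv", index=False)
        grid.to_csv(out_dir / "grid_current.csv")
        for sc in scenarios:
            out[f"grid_{sc.epoch}"].to_csv(out_dir / f"grid_{sc.epoch}.csv")
    return out


def benchmark_config(seed: int = 0, **overrides) -> LandscapeConfig:
    """The standard synthetic design: 17 populations on a 20x10 grid, one
    west-east linear driver (E1) plus four independent noise variables,
    12 diploids per population."""
    variables = (
        EnvVariable("E1", kind="linear", axis="lon", amplitude=10.0),
        EnvVariable("N1", kind="noise", amplitude=1.0, length_scale=2.0),
        EnvVariable("N2", kind="noise", amplitude=1.0, length_scale=2.0),
        EnvVariable("N3", kind="noise", amplitude=1.0, length_scale=2.0),
        EnvVariable("N4", kind="noise", amplitude=1.0, length_scale=2.0),
    )
    cfg = LandscapeConfig(variables=variables, n_pops=17,
                          samples_per_pop=12, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def benchmark_architecture(**overrides) -> GeneticArchitecture:
    """500 SNPs (450 neutral + 50 adaptive, beta = 2 on E1), 5% missingness,
    mild spatially autocorrelated drift."""
    arch = GeneticArchitecture(n_neutral=450, n_adaptive=50, beta=2.0,
                               drivers="E1", neutral_sd=0.5,
                               neutral_length=3.0, missing_rate=0.05)
    return replace(arch, **overrides) if overrides else arch
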