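"""Generate a synthetic landscape-genomic dataset and write its files.

Builds a 17-population landscape with one west-east climate driver (E1)
and four spatially autocorrelated noise variables, simulates 500 SNPs
(450 neutral with spatially autocorrelated drift, 50 adaptive clines on
E1), samples 12 diploids per population with 5% missing calls, and writes
VCF + popmap + coordinate/environment/grid CSVs.
"""

import landgen as lg

cfg = lg.benchmark_config(seed=1)
arch = lg.benchmark_architecture()
data = lg.generate_dataset(cfg, arch, out_dir="example_output/sim", scenarios=[
    lg.ScenarioShift(add={"E1": 2.0}, epoch="2055-moderate"),
    lg.ScenarioShift(add={"E1": 4.0}, epoch="2085-extreme")])

g = data["genotypes"]
print(f"individuals: {g.n_individuals}, SNPs: {g.n_snps}, "
      f"populations: {len(g.pop_names)}")
print(f"grid cells: {len(data['grid'].table)}, variables: {data['grid'].variables}")
print("files written under example_output/sim/ (VCF, popmap, env, coords, grids)")
# The adaptive loci are the last 50 columns; their true frequencies follow
# logistic clines on E1, so every downstream stage has a known answer key.
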