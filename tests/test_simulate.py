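"""The synthetic generator: determinism, frequency calibration, planted sweeps."""

import numpy as np
import pandas as pd
import pytest

from hpscan import (
    ConfigError,
    InputError,
    MafDistribution,
    SimConfig,
    Sweep,
    genotype_samples,
    simulate_sites,
    write_truth,
    write_vcf,
)
from hpscan.simulate import (
    SimTruth,
    pool_genotype_matrix,
    simulate_dataset,
    simulate_population,
)

from conftest import pooled_site_table


BASE = dict(
    chrom_lengths={"1": 500_000},
    n_diploid_samples=6,
    snp_density=8.0,
    missing_rate=0.0,
    populations=("p",),
)


def test_sites_sorted_deterministic_and_poisson_scaled():
    cfg = SimConfig(**BASE, sweeps=(), seed=42)
    a = simulate_sites(cfg, "p")
    b = simulate_sites(cfg, "p")
    pd.testing.assert_frame_equal(a, b)
    assert a["pos"].is_monotonic_increasing and a["pos"].is_unique
    expected = 8.0 / 1000 * 500_000  # Poisson mean
    assert abs(len(a) - expected) < 5 * np.sqrt(expected)


def test_other_populations_unperturbed_by_adding_one():
    cfg2 = SimConfig(**{**BASE, "populations": ("p", "q")}, sweeps=(), seed=42)
    cfg3 = SimConfig(**{**BASE, "populations": ("p", "q", "r")}, sweeps=(), seed=42)
    pd.testing.assert_frame_equal(simulate_sites(cfg2, "q"), simulate_sites(cfg3, "q"))


def test_zero_maf_ceiling_makes_in_sweep_sites_monomorphic():
    cfg = SimConfig(**BASE, sweeps=(Sweep("1", 100_001, 200_000, 0.0),), seed=7)
    sites = simulate_sites(cfg, "p")
    inside = sites[(sites.pos >= 100_001) & (sites.pos <= 200_000)]
    assert len(inside) > 100
    assert np.isin(inside["freq"], [0.0, 1.0]).all()
    outside = sites[(sites.pos < 100_001) | (sites.pos > 200_000)]
    maf = np.minimum(outside["freq"], 1 - outside["freq"])
    assert (maf >= 0.05).all() and (maf <= 0.5).all()


def test_mean_site_heterozygosity_matches_uniform_integral():
    """E[2f(1-f)] under MAF ~ U(0.05, 0.5), by independent numerical integration."""
    grid = np.linspace(0.05, 0.5, 20_001)
    expected = np.trapezoid(2 * grid * (1 - grid), grid) / (0.5 - 0.05)
    cfg = SimConfig(
        **{**BASE, "chrom_lengths": {"1": 5_000_000}}, sweeps=(), seed=3
    )
    sites = simulate_sites(cfg, "p")
    het = 2 * sites["freq"] * (1 - sites["freq"])
    assert het.mean() == pytest.approx(expected, abs=3 * het.std() / np.sqrt(len(het)))


def test_sweep_config_validation():
    with pytest.raises(ConfigError, match="overlap"):
        SimConfig(**BASE, sweeps=(Sweep("1", 1, 100_000), Sweep("1", 50_000, 150_000)))
    with pytest.raises(ConfigError, match="outside"):
        SimConfig(**BASE, sweeps=(Sweep("1", 400_000, 600_000),))
    with pytest.raises(ConfigError, match="below the background"):
        SimConfig(**BASE, sweeps=(Sweep("1", 1, 1000, maf_ceiling=0.1),))
    with pytest.raises(ConfigError, match="missing_rate"):
        SimConfig(**{**BASE, "missing_rate": 1.0}, sweeps=())


def test_genotypes_fixed_alt_and_missing_conventions():
    sites = pd.DataFrame({"chrom": "1", "pos": [10, 20], "freq": [1.0, 1.0]})
    g = genotype_samples(sites, 5, 0.0, 1)
    assert (g == 1).all()
    with pytest.raises(ConfigError, match="missing_rate"):
        genotype_samples(sites, 5, 1.0, 1)
    with pytest.raises(ConfigError, match="n_diploid_samples"):
        genotype_samples(sites, 0, 0.0, 1)


def test_genotype_sampling_matches_binomial_se():
    sites = pd.DataFrame({"chrom": "1", "pos": [100], "freq": [0.5]})
    g = genotype_samples(sites, 10_000, 0.0, 123)
    frac = g.mean()
    se = np.sqrt(0.5 * 0.5 / 20_000)
    assert abs(frac - 0.5) < 3 * se


def test_vcf_round_trip_preserves_pooled_counts(tmp_path):
    """Counts read back through the VCF equal the direct genotype-matrix tally."""
    from hpscan.ingest import PopulationSpec, read_biallelic_snps

    cfg = SimConfig(
        **{**BASE, "missing_rate": 0.1, "chrom_lengths": {"1": 100_000}},
        sweeps=(),
        seed=9,
    )
    sites, genotypes = simulate_population(cfg, "p")
    names = [f"s{i}" for i in range(cfg.n_diploid_samples)]
    path = tmp_path / "t.vcf"
    write_vcf(sites, genotypes, names, cfg.chrom_lengths, path)
    tables, _ = read_biallelic_snps(path, [PopulationSpec("p", tuple(names))], ["1"])
    got = tables["p"]

    pooled = pool_genotype_matrix(genotypes)
    keep = (pooled["n_ref"] + pooled["n_alt"]) > 0
    exp_major = np.maximum(pooled["n_ref"], pooled["n_alt"])[keep].to_numpy()
    exp_minor = np.minimum(pooled["n_ref"], pooled["n_alt"])[keep].to_numpy()
    assert len(got) == int(keep.sum())
    np.testing.assert_array_equal(got["n_major"].to_numpy(), exp_major)
    np.testing.assert_array_equal(got["n_minor"].to_numpy(), exp_minor)
    np.testing.assert_array_equal(got["pos"].to_numpy(), sites.loc[keep.to_numpy(), "pos"].to_numpy())


def test_vcf_writer_edge_cases(tmp_path):
    empty = pd.DataFrame({"chrom": [], "pos": [], "ref": [], "alt": [], "freq": []})
    path = tmp_path / "empty.vcf"
    write_vcf(empty, np.zeros((0, 2, 2), dtype=np.int8), ["a", "b"], {"1": 1000}, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "##fileformat=VCFv4.2"
    assert all(l.startswith("#") for l in lines)

    sites = pd.DataFrame(
        {"chrom": ["1", "1"], "pos": [50, 20], "ref": ["A", "C"], "alt": ["G", "T"]}
    )
    with pytest.raises(InputError, match="sorted"):
        write_vcf(sites, np.zeros((2, 1, 2), dtype=np.int8), ["a"], {"1": 1000}, tmp_path / "x.vcf")

    ok = sites.sort_values("pos").reset_index(drop=True)
    geno = np.array([[[-1, -1]], [[0, 1]]], dtype=np.int8)
    write_vcf(ok, geno, ["a"], {"1": 1000}, tmp_path / "m.vcf")
    body = [l for l in (tmp_path / "m.vcf").read_text().splitlines() if not l.startswith("#")]
    assert body[0].endswith("./.") and body[1].endswith("0/1")


def test_truth_bed_is_zero_based_half_open_and_sorted(tmp_path):
    truth = SimTruth(
        sweeps=(Sweep("2", 5_000, 9_000, 0.01), Sweep("1", 100_000, 200_000, 0.02)),
        realized_snp_counts={"p": {"1": 10, "2": 10}},
        seed=0,
    )
    path = tmp_path / "truth.bed"
    write_truth(truth, path)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t")[:3] == ["1", "99999", "200000"]
    assert lines[1].split("\t")[:3] == ["2", "4999", "9000"]

    write_truth(SimTruth(sweeps=(), realized_snp_counts={"p": {"1": 1}}, seed=0), path)
    assert path.read_text() == ""


def test_dataset_determinism_byte_identical(tmp_path):
    cfg = SimConfig(
        **{**BASE, "chrom_lengths": {"1": 100_000}, "populations": ("x", "y")},
        sweeps=(),
        seed=21,
    )
    simulate_dataset(cfg, tmp_path / "a")
    simulate_dataset(cfg, tmp_path / "b")
    for name in ("x.vcf", "y.vcf", "truth.bed", "populations.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_calibration_genome_mean_window_hp(small_scan):
    """Default-style background lands in the realistic genome-mean Hp band."""
    s = small_scan.summary_
    assert s.total_windows >= 100
    assert 0.25 <= s.mean_hp <= 0.40


def test_default_config_calibration_over_thousand_windows():
    from hpscan import HpScan

    cfg = SimConfig(seed=2)
    sites = pooled_site_table(cfg, cfg.populations[0])
    res = HpScan(sites, cfg.chrom_lengths, population="d").fit()
    assert res.summary_.total_windows >= 990
    assert 0.25 <= res.mean_hp <= 0.40


def test_sweep_windows_far_below_background(small_sim_config):
    """Mean Hp inside low-MAF sweeps sits > 4 background SDs under the mean."""
    from hpscan import ScanConfig, make_windows, window_stats

    sites = pooled_site_table(small_sim_config, "popA")
    windows = window_stats(sites, make_windows(small_sim_config.chrom_lengths, ScanConfig()))
    in_sweep = np.zeros(len(windows), dtype=bool)
    for sw in small_sim_config.sweeps:
        in_sweep |= (
            (windows["chrom"] == sw.chrom)
            & (windows["start"] >= sw.start)
            & (windows["end"] <= sw.end)
        ).to_numpy()
    bg = windows.loc[~in_sweep, "hp"]
    assert windows.loc[in_sweep, "hp"].mean() < bg.mean() - 4 * bg.std()


def test_maf_distribution_families():
    assert MafDistribution("uniform", (0.05, 0.5)).support_low == 0.05
    beta = MafDistribution("beta", (2.0, 2.0))
    draws = beta.sample(np.random.default_rng(0), 1000)
    assert (draws >= 0).all() and (draws <= 0.5).all()
    with pytest.raises(ConfigError):
        MafDistribution("gamma", (1.0,))
    with pytest.raises(ConfigError):
        MafDistribution("uniform", (0.3, 0.2))
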