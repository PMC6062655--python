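import numpy as np
import pandas as pd
import pytest

from hpscan import ScanConfig, SimConfig, Sweep
from hpscan.simulate import pool_genotype_matrix, simulate_population


def make_sites(chrom, positions, n_major, n_minor):
    """SiteAlleleCounts table from parallel arrays (single chromosome)."""
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": ["A"] * n,
            "alt": ["G"] * n,
            "n_major": np.asarray(n_major, dtype=np.int64),
            "n_minor": np.asarray(n_minor, dtype=np.int64),
        }
    )


def make_window_frame(hp_values, chrom="1", width=20_000, step=10_000, n_snps=100):
    """Window table with given Hp values, all passing the SNP filter."""
    rows = []
    for i, hp in enumerate(hp_values):
        start = 1 + i * step
        rows.append((chrom, start, start + width - 1, n_snps, 0, 0, hp, np.nan, True))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_snps", "sum_major", "sum_minor",
            "hp", "z_hp", "passes_filter",
        ],
    )


def pooled_site_table(config: SimConfig, population: str) -> pd.DataFrame:
    """Simulate one population and pool its genotype matrix directly.

    Bypasses the VCF writer/reader (tested separately) to give scan-level
    tests a fast path from simulation to SiteAlleleCounts.
    """
    sites, genotypes = simulate_population(config, population)
    pooled = pool_genotype_matrix(genotypes)
    keep = (pooled["n_ref"] + pooled["n_alt"]) > 0
    df = sites.loc[keep.to_numpy()].reset_index(drop=True)
    n_ref = pooled.loc[keep, "n_ref"].to_numpy()
    n_alt = pooled.loc[keep, "n_alt"].to_numpy()
    df["n_major"] = np.maximum(n_ref, n_alt)
    df["n_minor"] = np.minimum(n_ref, n_alt)
    df["major_is_ref"] = n_ref >= n_alt
    return df


@pytest.fixture(scope="session")
def small_sim_config():
    """A 2x2-Mb genome with two planted sweeps, cheap enough for many tests."""
    return SimConfig(
        chrom_lengths={"1": 2_000_000, "2": 2_000_000},
        n_diploid_samples=8,
        snp_density=10.0,
        sweeps=(
            Sweep("1", 500_001, 560_000, 0.0),
            Sweep("2", 1_200_001, 1_260_000, 0.01),
        ),
        missing_rate=0.02,
        populations=("popA",),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_scan(small_sim_config):
    """Fitted HpScanResults on the small simulated genome."""
    from hpscan import HpScan

    sites = pooled_site_table(small_sim_config, "popA")
    model = HpScan(
        sites,
        small_sim_config.chrom_lengths,
        config=ScanConfig(),
        population="popA",
        n_samples=small_sim_config.n_diploid_samples,
    )
    return model.fit()
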