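"""Windowed pooled heterozygosity and its genome-wide Z-transform.

The scan tiles each chromosome with sliding windows (default 20 kb advanced
by 10 kb), sums the pooled major/minor allele counts of the SNPs in each
window, and computes the pooled heterozygosity

    Hp = 2 * sum_nMAJ * sum_nMIN / (sum_nMAJ + sum_nMIN)**2,

which equals 2p(1-p) for p the pooled major-allele fraction and therefore
lies in [0, 0.5]. Windows with fewer than a minimum number of SNPs (default
50) are excluded, and the surviving windows are standardised genome-wide:

    Z(Hp) = (Hp - mean(Hp)) / sd(Hp),

with the mean and the sample standard deviation (n-1 denominator) taken over
the analysed windows of one population, pooled across chromosomes. Strongly
negative Z(Hp) marks candidate selective sweeps.

The user-facing surface is the ``HpScan`` model (one population's site table
plus a ScanConfig) whose ``fit()`` returns an ``HpScanResults`` carrying the
window table, the genome mean/SD, a summary table, and region calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import ScanConfig
from .errors import DegenerateDataError, InputError
from . import regions as _regions

WINDOW_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_snps",
    "sum_major",
    "sum_minor",
    "hp",
    "z_hp",
    "passes_filter",
]


@dataclass(frozen=True)
class ScanSummary:
    """Genome-wide bookkeeping of one population's scan."""

    total_windows: int
    analyzed_windows: int
    excluded_windows: int
    mean_hp: float
    sd_hp: float

    def __post_init__(self) -> None:
        assert self.analyzed_windows + self.excluded_windows == self.total_windows


def make_windows(chrom_lengths: Mapping[str, int], config: ScanConfig) -> pd.DataFrame:
    """Tile chromosomes with sliding windows (1-based inclusive coordinates).

    Windows start at position 1 and advance by ``config.step``; they never
    cross chromosomes. A truncated terminal window is emitted only if it is
    at least one step long *and* extends past the previous window's end, so
    the chromosome tail is covered exactly once.
    """
    w, s = config.window_size, config.step
    rows = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise InputError(f"chromosome {chrom!r} has non-positive length {length}")
        prev_end = 0
        start = 1
        while start <= length:
            end = min(start + w - 1, length)
            if end - start + 1 >= s and end > prev_end:
                rows.append((chrom, start, end))
                prev_end = end
            start += s
        if prev_end == 0:
            # chromosome shorter than one step: cover it with a single window
            rows.append((chrom, 1, length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_stats(sites: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Per-window SNP count, summed pooled counts, and Hp.

    Sites must be sorted by position within each chromosome. A site belongs
    to every window with start <= pos <= end (overlapping windows count it
    more than once by construction). Windows with zero sites get Hp = NaN.
    """
    out = windows.copy()
    n = len(out)
    n_snps = np.zeros(n, dtype=np.int64)
    sum_major = np.zeros(n, dtype=np.int64)
    sum_minor = np.zeros(n, dtype=np.int64)
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise InputError(f"sites on chromosome {chrom} are not strictly increasing")
        cmaj = np.concatenate([[0], np.cumsum(grp["n_major"].to_numpy(dtype=np.int64))])
        cmin = np.concatenate([[0], np.cumsum(grp["n_minor"].to_numpy(dtype=np.int64))])
        mask = (out["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        lo = np.searchsorted(pos, out.loc[mask, "start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, out.loc[mask, "end"].to_numpy(), side="right")
        n_snps[mask] = hi - lo
        sum_major[mask] = cmaj[hi] - cmaj[lo]
        sum_minor[mask] = cmin[hi] - cmin[lo]
    out["n_snps"] = n_snps
    out["sum_major"] = sum_major
    out["sum_minor"] = sum_minor
    out["hp"] = pooled_heterozygosity(sum_major, sum_minor)
    return out


def pooled_heterozygosity(sum_major, sum_minor) -> np.ndarray:
    """Hp = 2*sum_major*sum_minor / (sum_major+sum_minor)^2; NaN for empty windows."""
    maj = np.asarray(sum_major, dtype=float)
    mino = np.asarray(sum_minor, dtype=float)
    tot = maj + mino
    with np.errstate(invalid="ignore", divide="ignore"):
        hp = np.where(tot > 0, 2.0 * maj * mino / (tot * tot), np.nan)
    return hp


def apply_min_snp_filter(windows: pd.DataFrame, config: ScanConfig) -> tuple[pd.DataFrame, int]:
    """Flag windows meeting the minimum-SNP requirement (inclusive bound).

    Returns the flagged table and the excluded-window count. Raises
    DegenerateDataError if no window passes (the Z-transform would be
    undefined).
    """
    out = windows.copy()
    out["passes_filter"] = out["n_snps"] >= config.min_snps
    n_excluded = int((~out["passes_filter"]).sum())
    if not out["passes_filter"].any():
        raise DegenerateDataError(
            f"no window has >= {config.min_snps} SNPs; cannot Z-transform a degenerate scan"
        )
    return out, n_excluded


def z_transform(windows: pd.DataFrame) -> tuple[pd.DataFrame, ScanSummary]:
    """Standardise Hp genome-wide over the windows passing the SNP filter.

    The mean and sample SD (n-1 denominator) are computed over passing
    windows only, pooled across chromosomes; excluded windows keep
    z_hp = NaN. Raises DegenerateDataError if fewer than two windows pass or
    the Hp values are constant.
    """
    out = windows.copy()
    passing = out["passes_filter"].to_numpy()
    hp = out.loc[passing, "hp"].to_numpy(dtype=float)
    if hp.size < 2:
        raise DegenerateDataError(
            f"only {hp.size} window(s) pass the SNP filter; need >= 2 to Z-transform"
        )
    mean = float(np.mean(hp))
    sd = float(np.std(hp, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("all analysed windows have identical Hp; SD is zero")
    out["z_hp"] = np.where(passing, (out["hp"] - mean) / sd, np.nan)
    summary = ScanSummary(
        total_windows=len(out),
        analyzed_windows=int(passing.sum()),
        excluded_windows=int((~passing).sum()),
        mean_hp=mean,
        sd_hp=sd,
    )
    return out, summary


class HpScan:
    """Pooled-heterozygosity scan model for one population.

    Parameters
    ----------
    sites : pandas.DataFrame
        SiteAlleleCounts table (columns chrom, pos, n_major, n_minor, ...),
        1-based positions sorted within chromosomes.
    chrom_lengths : mapping of chromosome name to length in bp.
    config : ScanConfig, optional
    population : str
        Label used in outputs.
    n_samples : int, optional
        Diploid sample count, reported in the summary table when known.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        chrom_lengths: Mapping[str, int],
        config: ScanConfig | None = None,
        population: str = "pop",
        n_samples: int | None = None,
    ) -> None:
        missing = {"chrom", "pos", "n_major", "n_minor"} - set(sites.columns)
        if missing:
            raise InputError(f"site table lacks required columns: {sorted(missing)}")
        self.sites = sites
        self.chrom_lengths = dict(chrom_lengths)
        self.config = config or ScanConfig()
        self.population = population
        self.n_samples = n_samples

    @classmethod
    def from_vcf(
        cls,
        vcf_path,
        populations,
        chrom_lengths: Mapping[str, int],
        config: ScanConfig | None = None,
        chrom_whitelist: Iterable[str] | None = None,
        drop_monomorphic: bool = False,
    ) -> dict[str, "HpScan"]:
        """Build one model per population from a multi-sample VCF.

        ``populations`` is a sequence of PopulationSpec. The chromosome
        whitelist defaults to the keys of ``chrom_lengths``.
        """
        from .ingest import read_biallelic_snps

        if chrom_whitelist is None:
            chrom_whitelist = list(chrom_lengths)
        tables, _ = read_biallelic_snps(
            vcf_path, populations, chrom_whitelist, drop_monomorphic=drop_monomorphic
        )
        return {
            spec.label: cls(
                tables[spec.label],
                chrom_lengths,
                config=config,
                population=spec.label,
                n_samples=len(spec.samples),
            )
            for spec in populations
        }

    def fit(self) -> "HpScanResults":
        """Run the windowing, SNP filter and genome-wide Z-transform."""
        cfg = self.config
        windows = make_windows(self.chrom_lengths, cfg)
        windows = window_stats(self.sites, windows)
        if cfg.filter_before_transform:
            windows, _ = apply_min_snp_filter(windows, cfg)
            windows, summary = z_transform(windows)
        else:
            # transform on all non-empty windows, then flag the filter
            windows["passes_filter"] = windows["n_snps"] > 0
            windows, summary = z_transform(windows)
            windows["passes_filter"] = windows["n_snps"] >= cfg.min_snps
            windows.loc[~windows["passes_filter"], "z_hp"] = np.nan
            summary = ScanSummary(
                total_windows=summary.total_windows,
                analyzed_windows=int(windows["passes_filter"].sum()),
                excluded_windows=int((~windows["passes_filter"]).sum()),
                mean_hp=summary.mean_hp,
                sd_hp=summary.sd_hp,
            )
        return HpScanResults(self, windows, summary)


class HpScanResults:
    """Fitted scan: the window table plus genome-wide moments and callers."""

    def __init__(self, model: HpScan, windows: pd.DataFrame, summary: ScanSummary) -> None:
        self.model = model
        self.windows = windows
        self.summary_ = summary

    @property
    def mean_hp(self) -> float:
        return self.summary_.mean_hp

    @property
    def sd_hp(self) -> float:
        return self.summary_.sd_hp

    @property
    def config(self) -> ScanConfig:
        return self.model.config

    @property
    def population(self) -> str:
        return self.model.population

    def significant_windows(self, threshold: float | None = None) -> pd.DataFrame:
        """Windows with Z(Hp) <= threshold among those passing the SNP filter."""
        return _regions.call_significant(self.windows, threshold if threshold is not None else self.config.z_threshold)

    def call_regions(
        self, threshold: float | None = None, max_gap: int | None = None
    ) -> pd.DataFrame:
        """Merge significant windows into candidate sweep regions."""
        sig = self.significant_windows(threshold)
        gap = self.config.max_merge_gap if max_gap is None else max_gap
        reg = _regions.merge_regions(sig, population=self.population, max_gap=gap)
        return _regions.annotate_snp_density(reg, self.model.sites)

    def summary_row(self) -> dict:
        """One row of the per-population summary table."""
        s = self.summary_
        n_sig = int(len(self.significant_windows()))
        n_regions = int(len(self.call_regions()))
        return {
            "population": self.population,
            "n_samples": self.model.n_samples,
            "total_windows": s.total_windows,
            "excluded_windows": s.excluded_windows,
            "mean_hp": s.mean_hp,
            "sd_hp": s.sd_hp,
            "windows_below_threshold": n_sig,
            "n_sweep_regions": n_regions,
        }

    def summary(self) -> str:
        """Human-readable genome summary in the style of a scan report table."""
        s = self.summary_
        row = self.summary_row()
        lines = [
            f"Pooled heterozygosity scan - population {self.population}",
            "=" * 58,
            f"Diploid samples:             {self.model.n_samples if self.model.n_samples is not None else 'n/a'}",
            f"Window / step (bp):          {self.config.window_size} / {self.config.step}",
            f"Total windows:               {s.total_windows}",
            f"Windows excluded (<{self.config.min_snps} SNPs): {s.excluded_windows}",
            f"Genome mean (Hp) +/- SD:     {s.mean_hp:.4f} +/- {s.sd_hp:.4f}",
            f"Windows with Z(Hp) <= {self.config.z_threshold:g}: {row['windows_below_threshold']}",
            f"Candidate sweep regions:     {row['n_sweep_regions']}",
        ]
        return "\n".join(lines)

    def manhattan_table(self) -> pd.DataFrame:
        """Plot-ready window table with cumulative genome coordinates."""
        from .report import export_manhattan_table

        return export_manhattan_table(
            self.windows, self.model.chrom_lengths, self.config.z_threshold
        )

    def plot_manhattan(self, ax=None):
        """Z(Hp) against cumulative genome position, chromosomes alternating shade."""
        import matplotlib.pyplot as plt

        tab = self.manhattan_table()
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        for parity, grp in tab.groupby("parity"):
            ax.scatter(
                grp["cum_pos"], grp["z_hp"], s=4,
                color="#1f4e79" if parity == 0 else "#7fa8d0",
            )
        ax.axhline(self.config.z_threshold, color="red", lw=0.8, ls="--")
        ax.set_xlabel("cumulative genome position (bp)")
        ax.set_ylabel("Z(Hp)")
        ax.set_title(f"{self.population}")
        return ax

    def to_tsv(self, path: str | Path) -> None:
        """Write the window table (the Manhattan-plot input) as TSV."""
        self.windows.to_csv(path, sep="\t", index=False, float_format="%.6g")
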