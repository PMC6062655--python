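"""Synthetic multi-sample VCFs with a neutral background and planted sweeps.

The generator emulates the downstream statistical structure of a pooled
whole-genome resequencing study of a few populations: a folded neutral
allele-frequency background (default minor-allele frequency uniform on
[0.05, 0.5]), SNP densities of order 10-20 SNPs/kb, occasional missing
genotypes, and planted sweep intervals in which minor-allele frequencies
collapse toward zero so that windowed pooled heterozygosity drops sharply.

Sites are drawn i.i.d. (no linkage): the Hp statistic consumes only per-site
pooled allele counts, so linkage structure is unnecessary for exercising it.

Each population gets its own RNG stream derived from the master seed and the
CRC-32 of the population label, so adding or removing a population never
perturbs the data simulated for the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class MafDistribution:
    """Named folded allele-frequency family for the neutral background.

    Supported families: ``uniform`` (params: low, high) on the minor-allele
    frequency, and ``beta`` (params: a, b) rescaled to [0, 0.5].
    """

    family: str = "uniform"
    params: tuple[float, ...] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.family == "uniform":
            low, high = self.params
            if not (0 <= low < high <= 0.5):
                raise ConfigError(
                    f"uniform MAF bounds must satisfy 0 <= low < high <= 0.5, got {self.params}"
                )
        elif self.family == "beta":
            a, b = self.params
            if a <= 0 or b <= 0:
                raise ConfigError(f"beta MAF parameters must be positive, got {self.params}")
        else:
            raise ConfigError(f"unknown MAF family {self.family!r}")

    @property
    def support_low(self) -> float:
        """Lower bound of the folded-frequency support."""
        return self.params[0] if self.family == "uniform" else 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "uniform":
            low, high = self.params
            return rng.uniform(low, high, size=size)
        a, b = self.params
        return 0.5 * rng.beta(a, b, size=size)


@dataclass(frozen=True)
class Sweep:
    """A planted sweep: an interval whose minor-allele frequencies are capped.

    Coordinates are 1-based inclusive. ``populations`` restricts the sweep to
    a subset of population labels; ``None`` plants it in every population.
    """

    chrom: str
    start: int
    end: int
    maf_ceiling: float = 0.02
    populations: tuple[str, ...] | None = None

    def applies_to(self, label: str) -> bool:
        return self.populations is None or label in self.populations


def _default_sweeps() -> tuple[Sweep, ...]:
    return (
        Sweep("1", 1_000_001, 1_200_000, 0.02),
        Sweep("1", 3_000_001, 3_040_000, 0.02),
        Sweep("2", 2_000_001, 2_100_000, 0.02),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the scale at which the scan is exercised end to end:
    two 5-Mb chromosomes, 10 diploid samples per population, 14 SNPs/kb, and
    three planted sweeps of 40-200 kb whose minor-allele frequencies are
    capped at 0.02 (well below the neutral background's 0.05 floor).
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"1": 5_000_000, "2": 5_000_000}
    )
    n_diploid_samples: int = 10
    snp_density: float = 14.0  # expected SNPs per kb
    background_maf: MafDistribution = field(default_factory=MafDistribution)
    sweeps: tuple[Sweep, ...] = field(default_factory=_default_sweeps)
    missing_rate: float = 0.02
    populations: tuple[str, ...] = ("pop1",)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths must not be empty")
        for chrom, length in self.chrom_lengths.items():
            if length < 1:
                raise ConfigError(f"chromosome {chrom!r} has non-positive length {length}")
        if self.n_diploid_samples <= 0:
            raise ConfigError(f"n_diploid_samples must be > 0, got {self.n_diploid_samples}")
        if not (np.isfinite(self.snp_density) and self.snp_density > 0):
            raise ConfigError(f"snp_density must be finite and > 0, got {self.snp_density}")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not self.populations:
            raise ConfigError("at least one population label is required")
        if len(set(self.populations)) != len(self.populations):
            raise ConfigError("population labels must be unique")
        by_chrom: dict[str, list[Sweep]] = {}
        for sw in self.sweeps:
            if sw.chrom not in self.chrom_lengths:
                raise ConfigError(f"sweep on unknown chromosome {sw.chrom!r}")
            if not (1 <= sw.start <= sw.end <= self.chrom_lengths[sw.chrom]):
                raise ConfigError(
                    f"sweep {sw.chrom}:{sw.start}-{sw.end} lies outside its chromosome"
                )
            if not (0 <= sw.maf_ceiling <= 0.5):
                raise ConfigError(f"sweep MAF ceiling must be in [0, 0.5], got {sw.maf_ceiling}")
            if sw.maf_ceiling >= self.background_maf.support_low and sw.maf_ceiling > 0:
                raise ConfigError(
                    f"sweep MAF ceiling {sw.maf_ceiling} must lie below the background MAF "
                    f"support lower bound {self.background_maf.support_low} so the sweep "
                    "depresses heterozygosity"
                )
            by_chrom.setdefault(sw.chrom, []).append(sw)
        for chrom, sweeps in by_chrom.items():
            ordered = sorted(sweeps, key=lambda s: s.start)
            for a, b in zip(ordered, ordered[1:]):
                if b.start <= a.end:
                    raise ConfigError(
                        f"overlapping sweep intervals on chromosome {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )


@dataclass
class SimTruth:
    """Planted-sweep truth emitted alongside the simulated VCFs."""

    sweeps: tuple[Sweep, ...]
    realized_snp_counts: dict[str, dict[str, int]]  # population -> chrom -> n sites
    seed: int

    def validate(self) -> None:
        for pop, counts in self.realized_snp_counts.items():
            for chrom, n in counts.items():
                if n <= 0:
                    raise InputError(
                        f"no sites realized on chromosome {chrom} for population {pop}"
                    )


def sim_config_from_dict(raw: dict, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from a parsed YAML/JSON mapping; ``seed`` overrides."""
    raw = dict(raw)
    if "background_maf" in raw:
        bm = raw["background_maf"]
        raw["background_maf"] = MafDistribution(
            family=bm.get("family", "uniform"), params=tuple(bm.get("params", (0.05, 0.5)))
        )
    if "sweeps" in raw:
        sweeps = []
        for sw in raw["sweeps"]:
            sw = dict(sw)
            if sw.get("populations") is not None:
                sw["populations"] = tuple(sw["populations"])
            sweeps.append(Sweep(**sw))
        raw["sweeps"] = tuple(sweeps)
    if "populations" in raw:
        raw["populations"] = tuple(raw["populations"])
    if "chrom_lengths" in raw:
        raw["chrom_lengths"] = {str(k): int(v) for k, v in raw["chrom_lengths"].items()}
    if seed is not None:
        raw["seed"] = seed
    try:
        return SimConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"bad simulation config: {exc}") from exc


def population_rng(seed: int, label: str) -> np.random.Generator:
    """Per-population RNG stream: seeded with (master seed, CRC-32 of label)."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def simulate_sites(config: SimConfig, population: str | None = None) -> pd.DataFrame:
    """Draw a site table for one population.

    Returns a DataFrame with columns ``chrom, pos, ref, alt, freq`` where
    ``freq`` is the true alt-allele frequency. Positions are strictly
    increasing within each chromosome. Site counts per chromosome are
    Poisson(snp_density per kb x length); sites inside a sweep interval that
    applies to this population draw a folded frequency no larger than the
    sweep's MAF ceiling.
    """
    if population is None:
        population = config.populations[0]
    if population not in config.populations:
        raise ConfigError(f"unknown population label {population!r}")
    rng = population_rng(config.seed, population)
    frames = []
    for chrom, length in config.chrom_lengths.items():
        n = rng.poisson(config.snp_density / 1000.0 * length)
        n = min(n, length)  # positions are distinct bp
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        maf = config.background_maf.sample(rng, n)
        for sw in config.sweeps:
            if sw.chrom != chrom or not sw.applies_to(population):
                continue
            inside = (pos >= sw.start) & (pos <= sw.end)
            maf[inside] = rng.uniform(0.0, sw.maf_ceiling, size=int(inside.sum()))
        # fold: the capped/background MAF lands on either allele
        flip = rng.random(n) < 0.5
        freq = np.where(flip, 1.0 - maf, maf)
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                    "freq": freq,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def genotype_samples(
    sites: pd.DataFrame,
    n_diploid_samples: int,
    missing_rate: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw diploid genotypes at each site.

    Returns an int8 array of shape (n_sites, n_samples, 2) with allele codes
    0 (ref) / 1 (alt); a genotype masked missing has both entries -1. Each
    allele is an independent Bernoulli draw at the site's alt frequency;
    genotypes go missing independently at ``missing_rate``.
    """
    if n_diploid_samples <= 0:
        raise ConfigError(f"n_diploid_samples must be > 0, got {n_diploid_samples}")
    if not (0 <= missing_rate < 1):
        raise ConfigError(
            f"missing_rate must be in [0, 1): rate {missing_rate} leaves no callable genotypes"
        )
    freq = np.asarray(sites["freq"], dtype=float)
    if freq.size and (freq.min() < 0 or freq.max() > 1):
        raise InputError("site frequencies must lie in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_sites = len(freq)
    geno = (
        rng.random((n_sites, n_diploid_samples, 2)) < freq[:, None, None]
    ).astype(np.int8)
    if missing_rate > 0:
        missing = rng.random((n_sites, n_diploid_samples)) < missing_rate
        geno[missing] = -1
    return geno


def pool_genotype_matrix(genotypes: np.ndarray) -> pd.DataFrame:
    """Brute-force pooled ref/alt allele counts from a genotype matrix.

    Missing alleles (-1) are excluded from both counts. Serves as the
    round-trip oracle for the VCF writer + reader path.
    """
    called = genotypes >= 0
    n_alt = np.where(called, genotypes, 0).sum(axis=(1, 2))
    n_called = called.sum(axis=(1, 2))
    return pd.DataFrame({"n_ref": n_called - n_alt, "n_alt": n_alt})


def write_vcf(
    sites: pd.DataFrame,
    genotypes: np.ndarray,
    sample_names: Sequence[str],
    chrom_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write a minimal GT-only VCF 4.2 file.

    Records are bi-allelic SNPs; missing genotypes are encoded ``./.``.
    Requires sites sorted by (chromosome in header order, position).
    """
    if len(sites) != len(genotypes):
        raise InputError("site table and genotype matrix have different lengths")
    order = {c: i for i, c in enumerate(chrom_lengths)}
    chrom_idx = sites["chrom"].map(order)
    if chrom_idx.isna().any():
        bad = sites.loc[chrom_idx.isna(), "chrom"].iloc[0]
        raise InputError(f"site on chromosome {bad!r} absent from chrom_lengths")
    key = list(zip(chrom_idx, sites["pos"]))
    if any(b <= a for a, b in zip(key, key[1:])):
        raise InputError("sites must be sorted by chromosome and strictly increasing position")

    gt_codes = {-1: ".", 0: "0", 1: "1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hpscan-simulate\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        chroms = sites["chrom"].to_numpy()
        poss = sites["pos"].to_numpy()
        refs = sites["ref"].to_numpy()
        alts = sites["alt"].to_numpy()
        for i in range(len(sites)):
            gts = "\t".join(
                f"{gt_codes[int(a)]}/{gt_codes[int(b)]}" for a, b in genotypes[i]
            )
            fh.write(
                f"{chroms[i]}\t{poss[i]}\t.\t{refs[i]}\t{alts[i]}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Write planted sweeps as a BED file (0-based half-open).

    Column 4 carries the sweep's MAF ceiling; column 5 lists the populations
    the sweep applies to ('*' = all).
    """
    rows = sorted(truth.sweeps, key=lambda s: (s.chrom, s.start))
    with open(path, "w") as fh:
        for sw in rows:
            pops = "*" if sw.populations is None else ",".join(sw.populations)
            fh.write(f"{sw.chrom}\t{sw.start - 1}\t{sw.end}\t{sw.maf_ceiling}\t{pops}\n")


def simulate_population(
    config: SimConfig, population: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Site table plus genotype matrix for one population.

    Sites and genotypes use two sub-streams of the population's seed sequence
    so either can be regenerated independently.
    """
    sites = simulate_sites(config, population)
    geno_rng = np.random.default_rng(
        [config.seed, zlib.crc32(population.encode()), 1]
    )
    genotypes = genotype_samples(
        sites, config.n_diploid_samples, config.missing_rate, geno_rng
    )
    return sites, genotypes


def sample_names(config: SimConfig, population: str) -> list[str]:
    return [f"{population}_s{i:02d}" for i in range(config.n_diploid_samples)]


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> SimTruth:
    """Simulate every population, writing one VCF per population plus truth files.

    Outputs in ``out_dir``: ``<pop>.vcf`` per population, ``truth.bed`` with
    the planted sweeps, and ``populations.tsv`` (sample, population).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    realized: dict[str, dict[str, int]] = {}
    pop_rows = []
    for pop in config.populations:
        sites, genotypes = simulate_population(config, pop)
        names = sample_names(config, pop)
        write_vcf(sites, genotypes, names, config.chrom_lengths, out / f"{pop}.vcf")
        realized[pop] = sites.groupby("chrom", sort=False).size().to_dict()
        pop_rows += [(n, pop) for n in names]
    truth = SimTruth(sweeps=tuple(config.sweeps), realized_snp_counts=realized, seed=config.seed)
    truth.validate()
    write_truth(truth, out / "truth.bed")
    pd.DataFrame(pop_rows).to_csv(
        out / "populations.tsv", sep="\t", header=False, index=False
    )
    return truth
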