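"""Read multi-sample VCFs and pool per-site allele counts within populations.

Only bi-allelic SNPs on whitelisted chromosomes are kept, matching the usual
restriction of pooled-heterozygosity scans to bi-allelic autosomal SNPs. For
each retained site and each population we count the pooled major and minor
alleles across that population's called genotypes:

* the major allele is the more frequent allele *within this population* at
  this site; ties are broken by calling the reference allele major (the
  statistic downstream is symmetric in the two counts, so the tie rule only
  fixes labelling);
* missing alleles are excluded from both counts, so the denominator reflects
  observed alleles only;
* a site with zero called alleles in a population is dropped for that
  population and logged;
* sites that are monomorphic within a population (minor count 0) are
  retained by default — a site fixed in one population but variable in the
  joint call set is exactly the depressed-heterozygosity signal the scan
  looks for. Pass ``drop_monomorphic=True`` to exclude them instead.

The per-population result is a pandas DataFrame with columns
``chrom, pos, ref, alt, n_major, n_minor, major_is_ref`` (positions 1-based),
the SiteAlleleCounts table consumed by the windowed scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import InputError

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "n_major", "n_minor", "major_is_ref"]

# cyvcf2 gt_types codes
_HOM_REF, _HET, _UNKNOWN, _HOM_ALT = 0, 1, 2, 3


@dataclass(frozen=True)
class PopulationSpec:
    """A population label and the VCF sample IDs belonging to it."""

    label: str
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.samples:
            raise InputError(f"population {self.label!r} has no samples")
        if len(set(self.samples)) != len(self.samples):
            raise InputError(f"population {self.label!r} has duplicate sample IDs")


@dataclass
class DropLog:
    """Per-category tallies of records and sites excluded during ingest."""

    multiallelic: int = 0
    non_snp: int = 0
    off_chromosome: int = 0
    no_called_alleles: dict[str, int] = field(default_factory=dict)
    monomorphic_dropped: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "multiallelic": self.multiallelic,
            "non_snp": self.non_snp,
            "off_chromosome": self.off_chromosome,
            "no_called_alleles": dict(self.no_called_alleles),
            "monomorphic_dropped": dict(self.monomorphic_dropped),
        }


def read_population_file(path: str | Path) -> list[PopulationSpec]:
    """Read a two-column (sample, population) TSV into PopulationSpecs."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    if df.isna().any().any():
        raise InputError(f"population file {path} has missing fields")
    specs = []
    for label, grp in df.groupby("population", sort=False):
        specs.append(PopulationSpec(label=str(label), samples=tuple(grp["sample"])))
    return specs


def pool_allele_counts(alleles: np.ndarray) -> tuple[int, int, bool] | None:
    """Pool one population's genotypes at one bi-allelic site.

    ``alleles`` is an integer array (any shape) of allele codes 0 (ref),
    1 (alt), -1 (missing). Returns (n_major, n_minor, major_is_ref), or None
    if no allele is called (the site is dropped).
    """
    a = np.asarray(alleles).ravel()
    n_alt = int((a == 1).sum())
    n_ref = int((a == 0).sum())
    if n_ref + n_alt == 0:
        return None
    if n_ref >= n_alt:  # tie -> reference allele labelled major
        return n_ref, n_alt, True
    return n_alt, n_ref, False


def read_biallelic_snps(
    vcf_path: str | Path,
    populations: Sequence[PopulationSpec],
    chrom_whitelist: Iterable[str] | None = None,
    drop_monomorphic: bool = False,
) -> tuple[dict[str, pd.DataFrame], DropLog]:
    """Stream a VCF into per-population pooled site tables.

    Multi-allelic records, non-SNP records (indels etc.) and records on
    chromosomes outside the whitelist are dropped and tallied. Raises
    InputError if a listed sample is absent from the VCF or if records are
    out of order.
    """
    vcf_path = str(vcf_path)
    try:
        vcf = VCF(vcf_path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise InputError(f"cannot open VCF {vcf_path}: {exc}") from exc
    vcf_samples = list(vcf.samples)
    sample_index = {s: i for i, s in enumerate(vcf_samples)}
    labels = [p.label for p in populations]
    if len(set(labels)) != len(labels):
        raise InputError(f"duplicate population labels: {labels}")
    pop_idx: dict[str, np.ndarray] = {}
    for spec in populations:
        missing = [s for s in spec.samples if s not in sample_index]
        if missing:
            raise InputError(
                f"sample(s) {missing} of population {spec.label!r} not present in {vcf_path}"
            )
        pop_idx[spec.label] = np.array([sample_index[s] for s in spec.samples])

    whitelist = set(chrom_whitelist) if chrom_whitelist is not None else None
    log = DropLog(
        no_called_alleles={p.label: 0 for p in populations},
        monomorphic_dropped={p.label: 0 for p in populations},
    )
    rows: dict[str, list[tuple]] = {p.label: [] for p in populations}
    last_key: tuple[str, int] | None = None
    record_no = 0
    for v in vcf:
        record_no += 1
        if whitelist is not None and v.CHROM not in whitelist:
            log.off_chromosome += 1
            continue
        if len(v.ALT) != 1:
            log.multiallelic += 1
            continue
        if not v.is_snp:
            log.non_snp += 1
            continue
        key = (v.CHROM, v.POS)
        if last_key is not None and key[0] == last_key[0] and key[1] <= last_key[1]:
            raise InputError(
                f"{vcf_path}: record {record_no} ({v.CHROM}:{v.POS}) is out of order"
            )
        last_key = key
        gt = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        for label, idx in pop_idx.items():
            sub = gt[idx]
            n_het = int((sub == _HET).sum())
            n_hom_alt = int((sub == _HOM_ALT).sum())
            n_called = 2 * int((sub != _UNKNOWN).sum())
            n_alt = n_het + 2 * n_hom_alt
            n_ref = n_called - n_alt
            if n_called == 0:
                log.no_called_alleles[label] += 1
                continue
            if n_ref >= n_alt:
                n_major, n_minor, major_is_ref = n_ref, n_alt, True
            else:
                n_major, n_minor, major_is_ref = n_alt, n_ref, False
            if drop_monomorphic and n_minor == 0:
                log.monomorphic_dropped[label] += 1
                continue
            rows[label].append(
                (v.CHROM, v.POS, v.REF, v.ALT[0], n_major, n_minor, major_is_ref)
            )
    vcf.close()

    tables = {
        label: pd.DataFrame(rows[label], columns=SITE_COLUMNS)
        for label in rows
    }
    for label, df in tables.items():
        df["pos"] = df["pos"].astype(np.int64) if len(df) else df["pos"]
    logger.info(
        "ingest %s: dropped %d multiallelic, %d non-SNP, %d off-chromosome records",
        vcf_path,
        log.multiallelic,
        log.non_snp,
        log.off_chromosome,
    )
    return tables, log


def site_key_set(sites: pd.DataFrame) -> set[tuple]:
    """Identity keys (chrom, pos, ref, alt) for SNP-sharing set algebra."""
    return set(
        zip(sites["chrom"], sites["pos"].astype(int), sites["ref"], sites["alt"])
    )
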