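"""Pipeline composition: scan runs, cross-population comparison, plot export.

These functions tie the ingest, scan and region modules into the file-level
pipeline the CLI exposes. Every scan run writes a resolved-configuration
snapshot next to its outputs so downstream comparison can verify that two
scans used identical parameters, and so a run is reproducible from its
output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .config import ScanConfig
from .errors import ConfigError, InputError
from .ingest import PopulationSpec, read_biallelic_snps, read_population_file, site_key_set
from .regions import (
    call_significant,
    intersect_populations,
    regions_to_bed,
    shared_snp_counts,
    venn_table,
)
from .scan import HpScan, HpScanResults

logger = logging.getLogger(__name__)


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Two-column (chromosome, length-in-bp) TSV, no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype=str)
    try:
        return {str(c): int(l) for c, l in zip(df["chrom"], df["length"])}
    except ValueError as exc:
        raise InputError(f"bad chromosome-length table {path}: {exc}") from exc


@dataclass
class PipelineConfig:
    """Everything a scan run needs: inputs, parameters, output location."""

    vcfs: tuple[str, ...]
    population_file: str
    chrom_lengths_file: str
    out_dir: str
    scan: ScanConfig = field(default_factory=ScanConfig)
    wild_label: str | None = None
    drop_monomorphic: bool = False
    log_level: str = "INFO"
    seed: int = 0

    def validate(self) -> None:
        for p in (*self.vcfs, self.population_file, self.chrom_lengths_file):
            if not Path(p).exists():
                raise ConfigError(f"input file does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scan = ScanConfig.from_dict(raw.pop("scan", {}) or {})
        known = {f.name for f in dataclasses.fields(cls)} - {"scan"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        raw["vcfs"] = tuple(raw.get("vcfs", ()))
        return cls(scan=scan, **raw)


def run_scan(config: PipelineConfig) -> dict[str, HpScanResults]:
    """Scan every population found in the configured VCFs.

    Writes, per population: the window table (``<pop>.windows.tsv``, the
    Manhattan-plot input), the pooled site table (``<pop>.sites.tsv``), and
    the candidate regions (``<pop>.regions.tsv`` / ``.bed``); plus a
    per-population summary table (``summary.tsv``) and the resolved scan
    configuration (``scan_config.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom_lengths = _stage("chromosome table", read_chrom_lengths, config.chrom_lengths_file)
    specs = _stage("population file", read_population_file, config.population_file)
    by_label = {s.label: s for s in specs}

    results: dict[str, HpScanResults] = {}
    summary_rows = []
    for vcf_path in config.vcfs:
        from cyvcf2 import VCF

        vcf_samples = set(VCF(str(vcf_path)).samples)
        here = [s for s in specs if set(s.samples) <= vcf_samples and s.label not in results]
        if not here:
            continue
        tables, drop_log = _stage(
            "variant ingest",
            read_biallelic_snps,
            vcf_path,
            here,
            list(chrom_lengths),
            config.drop_monomorphic,
        )
        logger.info("dropped records: %s", drop_log.as_dict())
        for spec in here:
            model = HpScan(
                tables[spec.label],
                chrom_lengths,
                config=config.scan,
                population=spec.label,
                n_samples=len(spec.samples),
            )
            res = _stage(f"scan of {spec.label}", model.fit)
            results[spec.label] = res
            res.to_tsv(out / f"{spec.label}.windows.tsv")
            tables[spec.label].to_csv(out / f"{spec.label}.sites.tsv", sep="\t", index=False)
            reg = res.call_regions()
            reg.to_csv(out / f"{spec.label}.regions.tsv", sep="\t", index=False)
            regions_to_bed(reg, out / f"{spec.label}.regions.bed")
            summary_rows.append(res.summary_row())
            logger.info(
                "%s: %d/%d windows analysed, %d excluded, %d regions",
                spec.label,
                res.summary_.analyzed_windows,
                res.summary_.total_windows,
                res.summary_.excluded_windows,
                len(reg),
            )
    missing = set(by_label) - set(results)
    if not results:
        raise InputError(
            "no population's samples were found in any supplied VCF"
        )
    if missing:
        logger.warning(
            "populations %s have samples absent from every supplied VCF; skipped",
            sorted(missing),
        )
    pd.DataFrame(summary_rows).to_csv(out / "summary.tsv", sep="\t", index=False)
    snapshot = {
        "scan": config.scan.to_dict(),
        "chrom_lengths": chrom_lengths,
        "populations": sorted(results),
        "seed": config.seed,
        "drop_monomorphic": config.drop_monomorphic,
    }
    (out / "scan_config.json").write_text(json.dumps(snapshot, indent=2))
    return results


def run_compare(
    scan_dirs: Sequence[str | Path],
    out_dir: str | Path,
    wild_label: str | None = None,
    min_populations: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-population sharing of sweep regions and SNPs from scan outputs.

    All scans must have used identical ScanConfig and chromosome tables
    (checked against their resolved-config snapshots). Writes
    ``shared_regions.tsv`` (window-level intersections with sharing classes)
    and ``venn_snps.tsv`` (exclusive shared/unique SNP counts).
    """
    snapshots = []
    for d in scan_dirs:
        snap_path = Path(d) / "scan_config.json"
        if not snap_path.exists():
            raise ConfigError(f"{d} is not a scan output directory (no scan_config.json)")
        snapshots.append(json.loads(snap_path.read_text()))
    ref = {k: snapshots[0][k] for k in ("scan", "chrom_lengths")}
    for d, snap in zip(scan_dirs, snapshots):
        if {k: snap[k] for k in ("scan", "chrom_lengths")} != ref:
            raise ConfigError(
                f"scan in {d} used a different configuration; comparison refused"
            )

    sig_by_pop: dict[str, pd.DataFrame] = {}
    sites_by_pop: dict[str, set] = {}
    threshold = ref["scan"]["z_threshold"]
    for d, snap in zip(scan_dirs, snapshots):
        for pop in snap["populations"]:
            if pop in sig_by_pop:
                raise ConfigError(f"population {pop!r} appears in more than one scan dir")
            windows = pd.read_csv(Path(d) / f"{pop}.windows.tsv", sep="\t", dtype={"chrom": str})
            sig_by_pop[pop] = call_significant(windows, threshold)
            sites = pd.read_csv(Path(d) / f"{pop}.sites.tsv", sep="\t", dtype={"chrom": str})
            sites_by_pop[pop] = site_key_set(sites)
    if len(sig_by_pop) < 2:
        raise ConfigError("comparison needs at least two populations")

    shared = intersect_populations(sig_by_pop, wild_label=wild_label, min_populations=min_populations)
    venn = venn_table(shared_snp_counts(sites_by_pop))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shared.to_csv(out / "shared_regions.tsv", sep="\t", index=False)
    venn.to_csv(out / "venn_snps.tsv", sep="\t", index=False)
    return shared, venn


def export_manhattan_table(
    windows: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    z_threshold: float,
) -> pd.DataFrame:
    """Window table with cumulative genome coordinates for Manhattan plots.

    Chromosomes are laid end to end in the order of ``chrom_lengths``;
    ``parity`` alternates 0/1 per chromosome for two-tone plotting. The
    threshold is attached as table metadata (``.attrs['z_threshold']``).
    Chromosomes with no windows are skipped with a warning.
    """
    windows = windows.assign(chrom=windows["chrom"].astype(str))
    frames = []
    offset = 0
    parity = 0
    for chrom, length in chrom_lengths.items():
        grp = windows[windows["chrom"] == str(chrom)]
        if grp.empty:
            warnings.warn(f"chromosome {chrom} has no windows; skipped in Manhattan export")
            offset += length
            continue
        g = grp.copy()
        g["cum_pos"] = g["start"] + offset
        g["cum_end"] = g["end"] + offset
        g["parity"] = parity
        frames.append(g)
        offset += length
        parity ^= 1
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = windows.iloc[0:0].copy()
        out[["cum_pos", "cum_end", "parity"]] = None
    out.attrs["z_threshold"] = z_threshold
    return out


def _stage(name: str, fn, *args):
    """Run one pipeline stage, prefixing any error with the stage name."""
    try:
        return fn(*args)
    except Exception as exc:
        if hasattr(exc, "exit_code"):
            exc.args = (f"[{name}] {exc}",)
            raise
        raise InputError(f"[{name}] {exc}") from exc
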