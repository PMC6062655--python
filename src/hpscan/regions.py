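"""Candidate sweep regions: calling, merging, density, cross-population sharing.

Significant windows (Z(Hp) <= threshold, inclusive) that overlap or abut on
one chromosome are merged into a single candidate region spanning their
union; with full 20-kb windows on a 10-kb step, a run of k windows spans
20 + (k-1)*10 kb, so region sizes fall on a 10-kb lattice. Region SNP
density follows the reporting convention of dividing the SNP count by the
region's *nominal* length (the span rounded to the nearest 10 kb, in kb) and
rounding half-up to an integer.

Sharing across populations is decided at the window level: a shared region
is a maximal interval covered by significant windows in *every* member
population, not merely an overlap of the merged regions.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

REGION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "span",
    "n_windows",
    "mean_zhp",
    "sd_zhp",
    "population",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up."""
    return int(math.floor(x + 0.5))


def call_significant(windows: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Windows that pass the SNP filter and have Z(Hp) <= threshold.

    The bound is inclusive: a window exactly at the threshold is significant.
    Windows excluded by the SNP filter have undefined Z(Hp) and are never
    significant.
    """
    ok = windows["passes_filter"] & windows["z_hp"].notna() & (windows["z_hp"] <= threshold)
    return windows.loc[ok].reset_index(drop=True)


def merge_regions(
    significant: pd.DataFrame, population: str = "pop", max_gap: int = 0
) -> pd.DataFrame:
    """Merge overlapping/abutting significant windows into candidate regions.

    Windows merge when the next window starts no more than ``max_gap + 1`` bp
    after the current region's end (gap 0 = overlapping or abutting only).
    Each region records its span (end - start + 1), member-window count, and
    the mean and sample SD of member Z(Hp) (SD 0 for a single window).
    """
    if max_gap < 0:
        raise ConfigError(f"max_gap must be >= 0, got {max_gap}")
    rows = []
    if len(significant):
        df = significant.sort_values(["chrom", "start"], kind="mergesort")
        cur = None  # [chrom, start, end, zhp_list]
        for chrom, start, end, zhp in zip(
            df["chrom"], df["start"], df["end"], df["z_hp"]
        ):
            if cur is not None and chrom == cur[0] and start <= cur[2] + 1 + max_gap:
                cur[2] = max(cur[2], end)
                cur[3].append(zhp)
            else:
                if cur is not None:
                    rows.append(cur)
                cur = [chrom, int(start), int(end), [zhp]]
        rows.append(cur)
    out = []
    for chrom, start, end, zhps in rows:
        z = np.asarray(zhps, dtype=float)
        out.append(
            (
                chrom,
                start,
                end,
                end - start + 1,
                len(z),
                float(np.mean(z)),
                float(np.std(z, ddof=1)) if len(z) > 1 else 0.0,
                population,
            )
        )
    return pd.DataFrame(out, columns=REGION_COLUMNS)


def nominal_length_kb(span: int) -> int:
    """Region length rounded to the nearest 10 kb, in kb (reporting convention)."""
    if span <= 0:
        raise InputError(f"zero-length region (span {span})")
    return 10 * round_half_up(span / 10_000.0)


def region_snp_density(
    start: int, end: int, positions: Sequence[int] | np.ndarray
) -> tuple[int, int]:
    """SNP count in [start, end] and rounded SNPs/kb over the nominal length.

    ``positions`` are the population's sorted site positions on the region's
    chromosome. Density = round-half-up(count / nominal length in kb), with
    the nominal length being the span rounded to the nearest 10 kb; regions
    shorter than 5 kb fall back to the exact span in kb.
    """
    span = end - start + 1
    if span <= 0:
        raise InputError(f"zero-length region {start}-{end}")
    pos = np.asarray(positions)
    count = int(np.searchsorted(pos, end, side="right") - np.searchsorted(pos, start, side="left"))
    kb = nominal_length_kb(span)
    if kb == 0:
        kb_exact = span / 1000.0
        return count, round_half_up(count / kb_exact)
    return count, round_half_up(count / kb)


def annotate_snp_density(regions: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Add n_snps and snps_per_kb columns to a region table."""
    out = regions.copy()
    counts, densities = [], []
    by_chrom = {c: g["pos"].to_numpy() for c, g in sites.groupby("chrom", sort=False)}
    for chrom, start, end in zip(out["chrom"], out["start"], out["end"]):
        pos = by_chrom.get(chrom, np.array([], dtype=np.int64))
        c, d = region_snp_density(int(start), int(end), pos)
        counts.append(c)
        densities.append(d)
    out["n_snps"] = counts
    out["snps_per_kb"] = densities
    return out


def _merged_intervals(windows: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    """Union of windows per chromosome as sorted half-open (start, end+1) pairs."""
    result: dict[str, list[tuple[int, int]]] = {}
    if windows.empty:
        return result
    for chrom, grp in windows.groupby("chrom", sort=False):
        ivs = sorted(zip(grp["start"].astype(int), grp["end"].astype(int) + 1))
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        result[chrom] = [(s, e) for s, e in merged]
    return result


def sharing_class(
    members: frozenset, all_populations: frozenset, wild_label: str | None
) -> str:
    """Name the sharing class of a region covered by exactly ``members``.

    With a designated wild population the classes are: all-domestic+wild,
    all-domestic, domestic+wild (any smaller group including the wild
    population), domestic-pair (two or more domestic populations), unique.
    Without one: all-populations / shared-by-k / unique.
    """
    k = len(members)
    if wild_label is not None and wild_label in all_populations:
        domestic = all_populations - {wild_label}
        if members == all_populations:
            return "all-domestic+wild"
        if members == domestic:
            return "all-domestic"
        if wild_label in members and k >= 2:
            return "domestic+wild"
        if k >= 2:
            return "domestic-pair"
        return "unique"
    if members == all_populations:
        return "all-populations"
    if k >= 2:
        return f"shared-by-{k}"
    return "unique"


def intersect_populations(
    significant_by_pop: Mapping[str, pd.DataFrame],
    wild_label: str | None = None,
    min_populations: int = 1,
) -> pd.DataFrame:
    """Window-level cross-population sharing table.

    ``significant_by_pop`` maps population label to that population's
    significant-window table (columns chrom, start, end). The genome is
    partitioned into maximal intervals with a constant set of covering
    populations; each interval covered by at least ``min_populations``
    populations becomes one row with per-population presence flags and a
    sharing class. Shared coordinates are therefore the intersection of the
    contributing windows, never the union of the merged regions.
    """
    labels = sorted(significant_by_pop)
    if len(labels) < 2:
        raise ConfigError("intersect_populations needs at least two populations")
    all_pops = frozenset(labels)
    return _build_sharing_table(significant_by_pop, labels, all_pops, wild_label, min_populations)


def _build_sharing_table(significant_by_pop, labels, all_pops, wild_label, min_populations):
    per_pop = {lab: _merged_intervals(significant_by_pop[lab]) for lab in labels}
    chroms = sorted({c for lab in labels for c in per_pop[lab]})
    records = []
    for chrom in chroms:
        points = sorted(
            {p for lab in labels for s, e in per_pop[lab].get(chrom, []) for p in (s, e)}
        )
        open_row = None  # [members, start, end_halfopen]
        for a, b in zip(points, points[1:]):
            members = frozenset(
                lab
                for lab in labels
                if any(s <= a and b <= e for s, e in per_pop[lab].get(chrom, []))
            )
            if len(members) < max(min_populations, 1):
                if open_row:
                    records.append((chrom, *open_row))
                    open_row = None
                continue
            if open_row and open_row[0] == members and open_row[2] == a:
                open_row[2] = b
            else:
                if open_row:
                    records.append((chrom, *open_row))
                open_row = [members, a, b]
        if open_row:
            records.append((chrom, *open_row))
    rows = []
    for chrom, members, s, e in records:
        row = {
            "chrom": chrom,
            "start": s,
            "end": e - 1,  # back to 1-based inclusive
            "n_pops": len(members),
            "sharing_class": sharing_class(members, all_pops, wild_label),
            "populations": ",".join(sorted(members)),
        }
        for lab in labels:
            row[f"in_{lab}"] = lab in members
        rows.append(row)
    cols = ["chrom", "start", "end", "n_pops", "sharing_class", "populations"] + [
        f"in_{lab}" for lab in labels
    ]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def shared_snp_counts(site_sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Exclusive Venn-region SNP counts for any grouping of populations.

    Sites are identity keys (chrom, pos, ref, alt). The returned dict maps
    each non-empty population subset to the number of sites found in exactly
    that subset; summing over subsets containing a population recovers its
    total, so inclusion-exclusion identities hold exactly.
    """
    membership: dict[tuple, set[str]] = {}
    for label, sites in site_sets.items():
        for key in sites:
            membership.setdefault(key, set()).add(label)
    counts: dict[frozenset, int] = {}
    for mem in membership.values():
        counts[frozenset(mem)] = counts.get(frozenset(mem), 0) + 1
    return counts


def venn_table(counts: dict[frozenset, int]) -> pd.DataFrame:
    """Exclusive Venn counts as a tidy table, largest groups first."""
    rows = [
        {"populations": ",".join(sorted(k)), "n_pops": len(k), "exclusive_snps": v}
        for k, v in counts.items()
    ]
    return (
        pd.DataFrame(rows, columns=["populations", "n_pops", "exclusive_snps"])
        .sort_values(["n_pops", "populations"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def pairwise_shared(counts: dict[frozenset, int], a: str, b: str) -> tuple[int, int, int]:
    """(shared, unique to a, unique to b) site counts for two populations."""
    shared = sum(v for k, v in counts.items() if a in k and b in k)
    only_a = sum(v for k, v in counts.items() if a in k and b not in k)
    only_b = sum(v for k, v in counts.items() if b in k and a not in k)
    return shared, only_a, only_b


def annotate_genes(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Join overlapping gene names onto regions (optional, user-supplied intervals).

    ``genes`` needs columns chrom, start, end (1-based inclusive), name.
    """
    out = regions.copy()
    names = []
    for chrom, start, end in zip(out["chrom"], out["start"], out["end"]):
        g = genes[(genes["chrom"] == chrom) & (genes["start"] <= end) & (genes["end"] >= start)]
        names.append(",".join(g["name"]) if len(g) else "-")
    out["genes"] = names
    return out


def regions_to_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write regions as BED (0-based half-open); score column holds mean Z(Hp)."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            fh.write(
                f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t"
                f"{r['population']}\t{r['mean_zhp']:.4f}\n"
            )
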