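"""Scan configuration.

The defaults are the standard parameters of the pooled-heterozygosity sweep
scan: 20-kb windows advanced in 10-kb steps, windows with fewer than 50 SNPs
excluded, and a genome-wide significance threshold of Z(Hp) <= -4.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of a windowed Hp / Z(Hp) scan.

    Parameters
    ----------
    window_size : int
        Window length in bp (default 20,000).
    step : int
        Sliding step in bp (default 10,000); must satisfy 0 < step <= window_size.
    min_snps : int
        Minimum SNPs per window for the window to enter the Z-transform and
        sweep calling (default 50; the bound is inclusive).
    z_threshold : float
        Significance threshold on Z(Hp); windows with Z(Hp) <= z_threshold are
        significant (default -4.0).
    max_merge_gap : int
        Maximum bp gap bridged when merging significant windows into regions
        (default 0: only overlapping or abutting windows merge).
    filter_before_transform : bool
        If True (default) the min-SNP exclusion is applied before computing the
        genome-wide mean and SD used by the Z-transform.
    """

    window_size: int = 20_000
    step: int = 10_000
    min_snps: int = 50
    z_threshold: float = -4.0
    max_merge_gap: int = 0
    filter_before_transform: bool = True

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise _cfg_err(f"window_size must be >= 1, got {self.window_size}")
        if not (0 < self.step <= self.window_size):
            raise _cfg_err(
                f"step must satisfy 0 < step <= window_size, got step={self.step}, "
                f"window_size={self.window_size}"
            )
        if self.min_snps < 1:
            raise _cfg_err(f"min_snps must be >= 1, got {self.min_snps}")
        if not math.isfinite(self.z_threshold):
            raise _cfg_err(f"z_threshold must be finite, got {self.z_threshold}")
        if self.max_merge_gap < 0:
            raise _cfg_err(f"max_merge_gap must be >= 0, got {self.max_merge_gap}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise _cfg_err(f"unknown ScanConfig keys: {sorted(unknown)}")
        return cls(**d)


def _cfg_err(msg: str):
    from .errors import ConfigError

    return ConfigError(msg)
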