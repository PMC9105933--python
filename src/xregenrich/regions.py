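"""Build query region sets from SNP association tables.

The query of the enrichment test is the set of genomic regions around SNPs
with a suggestive association signal (nominal p < 5e-4).  Association outputs
give a point position per SNP, not a region, so each passing SNP is expanded
to a symmetric fixed-flank window and overlapping/book-ended windows are
merged — a modelling choice, with the default 75 kb flank giving a singleton
SNP a ~150 kb region, the scale of the published mean region length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegionSet, merge_intervals

__all__ = [
    "SnpRecord",
    "RegionBuildConfig",
    "RegionSummary",
    "read_snp_table",
    "build_regions_from_snps",
    "summarize_region_set",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpRecord:
    """One SNP from an association table; ``position`` is 1-based."""

    snp_id: str
    chrom: str
    position: int
    assoc_p: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1 (1-based), got {self.position}")
        if not (0.0 < self.assoc_p <= 1.0):
            raise ValueError(f"assoc_p must lie in (0, 1], got {self.assoc_p}")


@dataclass(frozen=True)
class RegionBuildConfig:
    """Parameters of the SNP-to-region construction.

    p_max : strict inclusion threshold on the association p-value.
    flank : symmetric padding in bases around each passing SNP.
    merge_gap : maximum gap bridged when merging padded windows (0 merges
        only overlapping or book-ended windows).
    """

    p_max: float = 0.0005
    flank: int = 75_000
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_max < 1.0):
            raise ValueError(f"p_max must lie in (0, 1), got {self.p_max}")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass(frozen=True)
class RegionSummary:
    """Descriptive geometry of a region set, at printed precision.

    Widths are reported in kb and the total in Mb, each rounded to one
    decimal.  The width SD uses the sample (n-1) denominator and is NaN for
    fewer than two regions; an empty set has NaN mean and total 0.0.
    """

    n_regions: int
    mean_width_kb: float
    total_width_mb: float
    width_sd_kb: float


def read_snp_table(path) -> list[SnpRecord]:
    """Read a TSV with header ``snp_id  chrom  pos  p`` into SNP records."""
    df = pd.read_csv(path, sep="\t")
    required = {"snp_id", "chrom", "pos", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    return [
        SnpRecord(str(r.snp_id), str(r.chrom), int(r.pos), float(r.p))
        for r in df.itertuples(index=False)
    ]


def build_regions_from_snps(
    snps: Iterable[SnpRecord],
    config: RegionBuildConfig = RegionBuildConfig(),
    chrom_length: int | None = None,
    name: str = "query",
) -> RegionSet:
    """Threshold SNPs and expand them into merged, disjoint query regions.

    SNPs with ``assoc_p < p_max`` (strict) are each expanded to the window
    ``[position - 1 - flank, position + flank)`` — the 1-based point position
    becomes a 0-based half-open window of width ``2*flank + 1`` — clipped to
    ``[0, chrom_length)``; windows within ``merge_gap`` are merged.  If no
    SNP passes, an empty set is returned with a logged warning.
    """
    windows = []
    for snp in snps:
        if snp.assoc_p >= config.p_max:
            continue
        start = max(0, snp.position - 1 - config.flank)
        end = snp.position + config.flank
        if chrom_length is not None:
            end = min(end, chrom_length)
        if end > start:
            windows.append(GenomicInterval(snp.chrom, start, end))
    if not windows:
        logger.warning(
            "no SNP passed the p < %g threshold; returning an empty region set",
            config.p_max,
        )
        return RegionSet(name, ())
    return merge_intervals(RegionSet(name, tuple(windows)), merge_gap=config.merge_gap)


def summarize_region_set(regions: RegionSet) -> RegionSummary:
    """Summarize geometry the way the published region table prints it:
    region count, mean width (kb), total width (Mb) and width SD (kb), each
    to one decimal."""
    if regions.n == 0:
        return RegionSummary(0, float("nan"), 0.0, float("nan"))
    widths = np.asarray(regions.widths, dtype=float)
    mean_kb = round(widths.mean() / 1e3, 1)
    total_mb = round(widths.sum() / 1e6, 1)
    sd_kb = round(float(widths.std(ddof=1)) / 1e3, 1) if regions.n > 1 else float("nan")
    return RegionSummary(regions.n, mean_kb, total_mb, sd_kb)
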