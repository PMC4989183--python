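"""SNP density in transcription-factor binding regions and DHS sites.

Regions are half-open 0-based intervals carrying a ChIP-Seq peak summit;
SNPs are catalogued single-base positions.  The module counts SNPs per
region, builds summit-centered density profiles (offset 0 = peak summit),
summarises density in the reciprocal "one SNP per N nucleotides" form, and
compares per-factor densities against a fixed reference density with a
single-sample t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class BindingRegion:
    chrom: str
    start: int  # half-open 0-based
    end: int
    summit: int  # absolute position of the peak
    factor: str = ""
    gene: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class SnpSet:
    """Sorted, de-duplicated 0-based SNP positions per chromosome."""

    def __init__(self, positions: Mapping[str, Iterable[int]],
                 source: str = ""):
        self.source = source
        self.positions: dict[str, np.ndarray] = {
            chrom: np.unique(np.asarray(list(pos), dtype=np.int64))
            for chrom, pos in positions.items()
        }

    def __len__(self) -> int:
        return sum(arr.size for arr in self.positions.values())

    def in_interval(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Positions p with start <= p < end (half-open)."""
        arr = self.positions.get(chrom)
        if arr is None:
            return np.empty(0, dtype=np.int64)
        lo, hi = np.searchsorted(arr, [start, end])
        return arr[lo:hi]

    def count_in(self, chrom: str, start: int, end: int) -> int:
        arr = self.positions.get(chrom)
        if arr is None:
            return 0
        lo, hi = np.searchsorted(arr, [start, end])
        return int(hi - lo)

    @classmethod
    def from_bed(cls, path, source: str = "") -> "SnpSet":
        """BED3: single-base features; the start column is the SNP position."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1], names=["chrom", "start"])
        grouped = df.groupby("chrom")["start"].apply(list)
        return cls(grouped.to_dict(), source=source or str(path))

    @classmethod
    def from_tsv(cls, path, source: str = "") -> "SnpSet":
        """Two-column chrom/pos table (0-based positions), with header."""
        df = pd.read_csv(path, sep="\t")
        chrom_col, pos_col = df.columns[:2]
        grouped = df.groupby(chrom_col)[pos_col].apply(list)
        return cls(grouped.to_dict(), source=source or str(path))


@dataclass
class DensitySummary:
    region_count: int
    snp_count: int
    total_length: int
    density: float
    reciprocal_density: float
    per_group_densities: dict[str, float] = field(default_factory=dict)
    t_statistic: float | None = None
    p_value: float | None = None


# ---------------------------------------------------------------------------
# Region I/O

def read_narrowpeak(path) -> list[BindingRegion]:
    """Read ENCODE narrowPeak (BED6+4); column 10 is the summit offset.

    A summit offset of -1 (not determined) falls back to the interval
    midpoint.  The name column is parsed as "factor" or "factor:gene".
    """
    names = ["chrom", "start", "end", "name", "score", "strand",
             "signal", "pvalue", "qvalue", "summit_offset"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=names)
    return _frame_to_regions(df, has_summit=True)


def read_bed_regions(path) -> list[BindingRegion]:
    """Read BED6 regions; the summit defaults to the interval midpoint."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=names, usecols=range(6))
    return _frame_to_regions(df, has_summit=False)


def _frame_to_regions(df: pd.DataFrame, has_summit: bool) -> list[BindingRegion]:
    regions = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if has_summit and int(row.summit_offset) >= 0:
            summit = start + int(row.summit_offset)
        else:
            summit = start + (end - start) // 2
        name = str(row.name)
        factor, _, gene = name.partition(":")
        regions.append(BindingRegion(
            chrom=str(row.chrom), start=start, end=end, summit=summit,
            factor=factor, gene=gene or None,
        ))
    return regions


def write_narrowpeak(regions: Sequence[BindingRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = f"{r.factor}:{r.gene}" if r.gene else r.factor or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t.\t0\t-1\t-1\t"
                     f"{r.summit - r.start}\n")


def write_snp_bed(snps: SnpSet, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(snps.positions):
            for p in snps.positions[chrom]:
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")


# ---------------------------------------------------------------------------
# Counting and profiles

def count_snps_per_region(snps: SnpSet, regions: Sequence[BindingRegion]
                          ) -> np.ndarray:
    """SNPs per region under half-open semantics (start <= p < end)."""
    return np.array([snps.count_in(r.chrom, r.start, r.end) for r in regions],
                    dtype=np.int64)


def counts_by_gene_factor(snps: SnpSet, regions: Sequence[BindingRegion]
                          ) -> pd.DataFrame:
    """Gene x factor SNP count matrix (Fig-5A-style aggregation)."""
    counts = count_snps_per_region(snps, regions)
    df = pd.DataFrame({
        "gene": [r.gene or "(unassigned)" for r in regions],
        "factor": [r.factor for r in regions],
        "n_snps": counts,
    })
    return (df.pivot_table(index="gene", columns="factor", values="n_snps",
                           aggfunc="sum", fill_value=0)
            .sort_index())


def peak_centered_profile(snps: SnpSet, regions: Sequence[BindingRegion],
                          window: int = 1000, binsize: int = 50) -> pd.DataFrame:
    """Average SNP density by offset from the peak summit.

    Each SNP inside a region (clipped to the window) is re-expressed as
    offset = position - summit and binned.  For each bin the frame reports
    the total SNP count, the number of regions whose extent covers any part
    of that bin (contributing regions), and count / (contributing * binsize)
    as the average per-base density.  Summing the count column recovers the
    total in-window SNP count.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if binsize <= 0 or window % binsize != 0:
        raise ValueError("binsize must divide window evenly")
    edges = np.arange(-window, window + binsize, binsize)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    contributing = np.zeros(edges.size - 1, dtype=np.int64)
    for r in regions:
        lo = max(r.start, r.summit - window)
        hi = min(r.end, r.summit + window)
        if hi > lo:
            offs = snps.in_interval(r.chrom, lo, hi) - r.summit
            counts += np.histogram(offs, bins=edges)[0]
        # Bin [e_i, e_{i+1}) receives this region iff it intersects the
        # clipped region extent in offset space.
        r_lo, r_hi = r.start - r.summit, r.end - r.summit
        contributing += (np.minimum(edges[1:], r_hi)
                         > np.maximum(edges[:-1], r_lo)).astype(np.int64)
    density = np.divide(counts, contributing * binsize,
                        out=np.zeros(counts.size, dtype=float),
                        where=contributing > 0)
    return pd.DataFrame({
        "offset_start": edges[:-1],
        "offset_center": edges[:-1] + binsize / 2.0,
        "count": counts,
        "n_regions": contributing,
        "density": density,
    })


# ---------------------------------------------------------------------------
# Densities

def merge_regions(regions: Sequence[BindingRegion]
                  ) -> list[tuple[str, int, int]]:
    """Union of region intervals per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def aggregate_density(snps: SnpSet, regions: Sequence[BindingRegion]
                      ) -> tuple[int, int]:
    """(unique SNP count, union length) over the merged region set.

    SNPs lying in overlapping regions are counted once here, even though
    per-region counts count them once per region.
    """
    merged = merge_regions(regions) if regions else []
    total_len = sum(e - s for _, s, e in merged)
    n_snps = sum(snps.count_in(chrom, s, e) for chrom, s, e in merged)
    return n_snps, total_len


def reciprocal_density(snps: SnpSet, regions: Sequence[BindingRegion]) -> float:
    """Nucleotides per SNP over the merged regions ("one SNP per N nt").

    Zero observed SNPs yields +inf (no SNPs observed), not an error.
    """
    n_snps, total_len = aggregate_density(snps, regions)
    if total_len == 0:
        raise ValueError("total region length is zero")
    return total_len / n_snps if n_snps > 0 else math.inf


def per_factor_densities(snps: SnpSet, regions: Sequence[BindingRegion]
                         ) -> dict[str, float]:
    """Per-base SNP density for each factor's merged region set."""
    by_factor: dict[str, list[BindingRegion]] = {}
    for r in regions:
        by_factor.setdefault(r.factor, []).append(r)
    out = {}
    for factor in sorted(by_factor):
        n, length = aggregate_density(snps, by_factor[factor])
        out[factor] = n / length if length else 0.0
    return out


def compare_dhs_density(group_densities: Mapping[str, float] | Sequence[float],
                        reference_mean: float) -> tuple[float, float]:
    """Two-sided single-sample t test of group densities vs a reference.

    The sample unit is one density per group (by default one per clock
    factor); df = k - 1.  Zero sample variance with mean equal to the
    reference gives (0, 1); with a different mean, p is reported as the
    smallest positive float with a warning.
    """
    values = np.asarray(
        list(group_densities.values()) if isinstance(group_densities, Mapping)
        else list(group_densities), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 group densities for a t test")
    if np.ptp(values) == 0.0:
        if values[0] == reference_mean:
            return 0.0, 1.0
        import warnings
        warnings.warn("zero variance with mean != reference; p floored",
                      RuntimeWarning, stacklevel=2)
        return math.copysign(math.inf, values[0] - reference_mean), \
            float(np.finfo(float).tiny)
    t_stat, p = stats.ttest_1samp(values, popmean=reference_mean)
    return float(t_stat), float(p)


def density_report(snps: SnpSet, regions: Sequence[BindingRegion],
                   reference_mean: float | None = None) -> DensitySummary:
    """Full density summary; the t test runs when a reference is supplied."""
    n_snps, total_len = aggregate_density(snps, regions)
    density = n_snps / total_len if total_len else 0.0
    per_group = per_factor_densities(snps, regions)
    t_stat = p = None
    if reference_mean is not None and len(per_group) >= 2:
        t_stat, p = compare_dhs_density(per_group, reference_mean)
    return DensitySummary(
        region_count=len(regions), snp_count=n_snps, total_length=total_len,
        density=density,
        reciprocal_density=total_len / n_snps if n_snps else math.inf,
        per_group_densities=per_group, t_statistic=t_stat, p_value=p,
    )
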