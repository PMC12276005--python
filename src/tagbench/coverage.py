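"""Binned coverage tracks, CPM, FRiP, count matrices and correlations.

Tracks are dense per-chromosome vectors at a fixed bin size (default 50 bp,
the resolution the downstream peak caller operates at).  Two counting modes
are offered: ``span`` increments every bin a fragment overlaps (used for
peak calling) and ``midpoint`` increments only the bin holding the fragment
midpoint, the analog of paired-end read centering; under midpoint counting
CPM normalization conserves a total of exactly 1e6 per library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import FragmentLibrary
from .intervals import GenomeLayout, IntervalSet


@dataclass
class CoverageTrack:
    bin_size: int
    values: dict[str, np.ndarray]  # chrom -> per-bin signal
    normalization: str  # "raw" | "cpm"
    library_id: str

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


def fragments_to_coverage(
    lib: FragmentLibrary,
    layout: GenomeLayout,
    bin_size: int = 50,
    mode: str = "midpoint",
    normalization: str = "raw",
) -> CoverageTrack:
    """Bin a fragment library into a coverage track.

    Reads are counted (each molecule weighted by its copy count), so a
    deduplicated library counts one per molecule.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if mode not in ("span", "midpoint"):
        raise ValueError(f"unknown counting mode {mode!r}")
    if normalization not in ("raw", "cpm"):
        raise ValueError(f"unknown normalization {normalization!r}")
    lib.validate_bounds(layout)
    sizes = layout.chrom_sizes
    values = {
        c: np.zeros(-(-length // bin_size), dtype=float) for c, length in layout.chromosomes
    }
    for chrom, sub in lib.frame.groupby("chrom", sort=False):
        vec = values[chrom]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        w = sub["copy_count"].to_numpy().astype(float)
        if mode == "midpoint":
            mid = (s + e) // 2  # left-biased for even lengths
            np.add.at(vec, mid // bin_size, w)
        else:
            first = s // bin_size
            last = (e - 1) // bin_size
            # difference-array trick over bin ranges
            diff = np.zeros(len(vec) + 1)
            np.add.at(diff, first, w)
            np.add.at(diff, last + 1, -w)
            vec += np.cumsum(diff[:-1])
    track = CoverageTrack(bin_size, values, "raw", lib.library_id)
    if normalization == "cpm":
        total = lib.total_reads
        if total == 0:
            raise ValueError("cannot CPM-normalize an empty library")
        for vec in values.values():
            vec *= 1e6 / total
        track.normalization = "cpm"
    return track


def frip(lib: FragmentLibrary, peaks: IntervalSet) -> float:
    """Fraction of reads overlapping any peak by >= 1 bp."""
    if len(lib) == 0:
        raise ValueError("FRiP undefined for an empty library")
    mask = lib.intervals().overlapping_mask(peaks)
    w = lib.frame["copy_count"].to_numpy()
    return float(w[mask].sum() / w.sum())


@dataclass
class CountMatrix:
    """Read counts per (merged) region per library, with optional size factors."""

    regions: IntervalSet
    data: pd.DataFrame  # rows align with regions.df rows; columns = library ids
    size_factors: pd.Series | None = None

    def __post_init__(self):
        if len(self.data) != len(self.regions):
            raise ValueError("count rows must match regions")
        if self.size_factors is not None:
            if not (self.size_factors > 0).all():
                raise ValueError("size factors must be positive")

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            return self.data.astype(float)
        return self.data / self.size_factors


def count_matrix(libs: list[FragmentLibrary], regions: IntervalSet) -> CountMatrix:
    """Count reads overlapping each region (>= 1 bp) in each library.

    Regions must be non-overlapping (merge them first); a fragment spanning
    two regions counts in both.
    """
    if not regions.is_merged:
        # abutting regions are fine for counting; genuine overlap is not
        for chrom, sub in regions.df.groupby("chrom"):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if len(s) > 1 and (s[1:] < e[:-1]).any():
                raise ValueError("regions overlap; merge them first")
    per_chrom = {
        chrom: (sub.index.to_numpy(), sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in regions.df.groupby("chrom", sort=False)
    }
    cols = {}
    for lib in libs:
        counts = np.zeros(len(regions), dtype=np.int64)
        for chrom, sub in lib.frame.groupby("chrom", sort=False):
            if chrom not in per_chrom:
                continue
            ridx, rs, re = per_chrom[chrom]
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            w = sub["copy_count"].to_numpy()
            lo = np.searchsorted(re, s, side="right")
            hi = np.searchsorted(rs, e, side="left")
            valid = hi > lo
            diff = np.zeros(len(ridx) + 1, dtype=np.int64)
            np.add.at(diff, lo[valid], w[valid])
            np.add.at(diff, hi[valid], -w[valid])
            counts[ridx] += np.cumsum(diff[:-1])
        cols[lib.library_id] = counts
    data = pd.DataFrame(cols, index=regions.df.index)
    return CountMatrix(regions, data)


def background_size_factors(
    libs: list[FragmentLibrary],
    layout: GenomeLayout,
    background_bin: int = 15_000,
) -> pd.Series:
    """Median-of-ratios size factors over large background bins.

    Fragments are counted per ``background_bin`` per library (midpoint
    counting); bins with a zero in any library are dropped, each bin's counts
    are divided by the bin's geometric mean across libraries and the per-
    library median of those ratios is the size factor.
    """
    if len(libs) < 2:
        raise ValueError("background normalization requires >= 2 libraries")
    mats = []
    for lib in libs:
        track = fragments_to_coverage(lib, layout, bin_size=background_bin, mode="midpoint")
        mats.append(np.concatenate([track.values[c] for c, _ in layout.chromosomes]))
    m = np.stack(mats, axis=1)  # bins x libraries
    nonzero = (m > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no background bin is nonzero in every library")
    m = m[nonzero]
    log_gm = np.log(m).mean(axis=1, keepdims=True)
    ratios = m / np.exp(log_gm)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=[lib.library_id for lib in libs], name="size_factor")


def correlation_matrix(m: CountMatrix) -> pd.DataFrame:
    """Pearson correlation of size-factor-normalized counts between libraries.

    Zero-variance columns yield NaN coefficients (flagged undefined, not 0).
    """
    if m.data.shape[1] < 2 or len(m.data) < 2:
        raise ValueError("correlation requires >= 2 libraries and >= 2 regions")
    norm = m.normalized()
    arr = norm.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return pd.DataFrame(corr, index=norm.columns, columns=norm.columns)


# ---------------------------------------------------------------------------
# bedGraph IO


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write the track with runs of equal value collapsed (zeros included)."""
    with open(path, "w") as fh:
        for chrom, vec in track.values.items():
            if len(vec) == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vec)]])
            for b0, b1 in zip(starts, ends):
                fh.write(
                    f"{chrom}\t{b0 * track.bin_size}\t{b1 * track.bin_size}\t"
                    f"{vec[b0]:g}\n"
                )


def read_bedgraph(path, bin_size: int, layout: GenomeLayout,
                  library_id: str = "track") -> CoverageTrack:
    """Read a bedGraph written at a known bin size back into a track."""
    values = {
        c: np.zeros(-(-length // bin_size), dtype=float)
        for c, length in layout.chromosomes
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in values:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            values[chrom][s // bin_size: -(-e // bin_size)] = v
    return CoverageTrack(bin_size, values, "raw", library_id)
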