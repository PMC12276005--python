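"""Paired-end tagmentation fragment libraries and their on-disk formats.

A :class:`FragmentLibrary` is a multiset of fragments (chrom, start, end)
with integer copy counts >= 1: one row per distinct molecule coordinate, the
copy count recording how many sequencing reads observed it.  Records sharing
identical endpoints are aggregated at construction, which makes the on-disk
round trip exact and matches paired-end deduplication semantics (a duplicate
is exact equality of both fragment endpoints).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import GenomeLayout, IntervalSet

_COLUMNS = ["chrom", "start", "end", "copy_count"]


class FragmentLibrary:
    def __init__(
        self,
        frame: pd.DataFrame | None,
        library_id: str = "lib",
        targeted: bool = False,
        deduplicated: bool = False,
    ):
        if frame is None or len(frame) == 0:
            frame = pd.DataFrame({c: pd.Series(dtype=np.int64 if c != "chrom" else str)
                                  for c in _COLUMNS})
        else:
            frame = pd.DataFrame(frame).copy()
            if "copy_count" not in frame.columns:
                frame["copy_count"] = 1
            frame["chrom"] = frame["chrom"].astype(str)
            for col in ("start", "end", "copy_count"):
                frame[col] = frame[col].astype(np.int64)
            if (frame["start"] >= frame["end"]).any():
                bad = frame[frame["start"] >= frame["end"]].iloc[0]
                raise ValueError(
                    f"invalid fragment {bad['chrom']}:{bad['start']}-{bad['end']}"
                )
            if (frame["copy_count"] < 1).any():
                raise ValueError("copy_count must be >= 1")
            frame = (
                frame.groupby(["chrom", "start", "end"], as_index=False, sort=True)
                ["copy_count"].sum()
            )
        if deduplicated and (frame["copy_count"] != 1).any():
            raise ValueError("deduplicated library must have all copy_count == 1")
        self.frame = frame.reset_index(drop=True)
        self.library_id = library_id
        self.targeted = targeted
        self.deduplicated = deduplicated

    # -- basics ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        return (f"FragmentLibrary({self.library_id!r}, unique={self.n_unique},"
                f" reads={self.total_reads}, dedup={self.deduplicated})")

    @property
    def n_unique(self) -> int:
        """Distinct fragment coordinates (observed unique molecules)."""
        return len(self.frame)

    @property
    def total_reads(self) -> int:
        return int(self.frame["copy_count"].sum())

    def intervals(self) -> IntervalSet:
        return IntervalSet(self.frame[["chrom", "start", "end"]])

    def validate_bounds(self, layout: GenomeLayout) -> None:
        sizes = layout.chrom_sizes
        for row in self.frame.itertuples(index=False):
            if row.chrom not in sizes or row.start < 0 or row.end > sizes[row.chrom]:
                raise ValueError(
                    f"fragment {row.chrom}:{row.start}-{row.end} outside"
                    " chromosome bounds"
                )

    def replace(self, frame: pd.DataFrame, deduplicated: bool | None = None) -> "FragmentLibrary":
        return FragmentLibrary(
            frame,
            library_id=self.library_id,
            targeted=self.targeted,
            deduplicated=self.deduplicated if deduplicated is None else deduplicated,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, FragmentLibrary):
            return NotImplemented
        return self.frame.equals(other.frame)


# ---------------------------------------------------------------------------
# IO: 4-column BED with count, or BEDPE expanded one record per copy


def write_fragments(lib: FragmentLibrary, path, fmt: str = "bed4") -> None:
    """Write a library as 4-column BED (with copy count) or BEDPE.

    BEDPE emits one record per sequencing copy; the two mate intervals
    jointly span the fragment (mate1 = left half, mate2 = right half).
    """
    if fmt not in ("bed4", "bedpe"):
        raise ValueError(f"unknown fragment format {fmt!r}")
    with open(path, "w") as fh:
        if fmt == "bed4":
            for row in lib.frame.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.copy_count}\n")
        else:
            i = 0
            for row in lib.frame.itertuples(index=False):
                # mates jointly span the fragment: [start, mid) + [mid, end)
                mid = row.start + max(1, (row.end - row.start) // 2)
                for _ in range(row.copy_count):
                    i += 1
                    fh.write(
                        f"{row.chrom}\t{row.start}\t{mid}\t"
                        f"{row.chrom}\t{mid}\t{row.end}\tfrag_{i}\n"
                    )


def read_fragments(
    path, fmt: str = "bed4", library_id: str | None = None, targeted: bool = False
) -> FragmentLibrary:
    """Read a fragment library written by :func:`write_fragments`."""
    if fmt not in ("bed4", "bedpe"):
        raise ValueError(f"unknown fragment format {fmt!r}")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    counts: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            try:
                if fmt == "bed4":
                    if len(parts) < 4:
                        raise ValueError("expected 4 columns")
                    chroms.append(parts[0])
                    starts.append(int(parts[1]))
                    ends.append(int(parts[2]))
                    counts.append(int(parts[3]))
                else:
                    if len(parts) < 7:
                        raise ValueError("expected 7 BEDPE columns")
                    c1, s1, e1, c2, s2, e2 = (
                        parts[0], int(parts[1]), int(parts[2]),
                        parts[3], int(parts[4]), int(parts[5]),
                    )
                    if c1 != c2:
                        raise ValueError("mates on different chromosomes")
                    chroms.append(c1)
                    starts.append(min(s1, s2))
                    ends.append(max(e1, e2))
                    counts.append(1)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed record ({err})") from err
    frame = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "copy_count": counts}
    )
    if library_id is None:
        library_id = str(path)
    return FragmentLibrary(frame, library_id=library_id, targeted=targeted)
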