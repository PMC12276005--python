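"""Genomic interval sets and interval-overlap benchmarking.

All coordinates are 0-based, half-open.  :class:`IntervalSet` is the
benchmarking currency of the package: peak sets, ground-truth site maps and
blacklists are all interval sets, and the statistics below (multi-library
consensus, precision/recall/F1, Jaccard, width-preserving shuffled nulls and
a Fisher-type association test) operate on pairs or lists of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class PlacementError(RuntimeError):
    """Raised when random interval placement cannot satisfy its constraints."""


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=str),
         "start": pd.Series(dtype=np.int64),
         "end": pd.Series(dtype=np.int64)}
    )


class IntervalSet:
    """A sorted set of genomic intervals with optional per-interval scores.

    Parameters
    ----------
    df:
        DataFrame with columns ``chrom``, ``start``, ``end`` and optionally
        ``score``.  Rows are copied, coerced and sorted by (chrom, start, end).
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None or len(df) == 0:
            frame = _empty_frame()
            if df is not None and "score" in getattr(df, "columns", ()):
                frame["score"] = pd.Series(dtype=float)
        else:
            frame = pd.DataFrame(df).copy()
            frame["chrom"] = frame["chrom"].astype(str)
            frame["start"] = frame["start"].astype(np.int64)
            frame["end"] = frame["end"].astype(np.int64)
            if (frame["start"] >= frame["end"]).any():
                bad = frame[frame["start"] >= frame["end"]].iloc[0]
                raise ValueError(
                    f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}"
                    " (start must be < end)"
                )
            frame = frame.sort_values(
                ["chrom", "start", "end"], kind="mergesort"
            ).reset_index(drop=True)
        self.df = frame
        self._merged_cache: bool | None = None

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[Sequence]) -> "IntervalSet":
        """Build from an iterable of (chrom, start, end[, score]) tuples."""
        records = list(records)
        if not records:
            return cls()
        cols = ["chrom", "start", "end"]
        if len(records[0]) > 3:
            cols.append("score")
        return cls(pd.DataFrame(records, columns=cols))

    # -- basics ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]]
        b = other.df[["chrom", "start", "end"]]
        return a.equals(b)

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, bp={self.total_bp()})"

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique().tolist())

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_bp(self) -> int:
        """Base pairs covered (overlaps counted once)."""
        return int(self.merge().widths().sum())

    def restrict_chroms(self, names: Iterable[str]) -> "IntervalSet":
        names = set(names)
        return IntervalSet(self.df[self.df["chrom"].isin(names)])

    def _per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for chrom, sub in self.df.groupby("chrom", sort=True):
            out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        return out

    # -- merging ---------------------------------------------------------
    @property
    def is_merged(self) -> bool:
        """True when no two intervals overlap or abut (book-ended)."""
        if self._merged_cache is None:
            ok = True
            for _, (starts, ends) in self._per_chrom().items():
                if len(starts) > 1 and (starts[1:] <= ends[:-1]).any():
                    ok = False
                    break
            self._merged_cache = ok
        return self._merged_cache

    def merge(self) -> "IntervalSet":
        """Merge overlapping and book-ended intervals (gap 0)."""
        if self.is_merged:
            return self
        rows = []
        for chrom, (starts, ends) in self._per_chrom().items():
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e:  # overlap or abut
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e))
        merged = IntervalSet.from_records(rows)
        merged._merged_cache = True
        return merged

    # -- overlap queries -------------------------------------------------
    def overlapping_mask(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per interval of self: overlaps any interval of other by >=1 bp."""
        other_m = other.merge()._per_chrom()
        mask = np.zeros(len(self), dtype=bool)
        for chrom, sub in self.df.groupby("chrom", sort=False):
            if chrom not in other_m:
                continue
            ostarts, oends = other_m[chrom]
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            # merged intervals: starts and ends are both sorted ascending
            idx = np.searchsorted(ostarts, e, side="left")
            hit = (idx > 0) & (oends[np.maximum(idx - 1, 0)] > s)
            mask[sub.index.to_numpy()] = hit
        return mask

    def count_overlapping_pairs(self, other: "IntervalSet") -> int:
        """Number of (self_i, other_j) pairs overlapping by >=1 bp."""
        other_m = other.merge()._per_chrom()
        total = 0
        for chrom, sub in self.df.groupby("chrom", sort=False):
            if chrom not in other_m:
                continue
            ostarts, oends = other_m[chrom]
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            hi = np.searchsorted(ostarts, e, side="left")
            lo = np.searchsorted(oends, s, side="right")
            total += int(np.maximum(hi - lo, 0).sum())
        return total

    def intersect_bp(self, other: "IntervalSet") -> int:
        """Base pairs in the intersection of the two covered sets."""
        a = self.merge()._per_chrom()
        b = other.merge()._per_chrom()
        total = 0
        for chrom in set(a) & set(b):
            astarts, aends = a[chrom]
            bstarts, bends = b[chrom]
            # coverage-below-x helper on b evaluated at a's endpoints
            cum = np.concatenate([[0], np.cumsum(bends - bstarts)])

            def below(x: np.ndarray) -> np.ndarray:
                i = np.searchsorted(bstarts, x, side="right")
                full = cum[i]
                trim = np.where(i > 0, np.maximum(bends[i - 1] - x, 0), 0)
                # subtract the part of the last-started interval beyond x
                trim = np.minimum(trim, np.where(i > 0, bends[i - 1] - bstarts[i - 1], 0))
                return full - trim

            total += int((below(aends) - below(astarts)).sum())
        return total


# ---------------------------------------------------------------------------
# genome layout


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus a blacklist of excluded intervals."""

    chromosomes: tuple[tuple[str, int], ...]
    blacklist: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be strictly positive")
        sizes = dict(self.chromosomes)
        for iv in self.blacklist:
            if iv.chrom not in sizes or iv.end > sizes[iv.chrom]:
                raise ValueError(
                    f"blacklist interval {iv.chrom}:{iv.start}-{iv.end}"
                    " outside chromosome bounds"
                )

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def total_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def allowed_segments(self) -> list[tuple[str, int, int]]:
        """Non-blacklist segments as (chrom, start, end) triples."""
        bl = self.blacklist.merge()._per_chrom()
        segs = []
        for chrom, length in self.chromosomes:
            pos = 0
            for s, e in zip(*bl.get(chrom, (np.array([]), np.array([])))):
                if s > pos:
                    segs.append((chrom, pos, int(s)))
                pos = max(pos, int(e))
            if pos < length:
                segs.append((chrom, pos, length))
        return segs

    def contains(self, iset: IntervalSet) -> bool:
        sizes = self.chrom_sizes
        for iv in iset:
            if iv.chrom not in sizes or iv.start < 0 or iv.end > sizes[iv.chrom]:
                return False
        return True


# ---------------------------------------------------------------------------
# consensus


def default_min_count(n_libraries: int) -> int:
    """Default consensus rule: present in at least 50% of libraries."""
    return max(1, math.ceil(n_libraries / 2))


def multi_consensus(sets: Sequence[IntervalSet], min_count: int | None = None) -> IntervalSet:
    """Consensus intervals present in at least ``min_count`` of the input sets.

    The genome is partitioned at the union of all interval breakpoints; atoms
    covered by >= ``min_count`` input sets (each set merged first, so a set
    contributes at most 1 to any base) are retained and book-ended retained
    atoms are merged.  With ``min_count=None`` the 50%-of-libraries default
    rule is applied.
    """
    if len(sets) == 0:
        raise ValueError("multi_consensus requires at least one interval set")
    if min_count is None:
        min_count = default_min_count(len(sets))
    if not 1 <= min_count <= len(sets):
        raise ValueError(f"min_count must be in [1, {len(sets)}]")
    merged = [s.merge()._per_chrom() for s in sets]
    chroms = sorted({c for m in merged for c in m})
    rows = []
    for chrom in chroms:
        starts = np.concatenate([m[chrom][0] for m in merged if chrom in m])
        ends = np.concatenate([m[chrom][1] for m in merged if chrom in m])
        points = np.unique(np.concatenate([starts, ends]))
        delta = np.zeros(len(points), dtype=np.int64)
        np.add.at(delta, np.searchsorted(points, starts), 1)
        np.add.at(delta, np.searchsorted(points, ends), -1)
        cov = np.cumsum(delta)[:-1]  # coverage on [points[i], points[i+1])
        keep = cov >= min_count
        for s, e in zip(points[:-1][keep], points[1:][keep]):
            rows.append((chrom, int(s), int(e)))
    return IntervalSet.from_records(rows).merge()


# ---------------------------------------------------------------------------
# precision / recall / F1


@dataclass(frozen=True)
class PrecisionRecall:
    precision: float
    recall: float
    f1: float
    n_query: int
    n_reference: int
    precision_defined: bool = True
    recall_defined: bool = True


def precision_recall_f1(query: IntervalSet, reference: IntervalSet) -> PrecisionRecall:
    """Peak-level precision/recall/F1 with a >=1 bp overlap criterion.

    precision = fraction of query intervals overlapping any reference
    interval; recall = fraction of reference intervals overlapped by any
    query interval.  Empty query (or reference) leaves precision (or recall)
    flagged undefined (NaN) rather than silently 0.
    """
    nq, nr = len(query), len(reference)
    p_def = nq > 0
    r_def = nr > 0
    precision = float(query.overlapping_mask(reference).mean()) if p_def else float("nan")
    recall = float(reference.overlapping_mask(query).mean()) if r_def else float("nan")
    if p_def and r_def:
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    else:
        f1 = float("nan")
    return PrecisionRecall(precision, recall, f1, nq, nr, p_def, r_def)


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Jaccard index: intersection bp / union bp of the covered sets."""
    am, bm = a.merge(), b.merge()
    abp, bbp = am.total_bp(), bm.total_bp()
    if abp == 0 and bbp == 0:
        return float("nan")
    inter = am.intersect_bp(bm)
    union = abp + bbp - inter
    return inter / union


# ---------------------------------------------------------------------------
# shuffled null


def shuffle_intervals(
    iset: IntervalSet,
    layout: GenomeLayout,
    exclude: IntervalSet | None = None,
    seed: int = 0,
    max_tries: int = 1000,
) -> IntervalSet:
    """Re-place each interval uniformly at random, preserving its width.

    Placements overlapping ``exclude`` (typically the blacklist) or any
    already-placed shuffled interval are rejected; after ``max_tries``
    rejections for a single interval a :class:`PlacementError` is raised.
    """
    rng = np.random.default_rng(seed)
    sizes = layout.chrom_sizes
    names = list(sizes)
    lengths = np.array([sizes[c] for c in names], dtype=float)
    probs = lengths / lengths.sum()
    excl = (exclude.merge() if exclude is not None else IntervalSet())._per_chrom()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in names}

    def clashes(chrom: str, s: int, e: int) -> bool:
        if chrom in excl:
            os, oe = excl[chrom]
            i = np.searchsorted(os, e, side="left")
            if i > 0 and oe[i - 1] > s:
                return True
        return any(ps < e and pe > s for ps, pe in placed[chrom])

    rows = []
    for iv in iset:
        width = iv.end - iv.start
        for attempt in range(max_tries):
            ci = rng.choice(len(names), p=probs)
            chrom = names[ci]
            limit = sizes[chrom] - width
            if limit < 0:
                continue
            s = int(rng.integers(0, limit + 1))
            e = s + width
            if not clashes(chrom, s, e):
                placed[chrom].append((s, e))
                rows.append((chrom, s, e))
                break
        else:
            raise PlacementError(
                f"could not place shuffled copy of {iv.chrom}:{iv.start}-{iv.end}"
                f" after {max_tries} tries"
            )
    return IntervalSet.from_records(rows)


# ---------------------------------------------------------------------------
# Fisher association


def fisher_overlap(
    a: IntervalSet, b: IntervalSet, layout: GenomeLayout
) -> tuple[np.ndarray, float]:
    """Fisher-type 2x2 association between two merged interval sets.

    The table counts overlapping a-b pairs (n11), a intervals not overlapping
    b (n12), b intervals not overlapping a (n21), and fills n22 with a
    genome-segmentation heuristic: the genome length in units of the mean
    interval width over a union b, minus the other three cells.  Returns the
    table and the two-sided Fisher exact p-value.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("fisher_overlap requires non-empty interval sets")
    am, bm = a.merge(), b.merge()
    n11 = am.count_overlapping_pairs(bm)
    n12 = len(am) - int(am.overlapping_mask(bm).sum())
    n21 = len(bm) - int(bm.overlapping_mask(am).sum())
    widths = np.concatenate([am.widths(), bm.widths()])
    mean_w = float(widths.mean())
    n22 = max(0, int(round(layout.total_bp() / mean_w)) - n11 - n12 - n21)
    table = np.array([[n11, n12], [n21, n22]], dtype=np.int64)
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return table, p


# ---------------------------------------------------------------------------
# benchmark bundle


@dataclass(frozen=True)
class BenchResult:
    query_id: str
    reference_id: str
    n_query: int
    n_reference: int
    precision: float
    recall: float
    f1: float
    jaccard: float
    fisher_table: np.ndarray
    fisher_p: float
    shuffled_f1_quantiles: dict[str, float] | None = None

    def to_row(self) -> dict:
        row = {
            "query_id": self.query_id,
            "reference_id": self.reference_id,
            "n_query": self.n_query,
            "n_reference": self.n_reference,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "jaccard": self.jaccard,
            "fisher_p": self.fisher_p,
        }
        if self.shuffled_f1_quantiles:
            for k, v in self.shuffled_f1_quantiles.items():
                row[f"shuffled_f1_{k}"] = v
        return row


def benchmark(
    query: IntervalSet,
    reference: IntervalSet,
    layout: GenomeLayout,
    query_id: str = "query",
    reference_id: str = "reference",
    n_shuffle: int = 0,
    seed: int = 0,
) -> BenchResult:
    """Full overlap benchmark of a query peak set against a reference set."""
    qm, rm = query.merge(), reference.merge()
    pr = precision_recall_f1(qm, rm)
    jac = jaccard(qm, rm)
    table, p = fisher_overlap(qm, rm, layout)
    quants = None
    if n_shuffle > 0:
        f1s = []
        for i in range(n_shuffle):
            shuf = shuffle_intervals(qm, layout, exclude=layout.blacklist, seed=seed + i)
            f1s.append(precision_recall_f1(shuf, rm).f1)
        f1s = np.array(f1s)
        quants = {
            "q50": float(np.quantile(f1s, 0.5)),
            "q95": float(np.quantile(f1s, 0.95)),
            "max": float(f1s.max()),
        }
    return BenchResult(
        query_id, reference_id, pr.n_query, pr.n_reference,
        pr.precision, pr.recall, pr.f1, jac, table, p, quants,
    )


# ---------------------------------------------------------------------------
# BED IO


def write_bed(iset: IntervalSet, path, names: bool = False) -> None:
    """Write BED3 (or BED6 with names/scores when ``names`` is set)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(iset):
            if names:
                score = getattr(iv, "score", 0.0)
                if score is None or (isinstance(score, float) and math.isnan(score)):
                    score = 0.0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i + 1}\t{score:g}\t.\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path) -> IntervalSet:
    """Read BED3/BED6; a numeric column 5 is kept as the score."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed BED record") from err
            if len(parts) >= 5:
                try:
                    rows.append((chrom, start, end, float(parts[4])))
                except ValueError:
                    rows.append((chrom, start, end))
            else:
                rows.append((chrom, start, end))
    return IntervalSet.from_records(rows)
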