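"""Genomic interval data model and peak-level operations.

Coordinates are 0-based half-open throughout (BED convention). Overlap means
at least one shared base pair; half-open adjacency is not overlap.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns every PeakSet dataframe carries, in canonical order.
PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "summit_offset", "clipped"]


class Peak(NamedTuple):
    """A scored genomic interval with an optional summit offset from ``start``."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    summit_offset: int = -1
    clipped: bool = False


@dataclass
class PeakSet:
    """An ordered collection of scored fixed-width intervals.

    Parameters
    ----------
    df:
        Dataframe with at least ``chrom``, ``start``, ``end``; missing
        ``name``/``score``/``summit_offset``/``clipped`` columns are filled
        with defaults. Rows are sorted by (chrom, start, end) on construction.
    width:
        Nominal fixed width in bp shared by all unclipped peaks (``None`` for
        heterogeneous sets such as blacklists).
    label:
        Free-text provenance (sample id, cell type, "consensus", ...).
    """

    df: pd.DataFrame
    width: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "name" not in df:
            df["name"] = "."
        if "score" not in df:
            df["score"] = 0.0
        if "summit_offset" not in df:
            df["summit_offset"] = -1
        if "clipped" not in df:
            df["clipped"] = False
        df = df[PEAK_COLUMNS]
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["score"] = df["score"].astype(float)
        if len(df):
            if (df["start"] < 0).any():
                raise ValueError("negative start coordinate")
            if (df["end"] <= df["start"]).any():
                raise ValueError("interval with end <= start")
            if (df["score"] < 0).any():
                raise ValueError("negative peak score")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Peak]:
        for row in self.df.itertuples(index=False):
            yield Peak(*row)

    @classmethod
    def from_peaks(cls, peaks: Iterable[Peak], width: int | None = None,
                   label: str = "") -> "PeakSet":
        rows = list(peaks)
        df = pd.DataFrame(rows, columns=PEAK_COLUMNS) if rows else empty_frame()
        return cls(df, width=width, label=label)

    def with_scores(self, scores: np.ndarray) -> "PeakSet":
        df = self.df.copy()
        df["score"] = np.asarray(scores, dtype=float)
        return PeakSet(df, width=self.width, label=self.label)

    def subset(self, mask: np.ndarray) -> "PeakSet":
        return PeakSet(self.df.loc[np.asarray(mask)], width=self.width,
                       label=self.label)


def empty_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=str),
        "start": pd.Series(dtype=np.int64),
        "end": pd.Series(dtype=np.int64),
        "name": pd.Series(dtype=str),
        "score": pd.Series(dtype=float),
        "summit_offset": pd.Series(dtype=np.int64),
        "clipped": pd.Series(dtype=bool),
    })


def extend_summits(summits: Iterable[tuple], flank: int,
                   chrom_sizes: Mapping[str, int]) -> PeakSet:
    """Extend point summits ``flank`` bp in both directions into fixed-width peaks.

    Each ``(chrom, position, score)`` record becomes the interval
    ``[position - flank, position + flank + 1)`` of width ``2*flank + 1``
    (the summit base is included), clipped to ``[0, chrom_length)``. Clipped
    peaks are retained and flagged rather than dropped. Records on unknown
    chromosomes are rejected with a logged warning.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    rows = []
    for i, rec in enumerate(summits):
        chrom, pos, score = rec[0], int(rec[1]), float(rec[2])
        name = rec[3] if len(rec) > 3 else f"summit_{i}"
        if chrom not in chrom_sizes:
            logger.warning("skipping summit on unknown chromosome %r", chrom)
            continue
        size = chrom_sizes[chrom]
        if not 0 <= pos < size:
            logger.warning("skipping out-of-bounds summit %s:%d", chrom, pos)
            continue
        start = pos - flank
        end = pos + flank + 1
        clipped = start < 0 or end > size
        start = max(start, 0)
        end = min(end, size)
        rows.append(Peak(chrom, start, end, name, score, pos - start, clipped))
    return PeakSet.from_peaks(rows, width=2 * flank + 1)


def _merged_intervals(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) of the merged union of intervals."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        m_starts, m_ends = [], []
        for s, e in zip(starts, ends):  # input sorted by start
            if m_ends and s <= m_ends[-1]:
                m_ends[-1] = max(m_ends[-1], e)
            else:
                m_starts.append(s)
                m_ends.append(e)
        out[chrom] = (np.asarray(m_starts), np.asarray(m_ends))
    return out


def overlaps_any(query: PeakSet, subject: PeakSet) -> np.ndarray:
    """Boolean mask: query peak i shares >= 1 bp with some subject interval."""
    mask = np.zeros(len(query), dtype=bool)
    if not len(subject):
        return mask
    merged = _merged_intervals(subject.df)
    for chrom, sub in query.df.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        m_starts, m_ends = merged[chrom]
        q_start = sub["start"].to_numpy()
        q_end = sub["end"].to_numpy()
        # first merged interval whose end exceeds the query start; overlap iff
        # that interval starts before the query end (merged intervals disjoint)
        j = np.searchsorted(m_ends, q_start, side="right")
        hit = (j < len(m_starts)) & (m_starts[np.minimum(j, len(m_starts) - 1)] < q_end)
        mask[sub.index.to_numpy()] = hit
    return mask


def filter_blacklist(peaks: PeakSet, blacklist: PeakSet) -> PeakSet:
    """Drop peaks overlapping any blacklist interval (>= 1 bp rule)."""
    if not len(blacklist):
        return peaks
    return peaks.subset(~overlaps_any(peaks, blacklist))


def normalize_scores_spm(peaks: PeakSet) -> PeakSet:
    """Score-per-million normalization: score_i * 1e6 / sum(scores)."""
    total = float(peaks.df["score"].sum())
    if total <= 0:
        raise ValueError("cannot normalize: all peak scores are zero")
    return peaks.with_scores(peaks.df["score"].to_numpy() * 1e6 / total)


def consolidate_nonoverlapping(peaks: PeakSet) -> PeakSet:
    """Iteratively retain the highest-scoring peak and drop all peaks overlapping it.

    Ties in score are broken by earlier (chrom, start, end) for determinism.
    The output is coordinate-sorted, is a subset of the input, and contains no
    overlapping pair on any chromosome.
    """
    df = peaks.df
    if len(df) <= 1:
        return PeakSet(df, width=peaks.width, label=peaks.label)
    order = df.sort_values(["score", "chrom", "start", "end"],
                           ascending=[False, True, True, True],
                           kind="mergesort").index
    kept_starts: dict[str, list[int]] = {}
    kept_ends: dict[str, list[int]] = {}
    keep_idx = []
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    for i in order:
        chrom, s, e = chroms[i], starts[i], ends[i]
        cs = kept_starts.setdefault(chrom, [])
        ce = kept_ends.setdefault(chrom, [])
        # retained intervals are disjoint, so starts and ends sort identically
        j = bisect_right(ce, s)
        if j < len(cs) and cs[j] < e:
            continue
        pos = bisect_left(cs, s)
        cs.insert(pos, s)
        ce.insert(pos, e)
        keep_idx.append(i)
    return PeakSet(df.loc[sorted(keep_idx)], width=peaks.width, label=peaks.label)
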