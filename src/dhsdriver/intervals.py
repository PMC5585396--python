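"""Interval algebra and I/O for BED-like genomic tracks.

All coordinates are BED convention: 0-based, half-open ``[start, end)``.
Tracks are backed by a pandas DataFrame sorted by (chrom, start); extra BED
columns are carried opaquely and re-emitted on write.  Strand is ignored —
DHS tracks are unstranded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "IntervalTrack",
    "MaskedDHS",
    "read_bed",
    "write_bed",
    "merge_overlapping",
    "subtract",
    "mask_track",
    "window",
    "flanks",
    "total_length",
    "overlaps_any",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strict overlap by at least one base pair; touching is not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class MaskedDHS:
    """A DHS with its unmasked pieces after repeat subtraction.

    One logical DHS keeps its original footprint ``[start, end)`` plus the
    list of unmasked sub-intervals; ``length`` is the scalar remaining
    (masked) length L that enters the Poisson model as mutational target
    size.
    """

    dhs_id: str
    chrom: str
    start: int
    end: int
    pieces: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.pieces)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


class IntervalTrack:
    """An ordered, per-chromosome collection of intervals.

    Parameters
    ----------
    df : DataFrame with at least columns ``chrom``, ``start``, ``end``.
        Any further columns are preserved as opaque annotations.
    name : track label.
    """

    def __init__(self, df: pd.DataFrame, name: str = ""):
        required = {"chrom", "start", "end"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"track is missing columns: {sorted(missing)}")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValueError("negative start coordinate")
        bad = df["end"] <= df["start"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            row = df.iloc[i]
            raise ValueError(
                f"end <= start at {row['chrom']}:{row['start']}-{row['end']}"
            )
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )
        self.name = name

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end))

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def on(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (starts, ends) arrays for one chromosome."""
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    @classmethod
    def from_intervals(cls, intervals, name: str = "") -> "IntervalTrack":
        rows = [(iv.chrom, iv.start, iv.end) for iv in intervals]
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]), name=name)


def read_bed(path, name: str | None = None) -> IntervalTrack:
    """Read a BED3+ file into an :class:`IntervalTrack`.

    Extra columns are kept as ``col4``, ``col5``, ... Lines starting with
    ``#``, ``track`` or ``browser`` are skipped.  Malformed lines raise a
    parse error naming the line number.
    """
    rows: list[list] = []
    ncols = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append([parts[0], start, end, *parts[3:]])
            ncols = max(ncols, len(parts))
    columns = ["chrom", "start", "end"] + [f"col{i}" for i in range(4, ncols + 1)]
    if not rows:
        return IntervalTrack(pd.DataFrame(columns=["chrom", "start", "end"]), name=name or "")
    df = pd.DataFrame([r + [None] * (ncols - len(r)) for r in rows], columns=columns)
    return IntervalTrack(df, name=name or str(path))


def write_bed(track: IntervalTrack, path) -> None:
    track.df.to_csv(path, sep="\t", header=False, index=False)


def merge_overlapping(track: IntervalTrack) -> IntervalTrack:
    """Combine intervals overlapping by at least one base pair.

    Adjacent-but-touching intervals (``end == next start``) stay separate.
    Annotation columns are dropped for merged output.
    """
    out = []
    for chrom in track.chromosomes:
        starts, ends = track.on(chrom)
        cur_s, cur_e = None, None
        for s, e in zip(starts, ends):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # strict overlap
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    df = pd.DataFrame(out, columns=["chrom", "start", "end"])
    return IntervalTrack(df, name=track.name)


def _subtract_one(start: int, end: int, mask_starts: np.ndarray, mask_ends: np.ndarray):
    """Pieces of [start, end) not covered by the sorted, merged mask."""
    pieces = []
    lo = int(np.searchsorted(mask_ends, start, side="right"))
    pos = start
    for i in range(lo, len(mask_starts)):
        ms, me = int(mask_starts[i]), int(mask_ends[i])
        if ms >= end:
            break
        if ms > pos:
            pieces.append((pos, ms))
        pos = max(pos, me)
        if pos >= end:
            break
    if pos < end:
        pieces.append((pos, end))
    return pieces


def subtract(track: IntervalTrack, mask: IntervalTrack) -> IntervalTrack:
    """Base-set subtraction: remove masked bases from every interval.

    Intervals fully covered by the mask are dropped (and logged).  Each
    output row keeps a ``source_index`` column pointing at the originating
    row of ``track``.
    """
    merged_mask = merge_overlapping(mask)
    rows = []
    dropped = 0
    for idx, row in enumerate(track.df.itertuples(index=False)):
        ms, me = merged_mask.on(row.chrom)
        pieces = _subtract_one(int(row.start), int(row.end), ms, me)
        if not pieces:
            dropped += 1
            continue
        for s, e in pieces:
            rows.append((row.chrom, s, e, idx))
    if dropped:
        logger.info("subtract: %d intervals fully masked and dropped", dropped)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "source_index"])
    return IntervalTrack(df, name=track.name)


def mask_track(dhs_track: IntervalTrack, repeat_track: IntervalTrack):
    """Apply a repeat mask to a DHS track.

    Returns ``(kept, dropped_ids)`` where *kept* is a list of
    :class:`MaskedDHS` with remaining length > 0 and *dropped_ids* names the
    DHSs whose remaining length is zero (omitted from analysis).
    """
    merged_mask = merge_overlapping(repeat_track)
    kept: list[MaskedDHS] = []
    dropped: list[str] = []
    for idx, row in enumerate(dhs_track.df.itertuples(index=False)):
        dhs_id = f"{row.chrom}:{row.start}-{row.end}"
        ms, me = merged_mask.on(row.chrom)
        pieces = _subtract_one(int(row.start), int(row.end), ms, me)
        if pieces:
            kept.append(MaskedDHS(dhs_id, row.chrom, int(row.start), int(row.end), pieces))
        else:
            dropped.append(dhs_id)
    if dropped:
        logger.info("mask_track: %d DHSs with remaining length zero omitted", len(dropped))
    return kept, dropped


def window(interval: GenomicInterval, flank: int, chrom_length: int) -> GenomicInterval:
    """Expand an interval by ``flank`` bp each side, clipped to the chromosome."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return GenomicInterval(
        interval.chrom,
        max(0, interval.start - flank),
        min(chrom_length, interval.end + flank),
    )


def flanks(interval: GenomicInterval, flank: int, chrom_length: int):
    """The two flank pieces around an interval, excluding the interval itself.

    Either piece may be absent (None) at a chromosome boundary.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    left = None
    if interval.start > 0 and flank > 0:
        left = GenomicInterval(interval.chrom, max(0, interval.start - flank), interval.start)
    right = None
    if interval.end < chrom_length and flank > 0:
        right = GenomicInterval(
            interval.chrom, interval.end, min(chrom_length, interval.end + flank)
        )
    return left, right


def total_length(track: IntervalTrack) -> int:
    return int((track.df["end"] - track.df["start"]).sum())


def overlaps_any(interval: GenomicInterval, track: IntervalTrack) -> bool:
    """Does the interval strictly overlap any interval of the (sorted) track?"""
    starts, ends = track.on(interval.chrom)
    if len(starts) == 0:
        return False
    i = int(np.searchsorted(starts, interval.end, side="left"))
    # any interval starting before interval.end that has not ended by interval.start
    return bool((ends[:i] > interval.start).any())
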