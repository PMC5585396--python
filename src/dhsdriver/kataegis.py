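"""Kataegis detection from rainfall (intermutation) distances.

Kataegis — localized somatic hypermutation — shows up on rainfall plots as
runs of closely spaced mutations.  A locus is called from a per-sample,
per-chromosome maximal run of consecutive mutations in which every adjacent
gap is below the cutoff (which guarantees the mean gap is too); runs of at
least ``min_run`` mutations are reported.  An alternative mode calls maximal
windows by mean gap only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .catalog import MutationCatalog
from .intervals import GenomicInterval, IntervalTrack, overlaps_any

__all__ = ["KataegisLocus", "KataegisDetector", "rainfall", "call_kataegis", "exclude_kataegis_dhs"]


@dataclass(frozen=True)
class KataegisLocus:
    chrom: str
    start: int  # 0-based inclusive -> half-open [start, end)
    end: int
    sample_id: str
    n_mutations: int
    mean_gap: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def rainfall(cat: MutationCatalog, sample_id: str) -> pd.DataFrame:
    """Per-mutation intermutation distance for one sample.

    The distance is the mean of the gaps to the upstream and downstream
    neighbors on the same chromosome; terminal mutations use their single
    neighbor; a lone mutation on a chromosome gets NaN (undefined).
    """
    sub = cat.for_sample(sample_id).sort_values(["chrom", "pos"], kind="mergesort")
    out = []
    for chrom, grp in sub.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        dist = np.full(len(pos), np.nan)
        if len(pos) >= 2:
            gaps = np.diff(pos).astype(float)
            dist[0] = gaps[0]
            dist[-1] = gaps[-1]
            if len(pos) > 2:
                dist[1:-1] = (gaps[:-1] + gaps[1:]) / 2.0
        for p, d in zip(pos, dist):
            out.append((chrom, int(p), d))
    df = pd.DataFrame(out, columns=["chrom", "pos", "intermutation_distance"])
    df["sample"] = sample_id
    return df


def _runs_by_gap(pos: np.ndarray, min_run: int, max_mean_gap: float):
    """Maximal runs where every adjacent gap < max_mean_gap."""
    runs = []
    start = 0
    for i in range(1, len(pos) + 1):
        if i == len(pos) or pos[i] - pos[i - 1] >= max_mean_gap:
            if i - start >= min_run:
                runs.append((start, i))
            start = i
    return runs


def _runs_by_mean(pos: np.ndarray, min_run: int, max_mean_gap: float):
    """Maximal windows of >= min_run mutations with mean gap < max_mean_gap.

    Quadratic scan; returns non-overlapping maximal windows, greedy from the
    left.
    """
    runs = []
    i = 0
    n = len(pos)
    while i + min_run <= n:
        best = None
        for j in range(i + min_run, n + 1):
            mean_gap = (pos[j - 1] - pos[i]) / (j - i - 1)
            if mean_gap < max_mean_gap:
                best = j
        if best is None:
            i += 1
        else:
            runs.append((i, best))
            i = best
    return runs


def call_kataegis(
    cat: MutationCatalog,
    min_run: int = 6,
    max_mean_gap: float = 1000.0,
    mode: str = "gap",
) -> list[KataegisLocus]:
    """Call kataegis loci per sample and chromosome.

    ``mode='gap'`` (default): maximal runs with every adjacent gap below the
    cutoff.  ``mode='mean'``: maximal windows by mean intermutation distance.
    Loci span first to last mutation, reported half-open.
    """
    if mode not in ("gap", "mean"):
        raise ValueError("mode must be 'gap' or 'mean'")
    finder = _runs_by_gap if mode == "gap" else _runs_by_mean
    loci = []
    for (sample_id, chrom), grp in cat.df.groupby(["sample", "chrom"], sort=True):
        pos = np.sort(grp["pos"].to_numpy())
        for i, j in finder(pos, min_run, max_mean_gap):
            span = int(pos[j - 1] - pos[i])
            loci.append(
                KataegisLocus(
                    chrom=chrom,
                    start=int(pos[i]),
                    end=int(pos[j - 1]) + 1,
                    sample_id=sample_id,
                    n_mutations=j - i,
                    mean_gap=span / (j - i - 1),
                )
            )
    return loci


def exclude_kataegis_dhs(dhs_track: IntervalTrack, loci: list[KataegisLocus]) -> IntervalTrack:
    """Remove DHSs overlapping any kataegis locus of any sample."""
    if not loci:
        return dhs_track
    locus_track = IntervalTrack.from_intervals([l.interval for l in loci], name="kataegis")
    keep = [
        not overlaps_any(GenomicInterval(r.chrom, int(r.start), int(r.end)), locus_track)
        for r in dhs_track.df.itertuples(index=False)
    ]
    return IntervalTrack(dhs_track.df[np.asarray(keep)], name=dhs_track.name)


def loci_to_frame(loci: list[KataegisLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.chrom, l.start, l.end, l.sample_id, l.n_mutations, l.mean_gap) for l in loci],
        columns=["chrom", "start", "end", "sample", "n_mutations", "mean_gap"],
    )


class KataegisDetector(BaseEstimator):
    """Estimator wrapper around :func:`call_kataegis`.

    Parameters
    ----------
    min_run : minimum mutations in a run (default 6).
    max_mean_gap : intermutation distance cutoff in bp (default 1000).
    mode : 'gap' (every adjacent gap below cutoff) or 'mean' (window mean).

    Attributes
    ----------
    loci_ : list of KataegisLocus found by :meth:`fit`.
    """

    def __init__(self, min_run: int = 6, max_mean_gap: float = 1000.0, mode: str = "gap"):
        self.min_run = min_run
        self.max_mean_gap = max_mean_gap
        self.mode = mode

    def fit(self, X: MutationCatalog, y=None) -> "KataegisDetector":
        self.loci_ = call_kataegis(X, self.min_run, self.max_mean_gap, self.mode)
        return self

    def transform(self, dhs_track: IntervalTrack) -> IntervalTrack:
        """Drop DHSs overlapping any fitted kataegis locus."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "loci_")
        return exclude_kataegis_dhs(dhs_track, self.loci_)
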