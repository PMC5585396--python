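"""Per-DHS covariates of local mutation rate.

Five covariates enter the clustering: replication timing, chromatin
compartment (open/closed, Hi-C derived), GC content, local gene density, and
the trinucleotide-context expected mutation rate

    mu_i = sum_t n_{i,t} * M_t / N_t        (t = AAA ... TTT, 64 contexts)

where ``n_{i,t}`` counts occurrences of context ``t`` in the DHS's unmasked
sequence, ``M_t`` is the genome-wide mutation count with central base in
context ``t`` and ``N_t`` the genome-wide occurrence count of ``t``.
Contexts are counted on the reference strand without collapsing; a
32-context collapsed mode is available behind a flag.  All covariates are
z-normalized (population SD) over the full DHS cohort before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import MutationCatalog
from .intervals import IntervalTrack, MaskedDHS, merge_overlapping

__all__ = [
    "TRINUCLEOTIDES",
    "TrinucleotideSpectrum",
    "count_trinucleotides",
    "build_spectrum",
    "expected_mutation_rate",
    "gc_fraction",
    "gene_density",
    "attach_track_scores",
    "normalize_covariates",
    "covariate_matrix",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TRINUCLEOTIDES = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)


def _tri_index(tri: str) -> int:
    return 16 * _BASE_INDEX[tri[0]] + 4 * _BASE_INDEX[tri[1]] + _BASE_INDEX[tri[2]]


def count_trinucleotides(seq: str) -> np.ndarray:
    """Occurrence counts of the 64 trinucleotide contexts in a sequence.

    Windows containing non-ACGT characters are skipped; a sequence shorter
    than 3 bp has no complete context.
    """
    counts = np.zeros(64, dtype=np.int64)
    s = seq.upper()
    codes = np.frombuffer(s.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    c = lut[codes]
    if len(c) < 3:
        return counts
    tri = 16 * c[:-2] + 4 * c[1:-1] + c[2:]
    valid = (c[:-2] >= 0) & (c[1:-1] >= 0) & (c[2:] >= 0)
    np.add.at(counts, tri[valid], 1)
    return counts


@dataclass
class TrinucleotideSpectrum:
    """Genome-wide mutation counts M_t and occurrence counts N_t per context."""

    M: np.ndarray = field(default_factory=lambda: np.zeros(64, dtype=np.int64))
    N: np.ndarray = field(default_factory=lambda: np.zeros(64, dtype=np.int64))

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int64)
        self.N = np.asarray(self.N, dtype=np.int64)
        if self.M.shape != (64,) or self.N.shape != (64,):
            raise ValueError("spectrum arrays must have shape (64,)")
        if (self.M < 0).any() or (self.N < 0).any():
            raise ValueError("spectrum counts must be >= 0")

    def rate(self) -> np.ndarray:
        """Per-occurrence mutation rate M_t / N_t (0 where N_t = 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.N > 0, self.M / np.maximum(self.N, 1), 0.0)
        return r

    def collapse_strands(self) -> "TrinucleotideSpectrum":
        """Fold each context onto its reverse complement (32-context mode)."""
        M = np.zeros(64, dtype=np.int64)
        N = np.zeros(64, dtype=np.int64)
        for i, tri in enumerate(TRINUCLEOTIDES):
            rc = tri.translate(_COMPLEMENT)[::-1]
            j = _tri_index(rc)
            k = min(i, j)
            M[k] += self.M[i] if i <= j else 0
            N[k] += self.N[i] if i <= j else 0
        for i, tri in enumerate(TRINUCLEOTIDES):
            rc = tri.translate(_COMPLEMENT)[::-1]
            j = _tri_index(rc)
            if i > j:
                M[j] += self.M[i]
                N[j] += self.N[i]
        return TrinucleotideSpectrum(M, N)


def build_spectrum(
    sequences: dict[str, str],
    cat: MutationCatalog,
    exclude: IntervalTrack | None = None,
) -> TrinucleotideSpectrum:
    """Count M_t and N_t over a genome, optionally excluding regions.

    ``sequences`` maps chromosome name to its full reference sequence (any
    object supporting slicing and ``str``, e.g. pyfaidx records).  A
    mutation's context is the reference triplet centered on its position;
    mutations at chromosome ends (no complete context) are skipped, as are
    mutations and occurrences inside excluded regions (e.g. centromeres).
    """
    N = np.zeros(64, dtype=np.int64)
    excl = merge_overlapping(exclude) if exclude is not None else None
    for chrom, seq in sequences.items():
        s = str(seq).upper()
        if excl is not None:
            starts, ends = excl.on(chrom)
            pos = 0
            for ms, me in zip(starts, ends):
                if ms > pos:
                    N += count_trinucleotides(s[pos:ms])
                pos = max(pos, int(me))
            if pos < len(s):
                N += count_trinucleotides(s[pos:])
        else:
            N += count_trinucleotides(s)
    M = np.zeros(64, dtype=np.int64)
    for row in cat.df.itertuples(index=False):
        seq = sequences.get(row.chrom)
        if seq is None:
            continue
        p = int(row.pos)
        if p < 1 or p + 2 > len(seq):
            continue
        if excl is not None:
            starts, ends = excl.on(row.chrom)
            idx = np.searchsorted(starts, p, side="right") - 1
            if idx >= 0 and ends[idx] > p:
                continue
        tri = str(seq[p - 1 : p + 2]).upper()
        if set(tri) <= set("ACGT"):
            M[_tri_index(tri)] += 1
    return TrinucleotideSpectrum(M, N)


def expected_mutation_rate(pieces: list[str], spectrum: TrinucleotideSpectrum) -> float:
    """Context-expected mutations for a DHS given its unmasked piece sequences.

    Each piece is scored independently, so contexts straddling mask
    boundaries are excluded.  Raises if the DHS contains a context absent
    from the genome-wide occurrence counts (spectrum/genome mismatch).
    """
    counts = np.zeros(64, dtype=np.int64)
    for seq in pieces:
        counts += count_trinucleotides(seq)
    bad = (counts > 0) & (spectrum.N == 0)
    if bad.any():
        tri = TRINUCLEOTIDES[int(np.flatnonzero(bad)[0])]
        raise ValueError(f"context {tri} present in DHS but absent genome-wide (N_t = 0)")
    return float(np.dot(counts, spectrum.rate()))


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#non-N); NaN for an all-N (or empty) sequence."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    denom = sum(s.count(b) for b in "ACGT")
    return gc / denom if denom else float("nan")


def gene_density(
    dhs: MaskedDHS,
    genes: IntervalTrack,
    chrom_length: int,
    half_window: int = 250_000,
) -> float:
    """Fraction of bases within ``half_window`` of the DHS covered by genes.

    The window runs from ``dhs.start - half_window`` to
    ``dhs.end + half_window`` (edges, not midpoint), clipped to the
    chromosome.  ``genes`` should be pre-merged.
    """
    lo = max(0, dhs.start - half_window)
    hi = min(chrom_length, dhs.end + half_window)
    starts, ends = genes.on(dhs.chrom)
    covered = 0
    for s, e in zip(starts, ends):
        covered += max(0, min(int(e), hi) - max(int(s), lo))
    return covered / (hi - lo) if hi > lo else 0.0


def attach_track_scores(dhs_list: list[MaskedDHS], score_track: pd.DataFrame) -> np.ndarray:
    """Coverage-weighted mean track score per DHS.

    ``score_track`` is a 4-column frame (chrom, start, end, value),
    bedGraph-like.  DHSs with no overlapping tile get NaN (flagged missing;
    imputed with the cohort mean at normalization).
    """
    out = np.full(len(dhs_list), np.nan)
    by_chrom = {
        c: g.sort_values("start") for c, g in score_track.groupby("chrom", sort=False)
    }
    for i, dhs in enumerate(dhs_list):
        g = by_chrom.get(dhs.chrom)
        if g is None:
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        vals = g["value"].to_numpy(dtype=float)
        w_total = 0.0
        acc = 0.0
        lo = np.searchsorted(ends, dhs.start, side="right")
        for j in range(lo, len(starts)):
            if starts[j] >= dhs.end:
                break
            ov = min(int(ends[j]), dhs.end) - max(int(starts[j]), dhs.start)
            if ov > 0:
                acc += ov * vals[j]
                w_total += ov
        if w_total > 0:
            out[i] = acc / w_total
    return out


def normalize_covariates(matrix: pd.DataFrame) -> pd.DataFrame:
    """z-normalize every covariate column to mean 0, SD 1 (population SD).

    Missing values are imputed with the column mean (z = 0).  Constant
    columns (zero SD) are dropped with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    if len(matrix) < 2:
        raise ValueError("need at least 2 DHSs to normalize covariates")
    out = {}
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        missing = np.isnan(x)
        mean = float(np.nanmean(x))
        x = np.where(missing, mean, x)
        sd = float(np.std(x))
        if sd == 0.0:
            logger.warning("covariate %r is constant; dropped", col)
            continue
        out[col] = (x - mean) / sd
    return pd.DataFrame(out, index=matrix.index)


def covariate_matrix(
    dhs_list: list[MaskedDHS],
    sequences: dict[str, str],
    spectrum: TrinucleotideSpectrum,
    genes: IntervalTrack,
    chrom_lengths: dict[str, int],
    replication_timing: pd.DataFrame,
    compartment: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the raw (un-normalized) five-covariate matrix for a cohort."""
    genes_merged = merge_overlapping(genes)
    rt = attach_track_scores(dhs_list, replication_timing)
    cc = attach_track_scores(dhs_list, compartment)
    gc = np.empty(len(dhs_list))
    gd = np.empty(len(dhs_list))
    mu = np.empty(len(dhs_list))
    for i, dhs in enumerate(dhs_list):
        pieces = [str(sequences[dhs.chrom][s:e]) for s, e in dhs.pieces]
        gc[i] = gc_fraction("".join(pieces))
        gd[i] = gene_density(dhs, genes_merged, chrom_lengths[dhs.chrom])
        mu[i] = expected_mutation_rate(pieces, spectrum)
    return pd.DataFrame(
        {
            "replication_timing": rt,
            "chromatin_compartment": cc,
            "gc_content": gc,
            "gene_density": gd,
            "expected_mutation_rate": mu,
        },
        index=[d.dhs_id for d in dhs_list],
    )
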