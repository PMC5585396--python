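"""Somatic mutation catalogs: ingestion, post-calling filters, intersection.

The canonical input is a tab-separated table with columns ``chrom``, ``pos``,
``ref``, ``alt``, ``sample``, ``tumor_depth``, ``normal_depth``, ``af``.
Positions are stored 0-based internally; 1-based (VCF-convention) input is
converted on read.  Only single-base substitutions are kept — rows with
multi-base alleles are rejected (and counted), not errored.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .intervals import IntervalTrack, MaskedDHS, merge_overlapping

logger = logging.getLogger(__name__)

__all__ = [
    "MutationCatalog",
    "read_catalog",
    "read_vcf",
    "apply_quality_filters",
    "exclude_by_tracks",
    "count_per_interval",
    "count_in_region",
]

_BASES = frozenset("ACGT")

REQUIRED_COLUMNS = ("chrom", "pos", "ref", "alt", "sample")
OPTIONAL_COLUMNS = ("tumor_depth", "normal_depth", "af")


class MutationCatalog:
    """A sorted catalog of somatic single-base substitutions.

    Backed by a DataFrame sorted by (chrom, pos); duplicates on
    (sample, chrom, pos, alt) are collapsed with a warning.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = ""):
        missing = set(REQUIRED_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"catalog is missing columns: {sorted(missing)}")
        df = df.copy()
        df["pos"] = df["pos"].astype(np.int64)
        ndup = int(df.duplicated(subset=["sample", "chrom", "pos", "alt"]).sum())
        if ndup:
            logger.warning("collapsed %d duplicate mutation rows", ndup)
            df = df.drop_duplicates(subset=["sample", "chrom", "pos", "alt"])
        self.df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        sub = self.df[self.df["sample"] == sample_id]
        if sub.empty:
            raise KeyError(f"unknown sample: {sample_id!r}")
        return sub

    def on(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()

    def subset(self, mask: np.ndarray) -> "MutationCatalog":
        return MutationCatalog(self.df[mask], provenance=self.provenance)


def _normalize_frame(df: pd.DataFrame, position_base: int) -> pd.DataFrame:
    if position_base not in (0, 1):
        raise ValueError("position_base must be 0 or 1")
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64) - position_base
    ref_ok = df["ref"].astype(str).str.upper().isin(_BASES)
    alt_ok = df["alt"].astype(str).str.upper().isin(_BASES)
    bad = ~(ref_ok & alt_ok)
    if bad.any():
        logger.warning("rejected %d rows with non-single-base or non-ACGT alleles", int(bad.sum()))
        df = df[~bad]
    df["ref"] = df["ref"].str.upper()
    df["alt"] = df["alt"].str.upper()
    same = df["ref"] == df["alt"]
    if same.any():
        logger.warning("rejected %d rows with ref == alt", int(same.sum()))
        df = df[~same]
    return df


def read_catalog(path, position_base: int = 1, provenance: str = "") -> MutationCatalog:
    """Read the canonical TSV mutation table.

    ``position_base=1`` (the default, VCF convention) shifts positions to the
    internal 0-based convention.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str, "sample": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return MutationCatalog(_normalize_frame(df, position_base), provenance=provenance)


def read_vcf(path, sample_column: str = "sample", provenance: str = "") -> MutationCatalog:
    """Minimal VCF 4.x reader for uncompressed single- or multi-sample files.

    Maps CHROM/POS/REF/ALT; per-sample genotype columns are scanned for AD
    (allelic depths), from which depth and allele fraction are derived when
    present.  Sites without any called non-reference genotype are skipped.
    """
    rows = []
    sample_names: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.rstrip("\n").split("\t")
                sample_names = fields[9:]
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alts = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            fmt = fields[8].split(":") if len(fields) > 8 else []
            for alt in alts.split(","):
                if len(ref) != 1 or len(alt) != 1:
                    continue
                for sidx, sname in enumerate(sample_names):
                    call = fields[9 + sidx].split(":")
                    info = dict(zip(fmt, call))
                    gt = info.get("GT", "./.")
                    if not any(ch not in "0./|" for ch in gt):
                        continue
                    depth, af = np.nan, np.nan
                    if "AD" in info:
                        try:
                            ads = [int(x) for x in info["AD"].split(",")]
                            depth = sum(ads)
                            af = ads[1] / depth if depth > 0 and len(ads) > 1 else np.nan
                        except ValueError:
                            pass
                    rows.append((chrom, pos, ref, alt, sname, depth, np.nan, af))
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "sample", "tumor_depth", "normal_depth", "af"],
    )
    return MutationCatalog(_normalize_frame(df, position_base=1), provenance=provenance)


def apply_quality_filters(
    cat: MutationCatalog,
    min_tumor_depth: int = 14,
    min_normal_depth: int = 8,
    min_af: float = 0.10,
) -> MutationCatalog:
    """Retain mutations with sufficient coverage and allelic fraction.

    All three thresholds are inclusive (>=); defaults are 14x tumor, 8x
    matched normal and allelic fraction 0.10.
    """
    if min(min_tumor_depth, min_normal_depth, min_af) < 0:
        raise ValueError("thresholds must be >= 0")
    df = cat.df
    keep = (
        (df["tumor_depth"] >= min_tumor_depth)
        & (df["normal_depth"] >= min_normal_depth)
        & (df["af"] >= min_af)
    )
    return cat.subset(keep.to_numpy())


def exclude_by_tracks(cat: MutationCatalog, masks: list[IntervalTrack]) -> MutationCatalog:
    """Remove mutations whose 1-bp interval intersects any mask track.

    Removal counts are logged per mask.  Half-open convention: a mutation at
    the exclusive end coordinate of a mask interval is retained.
    """
    keep = np.ones(len(cat.df), dtype=bool)
    for mask in masks:
        merged = merge_overlapping(mask)
        hit = np.zeros(len(cat.df), dtype=bool)
        for chrom in merged.chromosomes:
            sel = (cat.df["chrom"] == chrom).to_numpy()
            if not sel.any():
                continue
            pos = cat.df.loc[sel, "pos"].to_numpy()
            ms, me = merged.on(chrom)
            # position is inside a mask interval iff the latest interval
            # starting at or before pos has end > pos
            idx = np.searchsorted(ms, pos, side="right") - 1
            inside = (idx >= 0) & (me[np.clip(idx, 0, None)] > pos)
            hit[np.flatnonzero(sel)] = inside
        logger.info("mask %r removed %d mutations", mask.name, int((hit & keep).sum()))
        keep &= ~hit
    return cat.subset(keep)


def count_per_interval(cat: MutationCatalog, dhs_list: list[MaskedDHS]) -> pd.DataFrame:
    """Count mutations per masked DHS, on unmasked pieces only.

    Returns a DataFrame indexed like ``dhs_list`` with columns ``dhs_id``,
    ``n`` and ``samples`` (sorted list of contributing sample ids).
    """
    records = []
    by_chrom = {c: cat.df[cat.df["chrom"] == c] for c in cat.df["chrom"].unique()}
    for dhs in dhs_list:
        sub = by_chrom.get(dhs.chrom)
        n = 0
        samples: set[str] = set()
        if sub is not None and len(sub):
            pos = sub["pos"].to_numpy()
            lo = np.searchsorted(pos, dhs.start, side="left")
            hi = np.searchsorted(pos, dhs.end, side="left")
            for s, e in dhs.pieces:
                plo = np.searchsorted(pos, s, side="left")
                phi = np.searchsorted(pos, e, side="left")
                if phi > plo:
                    n += int(phi - plo)
                    samples.update(sub["sample"].iloc[plo:phi])
            del lo, hi
        records.append((dhs.dhs_id, n, sorted(samples)))
    return pd.DataFrame(records, columns=["dhs_id", "n", "samples"])


def count_in_region(cat: MutationCatalog, chrom: str, pieces: list[tuple[int, int]]) -> int:
    """Total mutations falling in a set of half-open pieces on one chromosome."""
    pos = cat.on(chrom)
    n = 0
    for s, e in pieces:
        n += int(np.searchsorted(pos, e, side="left") - np.searchsorted(pos, s, side="left"))
    return n
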