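"""Enrichment filters applied to significantly mutated DHSs.

Filter 2 removes DHSs whose sequencing/alignment quality is an outlier
within their own covariate cluster (read-count or read-quality Z below -2,
or improperly-aligned-read-fraction Z above +2).  Filter 3 keeps DHSs with
a known target gene within 500 kb — linked by a physical or predicted
interaction — that is aberrantly expressed (two-sided rank-sum p < 0.05) in
the tumors carrying the DHS mutation, with genes overlapping a CNV in any
mutated sample excluded.  Filter 4 requires recurrence: at least one
mutation in each of two independent replication catalogs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import MutationCatalog, count_in_region
from .intervals import GenomicInterval, IntervalTrack, MaskedDHS

logger = logging.getLogger(__name__)

__all__ = [
    "quality_filter",
    "link_targets",
    "aberrant_expression_test",
    "median_of_ratios_factors",
    "cnv_exclude",
    "replication_filter",
    "enrichment_comparison",
    "InteractionEvidence",
]

QUALITY_METRICS = ("mean_read_count", "mean_read_quality", "improper_fraction")


@dataclass(frozen=True)
class InteractionEvidence:
    """One pairwise interaction (BEDPE-like), e.g. Hi-C / ChIA-PET / predicted."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    source: str = ""


def quality_filter(records: pd.DataFrame, labels: np.ndarray, z_cutoff: float = 2.0):
    """Cluster-relative sequencing-quality exclusion (Filter 2).

    ``records`` holds one row per DHS with the three metric columns
    (``mean_read_count``, ``mean_read_quality``, ``improper_fraction``);
    ``labels`` gives each DHS's cluster.  Z-scores are computed against the
    DHS's own cluster mean/SD (population SD).  A DHS is removed iff
    read-count Z < -cutoff OR read-quality Z < -cutoff OR improper-fraction
    Z > +cutoff (strict inequalities).  Zero-SD metrics leave Z undefined
    and the DHS retained (warned).

    Returns ``(retained_mask, zscores)``.
    """
    missing = set(QUALITY_METRICS) - set(records.columns)
    if missing:
        raise ValueError(f"quality records missing columns: {sorted(missing)}")
    labels = np.asarray(labels)
    z = pd.DataFrame(index=records.index, columns=QUALITY_METRICS, dtype=float)
    for metric in QUALITY_METRICS:
        x = records[metric].to_numpy(dtype=float)
        for cl in np.unique(labels):
            sel = labels == cl
            mean, sd = float(x[sel].mean()), float(x[sel].std())
            if sd == 0.0:
                logger.warning("cluster %s: zero SD for %s; DHSs retained", cl, metric)
                z.loc[sel, metric] = np.nan
            else:
                z.loc[sel, metric] = (x[sel] - mean) / sd
    removed = (
        (z["mean_read_count"] < -z_cutoff)
        | (z["mean_read_quality"] < -z_cutoff)
        | (z["improper_fraction"] > z_cutoff)
    ).fillna(False)
    return ~removed.to_numpy(), z


def _promoter(gene_start: int, gene_end: int, window: int) -> tuple[int, int]:
    # unstranded gene table: promoter window taken upstream of the start
    return max(0, gene_start - window), gene_start


def link_targets(
    dhs: MaskedDHS,
    genes: pd.DataFrame,
    interactions: list[InteractionEvidence],
    max_distance: int = 500_000,
    promoter_window: int = 2_000,
) -> pd.DataFrame:
    """Candidate target genes of a DHS (Filter 3, linkage step).

    A gene qualifies iff its body lies within ``max_distance`` bp of the DHS
    (edge-to-edge) AND some interaction has one anchor overlapping the DHS
    and the other overlapping the gene body or its promoter (default 2 kb
    upstream of the gene start).  ``genes`` needs columns ``gene``,
    ``chrom``, ``start``, ``end``.
    """
    dhs_iv = dhs.interval
    rows = []
    anchored = [
        ev for ev in interactions
        if ev.anchor1.overlaps(dhs_iv) or ev.anchor2.overlaps(dhs_iv)
    ]
    for g in genes.itertuples(index=False):
        if g.chrom != dhs.chrom:
            continue
        distance = max(0, max(g.start - dhs.end, dhs.start - g.end))
        if distance > max_distance:
            continue
        body = GenomicInterval(g.chrom, int(g.start), int(g.end))
        ps, pe = _promoter(int(g.start), int(g.end), promoter_window)
        prom = GenomicInterval(g.chrom, ps, pe) if pe > ps else None
        evidence = []
        for ev in anchored:
            other = ev.anchor2 if ev.anchor1.overlaps(dhs_iv) else ev.anchor1
            if other.overlaps(body) or (prom is not None and other.overlaps(prom)):
                evidence.append(ev.source or "interaction")
        if evidence:
            rows.append((g.gene, distance, ";".join(evidence)))
    return pd.DataFrame(rows, columns=["gene", "distance", "evidence"])


def aberrant_expression_test(tumor_values, normal_values) -> tuple[float, str]:
    """Two-sided rank-sum comparison of tumor vs normal-panel expression.

    Exact distribution when both groups have <= 25 values and no ties span
    the groups; normal approximation with continuity correction otherwise.
    Returns ``(p, direction)`` with direction 'over', 'under' or 'none' (by
    median difference).  All values identical gives p = 1.
    """
    t = np.asarray(tumor_values, dtype=float)
    m = np.asarray(normal_values, dtype=float)
    if t.size < 1 or m.size < 2:
        raise ValueError("need >=1 tumor and >=2 normal values")
    if np.all(t == t[0]) and np.all(m == t[0]):
        return 1.0, "none"
    pooled = np.concatenate([t, m])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (t.size <= 25 and m.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(t, m, alternative="two-sided", method=method,
                             use_continuity=True)
    med_diff = float(np.median(t) - np.median(m))
    direction = "over" if med_diff > 0 else ("under" if med_diff < 0 else "none")
    return float(res.pvalue), direction


def median_of_ratios_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors for a count matrix.

    Rows are genes, columns samples.  The pseudo-reference is the geometric
    mean across samples over genes expressed everywhere; each sample's
    factor is the median ratio to that reference.  Dividing a sample's
    counts by its factor puts samples on a common scale.
    """
    counts = matrix.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with positive counts in every sample")
    logref = np.log(counts[positive]).mean(axis=1)
    factors = np.exp(np.median(np.log(counts[positive]) - logref[:, None], axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def cnv_exclude(
    gene_interval: GenomicInterval,
    mutated_samples: list[str],
    cnv_tracks: dict[str, IntervalTrack],
) -> bool:
    """True iff the gene body overlaps a CNV in any sample mutated at the DHS."""
    from .intervals import overlaps_any

    for sample in mutated_samples:
        track = cnv_tracks.get(sample)
        if track is not None and overlaps_any(gene_interval, track):
            return True
    return False


def replication_filter(
    candidates: list[MaskedDHS], replication_catalogs: list[MutationCatalog]
) -> pd.DataFrame:
    """Recurrence in independent replication sets (Filter 4).

    A DHS passes iff it carries >= 1 mutation (on unmasked pieces) in every
    replication catalog.  Returns per-DHS per-set counts and the pass flag.
    """
    rows = []
    for dhs in candidates:
        counts = [
            count_in_region(cat, dhs.chrom, dhs.pieces) for cat in replication_catalogs
        ]
        rows.append((dhs.dhs_id, *counts, all(c >= 1 for c in counts)))
    cols = ["dhs_id"] + [f"n_rep{i+1}" for i in range(len(replication_catalogs))] + ["passed"]
    return pd.DataFrame(rows, columns=cols)


def enrichment_comparison(
    group_a: tuple[int, int], group_b: tuple[int, int], method: str = "chi2"
) -> tuple[float, float]:
    """2x2 contingency test of hit proportions between two groups.

    Each group is ``(hits, total)``; rows of the table are (hits,
    total - hits).  Returns ``(statistic, p)``; for Fisher the statistic is
    the odds ratio.
    """
    (a_hits, a_total), (b_hits, b_total) = group_a, group_b
    if a_total <= 0 or b_total <= 0:
        raise ValueError("group totals must be > 0")
    table = np.array([[a_hits, a_total - a_hits], [b_hits, b_total - b_hits]])
    if (table < 0).any():
        raise ValueError("hits cannot exceed totals")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table (zero margin)")
    if method == "chi2":
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p)
    if method == "fisher":
        odds, p = stats.fisher_exact(table)
        return float(odds), float(p)
    raise ValueError("method must be 'chi2' or 'fisher'")
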