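"""Pan-cancer recurrence tests for candidate driver DHSs.

Two tests against pooled multi-tumor-type catalogs: the *interval* analysis
compares a DHS's mutation density with its +/-50 kb flanks (repeat-masked
bases only), and the *cluster* analysis compares it with 20 DHSs sampled at
random from the same covariate cluster.  Both reduce to the same Poisson
tail: a background per-bp rate mu is estimated from the comparison region,
lambda_hat = mu * L_dhs, and p = P(X >= n_dhs | lambda_hat).  Significance
is set by the empirical simulated-null FDR at q = 0.05; a pan-cancer
recurrence call requires significance in both tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import MutationCatalog, count_in_region
from .intervals import GenomicInterval, IntervalTrack, MaskedDHS, flanks, mask_track
from .significance import fdr_curve, poisson_tail_p, poisson_tail_p_array, select_threshold

logger = logging.getLogger(__name__)

__all__ = ["RecurrenceResult", "interval_analysis", "cluster_analysis", "recurrence_fdr"]


@dataclass
class RecurrenceResult:
    dhs_id: str
    basis: str            # "interval" or "cluster"
    n_dhs: int
    background_mu: float  # per-bp background rate
    lam: float            # background_mu * L_dhs
    p: float
    defined: bool = True


def _masked_pieces(region: GenomicInterval, repeat_track: IntervalTrack | None):
    if repeat_track is None:
        return [(region.start, region.end)]
    dummy = IntervalTrack.from_intervals([region])
    kept, _ = mask_track(dummy, repeat_track)
    return kept[0].pieces if kept else []


def interval_analysis(
    dhs: MaskedDHS,
    catalog: MutationCatalog,
    chrom_length: int,
    flank: int = 50_000,
    repeat_track: IntervalTrack | None = None,
    exclude_track: IntervalTrack | None = None,
) -> RecurrenceResult:
    """Compare a DHS's mutation density with its +/-``flank`` bp flanks.

    Flank densities use non-repetitive bases only.  ``exclude_track`` (e.g.
    the other candidate DHSs) is additionally subtracted from the flanks so
    potentially selected neighbors do not contaminate the background; pass
    None for strict flanks.
    """
    left, right = flanks(dhs.interval, flank, chrom_length)
    pieces: list[tuple[int, int]] = []
    for side in (left, right):
        if side is None:
            continue
        for s, e in _masked_pieces(side, repeat_track):
            pieces.append((s, e))
    if exclude_track is not None:
        pruned = []
        starts, ends = exclude_track.on(dhs.chrom)
        for s, e in pieces:
            pos = s
            i = int(np.searchsorted(ends, s, side="right"))
            while pos < e and i < len(starts) and starts[i] < e:
                xs, xe = int(starts[i]), int(ends[i])
                if xs > pos:
                    pruned.append((pos, min(xs, e)))
                pos = max(pos, xe)
                i += 1
            if pos < e:
                pruned.append((pos, e))
        pieces = pruned
    flank_len = sum(e - s for s, e in pieces)
    n_dhs = count_in_region(catalog, dhs.chrom, dhs.pieces)
    if flank_len == 0:
        logger.warning("DHS %s: zero masked flank length; result undefined", dhs.dhs_id)
        return RecurrenceResult(dhs.dhs_id, "interval", n_dhs, np.nan, np.nan, np.nan, False)
    n_flank = count_in_region(catalog, dhs.chrom, pieces)
    mu = n_flank / flank_len
    lam = mu * dhs.length
    return RecurrenceResult(dhs.dhs_id, "interval", n_dhs, mu, lam, poisson_tail_p(n_dhs, lam))


def cluster_analysis(
    dhs: MaskedDHS,
    cluster_members: pd.DataFrame,
    catalog: MutationCatalog | None = None,
    n_background: int = 20,
    seed: int | None = None,
    dhs_n: int | None = None,
) -> RecurrenceResult:
    """Compare a DHS with ``n_background`` random same-cluster DHSs.

    ``cluster_members`` has one row per *other* cluster member with columns
    ``dhs_id``, ``n``, ``L``.  The focal DHS's own count may be given as
    ``dhs_n``; otherwise it is recounted from ``catalog``.
    """
    members = cluster_members[cluster_members["dhs_id"] != dhs.dhs_id]
    rng = np.random.default_rng(seed)
    if len(members) < n_background:
        logger.warning(
            "cluster of %s has only %d other members (< %d); using all",
            dhs.dhs_id, len(members), n_background,
        )
        sample = members
    else:
        sample = members.iloc[rng.choice(len(members), size=n_background, replace=False)]
    if dhs_n is None:
        if catalog is None:
            raise ValueError("need dhs_n or a catalog to count focal mutations")
        dhs_n = count_in_region(catalog, dhs.chrom, dhs.pieces)
    total_l = float(sample["L"].sum())
    if total_l <= 0:
        return RecurrenceResult(dhs.dhs_id, "cluster", dhs_n, np.nan, np.nan, np.nan, False)
    mu = float(sample["n"].sum()) / total_l
    lam = mu * dhs.length
    return RecurrenceResult(dhs.dhs_id, "cluster", dhs_n, mu, lam, poisson_tail_p(dhs_n, lam))


def recurrence_fdr(
    results: list[RecurrenceResult],
    q: float = 0.05,
    replicates: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Empirical-FDR thresholding of one recurrence test's results.

    The null pool is simulated from each result's own lambda_hat (counts
    redrawn Poisson, p recomputed), reusing the significance module's FDR
    curve.  Returns a per-DHS frame with p and the significant flag.
    """
    defined = [r for r in results if r.defined]
    if not defined:
        return pd.DataFrame(columns=["dhs_id", "basis", "n", "lambda_hat", "p", "significant"])
    lam = np.array([r.lam for r in defined])
    obs_p = np.array([r.p for r in defined])
    rng = np.random.default_rng(seed)
    pools = []
    for _ in range(replicates):
        n_sim = rng.poisson(lam)
        pools.append(poisson_tail_p_array(n_sim, lam))
    curve = fdr_curve(obs_p, np.concatenate(pools))
    p_star, _ = select_threshold(curve, q)
    sig = obs_p < p_star if p_star is not None else np.zeros(len(defined), bool)
    return pd.DataFrame(
        {
            "dhs_id": [r.dhs_id for r in defined],
            "basis": [r.basis for r in defined],
            "n": [r.n_dhs for r in defined],
            "lambda_hat": lam,
            "p": obs_p,
            "significant": sig,
        }
    )


def combined_calls(interval_results: pd.DataFrame, cluster_results: pd.DataFrame) -> list[str]:
    """DHSs significant in BOTH the interval and the cluster analysis."""
    a = set(interval_results.loc[interval_results["significant"], "dhs_id"])
    b = set(cluster_results.loc[cluster_results["significant"], "dhs_id"])
    return sorted(a & b)
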