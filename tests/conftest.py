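import numpy as np
import pandas as pd
import pytest

from dhsdriver.catalog import MutationCatalog
from dhsdriver.intervals import IntervalTrack


def make_track(rows, name="t"):
    """rows: list of (chrom, start, end[, extra...])."""
    ncols = max(len(r) for r in rows) if rows else 3
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(4, ncols + 1)]
    return IntervalTrack(pd.DataFrame(rows, columns=cols[: ncols]), name=name)


def make_catalog(rows, **kwargs):
    """rows: list of (chrom, pos0, ref, alt, sample[, tdepth, ndepth, af])."""
    full = []
    for r in rows:
        r = list(r) + [50, 30, 0.5][len(r) - 5 :]
        full.append(r)
    df = pd.DataFrame(
        full,
        columns=["chrom", "pos", "ref", "alt", "sample", "tumor_depth", "normal_depth", "af"],
    )
    return MutationCatalog(df, **kwargs)


def base_set(track):
    """Per-base boolean oracle: set of (chrom, pos) covered by a track."""
    out = set()
    for iv in track:
        out.update((iv.chrom, p) for p in range(iv.start, iv.end))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)
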