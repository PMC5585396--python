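"""Synthetic data with the statistical structure the method assumes.

Two granularities:

* :func:`simulate_cohort` — count-level cohorts (one row per DHS with
  covariates, masked length, true rate and Poisson count) for calibration
  and driver-recovery experiments at scale.  Rates are constant within
  latent covariate archetypes, the structure k-means is meant to recover.
* :func:`simulate_genome` / :func:`simulate_mutations` /
  :func:`simulate_expression` — full fixtures (FASTA, BED tracks, covariate
  tracks, mutation TSVs, expression matrices, BEDPE interactions, CNVs)
  exercising the whole pipeline end to end on a small multi-chromosome
  genome.

Defaults emulate a pooled multi-hundred-genome somatic catalog (cohort-wide
density 3e-3 mutations/bp) over DHSs with the cohort length scale of real
DNase tracks (~300 bp median).  Everything is deterministic under a fixed
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import MutationCatalog
from .intervals import IntervalTrack

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "simulate_genome",
    "simulate_mutations",
    "simulate_expression",
    "GenomeFixture",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic generative model (defaults = study conditions)."""

    # genome
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 400_000, "chr2": 300_000, "chr3": 300_000}
    )
    gc_targets: dict[str, float] = field(
        default_factory=lambda: {"chr1": 0.38, "chr2": 0.46, "chr3": 0.52}
    )
    n_dhs: int = 600
    dhs_length_log_mean: float = math.log(300.0)
    dhs_length_log_sd: float = 0.5
    repeat_density: float = 0.10       # fraction of genome masked
    repeat_length_mean: int = 300
    n_genes: int = 45
    gene_length_mean: int = 15_000
    score_tile: int = 20_000           # covariate track resolution (bp)
    # mutations
    n_samples: int = 20
    baseline_rate: float = 3e-3        # cohort-wide mutations per bp
    rate_spread: float = 0.5           # log-normal spread of archetype rates
    n_archetypes_per_chrom: int = 4
    intergenic_rate_factor: float = 1.0
    # drivers
    n_drivers: int = 0
    driver_multiplier: float = 5.0
    driver_min_length: int = 1_000
    driver_max_length: int = 2_500
    # kataegis injection
    n_kataegis: int = 0
    kataegis_mutations: int = 8
    kataegis_gap_scale: int = 200      # mean gap; gaps uniform on [1, 2*scale]
    # expression
    n_normals: int = 20
    expression_mean: float = 200.0
    expression_dispersion: float = 0.15
    driver_target_shift: float = 4.0   # fold-change in tumors mutated at a driver
    n_decoy_interactions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dhs <= 0 or self.n_samples <= 0:
            raise ValueError("counts must be > 0")
        if self.driver_multiplier < 1:
            raise ValueError("driver multiplier must be >= 1")
        if 2 * self.kataegis_gap_scale >= 1000:
            raise ValueError("kataegis gap scale too large to form sub-kb loci")


# ---------------------------------------------------------------------------
# count-level cohorts

def simulate_cohort(
    n_dhs: int = 20_000,
    n_groups: int = 40,
    n_chromosomes: int = 5,
    n_drivers: int = 0,
    driver_multiplier: float = 5.0,
    driver_min_length: int = 1_000,
    driver_max_length: int = 2_500,
    baseline_rate: float = 3e-3,
    rate_spread: float = 0.5,
    covariate_noise: float = 0.15,
    seed: int | None = None,
) -> pd.DataFrame:
    """A count-level DHS cohort with covariate-structured Poisson rates.

    Each chromosome carries its own set of archetypes (latent rate groups);
    a DHS's five covariates sit near its archetype's center and its neutral
    rate is the archetype rate.  Driver DHSs get ``driver_multiplier`` times
    the neutral rate and lengths drawn uniform on
    ``[driver_min_length, driver_max_length]``.

    Returns one row per DHS: ``dhs_id``, ``chrom``, ``group`` (ground-truth
    archetype), ``L``, ``n``, ``mu_true``, ``is_driver`` and the five
    covariate columns.
    """
    rng = np.random.default_rng(seed)
    per_chrom = max(1, n_groups // n_chromosomes)
    chrom_of_group = np.repeat(np.arange(n_chromosomes), per_chrom)[:n_groups]
    centers = rng.standard_normal((n_groups, 5))
    # archetype rates: log-normal around baseline, mean-corrected
    group_rate = baseline_rate * np.exp(
        rate_spread * rng.standard_normal(n_groups) - rate_spread**2 / 2
    )
    group = rng.integers(0, n_groups, n_dhs)
    chrom = np.array([f"chr{c + 1}" for c in chrom_of_group[group]])
    X = centers[group] + covariate_noise * rng.standard_normal((n_dhs, 5))
    L = np.exp(rng.normal(math.log(300.0), 0.5, n_dhs)).clip(100, 5000).astype(np.int64)
    is_driver = np.zeros(n_dhs, dtype=bool)
    if n_drivers > 0:
        drv = rng.choice(n_dhs, size=n_drivers, replace=False)
        is_driver[drv] = True
        L[drv] = rng.integers(driver_min_length, driver_max_length + 1, n_drivers)
    mu_true = group_rate[group]
    mult = np.where(is_driver, driver_multiplier, 1.0)
    n = rng.poisson(mult * mu_true * L)
    cov_cols = [
        "replication_timing",
        "chromatin_compartment",
        "gc_content",
        "gene_density",
        "expected_mutation_rate",
    ]
    df = pd.DataFrame(X, columns=cov_cols)
    df.insert(0, "dhs_id", [f"dhs{i:06d}" for i in range(n_dhs)])
    df.insert(1, "chrom", chrom)
    df.insert(2, "group", group)
    df.insert(3, "L", L)
    df.insert(4, "n", n)
    df.insert(5, "mu_true", mu_true)
    df.insert(6, "is_driver", is_driver)
    return df


# ---------------------------------------------------------------------------
# full genome fixtures

@dataclass
class GenomeFixture:
    sequences: dict[str, str]
    chrom_lengths: dict[str, int]
    dhs_track: IntervalTrack
    repeat_track: IntervalTrack
    gene_track: IntervalTrack
    replication_timing: pd.DataFrame
    compartment: pd.DataFrame
    dhs_archetype: np.ndarray       # latent rate group per DHS
    archetype_rate: np.ndarray      # per-bp neutral rate per archetype


def _random_sequence(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _place_intervals(rng, chrom_length, n, lengths, forbidden=None):
    """Place n non-overlapping intervals of given lengths uniformly."""
    placed = []
    taken = sorted(forbidden or [])
    attempts = 0
    i = 0
    while i < n and attempts < 50 * n:
        attempts += 1
        ln = int(lengths[i % len(lengths)])
        if ln >= chrom_length:
            i += 1
            continue
        s = int(rng.integers(0, chrom_length - ln))
        e = s + ln
        if any(s < te and ts < e for ts, te in taken):
            continue
        taken.append((s, e))
        taken.sort()
        placed.append((s, e))
        i += 1
    return placed


def simulate_genome(config: SimulationConfig, outdir: str | Path | None = None) -> GenomeFixture:
    """Generate a small multi-chromosome genome with DHS/repeat/gene tracks.

    Trinucleotide composition varies across chromosomes via per-chromosome
    GC targets.  Covariate tracks (replication timing, compartment score)
    are smooth tilings; each chromosome hosts its own DHS archetypes whose
    latent scores feed both the tracks and the mutation rates.
    """
    rng = np.random.default_rng(config.seed)
    sequences = {
        c: _random_sequence(rng, ln, config.gc_targets.get(c, 0.42))
        for c, ln in config.chrom_lengths.items()
    }
    chroms = list(config.chrom_lengths)
    genome_len = sum(config.chrom_lengths.values())

    # archetypes: per chromosome, with smooth latent covariates and a rate
    n_arch = config.n_archetypes_per_chrom * len(chroms)
    arch_rate = config.baseline_rate * np.exp(
        config.rate_spread * rng.standard_normal(n_arch) - config.rate_spread**2 / 2
    )

    # driver-sized DHS lengths planted up front (oversampled so that repeat
    # masking cannot shrink the eligible pool below n_drivers)
    driver_lengths = list(
        rng.integers(config.driver_min_length, config.driver_max_length + 1,
                     2 * config.n_drivers)
    )

    dhs_rows, dhs_arch = [], []
    repeat_rows, gene_rows = [], []
    rt_rows, cc_rows = [], []
    for ci, chrom in enumerate(chroms):
        clen = config.chrom_lengths[chrom]
        share = max(1, round(config.n_dhs * clen / genome_len))
        lengths = np.exp(
            rng.normal(config.dhs_length_log_mean, config.dhs_length_log_sd, share)
        ).clip(150, 4000).astype(int)
        take = min(len(driver_lengths), max(1, round(2 * config.n_drivers * clen / genome_len)))
        for j in range(min(take, share)):
            lengths[j] = driver_lengths.pop()
        for s, e in sorted(_place_intervals(rng, clen, share, lengths)):
            dhs_rows.append((chrom, s, e))
            dhs_arch.append(
                ci * config.n_archetypes_per_chrom
                + int(rng.integers(0, config.n_archetypes_per_chrom))
            )
        # repeats: random placements to target density (may overlap DHSs)
        n_rep = int(config.repeat_density * clen / config.repeat_length_mean)
        rep_lengths = rng.poisson(config.repeat_length_mean, max(n_rep, 1)).clip(30)
        for s, e in _place_intervals(rng, clen, n_rep, rep_lengths):
            repeat_rows.append((chrom, s, e))
        n_gene = max(1, round(config.n_genes * clen / genome_len))
        gene_lengths = rng.poisson(config.gene_length_mean, n_gene).clip(2000)
        for gi, (s, e) in enumerate(sorted(_place_intervals(rng, clen, n_gene, gene_lengths))):
            gene_rows.append((chrom, s, e, f"{chrom}_g{gi}"))
        # smooth covariate tracks: random walks over tiles
        n_tiles = math.ceil(clen / config.score_tile)
        rt = np.cumsum(rng.normal(0, 0.15, n_tiles))
        cc = np.cumsum(rng.normal(0, 0.15, n_tiles))
        for t in range(n_tiles):
            s, e = t * config.score_tile, min(clen, (t + 1) * config.score_tile)
            rt_rows.append((chrom, s, e, float(rt[t])))
            cc_rows.append((chrom, s, e, float(cc[t])))

    fixture = GenomeFixture(
        sequences=sequences,
        chrom_lengths=dict(config.chrom_lengths),
        dhs_track=IntervalTrack(
            pd.DataFrame(dhs_rows, columns=["chrom", "start", "end"]), name="dhs"
        ),
        repeat_track=IntervalTrack(
            pd.DataFrame(repeat_rows, columns=["chrom", "start", "end"]), name="repeats"
        ),
        gene_track=IntervalTrack(
            pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "col4"]), name="genes"
        ),
        replication_timing=pd.DataFrame(rt_rows, columns=["chrom", "start", "end", "value"]),
        compartment=pd.DataFrame(cc_rows, columns=["chrom", "start", "end", "value"]),
        dhs_archetype=np.array(dhs_arch),
        archetype_rate=arch_rate,
    )
    if outdir is not None:
        _write_genome(fixture, Path(outdir))
    return fixture


def _write_genome(fx: GenomeFixture, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in fx.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    from .intervals import write_bed

    write_bed(fx.dhs_track, outdir / "dhs.bed")
    write_bed(fx.repeat_track, outdir / "repeats.bed")
    write_bed(fx.gene_track, outdir / "genes.bed")
    fx.replication_timing.to_csv(
        outdir / "replication_timing.tsv", sep="\t", header=False, index=False
    )
    fx.compartment.to_csv(outdir / "compartment.tsv", sep="\t", header=False, index=False)


def _draw_positions(rng, pieces: list[tuple[int, int]], k: int) -> np.ndarray:
    lens = np.array([e - s for s, e in pieces])
    if lens.sum() == 0 or k == 0:
        return np.array([], dtype=int)
    offsets = rng.integers(0, lens.sum(), k)
    bounds = np.cumsum(lens)
    piece_idx = np.searchsorted(bounds, offsets, side="right")
    within = offsets - np.concatenate([[0], bounds[:-1]])[piece_idx]
    return np.array([pieces[i][0] + int(w) for i, w in zip(piece_idx, within)])


def simulate_mutations(
    config: SimulationConfig, fixture: GenomeFixture
) -> tuple[MutationCatalog, pd.DataFrame]:
    """Draw a somatic catalog over a genome fixture, with ground truth.

    Per-DHS counts are Poisson with the archetype rate times the unmasked
    length; driver DHSs (the ``n_drivers`` longest, to respect the minimum
    driver length) get the configured multiplier.  Positions are uniform on
    unmasked pieces.  Intergenic background mutations cover the rest of the
    genome at the baseline rate, and ``n_kataegis`` tight mutation clusters
    are injected at random sites in random samples.

    Returns the catalog plus a ground-truth table (per-DHS true rate,
    driver flag, injected count) with kataegis loci listed in its ``attrs``.
    """
    from .intervals import mask_track

    rng = np.random.default_rng(config.seed + 1)
    masked, _dropped = mask_track(fixture.dhs_track, fixture.repeat_track)
    arch = fixture.dhs_archetype
    # map masked DHSs back to track rows via footprint
    foot_to_arch = {
        (r.chrom, int(r.start), int(r.end)): arch[i]
        for i, r in enumerate(fixture.dhs_track.df.itertuples(index=False))
    }
    samples = [f"s{j:03d}" for j in range(config.n_samples)]
    rows = []
    truth_rows = []
    # drivers: longest masked DHSs satisfying the minimum length
    order = np.argsort([-d.length for d in masked])
    driver_idx = set()
    for i in order:
        if len(driver_idx) >= config.n_drivers:
            break
        if masked[i].length >= config.driver_min_length:
            driver_idx.add(i)

    def add_mutation(chrom, pos, sample):
        seq = fixture.sequences[chrom]
        ref = seq[pos]
        if ref not in "ACGT":
            return
        alt = rng.choice([b for b in "ACGT" if b != ref])
        t_depth = 30 + rng.poisson(30)
        n_depth = 20 + rng.poisson(20)
        af = float(np.clip(rng.beta(5, 5), 0.12, 0.95))
        rows.append((chrom, pos + 1, ref, alt, sample, t_depth, n_depth, af))

    for i, dhs in enumerate(masked):
        a = foot_to_arch[(dhs.chrom, dhs.start, dhs.end)]
        mu = fixture.archetype_rate[a]
        mult = config.driver_multiplier if i in driver_idx else 1.0
        k = rng.poisson(mult * mu * dhs.length)
        for pos in _draw_positions(rng, dhs.pieces, k):
            add_mutation(dhs.chrom, int(pos), samples[rng.integers(0, len(samples))])
        truth_rows.append((dhs.dhs_id, dhs.chrom, dhs.length, mu, i in driver_idx, int(k)))

    # intergenic background outside DHS footprints
    for chrom, clen in fixture.chrom_lengths.items():
        starts, ends = fixture.dhs_track.on(chrom)
        pieces, pos = [], 0
        for s, e in zip(starts, ends):
            if s > pos:
                pieces.append((pos, int(s)))
            pos = max(pos, int(e))
        if pos < clen:
            pieces.append((pos, clen))
        bg_len = sum(e - s for s, e in pieces)
        k = rng.poisson(config.intergenic_rate_factor * config.baseline_rate * bg_len)
        for p in _draw_positions(rng, pieces, k):
            add_mutation(chrom, int(p), samples[rng.integers(0, len(samples))])

    # kataegis injection: tight runs in a single sample
    kataegis_truth = []
    chroms = list(fixture.chrom_lengths)
    for _ in range(config.n_kataegis):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = fixture.chrom_lengths[chrom]
        gaps = rng.integers(1, 2 * config.kataegis_gap_scale + 1, config.kataegis_mutations - 1)
        span = int(gaps.sum())
        start = int(rng.integers(0, clen - span - 1))
        sample = samples[int(rng.integers(0, len(samples)))]
        positions = start + np.concatenate([[0], np.cumsum(gaps)])
        for p in positions:
            add_mutation(chrom, int(p), sample)
        kataegis_truth.append((chrom, int(positions[0]), int(positions[-1]) + 1, sample))

    cat_df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "sample", "tumor_depth", "normal_depth", "af"],
    )
    catalog = MutationCatalog(
        cat_df.assign(pos=cat_df["pos"] - 1), provenance="synthetic"
    )
    truth = pd.DataFrame(
        truth_rows, columns=["dhs_id", "chrom", "L", "mu_true", "is_driver", "n_injected"]
    )
    truth.attrs["kataegis"] = kataegis_truth
    truth.attrs["seed"] = config.seed
    return catalog, truth


def simulate_expression(
    config: SimulationConfig,
    fixture: GenomeFixture,
    truth: pd.DataFrame,
    catalog: MutationCatalog,
) -> dict:
    """Expression matrix, interaction list and CNV tracks for Filter 3.

    Normal-panel counts are negative-binomial (mean--dispersion); tumor
    samples carrying a mutation in a driver DHS have the configured
    fold-shift on that driver's target gene (the nearest gene within
    500 kb).  Each driver gets a linking interaction; decoy interactions
    connect random DHSs and genes.
    """
    from .filters import InteractionEvidence
    from .intervals import GenomicInterval

    rng = np.random.default_rng(config.seed + 2)
    genes = fixture.gene_track.df
    gene_ids = list(genes["col4"])
    samples = [f"s{j:03d}" for j in range(config.n_samples)]
    normals = [f"n{j:03d}" for j in range(config.n_normals)]

    def nb(mean, size):
        # NB via gamma-Poisson; dispersion d gives var = mean + d*mean^2
        d = config.expression_dispersion
        shape = 1.0 / d
        lam = rng.gamma(shape, mean * d, size)
        return rng.poisson(lam)

    base_mean = config.expression_mean * np.exp(rng.normal(0, 0.3, len(gene_ids)))
    expr = {}
    for j, s in enumerate(normals + samples):
        expr[s] = nb(base_mean, len(gene_ids))
    matrix = pd.DataFrame(expr, index=gene_ids)

    interactions: list[InteractionEvidence] = []
    targets = {}
    driver_rows = truth[truth["is_driver"]]
    for row in driver_rows.itertuples(index=False):
        chrom, se = row.dhs_id.split(":")
        s, e = map(int, se.split("-"))
        cand = genes[genes["chrom"] == chrom]
        if cand.empty:
            continue
        dist = np.maximum(0, np.maximum(cand["start"] - e, s - cand["end"]))
        near = cand[dist <= 500_000]
        if near.empty:
            continue
        g = near.iloc[int(np.argmin(dist[dist <= 500_000].to_numpy()))]
        targets[row.dhs_id] = g["col4"]
        interactions.append(
            InteractionEvidence(
                GenomicInterval(chrom, s, e),
                GenomicInterval(g["chrom"], int(g["start"]), int(g["end"])),
                source="synthetic-assay",
            )
        )
        # shift target expression in tumors mutated at this driver
        pos = catalog.df[
            (catalog.df["chrom"] == chrom)
            & (catalog.df["pos"] >= s)
            & (catalog.df["pos"] < e)
        ]
        mutated = sorted(set(pos["sample"]))
        gi = gene_ids.index(g["col4"])
        for sm in mutated:
            if sm in matrix.columns:
                matrix.loc[g["col4"], sm] = nb(
                    base_mean[gi] * config.driver_target_shift, 1
                )[0]
    for _ in range(config.n_decoy_interactions):
        d = fixture.dhs_track.df.iloc[int(rng.integers(0, len(fixture.dhs_track.df)))]
        g = genes.iloc[int(rng.integers(0, len(genes)))]
        interactions.append(
            InteractionEvidence(
                GenomicInterval(d["chrom"], int(d["start"]), int(d["end"])),
                GenomicInterval(g["chrom"], int(g["start"]), int(g["end"])),
                source="synthetic-decoy",
            )
        )
    # CNVs: a few random intervals per tumor sample
    cnv_tracks = {}
    for s in samples:
        rows = []
        for _ in range(2):
            chrom = list(fixture.chrom_lengths)[int(rng.integers(0, len(fixture.chrom_lengths)))]
            clen = fixture.chrom_lengths[chrom]
            ln = int(rng.integers(5_000, 40_000))
            st = int(rng.integers(0, clen - ln))
            rows.append((chrom, st, st + ln))
        cnv_tracks[s] = IntervalTrack(
            pd.DataFrame(rows, columns=["chrom", "start", "end"]), name=f"cnv_{s}"
        )
    return {
        "matrix": matrix,
        "normal_samples": normals,
        "tumor_samples": samples,
        "interactions": interactions,
        "targets": targets,
        "cnv": cnv_tracks,
    }
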