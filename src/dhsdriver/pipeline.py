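"""End-to-end orchestration of the driver-DHS analysis.

Stages: catalog filtering -> kataegis exclusion -> DHS preprocessing
(merge, repeat masking) -> covariates -> per-chromosome clustering ->
cluster-Poisson significance with empirical FDR (Filter 1) -> quality
(Filter 2) -> target-gene association with aberrant expression and CNV
exclusion (Filter 3) -> replication recurrence (Filter 4).  Every stage's
table is written under the run directory together with a manifest of all
parameters and the seed; stage counts are logged so a run can be audited
filter by filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from .catalog import (
    MutationCatalog,
    apply_quality_filters,
    count_per_interval,
    exclude_by_tracks,
    read_catalog,
)
from .clustering import CovariateKMeans, summarize_clusters
from .filters import (
    InteractionEvidence,
    aberrant_expression_test,
    cnv_exclude,
    link_targets,
    quality_filter,
    replication_filter,
)
from .intervals import (
    GenomicInterval,
    IntervalTrack,
    MaskedDHS,
    mask_track,
    merge_overlapping,
    read_bed,
)
from .kataegis import KataegisDetector, loci_to_frame
from .significance import ClusterPoissonTest

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_all", "read_bedpe"]


@dataclass
class RunConfig:
    """Paths and parameters of a full run; defaults are the method's own."""

    # inputs
    fasta: str | None = None
    dhs_bed: str = ""
    repeat_bed: str | None = None
    gene_bed: str | None = None
    dbsnp_bed: str | None = None
    mutations_tsv: str = ""
    replication_timing_tsv: str | None = None
    compartment_tsv: str | None = None
    quality_tsv: str | None = None
    expression_tsv: str | None = None
    interactions_bedpe: str | None = None
    cnv_dir: str | None = None
    replication_tsvs: list[str] = field(default_factory=list)
    normal_samples: list[str] = field(default_factory=list)
    # parameters (defaults are the printed analysis values)
    min_tumor_depth: int = 14
    min_normal_depth: int = 8
    min_af: float = 0.10
    kataegis_min_run: int = 6
    kataegis_max_mean_gap: float = 1000.0
    n_clusters: int = 223
    fdr_target: float = 0.25
    null_replicates: int = 100
    quality_z: float = 2.0
    target_max_distance: int = 500_000
    wilcoxon_alpha: float = 0.05
    seed: int = 0
    outdir: str = "run"


@dataclass
class PipelineResult:
    masked_dhs: list[MaskedDHS]
    counts: pd.DataFrame
    labels: np.ndarray
    test: ClusterPoissonTest
    cascade: list[tuple[str, int]]
    filter_reports: dict[str, pd.DataFrame]
    targets: pd.DataFrame | None = None


def read_bedpe(path) -> list[InteractionEvidence]:
    """Read a BEDPE-like interaction list (6+ tab-separated columns)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 columns")
            out.append(
                InteractionEvidence(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                    GenomicInterval(parts[3], int(parts[4]), int(parts[5])),
                    source=parts[6] if len(parts) > 6 else "",
                )
            )
    return out


def _load_chrom_lengths(fasta_path) -> tuple[dict[str, str], dict[str, int]]:
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), as_raw=True)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    return seqs, {name: len(s) for name, s in seqs.items()}


def run_all(config: RunConfig) -> PipelineResult:
    """Run the full filter cascade; see module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cascade: list[tuple[str, int]] = []
    reports: dict[str, pd.DataFrame] = {}

    # --- mutation catalog and post-calling filters
    catalog = read_catalog(config.mutations_tsv, position_base=1, provenance="discovery")
    n0 = len(catalog)
    catalog = apply_quality_filters(
        catalog, config.min_tumor_depth, config.min_normal_depth, config.min_af
    )
    masks = []
    if config.repeat_bed:
        masks.append(read_bed(config.repeat_bed, name="repeats"))
    if config.dbsnp_bed:
        masks.append(read_bed(config.dbsnp_bed, name="dbsnp"))
    if masks:
        catalog = exclude_by_tracks(catalog, masks)
    logger.info("catalog: %d of %d mutations retained after filters", len(catalog), n0)

    # --- kataegis
    detector = KataegisDetector(config.kataegis_min_run, config.kataegis_max_mean_gap)
    detector.fit(catalog)
    loci_to_frame(detector.loci_).to_csv(outdir / "kataegis.tsv", sep="\t", index=False)

    # --- DHS preprocessing
    dhs_raw = read_bed(config.dhs_bed, name="dhs")
    dhs_merged = merge_overlapping(dhs_raw)
    cascade.append(("merged DHSs", len(dhs_merged)))
    dhs_nok = detector.transform(dhs_merged)
    cascade.append(("after kataegis exclusion", len(dhs_nok)))
    repeat_track = (
        read_bed(config.repeat_bed, name="repeats")
        if config.repeat_bed
        else IntervalTrack(pd.DataFrame(columns=["chrom", "start", "end"]))
    )
    masked, dropped = mask_track(dhs_nok, repeat_track)
    cascade.append(("after repeat masking (L > 0)", len(masked)))

    counts = count_per_interval(catalog, masked)
    counts["L"] = [d.length for d in masked]
    counts["chrom"] = [d.chrom for d in masked]

    # --- covariates
    if not config.fasta:
        raise ValueError("run_all requires a FASTA reference for covariates")
    sequences, chrom_lengths = _load_chrom_lengths(config.fasta)
    spectrum = cov.build_spectrum(sequences, catalog)
    genes = (
        read_bed(config.gene_bed, name="genes")
        if config.gene_bed
        else IntervalTrack(pd.DataFrame(columns=["chrom", "start", "end"]))
    )
    rt = _read_score(config.replication_timing_tsv)
    cc = _read_score(config.compartment_tsv)
    matrix = cov.covariate_matrix(masked, sequences, spectrum, genes, chrom_lengths, rt, cc)
    normalized = cov.normalize_covariates(matrix)
    normalized.to_csv(outdir / "covariates.tsv", sep="\t")

    # --- clustering
    km = CovariateKMeans(n_clusters=config.n_clusters, random_state=config.seed)
    labels = km.fit_predict(
        normalized.to_numpy(),
        chrom=counts["chrom"].to_numpy(),
        lengths=counts["L"].to_numpy(),
    )
    summarize_clusters(labels, counts["L"].to_numpy(), counts["n"].to_numpy()).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False
    )

    # --- Filter 1: significance
    table = pd.DataFrame(
        {"n": counts["n"].to_numpy(), "L": counts["L"].to_numpy(), "cluster": labels},
        index=pd.Index(counts["dhs_id"], name="dhs_id"),
    )
    test = ClusterPoissonTest(
        fdr_target=config.fdr_target,
        null_replicates=config.null_replicates,
        random_state=config.seed,
    ).fit(table)
    test.results_.to_csv(outdir / "significance.tsv", sep="\t")
    test.fdr_curve_.to_frame().to_csv(outdir / "fdr_curve.tsv", sep="\t", index=False)
    survivors = list(test.significant_)
    cascade.append(("Filter 1: significantly mutated", len(survivors)))

    # --- Filter 2: sequencing quality
    if config.quality_tsv:
        qual = pd.read_csv(config.quality_tsv, sep="\t", index_col=0)
        qual = qual.reindex(counts["dhs_id"])
        retained_mask, z = quality_filter(qual, labels, config.quality_z)
        ok = dict(zip(counts["dhs_id"], retained_mask))
        survivors = [d for d in survivors if ok.get(d, True)]
        reports["quality"] = z
    cascade.append(("Filter 2: quality", len(survivors)))

    # --- Filter 3: target gene with aberrant expression, CNV-excluded
    targets = None
    if config.expression_tsv and config.interactions_bedpe:
        expr = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
        interactions = read_bedpe(config.interactions_bedpe)
        cnv_tracks = _load_cnvs(config.cnv_dir)
        by_id = {d.dhs_id: d for d in masked}
        sample_of = dict(zip(counts["dhs_id"], counts["samples"]))
        gene_df = genes.df.rename(columns={"col4": "gene"})
        normal_cols = config.normal_samples or [
            c for c in expr.columns if c.startswith("n")
        ]
        rows = []
        passing = []
        for dhs_id in survivors:
            dhs = by_id[dhs_id]
            cand = link_targets(dhs, gene_df, interactions, config.target_max_distance)
            mutated = [s for s in sample_of.get(dhs_id, []) if s in expr.columns]
            hit = False
            for g in cand.itertuples(index=False):
                if g.gene not in expr.index or not mutated:
                    continue
                grow = gene_df[gene_df["gene"] == g.gene].iloc[0]
                excluded = cnv_exclude(
                    GenomicInterval(grow["chrom"], int(grow["start"]), int(grow["end"])),
                    mutated,
                    cnv_tracks,
                )
                if excluded:
                    rows.append((dhs_id, g.gene, g.distance, np.nan, "cnv_excluded"))
                    continue
                pval, direction = aberrant_expression_test(
                    expr.loc[g.gene, mutated].to_numpy(),
                    expr.loc[g.gene, normal_cols].to_numpy(),
                )
                status = "aberrant" if pval < config.wilcoxon_alpha else "ns"
                rows.append((dhs_id, g.gene, g.distance, pval, status))
                if status == "aberrant":
                    hit = True
            if hit:
                passing.append(dhs_id)
        targets = pd.DataFrame(
            rows, columns=["dhs_id", "gene", "distance", "wilcoxon_p", "status"]
        )
        targets.to_csv(outdir / "targets.tsv", sep="\t", index=False)
        survivors = passing
    cascade.append(("Filter 3: aberrant target expression", len(survivors)))

    # --- Filter 4: replication recurrence
    if config.replication_tsvs:
        rep_catalogs = [
            apply_quality_filters(
                read_catalog(p, provenance=f"replication-{i+1}"),
                config.min_tumor_depth, config.min_normal_depth, config.min_af,
            )
            for i, p in enumerate(config.replication_tsvs)
        ]
        by_id = {d.dhs_id: d for d in masked}
        rep = replication_filter([by_id[d] for d in survivors], rep_catalogs)
        reports["replication"] = rep
        rep.to_csv(outdir / "replication.tsv", sep="\t", index=False)
        survivors = list(rep.loc[rep["passed"], "dhs_id"])
    cascade.append(("Filter 4: replicated", len(survivors)))

    from .report import cascade_table

    cascade_table(cascade).to_csv(outdir / "cascade.tsv", sep="\t", index=False)
    manifest = {"config": asdict(config), "p_star": test.p_star_,
                "n_significant": int(test.results_["significant"].sum())}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return PipelineResult(masked, counts, labels, test, cascade, reports, targets)


def _read_score(path) -> pd.DataFrame:
    if not path:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "value"]
    return df


def _load_cnvs(cnv_dir) -> dict[str, IntervalTrack]:
    if not cnv_dir:
        return {}
    out = {}
    for p in sorted(Path(cnv_dir).glob("*.bed")):
        out[p.stem] = read_bed(p, name=p.stem)
    return out
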