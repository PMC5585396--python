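import numpy as np
import pandas as pd
import pytest

from dhsdriver.filters import (
    InteractionEvidence,
    aberrant_expression_test,
    cnv_exclude,
    enrichment_comparison,
    link_targets,
    median_of_ratios_factors,
    quality_filter,
    replication_filter,
)
from dhsdriver.intervals import GenomicInterval, MaskedDHS

from conftest import make_catalog, make_track


def quality_frame(values, metric="mean_read_count"):
    base = {
        "mean_read_count": 10.0,
        "mean_read_quality": 30.0,
        "improper_fraction": 0.05,
    }
    rows = []
    for v in values:
        row = dict(base)
        row[metric] = v
        rows.append(row)
    return pd.DataFrame(rows)


class TestQualityFilter:
    def test_z_exactly_minus_two_is_retained(self):
        # mean 0, population SD 1 -> first value sits exactly at Z = -2;
        # the rule is strict ("lower than -2"), so it survives
        values = [-2.0, 0.5, 0.5, 0.5, 0.5]
        retained, z = quality_filter(quality_frame(values), np.zeros(5, dtype=int))
        assert z["mean_read_count"].iloc[0] == pytest.approx(-2.0)
        assert retained.all()

    def test_below_minus_two_removed(self):
        values = [1.0, 10.0, 10.0, 10.0, 11.0, 9.0, 10.0, 10.0]
        retained, z = quality_filter(quality_frame(values), np.zeros(8, dtype=int))
        assert z["mean_read_count"].iloc[0] < -2
        assert not retained[0]
        assert retained[1:].all()

    def test_improper_fraction_cut_is_upper_tail(self):
        values = [0.5, 0.05, 0.05, 0.05, 0.06, 0.04, 0.05, 0.05]
        retained, z = quality_filter(
            quality_frame(values, metric="improper_fraction"), np.zeros(8, dtype=int)
        )
        assert not retained[0] and retained[1:].all()

    def test_zero_sd_cluster_retains_all(self):
        retained, _ = quality_filter(quality_frame([5.0, 5.0, 5.0]), np.zeros(3, dtype=int))
        assert retained.all()

    def test_removal_set_matches_brute_force(self, rng):
        df = pd.DataFrame(
            {
                "mean_read_count": rng.normal(10, 3, 200),
                "mean_read_quality": rng.normal(30, 5, 200),
                "improper_fraction": rng.beta(2, 30, 200),
            }
        )
        labels = rng.integers(0, 4, 200)
        retained, _ = quality_filter(df, labels)
        for cl in range(4):
            sel = labels == cl
            for metric, sign in [
                ("mean_read_count", -1),
                ("mean_read_quality", -1),
                ("improper_fraction", +1),
            ]:
                x = df.loc[sel, metric].to_numpy()
                z = (x - x.mean()) / x.std()
                for i, zi in zip(np.flatnonzero(sel), z):
                    if sign * zi > 2:
                        assert not retained[i]


class TestLinkTargets:
    dhs = MaskedDHS("d1", "chr1", 1_000_000, 1_002_000, [(1_000_000, 1_002_000)])

    def interactions(self, other_start, other_end):
        return [
            InteractionEvidence(
                GenomicInterval("chr1", 1_000_500, 1_001_000),
                GenomicInterval("chr1", other_start, other_end),
                source="assay",
            )
        ]

    def test_gene_with_anchor_within_range_is_candidate(self):
        genes = pd.DataFrame(
            [("g1", "chr1", 1_100_000, 1_110_000)], columns=["gene", "chrom", "start", "end"]
        )
        out = link_targets(self.dhs, genes, self.interactions(1_100_100, 1_100_200))
        assert out["gene"].tolist() == ["g1"]
        assert out["distance"].iloc[0] == 98_000

    def test_distant_gene_rejected_despite_interaction(self):
        genes = pd.DataFrame(
            [("g1", "chr1", 1_700_000, 1_710_000)], columns=["gene", "chrom", "start", "end"]
        )
        out = link_targets(self.dhs, genes, self.interactions(1_700_100, 1_700_200))
        assert out.empty

    def test_near_gene_without_interaction_rejected(self):
        genes = pd.DataFrame(
            [("g1", "chr1", 1_100_000, 1_110_000)], columns=["gene", "chrom", "start", "end"]
        )
        assert link_targets(self.dhs, genes, []).empty

    def test_promoter_anchor_counts(self):
        genes = pd.DataFrame(
            [("g1", "chr1", 1_100_000, 1_110_000)], columns=["gene", "chrom", "start", "end"]
        )
        # anchor in the 2-kb window upstream of the gene start
        out = link_targets(self.dhs, genes, self.interactions(1_098_500, 1_099_000))
        assert out["gene"].tolist() == ["g1"]

    def test_toy_matches_quadratic_brute_force(self, rng):
        genes = pd.DataFrame(
            [
                (f"g{i}", "chr1", int(s), int(s) + 5000)
                for i, s in enumerate(rng.integers(0, 2_000_000, 30))
            ],
            columns=["gene", "chrom", "start", "end"],
        )
        interactions = []
        for _ in range(50):
            a = int(rng.integers(0, 2_000_000))
            b = int(rng.integers(0, 2_000_000))
            interactions.append(
                InteractionEvidence(
                    GenomicInterval("chr1", a, a + 1000),
                    GenomicInterval("chr1", b, b + 1000),
                )
            )
        out = set(link_targets(self.dhs, genes, interactions)["gene"])
        expected = set()
        for g in genes.itertuples(index=False):
            dist = max(0, max(g.start - self.dhs.end, self.dhs.start - g.end))
            if dist > 500_000:
                continue
            body = (g.start, g.end)
            prom = (max(0, g.start - 2000), g.start)
            for ev in interactions:
                anchors = [(ev.anchor1.start, ev.anchor1.end), (ev.anchor2.start, ev.anchor2.end)]
                for (s1, e1), (s2, e2) in (anchors, anchors[::-1]):
                    dhs_hit = s1 < self.dhs.end and self.dhs.start < e1
                    gene_hit = (s2 < body[1] and body[0] < e2) or (s2 < prom[1] and prom[0] < e2)
                    if dhs_hit and gene_hit:
                        expected.add(g.gene)
        assert out == expected


class TestAberrantExpression:
    def test_exact_two_sided_enumeration(self):
        # both tumors above all normals: p = 2 / C(10, 2) = 2/45
        p, direction = aberrant_expression_test([10, 11], [1, 2, 3, 4, 5, 6, 7, 8])
        assert p == pytest.approx(2 / 45)
        assert direction == "over"

    def test_identical_groups(self):
        p, direction = aberrant_expression_test([5.0], [5.0, 5.0])
        assert p == 1.0 and direction == "none"

    def test_downregulation_direction(self):
        p, direction = aberrant_expression_test([1, 2], [5, 6, 7, 8, 9])
        assert direction == "under"

    def test_type_i_error_calibrated(self, rng):
        # no-shift simulation: rejection rate at alpha=0.05 stays near nominal
        rejections = 0
        reps = 1000
        for _ in range(reps):
            t = rng.normal(0, 1, 5)
            m = rng.normal(0, 1, 20)
            p, _ = aberrant_expression_test(t, m)
            rejections += p < 0.05
        assert rejections / reps <= 0.06


class TestCNVExclude:
    gene = GenomicInterval("chr1", 100, 200)

    def test_cnv_in_mutated_sample_excludes(self):
        tracks = {"s1": make_track([("chr1", 150, 300)])}
        assert cnv_exclude(self.gene, ["s1"], tracks)

    def test_cnv_in_unrelated_sample_does_not(self):
        tracks = {"s2": make_track([("chr1", 150, 300)])}
        assert not cnv_exclude(self.gene, ["s1"], tracks)

    def test_toy_matches_brute_force(self, rng):
        samples = [f"s{i}" for i in range(5)]
        tracks = {
            s: make_track(
                [("chr1", int(a), int(a) + 50) for a in rng.integers(0, 1000, 3)]
            )
            for s in samples
        }
        mutated = samples[:2]
        expected = any(
            iv.start < self.gene.end and self.gene.start < iv.end
            for s in mutated
            for iv in tracks[s]
        )
        assert cnv_exclude(self.gene, mutated, tracks) == expected


class TestReplicationFilter:
    dhs = [MaskedDHS("d1", "chr1", 0, 100, [(0, 100)])]

    def test_requires_hits_in_both_sets(self):
        rep1 = make_catalog([("chr1", 10, "C", "T", "r1")])
        rep2 = make_catalog([("chr2", 10, "C", "T", "r2")])
        out = replication_filter(self.dhs, [rep1, rep2])
        assert out["n_rep1"].iloc[0] == 1 and out["n_rep2"].iloc[0] == 0
        assert not out["passed"].iloc[0]

    def test_passes_with_hits_everywhere(self):
        rep1 = make_catalog([("chr1", 10, "C", "T", "r1"), ("chr1", 20, "C", "T", "r1")])
        rep2 = make_catalog([("chr1", 30, "C", "T", "r2")])
        assert replication_filter(self.dhs, [rep1, rep2])["passed"].iloc[0]

    def test_masked_pieces_respected(self):
        dhs = [MaskedDHS("d1", "chr1", 0, 100, [(0, 10)])]
        rep = make_catalog([("chr1", 50, "C", "T", "r1")])
        assert replication_filter(dhs, [rep])["n_rep1"].iloc[0] == 0


class TestEnrichmentComparison:
    def test_identical_proportions_not_significant(self):
        _, p = enrichment_comparison((10, 100), (100, 1000))
        assert p > 0.9

    def test_filtered_set_enrichment_is_extreme(self):
        # mirrors comparing 73/596 significant DHSs vs 402/14,087 mutated DHSs
        stat, p = enrichment_comparison((73, 596), (329, 13_491))
        assert p < 1e-10
        _, p_fisher = enrichment_comparison((73, 596), (329, 13_491), method="fisher")
        assert p_fisher < 1e-10

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            enrichment_comparison((0, 10), (0, 20))


def test_median_of_ratios_recovers_scaling():
    rng = np.random.default_rng(5)
    base = rng.integers(50, 500, 100).astype(float)
    matrix = pd.DataFrame(
        {"a": base, "b": base * 2.0, "c": base * 0.5}, index=[f"g{i}" for i in range(100)]
    )
    f = median_of_ratios_factors(matrix)
    assert f["b"] / f["a"] == pytest.approx(2.0)
    assert f["c"] / f["a"] == pytest.approx(0.5)
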