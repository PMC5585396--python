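import numpy as np
import pandas as pd
import pytest

from dhsdriver.covariates import (
    TRINUCLEOTIDES,
    TrinucleotideSpectrum,
    attach_track_scores,
    build_spectrum,
    count_trinucleotides,
    expected_mutation_rate,
    gc_fraction,
    gene_density,
    normalize_covariates,
)
from dhsdriver.intervals import MaskedDHS, merge_overlapping

from conftest import make_catalog, make_track


def spectrum_with(**kv):
    M = np.zeros(64, dtype=int)
    N = np.full(64, 1000, dtype=int)
    for tri, (m, n) in kv.items():
        i = TRINUCLEOTIDES.index(tri)
        M[i], N[i] = m, n
    return TrinucleotideSpectrum(M, N)


class TestExpectedMutationRate:
    def test_single_context_sum(self):
        # 5 AAA occurrences, M=10, N=1000 -> mu = 5 * 10/1000 = 0.05
        spec = spectrum_with(AAA=(10, 1000))
        assert expected_mutation_rate(["AAAAAAA"], spec) == pytest.approx(0.05)

    def test_sequence_shorter_than_context_gives_zero(self):
        spec = spectrum_with(AAA=(10, 1000))
        assert expected_mutation_rate(["AA"], spec) == 0.0

    def test_missing_genome_context_is_config_error(self):
        spec = TrinucleotideSpectrum(np.zeros(64), np.zeros(64))
        with pytest.raises(ValueError, match="absent genome-wide"):
            expected_mutation_rate(["ACGT"], spec)

    def test_random_sequence_matches_sliding_window_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 500))
        M = rng.integers(0, 50, 64)
        N = rng.integers(1, 1000, 64)
        spec = TrinucleotideSpectrum(M, N)
        expected = sum(
            M[TRINUCLEOTIDES.index(seq[i : i + 3])] / N[TRINUCLEOTIDES.index(seq[i : i + 3])]
            for i in range(len(seq) - 2)
        )
        assert expected_mutation_rate([seq], spec) == pytest.approx(expected, rel=1e-12)

    def test_additive_over_pieces(self, rng):
        seq1 = "".join(rng.choice(list("ACGT"), 120))
        seq2 = "".join(rng.choice(list("ACGT"), 80))
        spec = TrinucleotideSpectrum(rng.integers(0, 20, 64), rng.integers(1, 500, 64))
        assert expected_mutation_rate([seq1, seq2], spec) == pytest.approx(
            expected_mutation_rate([seq1], spec) + expected_mutation_rate([seq2], spec)
        )

    def test_linear_in_mutation_counts(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        M = rng.integers(0, 20, 64)
        N = rng.integers(1, 500, 64)
        mu1 = expected_mutation_rate([seq], TrinucleotideSpectrum(M, N))
        mu3 = expected_mutation_rate([seq], TrinucleotideSpectrum(3 * M, N))
        assert mu3 == pytest.approx(3 * mu1)


class TestSpectrumConstruction:
    def test_counts_mutations_by_reference_context(self):
        sequences = {"chr1": "AACGTT"}
        cat = make_catalog([("chr1", 2, "C", "T", "s1"), ("chr1", 0, "A", "G", "s1")])
        spec = build_spectrum(sequences, cat)
        # mutation at pos 2 has context ACG; the one at pos 0 has no full context
        assert spec.M[TRINUCLEOTIDES.index("ACG")] == 1
        assert spec.M.sum() == 1
        assert spec.N.sum() == 4  # AAC, ACG, CGT, GTT

    def test_excluded_regions_drop_occurrences_and_mutations(self):
        sequences = {"chr1": "A" * 100}
        cat = make_catalog([("chr1", 50, "A", "G", "s1")])
        excl = make_track([("chr1", 40, 60)])
        spec = build_spectrum(sequences, cat, exclude=excl)
        assert spec.M.sum() == 0
        # 100-bp poly-A minus 20 excluded leaves two 40/ 40-bp pieces -> 38+38 AAA windows
        assert spec.N[TRINUCLEOTIDES.index("AAA")] == 76


class TestSimpleCovariates:
    @pytest.mark.parametrize(
        "seq,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("GCAT", 0.5), ("GCNN", 1.0)]
    )
    def test_gc_fraction(self, seq, expected):
        assert gc_fraction(seq) == expected

    def test_gc_fraction_all_n_is_nan(self):
        assert np.isnan(gc_fraction("NNN"))

    def test_gene_density_fraction(self):
        # 500-kb window holding 125,000 gene bases -> 0.25
        dhs = MaskedDHS("d", "chr1", 200_000, 300_000, [(200_000, 300_000)])
        genes = merge_overlapping(make_track([("chr1", 0, 125_000)]))
        val = gene_density(dhs, genes, chrom_length=10**9, half_window=200_000)
        assert val == pytest.approx(0.25)

    def test_gene_density_no_genes_is_zero(self):
        dhs = MaskedDHS("d", "chr1", 1000, 1200, [(1000, 1200)])
        genes = make_track([("chr2", 0, 100)])
        assert gene_density(dhs, genes, chrom_length=10**6) == 0.0

    def test_gene_density_toy_matches_per_base_oracle(self, rng):
        genes = merge_overlapping(
            make_track(
                [("chr1", int(s), int(s + l))
                 for s, l in zip(rng.integers(0, 90_000, 12), rng.integers(100, 8000, 12))]
            )
        )
        dhs = MaskedDHS("d", "chr1", 40_000, 40_500, [(40_000, 40_500)])
        val = gene_density(dhs, genes, chrom_length=100_000, half_window=20_000)
        window = range(20_000, 60_500)
        covered = {p for iv in genes for p in range(iv.start, iv.end)}
        assert val == pytest.approx(len(covered & set(window)) / len(window))


class TestTrackScores:
    def test_single_tile(self):
        dhs = [MaskedDHS("d", "chr1", 10, 20, [(10, 20)])]
        track = pd.DataFrame([("chr1", 0, 100, 0.7)], columns=["chrom", "start", "end", "value"])
        assert attach_track_scores(dhs, track)[0] == pytest.approx(0.7)

    def test_even_split_across_tiles(self):
        dhs = [MaskedDHS("d", "chr1", 90, 110, [(90, 110)])]
        track = pd.DataFrame(
            [("chr1", 0, 100, 0.0), ("chr1", 100, 200, 1.0)],
            columns=["chrom", "start", "end", "value"],
        )
        assert attach_track_scores(dhs, track)[0] == pytest.approx(0.5)

    def test_no_overlap_flagged_missing(self):
        dhs = [MaskedDHS("d", "chr2", 0, 10, [(0, 10)])]
        track = pd.DataFrame([("chr1", 0, 100, 0.7)], columns=["chrom", "start", "end", "value"])
        assert np.isnan(attach_track_scores(dhs, track)[0])

    def test_random_tiling_matches_per_base_oracle(self, rng):
        bounds = np.sort(rng.choice(np.arange(1, 1000), 9, replace=False))
        edges = [0, *bounds.tolist(), 1000]
        vals = rng.random(len(edges) - 1)
        track = pd.DataFrame(
            [("chr1", s, e, v) for s, e, v in zip(edges[:-1], edges[1:], vals)],
            columns=["chrom", "start", "end", "value"],
        )
        dhs = [MaskedDHS("d", "chr1", 123, 877, [(123, 877)])]
        per_base = np.empty(1000)
        for s, e, v in zip(edges[:-1], edges[1:], vals):
            per_base[s:e] = v
        assert attach_track_scores(dhs, track)[0] == pytest.approx(per_base[123:877].mean())


class TestNormalize:
    def test_two_values_give_plus_minus_one(self):
        out = normalize_covariates(pd.DataFrame({"x": [1.0, 3.0]}))
        assert out["x"].tolist() == [-1.0, 1.0]

    def test_constant_covariate_dropped(self):
        out = normalize_covariates(pd.DataFrame({"x": [1.0, 2.0], "c": [5.0, 5.0]}))
        assert list(out.columns) == ["x"]

    def test_moments_after_normalization(self, rng):
        df = pd.DataFrame(rng.random((1000, 3)) * [1, 50, 1e-3], columns=list("abc"))
        out = normalize_covariates(df)
        assert np.allclose(out.mean(), 0, atol=1e-12)
        assert np.allclose(out.std(ddof=0), 1, atol=1e-12)

    def test_missing_values_imputed_to_zero(self):
        out = normalize_covariates(pd.DataFrame({"x": [1.0, np.nan, 3.0]}))
        assert out["x"].iloc[1] == pytest.approx(0.0)
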