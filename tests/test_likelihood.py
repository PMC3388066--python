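"""Likelihood-engine checks against independent brute-force computations."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.linalg import expm

from znfarray.selection.alignment import CodonAlignment
from znfarray.selection.codon import (
    CODONS,
    N_CODONS,
    CodonFrequencies,
    empirical_frequencies,
    rate_matrix,
    stationary_pi,
    uniform_frequencies,
)
from znfarray.selection.likelihood import (
    MixtureLikelihood,
    dense_log_likelihood,
    transition_matrices,
)
from znfarray.selection.trees import PhyloTree

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def slow_rate_matrix(kappa, omega, pi):
    """Independently coded GY-style generator built from codon strings."""
    Q = np.zeros((N_CODONS, N_CODONS))
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            rate = pi[j]
            if frozenset((ci[p], cj[p])) in TRANSITIONS:
                rate *= kappa
            if str(Seq(ci).translate()) != str(Seq(cj).translate()):
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class TestRateMatrix:
    def test_matches_independent_construction(self, rng):
        freqs = uniform_frequencies()
        for kappa, omega in [(1.0, 1.0), (2.5, 0.3), (4.0, 8.0)]:
            Q, pi, rate = rate_matrix(kappa, omega, freqs)
            assert np.allclose(Q, slow_rate_matrix(kappa, omega, freqs.pi))
            assert rate == pytest.approx(-(pi * np.diag(Q)).sum())

    def test_rows_sum_to_zero(self):
        freqs = uniform_frequencies()
        Q, _, _ = rate_matrix(2.0, 0.5, freqs)
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_detailed_balance_both_styles(self):
        idx = np.arange(61).reshape(1, 61) % 61
        freqs = empirical_frequencies(np.tile(idx, (1, 3)), "F3x4")
        for style in ("goldmanwhelan", "musegaut"):
            Q, pi, _ = rate_matrix(1.7, 0.4, freqs, style)
            flux = pi[:, None] * Q
            assert np.allclose(flux, flux.T, atol=1e-12)

    def test_musegaut_requires_product_form(self):
        freqs = uniform_frequencies()  # declared F61
        with pytest.raises(ValueError):
            stationary_pi(freqs, "musegaut")


class TestCodonFrequencies:
    @pytest.mark.parametrize("model", ["F1x4", "F3x4", "F61"])
    def test_sum_to_one_over_sense_codons(self, model, rng):
        idx = rng.integers(0, N_CODONS, size=(5, 40))
        freqs = empirical_frequencies(idx, model)
        assert freqs.pi.shape == (61,)
        assert freqs.pi.sum() == pytest.approx(1.0)
        assert (freqs.pi > 0).all()
        assert np.allclose(freqs.pos_nt.sum(axis=1), 1.0)

    def test_f60_alias(self, rng):
        idx = rng.integers(0, N_CODONS, size=(2, 30))
        assert empirical_frequencies(idx, "F60").model == "F61"

    def test_f1x4_positions_identical(self, rng):
        idx = rng.integers(0, N_CODONS, size=(3, 50))
        freqs = empirical_frequencies(idx, "F1x4")
        assert np.allclose(freqs.pos_nt[0], freqs.pos_nt[1])
        assert np.allclose(freqs.pos_nt[0], freqs.pos_nt[2])


class TestTransitionMatrices:
    def test_matches_expm(self):
        freqs = uniform_frequencies()
        Q, pi, _ = rate_matrix(2.0, 0.5, freqs)
        lengths = np.array([0.01, 0.3, 2.0])
        P = transition_matrices(Q, pi, lengths)
        for b, t in enumerate(lengths):
            assert np.allclose(P[b], expm(Q * t), atol=1e-10)

    def test_rows_are_distributions(self):
        freqs = uniform_frequencies()
        Q, pi, _ = rate_matrix(3.0, 2.0, freqs)
        P = transition_matrices(Q, pi, np.array([0.5]))
        assert np.allclose(P[0].sum(axis=1), 1.0)
        assert (P[0] >= 0).all()


class TestPruningVsDenseOracle:
    @pytest.mark.parametrize(
        "newick,labels,seqs",
        [
            ("(a:0.1,b:0.2);", ["a", "b"], ["ATGGCTAAA", "ATGGCAAGA"]),
            ("(a:0.05,b:0.4,c:0.15);", ["a", "b", "c"], ["ATGGCT", "ATGTCT", "CTGGCA"]),
        ],
    )
    def test_toy_instances_to_1e8(self, newick, labels, seqs):
        aln = CodonAlignment.from_nt(labels, seqs)
        tree = PhyloTree.from_newick(newick)
        freqs = uniform_frequencies()
        for kappa, omega in [(2.0, 0.5), (1.0, 1.0), (3.0, 5.0)]:
            engine = MixtureLikelihood(aln, tree, freqs=freqs)
            ev = engine.evaluate(kappa, [omega], [1.0])
            _, _, rate = rate_matrix(kappa, omega, freqs)
            dense = dense_log_likelihood(aln, tree, kappa, omega, freqs, scale=rate)
            assert ev.lnL == pytest.approx(dense, abs=1e-8)

    def test_empirical_frequencies_path(self):
        aln = CodonAlignment.from_nt(["a", "b"], ["ATGAAAGCT", "ATGAAGGCA"])
        tree = PhyloTree.from_newick("(a:0.07,b:0.11);")
        engine = MixtureLikelihood(aln, tree, codon_freq_model="F3x4")
        ev = engine.evaluate(1.5, [0.7], [1.0])
        _, _, rate = rate_matrix(1.5, 0.7, engine.freqs)
        dense = dense_log_likelihood(aln, tree, 1.5, 0.7, engine.freqs, scale=rate)
        assert ev.lnL == pytest.approx(dense, abs=1e-8)


class TestPatternCompression:
    def test_weights_expand_consistency(self):
        aln = CodonAlignment.from_nt(
            ["a", "b"], ["ATGATGGCTATG", "ATGATGGCAATG"]
        )
        tree = PhyloTree.from_newick("(a:0.1,b:0.1);")
        engine = MixtureLikelihood(aln, tree, freqs=uniform_frequencies())
        assert engine.weights.sum() == aln.n_sites
        per_pattern = np.arange(engine.n_patterns, dtype=float)
        assert engine.expand(per_pattern).shape == (aln.n_sites,)

    def test_compression_does_not_change_lnL(self):
        # duplicated columns must contribute multiplicatively
        aln1 = CodonAlignment.from_nt(["a", "b"], ["ATGGCT", "ATGTCA"])
        aln2 = CodonAlignment.from_nt(["a", "b"], ["ATGGCTATG", "ATGTCAATG"])
        tree = PhyloTree.from_newick("(a:0.2,b:0.3);")
        freqs = uniform_frequencies()
        e1 = MixtureLikelihood(aln1, tree, freqs=freqs).evaluate(2.0, [0.5], [1.0]).lnL
        e2 = MixtureLikelihood(aln2, tree, freqs=freqs).evaluate(2.0, [0.5], [1.0]).lnL
        # alignment 2 repeats the first column of alignment 1 once more
        single = MixtureLikelihood(
            CodonAlignment.from_nt(["a", "b"], ["ATG", "ATG"]), tree, freqs=freqs
        ).evaluate(2.0, [0.5], [1.0]).lnL
        assert e2 == pytest.approx(e1 + single, abs=1e-9)


class TestAlignment:
    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop codon"):
            CodonAlignment.from_nt(["a"], ["ATGTAA"])

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            CodonAlignment.from_nt(["a", "b"], ["ATGGCT", "ATG"])

    def test_build_deduplicates(self, small_library):
        from znfarray.parser import parse_allele
        from znfarray.selection.alignment import build_codon_alignment

        lib = small_library.repeats_nt
        alleles = [
            parse_allele("a1", lib[0] + lib[1] + lib[0]),
            parse_allele("a2", lib[1] + lib[2] + lib[2]),
        ]
        aln = build_codon_alignment(alleles)
        assert aln.n_taxa == len({lib[0], lib[1], lib[2]})
        assert aln.n_sites == 28

    def test_build_excludes_truncated(self, small_library):
        from znfarray.parser import parse_allele
        from znfarray.selection.alignment import build_codon_alignment

        lib = small_library.repeats_nt
        allele = parse_allele("a1", lib[0][-27:] + lib[0] + lib[1], leading_truncated=True)
        aln = build_codon_alignment([allele])
        assert aln.n_taxa == 2
        assert aln.excluded == ["truncated@0"]
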