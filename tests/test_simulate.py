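import dataclasses

import numpy as np
import pytest

from znfarray.catalog import (
    collapse_to_aa_alleles,
    collapse_to_nt_alleles,
    cross_group_sharing,
    find_polymorphic_sites,
)
from znfarray.io import LabeledSequence
from znfarray.simulate import (
    CONTACT_VARIABLE_OFFSETS,
    SimulationConfig,
    TEMPLATE_AA,
    TEMPLATE_NT,
    make_two_block_array,
    random_tree,
    simulate_codon_alignment,
    simulate_grouped_spectrum,
    simulate_repeat_library,
    simulate_znf_population,
)


def as_labeled(pop):
    return [LabeledSequence(rid, sid, g, seq) for rid, sid, g, seq in pop.records]


class TestTemplate:
    def test_template_consistency(self):
        from Bio.Seq import Seq

        assert len(TEMPLATE_NT) == 84
        assert str(Seq(TEMPLATE_NT).translate()) == TEMPLATE_AA
        assert TEMPLATE_AA[18] == "S"


class TestRepeatLibrary:
    def test_deterministic_under_seed(self):
        a = simulate_repeat_library(SimulationConfig(seed=9))
        b = simulate_repeat_library(SimulationConfig(seed=9))
        assert a.repeats_nt == b.repeats_nt
        assert a.truth.variable_columns == b.truth.variable_columns

    def test_zero_multiplier_keeps_contacts_fixed(self):
        cfg = SimulationConfig(seed=2, contact_rate_multiplier=0.0, n_variable_columns=4)
        lib = simulate_repeat_library(cfg)
        assert lib.truth.contact_columns == []
        for off in CONTACT_VARIABLE_OFFSETS:
            assert len({aa[off] for aa in lib.repeats_aa}) == 1

    def test_closure_with_polymorphic_sites(self):
        cfg = SimulationConfig(seed=4, n_variable_columns=6, contact_fraction=0.5)
        lib = simulate_repeat_library(cfg)
        rep = find_polymorphic_sites(lib.repeats_aa, contact_offsets=CONTACT_VARIABLE_OFFSETS)
        assert rep.columns == lib.truth.variable_columns
        assert rep.contact_fraction == pytest.approx(0.5)

    def test_too_many_columns_rejected(self):
        with pytest.raises(ValueError):
            simulate_repeat_library(SimulationConfig(seed=1, n_variable_columns=40))

    def test_synonymous_variants_recorded(self, small_library):
        from Bio.Seq import Seq

        for src, var in small_library.truth.synonymous_pairs:
            assert small_library.repeats_nt[src] != small_library.repeats_nt[var]
            assert (
                str(Seq(small_library.repeats_nt[src]).translate())
                == str(Seq(small_library.repeats_nt[var]).translate())
            )


class TestPopulation:
    def test_known_spectrum_closure(self):
        cfg = SimulationConfig(
            seed=5, groups=("Pts",), allele_counts={"Pts": (6, 1, 1, 1, 1)}, dropout=0.0
        )
        pop = simulate_znf_population(cfg)
        table = collapse_to_nt_alleles(as_labeled(pop))
        assert len(table) == 5
        assert sorted((r.count for r in table.rows), reverse=True) == [6, 1, 1, 1, 1]

    def test_dropout_one_gives_one_record_per_individual(self):
        cfg = SimulationConfig(seed=6, groups=("g1",), dropout=1.0)
        pop = simulate_znf_population(cfg)
        samples = [sid for _, sid, _, _ in pop.records]
        assert len(samples) == len(set(samples))
        assert len(pop.truth.dropped_records) == len(samples)

    def test_shared_allele_closure(self, small_population):
        _, pop = small_population
        nt = collapse_to_nt_alleles(as_labeled(pop))
        aa = collapse_to_aa_alleles(nt)
        report = cross_group_sharing(nt, aa)
        assert len(report.nt_shared) == 1
        (groups,) = report.nt_shared.values()
        assert groups == ("g1", "g2")

    def test_array_lengths_in_range(self, small_population):
        cfg, pop = small_population
        for _, _, _, seq in pop.records:
            n = len(seq) // cfg.repeat_length
            assert cfg.min_repeats <= n <= cfg.max_repeats
            assert len(seq) % cfg.repeat_length == 0

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=12, dropout=0.3)
        assert simulate_znf_population(cfg).records == simulate_znf_population(cfg).records

    def test_odd_group_size_rejected(self):
        cfg = SimulationConfig(seed=1, groups=("g1",), allele_counts={"g1": (2, 1)})
        with pytest.raises(ValueError):
            simulate_znf_population(cfg)


class TestSpectrumGenerator:
    def test_literal_counts_reproduced(self):
        from znfarray.datasets import PAN_SPECTRUM_NT
        from znfarray.diversity import dispersion_statistic_multi_group

        spectrum, truth = simulate_grouped_spectrum(SimulationConfig(), counts=PAN_SPECTRUM_NT)
        assert round(dispersion_statistic_multi_group(spectrum), 3) == 0.070
        assert truth.spectrum == PAN_SPECTRUM_NT

    def test_single_group_statistic_errors_downstream(self):
        from znfarray.diversity import dispersion_statistic_multi_group

        spectrum, _ = simulate_grouped_spectrum(SimulationConfig(groups=("only",)))
        with pytest.raises(ValueError):
            dispersion_statistic_multi_group(spectrum)

    def test_seed_reproducibility(self):
        a, _ = simulate_grouped_spectrum(SimulationConfig(seed=8))
        b, _ = simulate_grouped_spectrum(SimulationConfig(seed=8))
        assert a.labels == b.labels


class TestTwoBlock:
    def test_zero_gap(self):
        from znfarray.dotplot import two_block_score

        allele, truth = make_two_block_array(SimulationConfig(seed=3, block_gap=0.0))
        assert truth.block_gap == 0.0
        assert two_block_score(allele) == pytest.approx(0.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            make_two_block_array(SimulationConfig(seed=3, block_repeats_per_half=1))


class TestCodonSimulation:
    def test_zero_length_branches_identical_rows(self):
        cfg = SimulationConfig(
            seed=14, n_codon_sites=20, n_taxa=5, branch_length_range=(0.0, 0.0)
        )
        aln, _, _ = simulate_codon_alignment(cfg)
        assert (aln.codon_idx == aln.codon_idx[0]).all()

    def test_neutral_limit_recovers_omega_one(self):
        from znfarray.selection.models import fit_site_model

        cfg = SimulationConfig(
            seed=15, site_model="M0", omegas=(1.0,), proportions=(1.0,),
            n_codon_sites=400, n_taxa=8,
        )
        aln, tree, _ = simulate_codon_alignment(cfg)
        fit = fit_site_model(aln, tree, model="M0", n_restarts=1, optimize_branch_lengths=False)
        assert fit.omegas[0] == pytest.approx(1.0, abs=0.15)

    def test_site_classes_match_mixture(self):
        cfg = SimulationConfig(seed=16, n_codon_sites=2000, n_taxa=4)
        _, _, truth = simulate_codon_alignment(cfg)
        freq = np.bincount(truth.site_classes, minlength=3) / 2000
        assert np.allclose(freq, cfg.proportions, atol=0.04)

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=17, n_codon_sites=30, n_taxa=6)
        a, _, _ = simulate_codon_alignment(cfg)
        b, _, _ = simulate_codon_alignment(cfg)
        assert (a.codon_idx == b.codon_idx).all()

    def test_random_tree_structure(self, rng):
        tree = random_tree(10, rng)
        assert len(tree.leaf_names) == 10
        assert len(set(tree.leaf_names)) == 10
        assert (tree.branch_lengths() >= 0).all()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dropout": 1.5},
            {"contact_fraction": -0.1},
            {"min_repeats": 0},
            {"max_repeats": 2, "min_repeats": 5},
            {"proportions": (0.5, 0.2), "omegas": (0.1, 1.0)},
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
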