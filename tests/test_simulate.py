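"""Synthetic-data generator: determinism, embedding, mixture fidelity,
chemistry filter, and error handling."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from pirnaquant.annotation import FeatureClass
from pirnaquant.simulate import (
    ConditionSpec,
    RUBY_MOTIF_PLACEHOLDER,
    SimGenomeConfig,
    SimulationError,
    apply_capseq_enrichment,
    expected_class_weights,
    simulate_genome,
    simulate_library,
)


class TestSimulateGenome:
    def test_deterministic_for_fixed_seed(self):
        g1, f1 = simulate_genome(SimGenomeConfig(seed=1))
        g2, f2 = simulate_genome(SimGenomeConfig(seed=1))
        assert g1.chroms == g2.chroms
        assert f1 == f2

    def test_different_seeds_differ(self):
        g1, _ = simulate_genome(SimGenomeConfig(seed=1))
        g2, _ = simulate_genome(SimGenomeConfig(seed=2))
        assert g1.chroms != g2.chroms

    def test_zero_type1_loci(self):
        _, features = simulate_genome(SimGenomeConfig(n_type1_pirna_loci=0, seed=3))
        assert not any(f.pirna_type == "I" for f in features)

    def test_mature_sequences_embedded_at_coordinates(self, default_sim):
        genome, features = default_sim
        matured = [f for f in features if f.mature_seq is not None]
        assert matured
        for f in matured:
            assert genome.fetch(f.chrom, f.start, f.end, f.strand) == f.mature_seq

    def test_pirna_matures_are_21u(self, default_sim):
        _, features = default_sim
        pirnas = [f for f in features if f.feature_class is FeatureClass.PIRNA]
        assert all(len(f.mature_seq) == 21 and f.mature_seq[0] == "T" for f in pirnas)

    def test_ruby_motif_tag_and_upstream_placement(self, default_sim):
        genome, features = default_sim
        for f in features:
            if f.pirna_type == "I":
                assert f.attributes["ruby_motif"] == RUBY_MOTIF_PLACEHOLDER
                if f.strand == "+":
                    seen = genome.fetch(f.chrom, f.start - 10, f.start - 2, "+")
                else:
                    seen = genome.fetch(f.chrom, f.end + 2, f.end + 10, "-")
                assert seen == RUBY_MOTIF_PLACEHOLDER
            elif f.pirna_type == "II":
                assert "ruby_motif" not in f.attributes

    def test_features_do_not_overlap(self, default_sim):
        _, features = default_sim
        by_chrom: dict[str, list] = {}
        for f in features:
            by_chrom.setdefault(f.chrom, []).append(f)
        for feats in by_chrom.values():
            feats.sort(key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                assert a.end <= b.start

    def test_footprint_overflow_names_class(self):
        cfg = SimGenomeConfig(
            n_chromosomes=1, chrom_length=2000, n_coding_genes=50, seed=1
        )
        with pytest.raises(SimulationError, match="footprint") as exc:
            simulate_genome(cfg)
        # the offending feature class is named
        assert any(
            cls in str(exc.value)
            for cls in ("piRNA", "miRNA", "protein_coding", "transposon",
                        "rRNA", "tRNA", "snoRNA", "snRNA")
        )

    def test_gene_class_fractions_validated(self):
        cfg = SimGenomeConfig(gene_class_fractions={"csr1_target": 0.5})
        with pytest.raises(SimulationError):
            simulate_genome(cfg)


class TestSimulateLibrary:
    def test_deterministic(self, default_sim):
        genome, features = default_sim
        cond = ConditionSpec.control()
        r1, t1 = simulate_library(genome, features, cond, 500, seed=9)
        r2, t2 = simulate_library(genome, features, cond, 500, seed=9)
        assert r1 == r2 and t1 == t2

    def test_zero_reads(self, default_sim):
        genome, features = default_sim
        reads, truth = simulate_library(
            genome, features, ConditionSpec.control(), 0, seed=1
        )
        assert reads == [] and truth == []

    def test_class_fold_zero_removes_class(self, default_sim):
        genome, features = default_sim
        cond = ConditionSpec(name="ko", class_fold={"mature_pirna": 0.0})
        _, truth = simulate_library(genome, features, cond, 3000, seed=2)
        assert not any(t.true_class == "mature_pirna" for t in truth)

    def test_truth_index_aligned_with_chemistry_model(self, default_sim):
        genome, features = default_sim
        reads, truth = simulate_library(
            genome, features, ConditionSpec.control(), 1000, seed=4
        )
        chem = {
            "pirna_precursor": "cap",
            "twenty_two_g": "triP",
            "mature_pirna": "monoP",
            "mirna": "monoP",
            "structural": "monoP",
            "other": "monoP",
        }
        assert [r.id for r in reads] == [t.read_id for t in truth]
        assert all(t.five_prime_chem == chem[t.true_class] for t in truth)

    def test_mixture_proportions_within_three_sigma(self, default_sim):
        genome, features = default_sim
        cond = ConditionSpec.control()
        n = 50_000
        _, truth = simulate_library(genome, features, cond, n, seed=6)
        observed = Counter(t.true_class for t in truth)
        expected = expected_class_weights(features, cond)
        assert abs(sum(expected.values()) - 1.0) < 1e-9
        for cls, p in expected.items():
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(observed[cls] - n * p) <= 3 * sigma, cls

    def test_condition_shifts_mixture(self, default_sim):
        genome, features = default_sim
        cond = ConditionSpec(name="ints-1", class_fold={"mature_pirna": 0.3})
        expected = expected_class_weights(features, cond)
        control = expected_class_weights(features, ConditionSpec.control())
        ratio = expected["mature_pirna"] / control["mature_pirna"]
        # renormalization makes the marginal ratio slightly above the fold
        assert 0.29 < ratio < 0.35

    def test_negative_multiplier_rejected(self, default_sim):
        genome, features = default_sim
        cond = ConditionSpec(name="bad", class_fold={"mirna": -1.0})
        with pytest.raises(SimulationError):
            simulate_library(genome, features, cond, 10, seed=1)

    def test_positive_weight_without_loci_is_error(self):
        genome, features = simulate_genome(
            SimGenomeConfig(n_mirna_loci=0, seed=8)
        )
        with pytest.raises(SimulationError, match="mirna"):
            simulate_library(
                genome, features, ConditionSpec.control(), 100, seed=1
            )

    def test_read_species_shapes(self, default_sim):
        genome, features = default_sim
        feat_by_id = {f.id: f for f in features}
        reads, truth = simulate_library(
            genome, features, ConditionSpec.control(), 4000, seed=12
        )
        for r, t in zip(reads, truth):
            src = feat_by_id[t.source_locus]
            if t.true_class == "mature_pirna":
                assert r.sequence == src.mature_seq
            elif t.true_class == "pirna_precursor":
                assert len(r.sequence) in {25, 41, 61}
                assert r.sequence[2:23] == src.mature_seq
            elif t.true_class == "twenty_two_g":
                assert 21 <= len(r.sequence) <= 23
                assert r.sequence[0] == "G"


class TestCapseqEnrichment:
    def test_pure_filter_keeps_caps_in_order(self, default_sim):
        genome, features = default_sim
        reads, truth = simulate_library(
            genome, features, ConditionSpec.control(), 3000, seed=13
        )
        cap_reads, cap_truth = apply_capseq_enrichment(reads, truth)
        n_cap = sum(1 for t in truth if t.five_prime_chem == "cap")
        assert len(cap_reads) == len(cap_truth) == n_cap
        assert all(t.five_prime_chem == "cap" for t in cap_truth)
        # order preserved and a subset of the input
        ids = [r.id for r in reads]
        cap_ids = [r.id for r in cap_reads]
        assert cap_ids == [i for i in ids if i in set(cap_ids)]

    def test_all_cap_identity_and_no_cap_empty(self, default_sim):
        genome, features = default_sim
        mix_prec = {"pirna_precursor": 1.0}
        reads, truth = simulate_library(
            genome, features, ConditionSpec.control(), 200, seed=14, class_mix=mix_prec
        )
        out_reads, out_truth = apply_capseq_enrichment(reads, truth)
        assert out_reads == reads and out_truth == truth

        mix_22g = {"twenty_two_g": 1.0}
        reads, truth = simulate_library(
            genome, features, ConditionSpec.control(), 200, seed=15, class_mix=mix_22g
        )
        assert apply_capseq_enrichment(reads, truth) == ([], [])

    def test_misaligned_inputs_rejected(self, default_sim):
        genome, features = default_sim
        reads, truth = simulate_library(
            genome, features, ConditionSpec.control(), 50, seed=16
        )
        with pytest.raises(ValueError):
            apply_capseq_enrichment(reads, truth[:-1])
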