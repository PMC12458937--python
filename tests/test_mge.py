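"""Direct-repeat scanner, element calling, mobility classification."""

from __future__ import annotations

import numpy as np
import pytest

from oracles import brute_force_repeats

from defensekit.io import GeneRecord, GeneTable
from defensekit.mge import (
    call_elements,
    classify_mobility,
    find_trna_anchored_repeats,
    reverse_complement,
)
from defensekit.simulate import (
    ElementSpec,
    GenomeSimConfig,
    simulate_genome_with_elements,
)


def _trnas(table):
    return [g for g in table.genes if g.feature_type in ("tRNA", "tmRNA")]


def _scan(table, truth):
    return find_trna_anchored_repeats(
        table.sequence, _trnas(table), max_span=truth["scan_max_span"]
    )


class TestScanner:
    def test_planted_exact_repeat_recovered_exactly(self):
        cfg = GenomeSimConfig(
            seed=11, length=25_000,
            elements=(ElementSpec(dr_length=18, dr_mismatches=0, span=8000),),
            scan_max_span=10_000,
        )
        table, truth = simulate_genome_with_elements(cfg)
        hits = _scan(table, truth)
        assert len(hits) == 1
        (hit,) = hits
        planted = truth["elements"][0]
        assert hit.anchor_span == tuple(planted["anchor_span"])
        assert hit.distal_span == tuple(planted["distal_span"])
        assert hit.mismatches == 0 and hit.length == 18

    def test_one_mismatch_repeat_recovered(self):
        cfg = GenomeSimConfig(
            seed=12, length=20_000,
            elements=(ElementSpec(dr_length=17, dr_mismatches=1, span=5000),),
            scan_max_span=8_000,
        )
        table, truth = simulate_genome_with_elements(cfg)
        (hit,) = _scan(table, truth)
        planted = truth["elements"][0]
        assert hit.distal_span == tuple(planted["distal_span"])
        assert hit.mismatches == 1

    def test_two_mismatch_repeat_not_reported(self):
        cfg = GenomeSimConfig(
            seed=13, length=16_000,
            elements=(ElementSpec(dr_length=18, dr_mismatches=2, span=4000),),
            scan_max_span=8_000,
        )
        table, truth = simulate_genome_with_elements(cfg)
        assert _scan(table, truth) == []

    def test_decoys_violating_one_constraint_each_are_silent(self):
        cfg = GenomeSimConfig(
            seed=14, length=20_000, elements=(),
            decoys=("too_short", "too_far", "two_mismatch", "no_trna"),
            scan_max_span=6_000,
        )
        table, truth = simulate_genome_with_elements(cfg)
        assert len(truth["decoys"]) == 4
        assert _scan(table, truth) == []

    def test_repeat_mismatch_count_equals_recomputed_hamming(self):
        cfg = GenomeSimConfig(
            seed=15, length=30_000,
            elements=(
                ElementSpec(dr_length=18, dr_mismatches=0, span=6000),
                ElementSpec(dr_length=20, dr_mismatches=1, span=5000, strand="-"),
            ),
            scan_max_span=8_000,
        )
        table, truth = simulate_genome_with_elements(cfg)
        for hit in _scan(table, truth):
            a = table.sequence[slice(*hit.anchor_span)]
            d = table.sequence[slice(*hit.distal_span)]
            assert sum(x != y for x, y in zip(a, d)) == hit.mismatches

    def test_strand_symmetry(self):
        """Reverse-complementing genome + annotations maps hits exactly."""
        cfg = GenomeSimConfig(
            seed=16, length=22_000,
            elements=(ElementSpec(dr_length=18, dr_mismatches=1, span=6000),),
            scan_max_span=8_000,
        )
        table, truth = simulate_genome_with_elements(cfg)
        n = len(table.sequence)
        flipped = [
            GeneRecord(
                g.gene_id, n - g.end, n - g.start,
                "-" if g.strand == "+" else "+",
                product=g.product, feature_type=g.feature_type,
            )
            for g in _trnas(table)
        ]
        fwd = _scan(table, truth)
        rev = find_trna_anchored_repeats(
            reverse_complement(table.sequence), flipped,
            max_span=truth["scan_max_span"],
        )
        mapped = {
            ((n - h.anchor_span[1], n - h.anchor_span[0]),
             (n - h.distal_span[1], n - h.distal_span[0]), h.mismatches)
            for h in rev
        }
        assert mapped == {
            (h.anchor_span, h.distal_span, h.mismatches) for h in fwd
        }

    def test_trna_outside_genome_rejected(self):
        trna = GeneRecord("t", 90, 170, "+", feature_type="tRNA")
        with pytest.raises(ValueError, match="outside"):
            find_trna_anchored_repeats("ACGT" * 30, [trna])

    def test_equivalence_with_brute_force_oracle(self):
        """Scanner output identical to exhaustive substring-pair enumeration."""
        for seed in (21, 22, 23):
            cfg = GenomeSimConfig(
                seed=seed, length=12_000,
                elements=(
                    ElementSpec(dr_length=16 + seed % 4, dr_mismatches=seed % 2,
                                span=3000,
                                strand="-" if seed % 2 else "+"),
                ),
                decoys=("two_mismatch",),
                scan_max_span=5_000,
            )
            table, truth = simulate_genome_with_elements(cfg)
            hits = _scan(table, truth)
            got = sorted(
                (h.trna_id, h.anchor_span, h.distal_span, h.length,
                 h.mismatches, h.strand)
                for h in hits
            )
            expected = brute_force_repeats(
                table.sequence, _trnas(table), max_span=truth["scan_max_span"]
            )
            assert got == expected


class TestCallElements:
    def _genome(self, seed=31, profiles=("active",)):
        specs = tuple(
            ElementSpec(dr_length=18, span=4000, n_cargo=6, marker_profile=p)
            for p in profiles
        )
        cfg = GenomeSimConfig(seed=seed, length=10_000 * len(specs) + 8000,
                              elements=specs, scan_max_span=6_000)
        return simulate_genome_with_elements(cfg)

    def test_span_and_cargo_match_truth(self):
        table, truth = self._genome()
        calls = call_elements(_scan(table, truth), table)
        assert len(calls) == 1
        planted = truth["elements"][0]
        assert calls[0].span == tuple(planted["element_span"])
        assert len(calls[0].cargo_genes) == planted["n_cargo"]

    def test_empty_cargo_call_kept(self):
        cfg = GenomeSimConfig(
            seed=32, length=12_000,
            elements=(ElementSpec(dr_length=18, span=1000, n_cargo=0,
                                  marker_profile="plain"),),
            scan_max_span=4_000,
        )
        table, truth = simulate_genome_with_elements(cfg)
        calls = call_elements(_scan(table, truth), table)
        assert len(calls) == 1 and calls[0].cargo_genes == ()

    def test_overlapping_spans_keep_longest(self):
        """Two candidate hits at one tRNA: greedy retention by span length."""
        from defensekit.mge import RepeatHit

        genes = GeneTable("chr", [GeneRecord("t1", 0, 76, "+",
                                             feature_type="tRNA")])
        short = RepeatHit("t1", (58, 76), (2076, 2094), 18, 0, "+")
        long = RepeatHit("t1", (58, 76), (5076, 5094), 18, 1, "+")
        calls = call_elements([short, long], genes)
        assert len(calls) == 1
        assert calls[0].span == (76, 5076)


class TestMobility:
    @pytest.mark.parametrize(
        "profile,expected",
        [
            ("active", "predicted_active"),
            ("immobilized", "immobilized"),
            ("unclassified", "unclassified"),
            ("plain", "immobilized"),  # no integrase at all
        ],
    )
    def test_marker_profiles(self, profile, expected):
        seeds = {"active": 41, "immobilized": 42, "unclassified": 44,
                 "plain": 45}
        cfg = GenomeSimConfig(
            seed=seeds[profile], length=12_000,
            elements=(ElementSpec(dr_length=18, span=4000, n_cargo=6,
                                  marker_profile=profile),),
            scan_max_span=6_000,
        )
        table, truth = simulate_genome_with_elements(cfg)
        (call,) = call_elements(_scan(table, truth), table)
        classified = classify_mobility(call, table)
        assert classified.mobility == expected

    def test_evidence_lists_matched_genes(self):
        table, truth = simulate_genome_with_elements(
            GenomeSimConfig(
                seed=43, length=12_000,
                elements=(ElementSpec(dr_length=18, span=4000, n_cargo=6,
                                      marker_profile="active"),),
                scan_max_span=6_000,
            )
        )
        (call,) = call_elements(_scan(table, truth), table)
        classified = classify_mobility(call, table)
        roles = {role for role, _, _ in classified.evidence}
        assert {"integrase", "excisionase"} <= roles

    def test_word_boundary_matching(self):
        """'repressor' must not satisfy the replication-initiator keyword."""
        genes = GeneTable(
            "chr",
            [
                GeneRecord("t1", 0, 76, "+", feature_type="tRNA"),
                GeneRecord("int1", 200, 500, "+", product="phage integrase"),
                GeneRecord("rep1", 600, 900, "+", product="transcriptional repressor"),
            ],
        )
        from defensekit.mge import ElementCall

        call = ElementCall("e", "chr", (76, 4000), (58, 76), (4000, 4018),
                           "t1", "+", 18, 0, ("int1", "rep1"))
        assert classify_mobility(call, genes).mobility == "unclassified"
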