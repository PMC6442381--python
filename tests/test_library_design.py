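"""Mutant-library design: masking, the five strategies, barcodes."""

import numpy as np
import pytest

from cpgmpra import (
    MotifAnnotation,
    PromoterRecord,
    cpg_positions,
    normalized_cpg_density,
)
from cpgmpra.library_design import (
    BarcodePattern,
    DesignError,
    addback_library,
    density_series_library,
    generate_barcodes,
    motif_mutation_library,
    mutable_cpgs,
    tiling_replacement_library,
    window_combination_library,
)

from conftest import random_dna


def promoter_with_motif(seq, motifs):
    return PromoterRecord(id="p", sequence=seq, motif_annotations=motifs)


class TestMutableCpgs:
    def test_cpg_inside_bound_motif_excluded(self):
        seq = "A" * 10 + "CG" + "A" * 10
        p = promoter_with_motif(seq, [MotifAnnotation("X", 8, 14, bound=True)])
        assert mutable_cpgs(p) == []

    def test_cpg_touching_bound_motif_at_second_base_excluded(self):
        # CpG spans [10, 12); motif [11, 17) intersects at position 11
        seq = "A" * 10 + "CG" + "A" * 10
        p = promoter_with_motif(seq, [MotifAnnotation("X", 11, 17, bound=True)])
        assert mutable_cpgs(p) == []

    def test_unbound_motif_does_not_mask(self):
        seq = "A" * 10 + "CG" + "A" * 10
        p = promoter_with_motif(seq, [MotifAnnotation("X", 8, 14, bound=False)])
        assert mutable_cpgs(p) == [10]

    def test_only_overlapping_cpgs_masked(self, annotated_promoter):
        masked = set(cpg_positions(annotated_promoter.sequence)) - set(
            mutable_cpgs(annotated_promoter)
        )
        for p in masked:
            assert p + 2 > 100 and p < 111  # all masked CpGs touch the bound motif


class TestWindowCombination:
    @pytest.mark.parametrize("k,expected", [(5, 32), (4, 16), (0, 1)])
    def test_construct_counts(self, rng, k, expected):
        seq = random_dna(rng, 500, gc=0.6)
        prom = PromoterRecord(id="p", sequence=seq)
        windows = [(i * 100, i * 100 + 100) for i in range(k)]
        lib = window_combination_library(prom, windows, "A", seed=0)
        assert len(lib) == expected

    def test_all_wt_combination_is_parent(self, rng):
        seq = random_dna(rng, 300, gc=0.6)
        prom = PromoterRecord(id="p", sequence=seq)
        lib = window_combination_library(prom, [(0, 150), (150, 300)], "T", seed=0)
        wt = [c for c in lib if not c.mutated_positions]
        assert len(wt) == 1 and wt[0].sequence == seq

    def test_mutant_windows_lose_all_mutable_cpgs(self, annotated_promoter):
        lib = window_combination_library(
            annotated_promoter, [(0, 200), (200, 400)], "A", seed=0
        )
        full_mut = max(lib, key=lambda c: len(c.mutated_positions))
        remaining = set(cpg_positions(full_mut.sequence))
        assert remaining.isdisjoint(mutable_cpgs(annotated_promoter))

    def test_overlapping_windows_rejected(self, rng):
        prom = PromoterRecord(id="p", sequence=random_dna(rng, 300))
        with pytest.raises(DesignError):
            window_combination_library(prom, [(0, 100), (50, 150)], "A", 0)


class TestDensitySeries:
    def test_retention_extremes(self, annotated_promoter):
        lib = density_series_library(annotated_promoter, [0.0, 1.0], "A", seed=1)
        zero, full = lib
        assert set(cpg_positions(zero.sequence)).isdisjoint(
            mutable_cpgs(annotated_promoter)
        )
        assert full.sequence == annotated_promoter.sequence

    def test_rounding_rule_12_of_35(self, rng):
        """Retaining 65.7% of 35 mutable CpGs keeps 23 and mutates 12."""
        # CpGs placed every 10 bp so substitutions cannot create new CGs
        seq = "".join("CG" + "A" * 8 for _ in range(35)) + "A" * 10
        prom = PromoterRecord(id="p", sequence=seq)
        lib = density_series_library(prom, [23 / 35], "A", seed=0)
        assert len(lib[0].mutated_positions) == 12
        assert len(cpg_positions(lib[0].sequence)) == 23

    def test_oe_monotone_in_retention(self, annotated_promoter):
        fractions = [0.0, 0.25, 0.5, 0.75, 1.0]
        lib = density_series_library(annotated_promoter, fractions, "A", seed=3)
        oes = [c.oe for c in lib]
        assert all(a <= b + 1e-12 for a, b in zip(oes, oes[1:]))

    def test_seed_reproducible(self, annotated_promoter):
        a = density_series_library(annotated_promoter, [0.5], "A", seed=9)
        b = density_series_library(annotated_promoter, [0.5], "A", seed=9)
        assert a[0].sequence == b[0].sequence

    def test_no_mutable_cpgs_is_error(self):
        prom = PromoterRecord(
            id="p",
            sequence="AACGAA" + "T" * 20,
            motif_annotations=[MotifAnnotation("X", 0, 8, bound=True)],
        )
        with pytest.raises(DesignError):
            density_series_library(prom, [0.5], "A", 0)


class TestMotifMutation:
    def test_enumeration_counts(self, rng):
        prom = PromoterRecord(id="p", sequence=random_dna(rng, 300, gc=0.5))
        sets = {
            "GABPA": [(10, 21), (50, 61)],
            "SP1": [(100, 110), (150, 160)],
        }
        lib = motif_mutation_library(prom, sets, seed=0)
        # 4 single-motif constructs + 2 all-motif constructs
        assert len(lib) == 6
        singles = [c for c in lib if not c.construct_id.endswith("_all")]
        assert len(singles) == 4

    def test_single_motif_tf_single_equals_all(self, rng):
        prom = PromoterRecord(id="p", sequence=random_dna(rng, 200))
        lib = motif_mutation_library(prom, {"NRF1": [(20, 31)]}, seed=5)
        assert lib[0].sequence == lib[1].sequence  # same seed stream per replace

    def test_empty_motif_set(self, rng):
        prom = PromoterRecord(id="p", sequence=random_dna(rng, 200))
        assert motif_mutation_library(prom, {}, seed=0) == []

    def test_replacement_cpg_free_and_length_preserved(self, rng):
        prom = PromoterRecord(id="p", sequence=random_dna(rng, 300, gc=0.7))
        lib = motif_mutation_library(prom, {"X": [(40, 60)]}, seed=2)
        for c in lib:
            assert len(c.sequence) == 300
            assert "CG" not in c.sequence[39:61]

    def test_score_constraint_destroys_motif(self, rng):
        from cpgmpra.binding_pred import PWM, logodds_scan

        pwm = PWM("X", np.eye(4)[[0, 1, 2, 3, 0, 1, 2, 3]])  # ACGTACGT
        prom = PromoterRecord(id="p", sequence="TTTT" + "ACGTACGT" + "TTTT")
        lib = motif_mutation_library(
            prom, {"X": [(4, 12)]}, seed=0,
            score_fn=lambda s: logodds_scan(s, pwm),
        )
        assert logodds_scan(lib[0].sequence[4:12], pwm) < 0


class TestTilingReplacement:
    def test_tile_count(self, rng):
        prom = PromoterRecord(id="p", sequence=random_dna(rng, 420, gc=0.6))
        lib = tiling_replacement_library(prom, window_size=10, seed=0)
        assert len(lib) == 42

    def test_replacements_cpg_free_including_junctions(self, rng):
        prom = PromoterRecord(id="p", sequence=random_dna(rng, 200, gc=0.7))
        for c in tiling_replacement_library(prom, window_size=10, seed=1):
            t = int(c.construct_id.rsplit("_", 1)[1])
            s, e = t * 10, t * 10 + 10
            lo = max(s - 1, 0)
            assert "CG" not in c.sequence[lo : e + 1]
            assert len(c.sequence) == 200

    def test_window_size_one_rejected(self, rng):
        prom = PromoterRecord(id="p", sequence=random_dna(rng, 100))
        with pytest.raises(DesignError):
            tiling_replacement_library(prom, window_size=1, seed=0)


class TestAddback:
    @pytest.fixture
    def setup(self, rng):
        seq = random_dna(rng, 400, gc=0.65)
        prom = PromoterRecord(id="p", sequence=seq)
        blocks = [(50, 120), (200, 280)]
        n_sites = len(
            [p for p in cpg_positions(seq) if any(s <= p and p + 2 <= e for s, e in blocks)]
        )
        return prom, blocks, n_sites

    def test_count_zero_is_baseline(self, setup):
        prom, blocks, _ = setup
        baseline, lib = addback_library(prom, blocks, [0], seed=0)
        assert lib[0].sequence == baseline.sequence

    def test_full_addback_restores_wt_cpg_positions_in_blocks(self, setup):
        prom, blocks, n_sites = setup
        assert n_sites >= 3
        baseline, lib = addback_library(prom, blocks, [n_sites], seed=0)
        wt_in_blocks = {
            p
            for p in cpg_positions(prom.sequence)
            if any(s <= p and p + 2 <= e for s, e in blocks)
        }
        got_in_blocks = {
            p
            for p in cpg_positions(lib[0].sequence)
            if any(s <= p and p + 2 <= e for s, e in blocks)
        }
        assert got_in_blocks == wt_in_blocks

    def test_oe_strictly_increasing_and_baseline_below_wt(self, setup):
        prom, blocks, n_sites = setup
        counts = list(range(0, n_sites + 1))
        baseline, lib = addback_library(prom, blocks, counts, seed=4)
        oes = [c.oe for c in lib]
        assert all(a < b for a, b in zip(oes, oes[1:]))
        assert baseline.oe < normalized_cpg_density(prom.sequence)

    def test_excess_count_rejected(self, setup):
        prom, blocks, n_sites = setup
        with pytest.raises(DesignError):
            addback_library(prom, blocks, [n_sites + 1], seed=0)


class TestBarcodes:
    def test_pattern_space_size(self):
        assert BarcodePattern().space_size == 4**13 * 2**2 == 268_435_456

    def test_generated_barcodes_match_pattern(self):
        pat = BarcodePattern()
        bcs = generate_barcodes(pat, n=50, min_pairwise_distance=3, seed=0)
        assert len(bcs) == len(set(bcs)) == 50
        for b in bcs:
            assert len(b) == 15
            assert pat.matches(b)
            assert b[4] in "AT" and b[9] in "AT"  # W positions

    def test_min_pairwise_distance(self):
        bcs = generate_barcodes(n=40, min_pairwise_distance=4, seed=1)
        arr = np.array([[ord(c) for c in b] for b in bcs])
        d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        np.fill_diagonal(d, 99)
        assert d.min() >= 4

    def test_zero_and_determinism(self):
        assert generate_barcodes(n=0, seed=0) == []
        assert generate_barcodes(n=20, seed=5) == generate_barcodes(n=20, seed=5)

    def test_unsatisfiable_raises(self):
        tiny = BarcodePattern(pattern="WW")
        with pytest.raises(DesignError):
            generate_barcodes(tiny, n=5, min_pairwise_distance=1, seed=0)


def test_designs_never_touch_bound_motifs(annotated_promoter):
    """No strategy except motif mutation alters a bound-motif base."""
    prom = annotated_promoter
    bound = [(m.start, m.end) for m in prom.motif_annotations if m.bound]
    libs = (
        window_combination_library(prom, [(0, 200), (200, 400)], "A", 0)
        + density_series_library(prom, [0.0, 0.5], "A", 0)
    )
    for c in libs:
        assert len(c.sequence) == len(prom.sequence)
        for p in c.mutated_positions:
            assert not any(s <= p < e for s, e in bound)
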