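"""Direct repeats, insertion mapping, excision, pattern merging, targets."""

from __future__ import annotations

import numpy as np
import pytest

from icespread.integration_sites import (
    RepeatNotFlankingError,
    classify_target,
    excise_element,
    find_direct_repeats,
    find_tandem_duplication,
    map_insertion_by_comparison,
    merge_recognition_patterns,
)
from icespread.io import Feature
from icespread.motifs import (
    BPLEBEIUS_RECOGNITION,
    GA1_PATTERN,
    GA2ABC_REPEAT,
    INTGA2CH_REPEAT,
    INTGA2D_REPEAT,
)
from icespread.synthetic_data import plant_ice, random_sequence


@pytest.mark.parametrize(
    "motif",
    [GA2ABC_REPEAT, INTGA2D_REPEAT, INTGA2CH_REPEAT],
    ids=["tRNA-Phe-22bp", "tRNA-Lys-20bp", "tRNA-Pro-19bp"],
)
def test_planted_duplication_recovered_exactly(motif, rng):
    bg = random_sequence(rng, 60_000)
    ice = random_sequence(rng, 8000)
    genome, rec = plant_ice(bg, ice, motif, rng)
    rep = find_direct_repeats(genome, rec.element_interval)
    assert rep is not None
    assert rep.length == len(motif)
    assert rep.mismatch_count == 0
    assert rep.repeat_sequence == rec.attB_sequence


def test_one_substituted_flank_reported_with_one_mismatch(rng):
    """A single internal substitution in one repeat copy (as seen in one
    carrier of the tRNA-Lys-targeting ICE) keeps the repeat call with
    mismatch_count 1."""
    bg = random_sequence(rng, 50_000)
    ice = random_sequence(rng, 6000)
    genome, rec = plant_ice(bg, ice, INTGA2D_REPEAT, rng)
    rs, re_ = rec.repeat.right_interval
    pos = rs + 17  # internal position of the 20-mer
    base = genome[pos]
    new_base = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
    genome = genome[:pos] + new_base + genome[pos + 1 :]
    rep = find_direct_repeats(genome, rec.element_interval)
    assert rep is not None
    assert rep.length == len(INTGA2D_REPEAT)
    assert rep.mismatch_count == 1


def test_unduplicated_insertion_yields_none(rng):
    bg = random_sequence(rng, 40_000)
    ice = random_sequence(rng, 5000)
    genome, rec = plant_ice(bg, ice, GA2ABC_REPEAT, rng, with_duplication=False)
    assert find_direct_repeats(genome, rec.element_interval) is None


class TestMapInsertionByComparison:
    def test_isogenic_pair_recovers_element_and_motif(self, rng):
        bg = random_sequence(rng, 60_000)
        ice = random_sequence(rng, 9000)
        occupied, rec = plant_ice(bg, ice, INTGA2D_REPEAT, rng)
        empty = rec.pre_insertion_sequence
        elem, rep, site = map_insertion_by_comparison(occupied, empty)
        assert elem == rec.element_interval
        assert occupied[elem[0] : elem[1]] == rec.element_sequence
        assert rep.length == len(INTGA2D_REPEAT)
        assert empty[site[0] : site[1]] == rec.attB_sequence

    def test_duplication_spans_only_the_motif(self, rng):
        """The inferred repeat must equal the single pre-insertion copy:
        flanks outside the motif align one-to-one."""
        bg = random_sequence(rng, 40_000)
        ice = random_sequence(rng, 5000)
        occupied, rec = plant_ice(bg, ice, GA2ABC_REPEAT, rng)
        _elem, rep, _site = map_insertion_by_comparison(
            occupied, rec.pre_insertion_sequence
        )
        assert rep.repeat_sequence == rec.attB_sequence

    def test_identical_genomes_rejected(self, rng):
        bg = random_sequence(rng, 10_000)
        with pytest.raises(ValueError):
            map_insertion_by_comparison(bg, bg)

    def test_cargo_swap_resolves_boundaries_at_shared_repeat(self, rng):
        """When the 'empty' genome carries a different cargo at the same
        site, element boundaries are still resolved at the repeat."""
        bg = random_sequence(rng, 50_000)
        ice_a = random_sequence(rng, 7000)
        ice_b = random_sequence(rng, 6000)
        genome_a, rec_a = plant_ice(bg, ice_a, INTGA2D_REPEAT, rng, site_index=0)
        genome_b, _rec_b = plant_ice(
            rec_a.pre_insertion_sequence, ice_b, INTGA2D_REPEAT, rng, site_index=0
        )
        elem, rep, _site = map_insertion_by_comparison(genome_a, genome_b)
        assert rep is not None and rep.length == len(INTGA2D_REPEAT)
        assert genome_a[elem[0] : elem[1]] == rec_a.element_sequence


class TestExciseElement:
    def test_round_trip_byte_exact_over_seeded_plants(self):
        """plant -> find_direct_repeats -> excise restores the
        pre-insertion genome byte-exactly across all published motif
        lengths (7/19/20/22 nt)."""
        motifs = [GA2ABC_REPEAT, INTGA2D_REPEAT, INTGA2CH_REPEAT, GA1_PATTERN]
        n_ok = 0
        trials = 0
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            bg = random_sequence(rng, 20_000)
            ice = random_sequence(rng, 3000)
            for motif in motifs:
                trials += 1
                genome, rec = plant_ice(bg, ice, motif, rng)
                rep = find_direct_repeats(genome, rec.element_interval)
                restored = excise_element(genome, rec.element_interval, rep)
                n_ok += restored == rec.pre_insertion_sequence
        assert trials == 100
        assert n_ok == 100

    def test_excision_at_wrong_interval_rejected(self, rng):
        bg = random_sequence(rng, 20_000)
        ice = random_sequence(rng, 3000)
        genome, rec = plant_ice(bg, ice, GA2ABC_REPEAT, rng)
        rep = find_direct_repeats(genome, rec.element_interval)
        wrong = (rec.element_interval[0] + 500, rec.element_interval[1] + 500)
        with pytest.raises(RepeatNotFlankingError):
            excise_element(genome, wrong, rep)

    def test_mismatched_copies_retain_left_copy(self, rng):
        bg = random_sequence(rng, 20_000)
        ice = random_sequence(rng, 3000)
        genome, rec = plant_ice(bg, ice, INTGA2D_REPEAT, rng)
        rs, _ = rec.repeat.right_interval
        pos = rs + 10
        sub = {"A": "G", "G": "A", "C": "T", "T": "C"}[genome[pos]]
        mutated = genome[:pos] + sub + genome[pos + 1 :]
        rep = find_direct_repeats(mutated, rec.element_interval)
        assert rep.mismatch_count == 1
        restored = excise_element(mutated, rec.element_interval, rep)
        left = rec.repeat.left_interval
        assert restored[left[0] : left[1]] == mutated[left[0] : left[1]]


class TestMergeRecognitionPatterns:
    def test_published_pair_yields_24nt_consensus(self):
        merged = merge_recognition_patterns(INTGA2D_REPEAT, BPLEBEIUS_RECOGNITION)
        assert len(merged) == 24
        assert merged.consensus == "ttcgagCCCCAGGCGGATCActca"
        assert merged.n_soft == 10

    def test_identical_inputs_all_core(self):
        merged = merge_recognition_patterns(INTGA2D_REPEAT, INTGA2D_REPEAT)
        assert merged.consensus == INTGA2D_REPEAT

    def test_disjoint_inputs_rejected(self):
        with pytest.raises(ValueError):
            merge_recognition_patterns("AAAAAAAAAAAA", "CCCCCCCCCCCC")

    def test_length_conservation(self, rng):
        a = random_sequence(rng, 20)
        b = a[8:] + random_sequence(rng, 6)
        merged = merge_recognition_patterns(a, b)
        assert len(merged) == len(a) + len(b) - 12


class TestClassifyTarget:
    feats = [
        Feature("trnF-1", "tRNA", "c1", 1000, 1076, "+", {"product": "tRNA-Phe"}),
        Feature("trnK-1", "tRNA", "c1", 5000, 5076, "+", {"isotype": "Lys"}),
        Feature("fucT", "CDS", "c1", 8000, 9200, "+", {}),
    ]

    def test_trna_phe_target(self):
        site = classify_target((1030, 1052), self.feats, contig="c1")
        assert site.target_class == "tRNA-Phe"

    def test_trna_lys_from_isotype(self):
        site = classify_target((5040, 5060), self.feats, contig="c1")
        assert site.target_class == "tRNA-Lys"

    def test_cds_interruption_is_intragenic_with_feature_id(self):
        site = classify_target((8500, 8507), self.feats, contig="c1")
        assert site.target_class == "intragenic"
        assert site.disrupted_feature == "fucT"

    def test_between_features_is_intergenic(self):
        assert classify_target((3000, 3007), self.feats, "c1").target_class == "intergenic"

    def test_without_annotations_unannotated(self):
        assert classify_target((10, 20)).target_class == "unannotated"


class TestFindTandemDuplication:
    def test_445bp_duplication_recovered(self, rng):
        region = random_sequence(rng, 6000)
        dup = region[:3000] + region[3000 - 445 : 3000] + region[3000:]
        td = find_tandem_duplication(dup, region)
        assert td is not None and td.length == 445

    def test_no_duplication_returns_none(self, rng):
        region = random_sequence(rng, 6000)
        assert find_tandem_duplication(region, region) is None

    def test_exact_recovery_over_50_random_lengths(self):
        ok = 0
        for t in range(50):
            r = np.random.default_rng(7000 + t)
            region = random_sequence(r, 5000)
            L = int(r.integers(100, 1001))
            pos = int(r.integers(L, 4000))
            dup = region[:pos] + region[pos - L : pos] + region[pos:]
            td = find_tandem_duplication(dup, region)
            ok += bool(td and td.length == L)
        assert ok == 50
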