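"""Intra-community spread classification, flank extraction, fixation."""

from __future__ import annotations

import numpy as np
import pytest

from icespread.io import Genome
from icespread.synthetic_data import (
    IcePlantSpec,
    SimulationConfig,
    SpeciesSpec,
    make_community,
    mutate_rate,
    random_sequence,
)
from icespread.t6ss_typing import LocusHit, build_concatemer, screen_genome
from icespread.transfer_detection import (
    CommunityDataset,
    assess_fixation,
    classify_spread,
    extract_region_with_flanks,
    infer_strains,
)


def _hit(gid, contig, start, end, label="GA2b"):
    return LocusHit(gid, label, [(contig, start, end, "+")], 100.0, 100.0)


class TestExtractRegionWithFlanks:
    def test_mid_contig_has_full_flanks(self, rng):
        seq = random_sequence(rng, 40_000)
        g = Genome("g", {"c": seq}, species="s")
        r = extract_region_with_flanks(g, _hit("g", "c", 15_000, 18_000))
        assert len(r.sequence) == 3000 + 20_000
        assert not r.truncated_left and not r.truncated_right

    def test_contig_start_truncates_left_flank(self, rng):
        seq = random_sequence(rng, 30_000)
        g = Genome("g", {"c": seq}, species="s")
        r = extract_region_with_flanks(g, _hit("g", "c", 2_000, 5_000))
        assert r.truncated_left and not r.truncated_right
        assert len(r.sequence) == 5_000 + 10_000

    def test_extracted_region_relocates_exactly(self, rng):
        seq = random_sequence(rng, 40_000)
        g = Genome("g", {"c": seq}, species="s")
        r = extract_region_with_flanks(g, _hit("g", "c", 12_000, 14_000))
        assert seq.find(r.sequence) == r.interval[0]


def _community_with_element(
    rng, carriers, n_species=6, locus_len=5000, genome_len=30_000,
    per_copy_mutations=0,
):
    cfg = SimulationConfig(
        seed=int(rng.integers(2**31)),
        community_id="T1",
        genome_length=genome_len,
        species=tuple(
            SpeciesSpec(label=f"sp{i+1}", isolates_per_strain=1)
            for i in range(n_species)
        ),
        ice_plants=(
            IcePlantSpec(
                "GA2b", "TTACCAA", tuple(carriers), cargo_length=locus_len,
                per_copy_mutations=per_copy_mutations,
            ),
        ),
    )
    genomes, _meta, manifest = make_community(cfg)
    rec = next(
        e
        for info in manifest.genomes.values()
        for e in info["elements"]
        if e.element_label == "GA2b"
    )
    query = build_concatemer(rec.element_sequence, [(1500, 2300)], "GA2b")
    hits = []
    for g in genomes:
        hits.extend(screen_genome(g, [query]))
    return CommunityDataset("T1", genomes), hits


class TestClassifySpread:
    def test_six_species_with_one_mismatch_is_multi_species(self, rng):
        """Copies in six species differing by at most one substitution
        sit above 99.99% identity and call as multi-species spread."""
        community, hits = _community_with_element(
            rng, [f"sp{i+1}" for i in range(6)], per_copy_mutations=1,
            locus_len=30_000, genome_len=20_000,
        )
        calls = classify_spread(community, hits, element_labels=["GA2b"])
        assert calls[0].classification == "multi_species_spread"
        assert calls[0].n_species_shared == 6
        assert calls[0].min_pairwise_identity_pct > 99.99

    def test_divergent_third_copy_excluded(self, rng):
        """Two identical copies plus a third at ~97.8% (another
        community's variant) classify as single-species spread."""
        community, hits = _community_with_element(rng, ["sp1", "sp2"])
        # give sp3 a diverged copy of the same element
        donor = community.genome(hits[0].genome_id)
        c, s, e, _ = hits[0].primary_segment
        diverged, _ = mutate_rate(donor.contigs[c][s:e], 0.022, rng)
        sp3 = next(g for g in community.genomes if g.species == "sp3")
        name = next(iter(sp3.contigs))
        sp3.contigs[name] = sp3.contigs[name][:5000] + diverged + sp3.contigs[name][5000:]
        hits.append(_hit(sp3.genome_id, name, 5000, 5000 + len(diverged)))
        calls = classify_spread(community, hits, element_labels=["GA2b"])
        assert calls[0].classification == "single_species_spread"
        assert calls[0].n_species_shared == 2

    def test_single_carrier_is_no_transfer(self, rng):
        community, hits = _community_with_element(rng, ["sp1"])
        calls = classify_spread(community, hits, element_labels=["GA2b"])
        assert calls[0].classification == "no_transfer"

    def test_absent_element_classified_absent(self, rng):
        community, hits = _community_with_element(rng, ["sp1"])
        calls = classify_spread(community, hits, element_labels=["GA1"])
        assert calls[0].classification == "absent"

    def test_is_insertion_masked_before_comparison(self, rng):
        """An IS element hopping into one copy must not break the
        transfer criterion when the IS library is supplied."""
        is_seq = random_sequence(rng, 1200)
        community, hits = _community_with_element(
            rng, ["sp1", "sp2", "sp3"], locus_len=8000
        )
        victim = community.genome(hits[-1].genome_id)
        c = hits[-1].segments[0][0]
        s = min(seg[1] for seg in hits[-1].segments)
        e = max(seg[2] for seg in hits[-1].segments)
        mid = (s + e) // 2
        victim.contigs[c] = victim.contigs[c][:mid] + is_seq + victim.contigs[c][mid:]
        hits[-1] = _hit(victim.genome_id, c, s, e + len(is_seq))
        with_mask = classify_spread(
            community, hits, is_library=[is_seq], element_labels=["GA2b"]
        )
        assert with_mask[0].classification == "multi_species_spread"
        without_mask = classify_spread(community, hits, element_labels=["GA2b"])
        assert without_mask[0].n_species_shared < 3

    def test_invariant_to_genome_order(self, rng):
        community, hits = _community_with_element(rng, ["sp1", "sp2", "sp3"])
        fwd = classify_spread(community, hits, element_labels=["GA2b"])
        rev_comm = CommunityDataset("T1", list(reversed(community.genomes)))
        rev = classify_spread(rev_comm, list(reversed(hits)), element_labels=["GA2b"])
        assert fwd[0].classification == rev[0].classification
        assert fwd[0].n_species_shared == rev[0].n_species_shared

    def test_below_threshold_genome_never_increases_sharing(self, rng):
        community, hits = _community_with_element(rng, ["sp1", "sp2", "sp3"])
        base = classify_spread(community, hits, element_labels=["GA2b"])[0]
        # add a fourth species with a 97%-identical copy (below threshold)
        donor = community.genome(hits[0].genome_id)
        c, s, e, _ = hits[0].primary_segment
        diverged, _ = mutate_rate(donor.contigs[c][s:e], 0.03, rng)
        extra = Genome("extra", {"cx": random_sequence(rng, 3000) + diverged},
                       species="sp9", community="T1")
        bigger = CommunityDataset("T1", community.genomes + [extra])
        hits2 = hits + [_hit("extra", "cx", 3000, 3000 + len(diverged))]
        grown = classify_spread(bigger, hits2, element_labels=["GA2b"])[0]
        assert grown.n_species_shared <= base.n_species_shared


class TestFixation:
    def _strained_community(self, rng, carrier_fraction=1.0, n_isolates=5):
        cfg = SimulationConfig(
            seed=int(rng.integers(2**31)),
            community_id="F1",
            genome_length=20_000,
            species=(
                SpeciesSpec("spA", isolates_per_strain=n_isolates),
                SpeciesSpec("spB", isolates_per_strain=2),
            ),
            ice_plants=(
                IcePlantSpec(
                    "GA1", "TTACCAA", ("spA",), cargo_length=4000,
                    carrier_fraction=carrier_fraction,
                ),
            ),
        )
        genomes, _meta, manifest = make_community(cfg)
        hits = [
            _hit(gid, f"{gid}_c1", *info["elements"][0].element_interval, "GA1")
            for gid, info in manifest.genomes.items()
            if info["elements"]
        ]
        return CommunityDataset("F1", genomes), hits

    def test_all_carriers_is_complete(self, rng):
        community, hits = self._strained_community(rng)
        rep = assess_fixation(community, "GA1", hits)
        assert rep.per_strain["spA_st1"] == "complete"
        assert rep.per_strain["spB_st1"] == "absent"

    def test_partial_carriage_reported(self, rng):
        community, hits = self._strained_community(rng, carrier_fraction=0.6)
        rep = assess_fixation(community, "GA1", hits)
        assert rep.per_strain["spA_st1"] == "partial"

    def test_single_isolate_strain_not_assessable(self, rng):
        cfg = SimulationConfig(
            seed=9, community_id="F2", genome_length=15_000,
            species=(SpeciesSpec("spA", isolates_per_strain=1),),
        )
        genomes, _m, _t = make_community(cfg)
        community = CommunityDataset("F2", genomes)
        rep = assess_fixation(community, "GA1", [])
        assert rep.per_strain["spA_st1"] == "not_assessable"

    def test_interstrain_carriage_difference_flagged(self, rng):
        """Two strains of one species, one fixed for the element and one
        without it, must raise the inter-strain difference flag."""
        cfg = SimulationConfig(
            seed=int(rng.integers(2**31)), community_id="F3",
            genome_length=20_000,
            species=(SpeciesSpec("spA", n_strains=2, isolates_per_strain=2),),
            ice_plants=(
                IcePlantSpec("GA2b", "TTACCAA", ("spA",), cargo_length=4000),
            ),
        )
        genomes, _meta, manifest = make_community(cfg)
        # strip the element from strain 2 by replacing its genomes with
        # element-free ones
        for g in genomes:
            if g.strain == "spA_st2":
                rec = manifest.genomes[g.genome_id]["elements"]
                if rec:
                    g.contigs[f"{g.genome_id}_c1"] = rec[0].pre_insertion_sequence
                    manifest.genomes[g.genome_id]["elements"] = []
        hits = [
            _hit(gid, f"{gid}_c1", *info["elements"][0].element_interval)
            for gid, info in manifest.genomes.items()
            if info["elements"]
        ]
        community = CommunityDataset("F3", genomes)
        rep = assess_fixation(community, "GA2b", hits)
        assert rep.per_strain["spA_st1"] == "complete"
        assert rep.per_strain["spA_st2"] == "absent"
        assert rep.inter_strain_differences == [("spA", "spA_st1", "spA_st2")]


def test_infer_strains_groups_near_isogenic_isolates(rng):
    backbone = random_sequence(rng, 20_000)
    iso1, _ = mutate_rate(backbone, 0.0001, rng)
    iso2, _ = mutate_rate(backbone, 0.0002, rng)
    other, _ = mutate_rate(backbone, 0.01, rng)  # a different strain
    gs = [
        Genome("a", {"c": iso1}, species="sp"),
        Genome("b", {"c": iso2}, species="sp"),
        Genome("c", {"c": other}, species="sp"),
    ]
    strains = infer_strains(gs)
    assert strains["a"] == strains["b"]
    assert strains["c"] != strains["a"]
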