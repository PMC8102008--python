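"""Intra-community transfer, spread and fixation calling.

Within one human subject's gut community, a mobile element shared at
>99.99% nucleotide identity between isolates of different species is
evidence of a recent (within-lifetime) transfer: two species sharing it
is a single-species spread event, three or more is multi-species
spread. Insertion sequences that hop in and out of these ICEs are
masked before comparison so they do not break the identity criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .io import Genome
from .sequence_core import global_identity, local_search
from .t6ss_typing import LocusHit


@dataclass
class CommunityDataset:
    community_id: str
    genomes: list[Genome]

    def __post_init__(self) -> None:
        if not self.genomes:
            raise ValueError("a community needs at least one genome")
        for g in self.genomes:
            if not g.species:
                raise ValueError(f"genome {g.genome_id} lacks a species label")

    def genome(self, genome_id: str) -> Genome:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)


@dataclass
class SpreadCall:
    community_id: str
    element_label: str
    species_present: set[str]
    n_species_shared: int
    classification: str  # absent | no_transfer | single_species_spread | multi_species_spread
    min_pairwise_identity_pct: float | None = None

    def __post_init__(self) -> None:
        expect = {3: "multi_species_spread", 2: "single_species_spread"}
        if self.n_species_shared >= 3 and self.classification != "multi_species_spread":
            raise ValueError(">=3 shared species must classify as multi_species_spread")
        if self.n_species_shared == 2 and self.classification != "single_species_spread":
            raise ValueError("exactly 2 shared species must classify as single_species_spread")


@dataclass
class RegionExtract:
    sequence: str
    contig: str
    interval: tuple[int, int]  # on the contig, flanks included
    truncated_left: bool
    truncated_right: bool


def extract_region_with_flanks(
    genome: Genome, hit: LocusHit, flank: int = 10_000
) -> RegionExtract:
    """Locus plus up to ``flank`` bp on both sides, truncated at contig ends.

    For a hit chained across contigs the longest segment is extracted
    (the flanks of the minor fragments are assembly artifacts).
    """
    contig, start, end, _strand = hit.primary_segment
    seq = genome.contigs[contig]
    s = max(0, start - flank)
    e = min(len(seq), end + flank)
    return RegionExtract(
        sequence=seq[s:e],
        contig=contig,
        interval=(s, e),
        truncated_left=s > start - flank or start - flank < 0,
        truncated_right=e < end + flank,
    )


def mask_is_elements(
    seq: str, is_library: list[str], min_identity_pct: float = 90.0
) -> str:
    """Remove IS-element occurrences (>=90% identity to the library) so that
    an IS hopping into one ICE copy does not break the identity criterion."""
    spans: list[tuple[int, int]] = []
    for is_seq in is_library:
        for h in local_search(
            is_seq, [seq], min_identity_pct=min_identity_pct,
            min_length=max(100, int(0.8 * len(is_seq))),
        ):
            spans.append(h.subject_interval)
    if not spans:
        return seq
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    pos = 0
    for s, e in merged:
        out.append(seq[pos:s])
        pos = e
    out.append(seq[pos:])
    return "".join(out)


def _hit_sequence(genome: Genome, hit: LocusHit) -> str:
    """The complete locus span of a hit, variable regions included.

    Per-contig, the span runs from the first to the last hit segment
    (concatemer queries produce one segment per conserved block; the
    comparison must cover the variable regions between them too)."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e, _ in hit.segments:
        by_contig.setdefault(contig, []).append((s, e))
    parts = []
    for contig in sorted(by_contig, key=lambda c: by_contig[c][0]):
        ivs = by_contig[contig]
        parts.append(genome.contigs[contig][min(s for s, _ in ivs) : max(e for _, e in ivs)])
    return "".join(parts)


def spread_identity(
    seq_a: str, seq_b: str, end_slack: int = 10
) -> float:
    """Pairwise identity for the transfer criterion.

    Extracted locus spans carry a base or two of boundary jitter (local
    hits may start/stop a few bases off the true element boundary when
    flanking bases match by chance); up to ``end_slack`` terminal
    non-match alignment columns per end are therefore excluded from the
    denominator before applying the strict identity threshold. Internal
    differences are never trimmed.
    """
    import edlib

    from .sequence_core import _CIGAR_RE, canonicalize

    res = edlib.align(canonicalize(seq_a), canonicalize(seq_b), task="path", mode="NW")
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(res["cigar"])]
    for trim_end in (False, True):
        budget = end_slack
        while ops and budget > 0:
            n, op = ops[-1] if trim_end else ops[0]
            if op == "=":
                break
            take = min(n, budget)
            budget -= take
            if take == n:
                ops.pop() if trim_end else ops.pop(0)
            else:
                rest = (n - take, op)
                if trim_end:
                    ops[-1] = rest
                else:
                    ops[0] = rest
                break
    m = sum(n for n, op in ops if op == "=")
    total = sum(n for n, _ in ops)
    return 100.0 * m / total if total else 0.0


def _single_linkage(
    items: list[int], linked: set[tuple[int, int]]
) -> list[set[int]]:
    groups = [{i} for i in items]
    for a, b in linked:
        ga = next(g for g in groups if a in g)
        gb = next(g for g in groups if b in g)
        if ga is not gb:
            ga |= gb
            groups.remove(gb)
    return groups


def classify_spread(
    community: CommunityDataset,
    hits: list[LocusHit],
    identity_threshold_pct: float = 99.99,
    is_library: list[str] | None = None,
    element_labels: list[str] | None = None,
) -> list[SpreadCall]:
    """One SpreadCall per element label for one community.

    Copies of an element are compared pairwise over their complete span
    (variable regions included, IS insertions masked out) and grouped by
    single linkage at identity strictly above the threshold; the group
    with the most species determines the classification.
    """
    by_id = {g.genome_id: g for g in community.genomes}
    for h in hits:
        if h.genome_id not in by_id:
            raise ValueError(f"hit genome {h.genome_id} not in community")
    labels = element_labels or sorted(
        {h.subtype and f"{h.ga_label}" or h.ga_label for h in hits}
    )
    labels = list(dict.fromkeys(labels))
    calls: list[SpreadCall] = []
    for label in labels:
        lhits = [h for h in hits if h.ga_label == label]
        if not lhits:
            calls.append(SpreadCall(community.community_id, label, set(), 0, "absent"))
            continue
        seqs = []
        species = []
        for h in lhits:
            s = _hit_sequence(by_id[h.genome_id], h)
            if is_library:
                s = mask_is_elements(s, is_library)
            seqs.append(s)
            species.append(by_id[h.genome_id].species)
        linked: set[tuple[int, int]] = set()
        pair_ident: dict[tuple[int, int], float] = {}
        for i, j in combinations(range(len(seqs)), 2):
            ident = spread_identity(seqs[i], seqs[j])
            pair_ident[(i, j)] = ident
            if ident > identity_threshold_pct:
                linked.add((i, j))
        groups = _single_linkage(list(range(len(seqs))), linked)
        best = max(groups, key=lambda g: len({species[i] for i in g}))
        n_sp = len({species[i] for i in best})
        min_id = None
        if len(best) > 1:
            min_id = min(
                pair_ident[(min(i, j), max(i, j))]
                for i, j in combinations(sorted(best), 2)
            )
        calls.append(
            SpreadCall(
                community.community_id,
                label,
                species_present={sp for sp in species},
                n_species_shared=n_sp if len(best) > 1 else 1,
                classification=_classify(n_sp if len(best) > 1 else 1),
                min_pairwise_identity_pct=min_id,
            )
        )
    return calls


def _classify(n_species_shared: int) -> str:
    if n_species_shared >= 3:
        return "multi_species_spread"
    if n_species_shared == 2:
        return "single_species_spread"
    return "no_transfer"


# ---------------------------------------------------------------------------
# strain grouping and fixation
# ---------------------------------------------------------------------------

def infer_strains(
    genomes: list[Genome], ani_threshold_pct: float = 99.9
) -> dict[str, str]:
    """Group same-species genomes into strains at genome-wide identity
    >= ``ani_threshold_pct`` ("near-isogenic"); used when metadata carries
    no strain column. Returns {genome_id: strain_label}."""
    assignment: dict[str, str] = {}
    by_species: dict[str, list[Genome]] = {}
    for g in genomes:
        by_species.setdefault(g.species or "", []).append(g)
    for sp, gs in by_species.items():
        reps: list[tuple[str, str]] = []  # (strain_label, sequence)
        for g in gs:
            seq = g.sequence()
            for label, rep in reps:
                if global_identity(seq, rep).identity_pct >= ani_threshold_pct:
                    assignment[g.genome_id] = label
                    break
            else:
                label = f"{sp}_strain{len(reps)+1}"
                reps.append((label, seq))
                assignment[g.genome_id] = label
    return assignment


@dataclass
class FixationReport:
    community_id: str
    element_label: str
    per_strain: dict[str, str]  # strain -> complete | partial | absent | not_assessable
    inter_strain_differences: list[tuple[str, str, str]] = field(default_factory=list)
    # (species, carrier strain, non-carrier strain)


def assess_fixation(
    community: CommunityDataset,
    element_label: str,
    hits: list[LocusHit],
) -> FixationReport:
    """Per-strain fixation of an element: complete (all isolates carry it),
    partial, or absent; strains with a single isolate are not assessable.
    Also flags same-species strain pairs that differ in carriage (one
    fixed, one free of the element) — coexistence of near-isogenic
    carriers and non-carriers."""
    strains_known = all(g.strain for g in community.genomes)
    strain_of = (
        {g.genome_id: g.strain for g in community.genomes}
        if strains_known
        else infer_strains(community.genomes)
    )
    carriers = {h.genome_id for h in hits if h.ga_label == element_label}
    members: dict[str, list[str]] = {}
    for g in community.genomes:
        members.setdefault(strain_of[g.genome_id], []).append(g.genome_id)
    per_strain: dict[str, str] = {}
    for strain, gids in members.items():
        if len(gids) < 2:
            per_strain[strain] = "not_assessable"
        else:
            n = sum(1 for gid in gids if gid in carriers)
            per_strain[strain] = (
                "complete" if n == len(gids) else "partial" if n else "absent"
            )
    species_of_strain = {
        strain_of[g.genome_id]: g.species for g in community.genomes
    }
    diffs = []
    strains = sorted(members)
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            if species_of_strain[a] != species_of_strain[b]:
                continue
            carrier_a = any(gid in carriers for gid in members[a])
            carrier_b = any(gid in carriers for gid in members[b])
            if carrier_a != carrier_b:
                ca, cb = (a, b) if carrier_a else (b, a)
                diffs.append((species_of_strain[a], ca, cb))
    return FixationReport(community.community_id, element_label, per_strain, diffs)
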