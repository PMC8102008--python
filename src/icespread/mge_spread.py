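"""Generic scanner for mobile genetic elements spreading across species.

An MGE spread event is a genomic segment of at least 4 kb shared at
>=99.99% identity by isolates of at least three different species
within one community. Candidate segments from all-vs-all comparison are
deduplicated (greedy, cd-hit-style at 0.99 identity), fragments are
joined on >=4 kb overlaps at 99.99% identity, the joined elements are
re-verified against the community, and verified elements from all
communities are clustered at 80% identity covering 80% of the larger
element.

"99.99% identity" over an alignment of length L is applied with an
integral-differences rule: allowed differences = floor(L * (1 - id)),
so a 4,000 bp alignment permits zero differences and a 10,001 bp
alignment permits one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import edlib
import networkx as nx

from .sequence_core import canonicalize, local_search, _cigar_counts
from .transfer_detection import CommunityDataset

MIN_ELEMENT_LENGTH = 4000
SPREAD_IDENTITY_PCT = 99.99
MIN_SPECIES = 3


def allowed_differences(length: int, identity_pct: float = SPREAD_IDENTITY_PCT) -> int:
    """floor(L * (1 - id)) differences permitted at a given identity."""
    return math.floor(length * (1.0 - identity_pct / 100.0) + 1e-9)


@dataclass
class MGESegment:
    genome_id: str
    contig: str
    interval: tuple[int, int]
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_ELEMENT_LENGTH:
            raise ValueError(
                f"MGE segment shorter than {MIN_ELEMENT_LENGTH} bp"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MGEElement:
    element_id: str
    sequence: str
    occurrences: list[tuple[str, str, tuple[int, int], float]] = field(
        default_factory=list
    )  # (genome_id, contig, interval, identity_pct)
    n_species: int = 0
    community_id: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MGECluster:
    cluster_id: str
    representative: MGEElement
    members: list[MGEElement]

    @property
    def communities_with_spread(self) -> list[str]:
        return sorted({m.community_id for m in self.members if m.community_id})


def _species_occurrences(
    seq: str, community: CommunityDataset, min_identity_pct: float,
    min_coverage: float = 0.99,
) -> list[tuple[str, str, tuple[int, int], float]]:
    """Genomes carrying ``seq`` near full length at the identity threshold."""
    occ = []
    for g in community.genomes:
        hits = local_search(
            seq, g.contigs, min_identity_pct=min_identity_pct,
            min_length=MIN_ELEMENT_LENGTH,
        )
        for h in hits:
            if (
                h.query_span >= min_coverage * len(seq)
                and (h.mismatches + h.gap_columns)
                <= allowed_differences(h.columns, min_identity_pct)
            ):
                occ.append((g.genome_id, h.subject_id or "0", h.subject_interval,
                            h.identity_pct))
                break
    return occ


def _is_fraction(seq: str, is_library: list[str]) -> float:
    """Fraction of a segment covered by IS-library matches."""
    spans: list[tuple[int, int]] = []
    for is_seq in is_library:
        for h in local_search(
            is_seq, [seq], min_identity_pct=90.0,
            min_length=max(100, int(0.8 * len(is_seq))),
        ):
            spans.append(h.subject_interval)
    if not spans:
        return 0.0
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return sum(e - s for s, e in merged) / len(seq)


def shared_segments(
    community: CommunityDataset,
    min_identity_pct: float = SPREAD_IDENTITY_PCT,
    min_length: int = MIN_ELEMENT_LENGTH,
    is_library: list[str] | None = None,
) -> list[MGESegment]:
    """All-vs-all candidate segments present in >=3 species of a community.

    Every contig of every genome is aligned against every other genome;
    qualifying local alignments yield candidate segments, each then
    required to occur in isolates of at least ``MIN_SPECIES`` different
    species. Segments consisting mostly (>50%) of IS-library sequence
    are excluded — transposases are ubiquitous and uninformative.
    """
    if len(community.genomes) < 2:
        raise ValueError("shared_segments needs at least two genomes")
    candidates: list[MGESegment] = []
    seen_seqs: set[str] = set()
    gs = community.genomes
    for i, j in combinations(range(len(gs)), 2):
        for cname, cseq in gs[i].contigs.items():
            for h in local_search(
                cseq, gs[j].contigs, min_identity_pct=min_identity_pct,
                min_length=min_length,
            ):
                if (h.mismatches + h.gap_columns) > allowed_differences(
                    h.columns, min_identity_pct
                ):
                    continue
                for gid, contig, iv in (
                    (gs[i].genome_id, cname, h.query_interval),
                    (gs[j].genome_id, h.subject_id, h.subject_interval),
                ):
                    seq = (
                        gs[i].contigs[cname][iv[0] : iv[1]]
                        if gid == gs[i].genome_id
                        else gs[j].contigs[contig][iv[0] : iv[1]]
                    )
                    if len(seq) < min_length or seq in seen_seqs:
                        continue
                    seen_seqs.add(seq)
                    candidates.append(MGESegment(gid, contig or "0", iv, seq))
    out = []
    for seg in candidates:
        if is_library and _is_fraction(seg.sequence, is_library) > 0.5:
            continue
        occ = _species_occurrences(seg.sequence, community, min_identity_pct)
        by_id = {g.genome_id: g for g in community.genomes}
        species = {by_id[gid].species for gid, *_ in occ}
        if len(species) >= MIN_SPECIES:
            out.append(seg)
    return out


def _cdhit_identity(shorter: str, longer: str) -> float:
    """cd-hit-style identity: identical bases over the shorter sequence."""
    res = edlib.align(shorter, longer, task="path", mode="HW")
    m, _x, _g = _cigar_counts(res["cigar"])
    return m / len(shorter)


def dedupe_segments(
    segments: list[MGESegment], identity_cutoff: float = 0.99
) -> list[MGESegment]:
    """Greedy longest-first redundancy reduction (cd-hit-est semantics):
    each segment joins the first existing representative it matches at
    >= ``identity_cutoff`` (identical bases / shorter length), else
    becomes a new representative."""
    reps: list[MGESegment] = []
    for seg in sorted(segments, key=lambda s: (-s.length, s.genome_id, s.interval)):
        for rep in reps:
            if _cdhit_identity(seg.sequence, rep.sequence) >= identity_cutoff:
                break
        else:
            reps.append(seg)
    return reps


def _find_overlap(
    a: str, b: str, min_overlap: int, min_identity_pct: float, anchor: int = 32
) -> int:
    """Length of a qualifying suffix(a)-prefix(b) overlap, or 0.

    Anchored on exact occurrences of b's first ``anchor`` bases within
    a; the full overlap is then verified at the identity threshold."""
    probe = b[:anchor]
    start = 0
    best = 0
    while True:
        p = a.find(probe, start)
        if p < 0:
            break
        L = min(len(a) - p, len(b))
        if L >= min_overlap:
            res = edlib.align(a[p : p + L], b[:L], task="distance", mode="NW")
            if res["editDistance"] <= allowed_differences(L, min_identity_pct):
                best = max(best, L)
        start = p + 1
    return best


def join_segments(
    representatives: list[MGESegment],
    min_overlap: int = MIN_ELEMENT_LENGTH,
    min_identity_pct: float = SPREAD_IDENTITY_PCT,
) -> tuple[list[str], list[MGESegment], list[list[MGESegment]]]:
    """Join fragmented segments on qualifying end-overlaps.

    Builds an overlap digraph and merges maximal unambiguous paths.
    Returns (joined sequences incl. singletons, branching segments kept
    unjoined and flagged, cycles reported as candidate circular
    elements).
    """
    reps = sorted(representatives, key=lambda s: (-s.length, s.genome_id, s.interval))
    g = nx.DiGraph()
    g.add_nodes_from(range(len(reps)))
    ovl: dict[tuple[int, int], int] = {}
    for i, j in combinations(range(len(reps)), 2):
        for a, b in ((i, j), (j, i)):
            # skip containments: joining is for end-overlapping fragments
            if reps[b].sequence in reps[a].sequence:
                continue
            L = _find_overlap(
                reps[a].sequence, reps[b].sequence, min_overlap, min_identity_pct
            )
            if L and L < min(reps[a].length, reps[b].length):
                g.add_edge(a, b)
                ovl[(a, b)] = L
    circular: list[list[MGESegment]] = [
        [reps[i] for i in cyc] for cyc in nx.simple_cycles(g)
    ]
    for cyc in nx.simple_cycles(g):
        nodes = list(cyc)
        for a, b in zip(nodes, nodes[1:] + nodes[:1]):
            if g.has_edge(a, b):
                g.remove_edge(a, b)
    flagged: list[MGESegment] = []
    for n in list(g.nodes):
        if g.out_degree(n) > 1 or g.in_degree(n) > 1:
            flagged.append(reps[n])
    ambiguous = {reps.index(s) for s in flagged}
    joined: list[str] = []
    used: set[int] = set()
    for n in sorted(g.nodes):
        if n in used or n in ambiguous:
            continue
        if any(p not in ambiguous for p in g.predecessors(n)):
            continue  # not a path start
        path = [n]
        cur = n
        while True:
            succs = [s for s in g.successors(cur) if s not in ambiguous and s not in used and s not in path]
            if len(succs) != 1:
                break
            cur = succs[0]
            path.append(cur)
        used.update(path)
        seq = reps[path[0]].sequence
        for a, b in zip(path, path[1:]):
            L = ovl[(a, b)]
            seq = seq + reps[b].sequence[L:]
        joined.append(seq)
    for s in flagged:
        joined.append(s.sequence)
    return joined, flagged, circular


def reverify(
    element_seqs: list[str],
    community: CommunityDataset,
    min_identity_pct: float = SPREAD_IDENTITY_PCT,
    prefix: str = "MGE",
) -> list[MGEElement]:
    """Keep an element only if found full-length in >=3 species at the
    identity threshold (guards against join chimeras)."""
    out = []
    by_id = {g.genome_id: g for g in community.genomes}
    for k, seq in enumerate(sorted(element_seqs, key=lambda s: (-len(s), s))):
        occ = _species_occurrences(seq, community, min_identity_pct)
        species = {by_id[gid].species for gid, *_ in occ}
        if len(species) >= MIN_SPECIES:
            out.append(
                MGEElement(
                    element_id=f"{prefix}_{community.community_id}_{k+1}",
                    sequence=seq,
                    occurrences=occ,
                    n_species=len(species),
                    community_id=community.community_id,
                )
            )
    return out


def _meets_8080(smaller: MGEElement, larger: MGEElement,
                identity_pct: float, coverage_of_larger: float) -> bool:
    res = edlib.align(smaller.sequence, larger.sequence, task="path", mode="HW")
    m, x, gcols = _cigar_counts(res["cigar"])
    ident = 100.0 * m / (m + x + gcols)
    loc = res["locations"][0]
    span = loc[1] + 1 - loc[0]
    return ident >= identity_pct and span >= coverage_of_larger / 100.0 * larger.length


def cluster_elements(
    elements: list[MGEElement],
    identity_pct: float = 80.0,
    coverage_of_larger_pct: float = 80.0,
) -> list[MGECluster]:
    """Cluster verified elements across communities (80/80 rule): greedy
    longest-first representatives; a member joins the first
    representative it aligns to at >= ``identity_pct`` covering
    >= ``coverage_of_larger_pct`` of the larger of the two. Clusters are
    returned sorted by number of communities with spread (descending)."""
    clusters: list[MGECluster] = []
    for el in sorted(elements, key=lambda e: (-e.length, e.element_id)):
        for cl in clusters:
            rep = cl.representative
            smaller, larger = (el, rep) if el.length <= rep.length else (rep, el)
            if _meets_8080(smaller, larger, identity_pct, coverage_of_larger_pct):
                cl.members.append(el)
                break
        else:
            clusters.append(MGECluster(f"cluster_{len(clusters)+1}", el, [el]))
    clusters.sort(key=lambda c: (-len(c.communities_with_spread), c.cluster_id))
    return clusters


def scan_community(
    community: CommunityDataset,
    min_identity_pct: float = SPREAD_IDENTITY_PCT,
    min_length: int = MIN_ELEMENT_LENGTH,
    is_library: list[str] | None = None,
) -> list[MGEElement]:
    """Full per-community pipeline: shared segments -> dedupe -> join ->
    re-verify. Output is invariant to genome input order (candidates are
    canonicalized and sorted at every stage)."""
    segs = shared_segments(community, min_identity_pct, min_length, is_library)
    reps = dedupe_segments(segs)
    joined, _flagged, _circ = join_segments(reps, min_length, min_identity_pct)
    # drop joined sequences contained in longer ones (duplicate paths)
    joined = sorted(set(joined), key=lambda s: (-len(s), s))
    kept: list[str] = []
    for s in joined:
        if not any(s in t for t in kept):
            kept.append(s)
    return reverify(kept, community, min_identity_pct)
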