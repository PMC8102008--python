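"""T6SS genetic-architecture typing and GA2 subtyping.

Gut Bacteroidales T6SS loci fall into three genetic architectures
(GA1, GA2, GA3); GA2 further splits into subtypes a-e. A locus is
detected with a *concatemer query*: the locus with its variable
effector/immunity regions excised and the conserved segments
concatenated. A genome is called positive when chained local hits to a
query reach >=95% identity over >=95% of the query, with chaining
across contigs to rescue fragmented assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import Genome
from .sequence_core import AlignmentResult, global_identity, local_search

GA_LABELS = ("GA1", "GA2a", "GA2b", "GA2c", "GA2d", "GA2e", "GA3")

#: genomic distance (bp) within which hits on one contig are treated as
#: one integration site; two planted copies sit much further apart.
SITE_LINK_DISTANCE = 50_000


class IntervalError(ValueError):
    pass


@dataclass(frozen=True)
class ConcatemerQuery:
    """A detection query: conserved locus segments concatenated in order.

    ``segment_map`` pairs each source-locus interval with its interval
    on the concatemer, so the excision is invertible.
    """

    ga_label: str
    sequence: str
    segment_map: tuple[tuple[tuple[int, int], tuple[int, int]], ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != sum(
            e - s for (_, (s, e)) in self.segment_map
        ):
            raise IntervalError("concatemer length != sum of segment lengths")


def build_concatemer(
    locus_seq: str,
    variable_intervals: list[tuple[int, int]],
    ga_label: str = "GA?",
) -> ConcatemerQuery:
    """Excise variable intervals from a locus; concatenate the conserved rest."""
    ivs = sorted(variable_intervals)
    prev_end = 0
    for s, e in ivs:
        if s < prev_end:
            raise IntervalError(f"overlapping variable intervals at {s}")
        if s < 0 or e > len(locus_seq) or e <= s:
            raise IntervalError(f"interval ({s},{e}) outside locus bounds")
        prev_end = e
    segments = []
    pos = 0
    cat = []
    cat_pos = 0
    for s, e in ivs + [(len(locus_seq), len(locus_seq))]:
        if s > pos:
            seg = locus_seq[pos:s]
            segments.append(((pos, s), (cat_pos, cat_pos + len(seg))))
            cat.append(seg)
            cat_pos += len(seg)
        pos = e
    return ConcatemerQuery(ga_label, "".join(cat), tuple(segments))


def restore_variable_regions(
    query: ConcatemerQuery, variable_segments: list[tuple[tuple[int, int], str]]
) -> str:
    """Inverse of :func:`build_concatemer`: re-insert the excised segments.

    ``variable_segments`` lists (source interval, sequence) for each
    excised region; the reconstruction is byte-exact.
    """
    pieces: list[tuple[int, str]] = []
    for (src, catv) in query.segment_map:
        pieces.append((src[0], query.sequence[catv[0] : catv[1]]))
    for (s, _e), seq in variable_segments:
        pieces.append((s, seq))
    return "".join(seq for _, seq in sorted(pieces))


@dataclass
class LocusHit:
    """A detected T6SS locus (possibly chained across contigs)."""

    genome_id: str
    ga_label: str
    segments: list[tuple[str, int, int, str]]  # (contig, start, end, strand)
    identity_pct: float
    query_coverage_pct: float
    fragmented: bool = False
    subtype: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.query_coverage_pct <= 100:
            raise ValueError("query_coverage_pct must be in (0, 100]")
        if self.subtype is not None and not self.ga_label.startswith("GA2"):
            raise ValueError("subtype is defined only for GA2 hits")

    @property
    def primary_segment(self) -> tuple[str, int, int, str]:
        return max(self.segments, key=lambda s: s[2] - s[1])


def _coverage(intervals: list[tuple[int, int]], qlen: int) -> float:
    """Percent of the query covered by the union of intervals (capped at 100)."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    cov = sum(e - s for s, e in merged)
    return min(100.0, 100.0 * cov / qlen)


def _weighted_identity(hits: list[AlignmentResult]) -> float:
    cols = sum(h.columns for h in hits)
    return 100.0 * sum(h.matches for h in hits) / cols


def _group_sites(hits: list[AlignmentResult]) -> list[list[AlignmentResult]]:
    """Group hits into genomic sites: same contig, within SITE_LINK_DISTANCE."""
    groups: list[list[AlignmentResult]] = []
    for h in sorted(hits, key=lambda h: (h.subject_id, h.subject_interval)):
        placed = False
        for g in groups:
            last = g[-1]
            if (
                last.subject_id == h.subject_id
                and h.subject_interval[0] - last.subject_interval[1]
                < SITE_LINK_DISTANCE
            ):
                g.append(h)
                placed = True
                break
        if not placed:
            groups.append([h])
    return groups


def _chain_query_compatible(hits: list[AlignmentResult]) -> list[AlignmentResult]:
    """Greedy longest-first selection of hits non-overlapping in query coords."""
    chosen: list[AlignmentResult] = []
    for h in sorted(hits, key=lambda h: -h.query_span):
        ok = True
        for c in chosen:
            ov = min(c.query_interval[1], h.query_interval[1]) - max(
                c.query_interval[0], h.query_interval[0]
            )
            if ov > 0.1 * min(c.query_span, h.query_span):
                ok = False
                break
        if ok:
            chosen.append(h)
    return chosen


def _emit(genome: Genome, query: ConcatemerQuery, hits: list[AlignmentResult],
          fragmented: bool) -> LocusHit:
    return LocusHit(
        genome_id=genome.genome_id,
        ga_label=query.ga_label,
        segments=[
            (h.subject_id or "0", h.subject_interval[0], h.subject_interval[1], h.strand)
            for h in sorted(hits, key=lambda h: (h.subject_id, h.subject_interval))
        ],
        identity_pct=_weighted_identity(hits),
        query_coverage_pct=_coverage([h.query_interval for h in hits], len(query.sequence)),
        fragmented=fragmented,
    )


def screen_genome(
    genome: Genome,
    queries: list[ConcatemerQuery],
    min_identity_pct: float = 95.0,
    min_coverage_pct: float = 95.0,
) -> list[LocusHit]:
    """Screen one genome for each concatemer query.

    Hits at one genomic site are chained locally; residual partial hits
    from different contigs are chained across contigs (greedy
    longest-first, non-overlapping in query coordinates), mirroring a
    manual scaffolding step for fragmented assemblies. A genome may
    carry the same architecture at two distinct sites (e.g. a GA2b and
    a GA2c ICE integrated at different chromosomal locations); every
    qualifying site is reported.
    """
    if not queries:
        raise ValueError("queries must be non-empty")
    out: list[LocusHit] = []
    for query in queries:
        raw = local_search(
            query.sequence,
            genome.contigs,
            min_identity_pct=min(90.0, min_identity_pct),
            min_length=200 if len(query.sequence) >= 400 else 100,
        )
        if not raw:
            continue
        sites = _group_sites(raw)
        leftover: list[AlignmentResult] = []
        for site_hits in sites:
            chained = _chain_query_compatible(site_hits)
            cov = _coverage([h.query_interval for h in chained], len(query.sequence))
            ident = _weighted_identity(chained)
            if cov >= min_coverage_pct and ident >= min_identity_pct:
                out.append(_emit(genome, query, chained, fragmented=False))
            else:
                leftover.extend(chained)
        if leftover and len({h.subject_id for h in leftover}) > 1:
            chained = _chain_query_compatible(leftover)
            cov = _coverage([h.query_interval for h in chained], len(query.sequence))
            ident = _weighted_identity(chained)
            if cov >= min_coverage_pct and ident >= min_identity_pct:
                out.append(_emit(genome, query, chained, fragmented=True))
    return out


@dataclass(frozen=True)
class SubtypeCall:
    subtype: str | None
    identity_pct: float
    status: str  # ok | ambiguous | unclassified | provisional
    runner_up: str | None = None
    margin: float | None = None


def assign_subtype(
    hit_region: str,
    subtype_refs: dict[str, ConcatemerQuery | str],
    min_identity_pct: float = 80.0,
    ambiguity_margin: float = 2.0,
) -> SubtypeCall:
    """Assign a GA2 region to the reference subtype of maximum global identity.

    The best subtype must beat the runner-up by ``ambiguity_margin``
    percentage points, else the call is flagged ambiguous; a region
    below ``min_identity_pct`` to every reference is a new-subtype
    candidate ("unclassified"). GA2e tolerates more within-subtype
    divergence than a-d, so GA2e calls below 90% identity are flagged
    provisional rather than rejected.
    """
    scored = []
    for name, ref in subtype_refs.items():
        seq = ref.sequence if isinstance(ref, ConcatemerQuery) else ref
        scored.append((global_identity(hit_region, seq).identity_pct, name))
    scored.sort(reverse=True)
    best_id, best = scored[0]
    if best_id < min_identity_pct:
        return SubtypeCall(None, best_id, "unclassified")
    if len(scored) > 1:
        second_id, second = scored[1]
        margin = best_id - second_id
        if margin < ambiguity_margin:
            return SubtypeCall(None, best_id, "ambiguous", runner_up=second, margin=margin)
    else:
        second, margin = None, None
    status = "provisional" if best == "GA2e" and best_id < 90.0 else "ok"
    return SubtypeCall(best, best_id, status, runner_up=second, margin=margin)
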