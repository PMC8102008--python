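"""ICE boundary mapping, target-site duplications, and integration targets.

Tyrosine-recombinase ICEs duplicate a short recognition sequence on
integration, leaving a direct repeat at the two element junctions (attL
and attR) and a single copy at the empty site (attB). The repeats of
interest here are short (7-24 bp): a low-selectivity 7-bp pattern for
GA1-type integrases and specific 19-24 bp sequences for GA2-type
integrases that target tRNA genes (tRNA-Phe, tRNA-Lys, tRNA-Pro).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import Feature, Genome
from .sequence_core import (
    DegeneratePattern,
    canonicalize,
    global_identity,
)


class NoSyntenicAnchorError(ValueError):
    """The two genomes share no alignable flank around a candidate insertion."""


class RepeatNotFlankingError(ValueError):
    """The supplied repeat does not flank the element interval."""


@dataclass(frozen=True)
class DirectRepeat:
    """The duplicated target-site motif flanking an integrated element."""

    left_interval: tuple[int, int]
    right_interval: tuple[int, int]
    repeat_sequence: str  # the left copy
    mismatch_count: int

    @property
    def length(self) -> int:
        return self.left_interval[1] - self.left_interval[0]


@dataclass(frozen=True)
class IntegrationSite:
    target_class: str  # tRNA-Phe | tRNA-Lys | tRNA-Pro | other-tRNA | intragenic | intergenic | unannotated
    repeat: DirectRepeat | None
    attL: tuple[int, int] | None = None
    attR: tuple[int, int] | None = None
    disrupted_feature: str | None = None

    def __post_init__(self) -> None:
        if self.target_class == "intragenic" and self.disrupted_feature is None:
            raise ValueError("intragenic site requires a disrupted feature id")


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def find_direct_repeats(
    genome_seq: str,
    element_interval: tuple[int, int],
    min_len: int = 6,
    max_len: int = 40,
    max_mismatch: int = 1,
    window: int = 200,
    junction_tolerance: int = 2,
) -> DirectRepeat | None:
    """Longest direct repeat whose copies abut the element junctions.

    The left copy must end, and the right copy begin, within
    ``junction_tolerance`` bp of the element start/end (real assemblies
    blur junctions by a base or two). Mismatches between the copies
    must be internal: the first and last positions of the copies are
    required to match exactly, the usual maximal-repeat convention —
    otherwise every repeat would be one-extendable by spending a
    mismatch on the boundary. Ties break toward fewer mismatches, then
    toward the copies closest to the junctions. The ``window`` bound
    only limits how far a copy may extend away from the junction; all
    published motifs are <=24 bp so 200 bp is ample.
    """
    seq = canonicalize(genome_seq)
    start, end = element_interval
    if not (0 <= start < end <= len(seq)):
        raise ValueError("element interval outside genome")
    best: tuple[int, int, int, DirectRepeat] | None = None  # (-L, mm, dist, repeat)
    for L in range(min(max_len, window), min_len - 1, -1):
        for dl in range(-junction_tolerance, junction_tolerance + 1):
            le = start + dl  # left copy end
            ls = le - L
            if ls < 0 or le > start + junction_tolerance:
                continue
            left = seq[ls:le]
            for dr in range(-junction_tolerance, junction_tolerance + 1):
                rs = end + dr
                re_ = rs + L
                if rs < end - junction_tolerance or re_ > len(seq):
                    continue
                right = seq[rs:re_]
                if left[0] != right[0] or left[-1] != right[-1]:
                    continue
                mm = _hamming(left, right)
                if mm > max_mismatch:
                    continue
                cand = (
                    -L,
                    mm,
                    abs(dl) + abs(dr),
                    DirectRepeat((ls, le), (rs, re_), left, mm),
                )
                if best is None or cand[:3] < best[:3]:
                    best = cand
        if best is not None and -best[0] == L:
            break  # longer lengths already exhausted; L is maximal
    return best[3] if best else None


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[len(a) - 1 - i] == b[len(b) - 1 - i]:
        i += 1
    return i


def _as_seq(g: Genome | str) -> str:
    return canonicalize(g.sequence() if isinstance(g, Genome) else g)


def map_insertion_by_comparison(
    genome_with: Genome | str,
    genome_without: Genome | str,
    min_anchor: int = 100,
) -> tuple[tuple[int, int], DirectRepeat | None, tuple[int, int]]:
    """Infer an element, its target-site duplication and the empty site by
    comparing an occupied genome with an isogenic unoccupied one.

    Junctions are anchored by the longest exact common prefix and
    suffix of the two sequences. For a clean insertion the prefix
    covers flank+motif and the suffix motif+flank, so their overlap on
    the empty genome *is* the duplicated motif — verifying that the
    duplication spans exactly that sequence (flanks outside it align
    1:1). When the "empty" genome carries a different cargo at the same
    site, boundaries are refined at the shared repeat instead.

    Returns ``(element_interval_on_with, repeat_or_None,
    empty_site_interval_on_without)``.
    """
    w = _as_seq(genome_with)
    wo = _as_seq(genome_without)
    if w == wo:
        raise ValueError("genomes are identical: no inserted element")
    p = _lcp(w, wo)
    s = _lcs(w, wo)
    if p < min_anchor or s < min_anchor:
        raise NoSyntenicAnchorError(
            "no syntenic anchor: shared flanks shorter than "
            f"{min_anchor} bp (prefix {p}, suffix {s})"
        )
    s = min(s, len(w) - p, len(wo))
    overlap = p + s - len(wo)
    if overlap >= 0:
        # clean insertion: overlap on the empty genome is the duplicated motif
        elem = (p, len(w) - s)
        motif_len = overlap
        empty_site = (p - motif_len, p)
        repeat = None
        if motif_len > 0:
            left = (p - motif_len, p)
            right = (len(w) - s, len(w) - s + motif_len)
            repeat = DirectRepeat(left, right, w[left[0] : left[1]], 0)
        return elem, repeat, empty_site
    # both genomes carry cargo at the site: resolve boundaries at the repeat.
    # the exact prefix/suffix anchors can stop a few tens of bases short of
    # the true junction (flank substitutions), so the repeat search runs
    # with a widened junction tolerance
    raw = (p, len(w) - s)
    repeat = find_direct_repeats(w, raw, junction_tolerance=40, window=250)
    if repeat is not None:
        elem = (repeat.left_interval[1], repeat.right_interval[0])
    else:
        elem = raw
    raw_wo = (p, len(wo) - s)
    other = find_direct_repeats(wo, raw_wo, junction_tolerance=40, window=250)
    if other is not None:
        empty_site = other.left_interval
    else:
        empty_site = (p, p + (repeat.length if repeat else 0))
    return elem, repeat, empty_site


def excise_element(
    genome_seq: str, element_interval: tuple[int, int], repeat: DirectRepeat
) -> str:
    """Remove the element plus one repeat copy, restoring the empty site.

    The left copy is retained (fixed convention; attB biology does not
    distinguish the copies). Round-trips insertion byte-exactly when
    the two copies are identical.
    """
    seq = canonicalize(genome_seq)
    start, end = element_interval
    if abs(repeat.left_interval[1] - start) > 2 or abs(repeat.right_interval[0] - end) > 2:
        raise RepeatNotFlankingError("repeat copies do not abut the element interval")
    left = seq[repeat.left_interval[0] : repeat.left_interval[1]]
    right = seq[repeat.right_interval[0] : repeat.right_interval[1]]
    if _hamming(left, right) != repeat.mismatch_count:
        raise RepeatNotFlankingError("stored repeat does not match the genome")
    return seq[: repeat.left_interval[1]] + seq[repeat.right_interval[1] :]


def merge_recognition_patterns(
    pattern_a: str, pattern_b: str, min_overlap: int = 10
) -> DegeneratePattern:
    """Merge two overlapping recognition sequences into one degenerate pattern.

    Positions covered by both inputs become the uppercase core;
    positions covered by only one become lowercase soft positions
    (mismatch-tolerant). The merged length is |a| + |b| - overlap.
    """
    a = canonicalize(pattern_a)
    b = canonicalize(pattern_b)
    if a in b or b in a:
        longer, shorter = (a, b) if len(a) >= len(b) else (b, a)
        i = longer.find(shorter)
        cons = (
            longer[:i].lower() + shorter + longer[i + len(shorter) :].lower()
        )
        return DegeneratePattern(cons)
    best = None  # (overlap, merged, core_start, core_len)
    for first, second in ((a, b), (b, a)):
        for L in range(min(len(a), len(b)), min_overlap - 1, -1):
            if first[-L:] == second[:L]:
                merged = first + second[L:]
                cand = (L, merged, len(first) - L, L)
                if best is None or L > best[0]:
                    best = cand
                break
    if best is None:
        raise ValueError(f"no exact overlap >= {min_overlap} nt between patterns")
    _, merged, cs, cl = best
    cons = merged[:cs].lower() + merged[cs : cs + cl] + merged[cs + cl :].lower()
    return DegeneratePattern(cons)


_TRNA_ISOTYPES = {"phe": "tRNA-Phe", "lys": "tRNA-Lys", "pro": "tRNA-Pro"}


def classify_target(
    empty_site: tuple[int, int],
    annotations: list[Feature] | None = None,
    contig: str | None = None,
    repeat: DirectRepeat | None = None,
    attL: tuple[int, int] | None = None,
    attR: tuple[int, int] | None = None,
) -> IntegrationSite:
    """Classify the chromosomal target of an integration site.

    With annotations, the site is classified by overlap: a tRNA gene
    (isotype read from the annotation) beats a CDS, which is reported
    as intragenic with the disrupted feature id; no overlap is
    intergenic. Without annotations the class is "unannotated".
    """
    if annotations is None:
        return IntegrationSite("unannotated", repeat, attL, attR)
    s, e = empty_site
    overlapping = [
        f
        for f in annotations
        if (contig is None or f.contig == contig) and f.start < e and f.end > s
    ]
    trnas = [f for f in overlapping if f.ftype.lower() in ("trna", "trna_gene")]
    if trnas:
        f = trnas[0]
        text = " ".join(
            [f.feature_id, f.attributes.get("product", ""), f.attributes.get("isotype", "")]
        ).lower()
        for key, label in _TRNA_ISOTYPES.items():
            if key in text:
                return IntegrationSite(label, repeat, attL, attR)
        return IntegrationSite("other-tRNA", repeat, attL, attR)
    cds = [f for f in overlapping if f.ftype.lower() in ("cds", "gene")]
    if cds:
        return IntegrationSite(
            "intragenic", repeat, attL, attR, disrupted_feature=cds[0].feature_id
        )
    return IntegrationSite("intergenic", repeat, attL, attR)


@dataclass(frozen=True)
class TandemDuplication:
    length: int
    position: int  # start of the duplicated copy on the carrier region


def find_tandem_duplication(
    region_a: str,
    region_b: str,
    min_len: int = 20,
    min_region_identity_pct: float = 95.0,
) -> TandemDuplication | None:
    """Detect an internal tandem duplication present in one of two
    otherwise near-identical regions (e.g. a 445-bp duplication inside a
    sheath gene distinguishing a subset of co-resident strains).

    The shorter region is anchored chunk-wise in the longer one; the
    insertion reveals itself as a jump in the chunk offsets (0 before,
    +d after, d the length difference). Around the jump, the longer
    region is tested directly for a span that equals its immediate
    successor (<=5% mismatches) — the signature of a tandem copy,
    robust to where an aligner would place the gap within the repeat.
    A same-length insertion of unrelated sequence fails the tandem
    check and returns none.
    """
    a = canonicalize(region_a)
    b = canonicalize(region_b)
    if len(a) == len(b):
        return None
    carrier, other = (a, b) if len(a) > len(b) else (b, a)
    d = len(carrier) - len(other)
    if d < min_len:
        return None
    if global_identity(a, b).identity_pct < min_region_identity_pct - 50:
        return None  # guard against wholly unrelated input
    chunk = 150
    last_zero_end = 0
    first_shift_start = len(other)
    prev_hit = 0
    for start in range(0, len(other) - chunk + 1, chunk):
        p = carrier.find(other[start : start + chunk], prev_hit)
        if p < 0:
            continue
        off = p - start
        prev_hit = p
        if off == 0:
            last_zero_end = start + chunk
        elif off >= d and first_shift_start == len(other):
            first_shift_start = start
    lo = max(0, last_zero_end - d - chunk)
    hi = min(len(carrier) - 2 * d, first_shift_start + d + chunk)
    tol = max(1, d // 20)
    for c in range(lo, hi + 1):
        if _hamming(carrier[c : c + d], carrier[c + d : c + 2 * d]) <= tol:
            return TandemDuplication(d, c)
    return None
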