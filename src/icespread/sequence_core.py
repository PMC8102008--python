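"""Alignment, identity and degenerate-pattern primitives.

All coordinates are 0-based half-open internally. Percent identity is
defined over *all* alignment columns, gap columns included::

    identity_pct = 100 * matches / (matches + mismatches + gap_columns)

This differs from BLAST-style identity (which some tools compute over
non-gap columns only); the convention here matches the whole-element
"global DNA percent identity" usage throughout the package.

Pairwise alignment is computed with edlib (unit-cost edit-distance
alignment with traceback). At the near-identity regimes this package
operates in (>=95% identity for every downstream threshold) the scoring
scheme does not change any call; it is fixed and documented here so that
identity values are reproducible.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = re.compile(r"^[ACGTN]*$")
_CIGAR_RE = re.compile(r"(\d+)([=XID])")

#: default exact-seed length for local search; safe because every
#: downstream threshold is >=95% identity, so a 15-mer exact seed is
#: expected multiple times in any qualifying hit.
SEED_SIZE = 15


class InvalidSequenceError(ValueError):
    """Raised for empty input where a non-empty nucleotide string is required."""


class InvalidPatternError(ValueError):
    """Raised when a degenerate pattern uses characters outside {ACGTNacgtn}."""


def canonicalize(seq: str) -> str:
    """Uppercase a nucleotide string, mapping ambiguity codes other than N to N.

    A warning is emitted when any non-ACGTN character is replaced.
    """
    up = seq.upper()
    if not _VALID.match(up):
        n_bad = sum(1 for c in up if c not in "ACGTN")
        warnings.warn(
            f"{n_bad} non-ACGTN character(s) mapped to N", stacklevel=2
        )
        up = "".join(c if c in "ACGTN" else "N" for c in up)
    return up


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment between a query and a subject interval.

    ``identity_pct`` uses the all-columns denominator (gaps count as
    differences). ``strand`` is the subject strand the query matched;
    query coordinates always refer to the forward query.
    """

    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    strand: str
    matches: int
    mismatches: int
    gap_columns: int
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.query_interval[1] <= self.query_interval[0]:
            raise ValueError("empty query interval")
        if self.subject_interval[1] <= self.subject_interval[0]:
            raise ValueError("empty subject interval")

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_columns

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.columns

    @property
    def query_span(self) -> int:
        return self.query_interval[1] - self.query_interval[0]

    @property
    def subject_span(self) -> int:
        return self.subject_interval[1] - self.subject_interval[0]


def _cigar_counts(cigar: str) -> tuple[int, int, int]:
    """Return (matches, mismatches, gap_columns) from an edlib extended cigar."""
    m = x = g = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            m += n
        elif op == "X":
            x += n
        else:  # I or D
            g += n
    return m, x, g


def global_identity(seq_a: str, seq_b: str) -> AlignmentResult:
    """End-to-end alignment of two sequences; identity over all columns.

    Symmetric in its arguments: ``identity(a, b) == identity(b, a)``
    because the underlying edit distance is symmetric and the column
    count of an optimal path is ``matches + editDistance``.
    """
    if not seq_a or not seq_b:
        raise InvalidSequenceError("global_identity requires non-empty sequences")
    a = canonicalize(seq_a)
    b = canonicalize(seq_b)
    res = edlib.align(a, b, task="path", mode="NW")
    m, x, g = _cigar_counts(res["cigar"])
    return AlignmentResult(
        query_interval=(0, len(a)),
        subject_interval=(0, len(b)),
        strand="+",
        matches=m,
        mismatches=x,
        gap_columns=g,
    )


# ---------------------------------------------------------------------------
# degenerate patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegeneratePattern:
    """Case-encoded consensus: uppercase = exact, 'n'/'N' = wildcard,
    lowercase (non-n) = soft position where up to ``max_soft_mismatches``
    total mismatches are tolerated across all soft positions."""

    consensus: str
    max_soft_mismatches: int = 1

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[ACGTNacgtn]+", self.consensus):
            raise InvalidPatternError(
                f"pattern alphabet restricted to ACGTN (both cases): {self.consensus!r}"
            )
        if self.max_soft_mismatches > self.n_soft:
            object.__setattr__(
                self, "max_soft_mismatches", self.n_soft
            )

    @property
    def n_soft(self) -> int:
        return sum(1 for c in self.consensus if c.islower() and c != "n")

    def __len__(self) -> int:
        return len(self.consensus)

    def reverse_complement(self) -> "DegeneratePattern":
        return DegeneratePattern(
            self.consensus.translate(_COMPLEMENT)[::-1], self.max_soft_mismatches
        )

    def matches_window(self, window: str) -> bool:
        if len(window) != len(self.consensus):
            return False
        soft_miss = 0
        for w, p in zip(window.upper(), self.consensus):
            if p in "Nn":
                continue
            if p.isupper():
                if w != p:
                    return False
            elif w != p.upper():
                soft_miss += 1
                if soft_miss > self.max_soft_mismatches:
                    return False
        return True


@dataclass(frozen=True)
class PatternMatch:
    position: int  # forward-strand 0-based start
    strand: str


def match_pattern(seq: str, pattern: DegeneratePattern) -> list[PatternMatch]:
    """All positions where the degenerate pattern matches, both strands.

    Positions are reported on the forward strand; a '-' hit means the
    reverse complement of the window matches the pattern.
    """
    s = canonicalize(seq)
    L = len(pattern)
    if L > len(s):
        raise InvalidSequenceError("pattern longer than sequence")
    out: list[PatternMatch] = []
    rc = pattern.reverse_complement()
    palindromic = rc.consensus.upper() == pattern.consensus.upper() and (
        rc.consensus == pattern.consensus
    )
    for i in range(len(s) - L + 1):
        w = s[i : i + L]
        if pattern.matches_window(w):
            out.append(PatternMatch(i, "+"))
        if not palindromic and rc.matches_window(w):
            out.append(PatternMatch(i, "-"))
    return out


# ---------------------------------------------------------------------------
# seeded local search
# ---------------------------------------------------------------------------

def _seed_index(query: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        if "N" in kmer:
            continue
        idx.setdefault(kmer, []).append(i)
    return idx


def _cluster_seeds(
    seeds: list[tuple[int, int]], band: int = 100, max_gap: int = 5000
) -> list[list[tuple[int, int]]]:
    """Group (qpos, spos) seed matches into roughly collinear clusters."""
    seeds = sorted(seeds, key=lambda t: (t[1] - t[0], t[1]))
    clusters: list[list[tuple[int, int]]] = []
    for qp, sp in seeds:
        placed = False
        for cl in clusters:
            q0, s0 = cl[-1]
            if abs((sp - qp) - (s0 - q0)) <= band and abs(sp - s0) <= max_gap:
                cl.append((qp, sp))
                placed = True
                break
        if not placed:
            clusters.append([(qp, sp)])
    return clusters


def _xdrop_extend(
    query: str, subject: str, q0: int, q1: int, s0: int, s1: int, xdrop: int = 20
) -> tuple[int, int, int, int]:
    """Ungapped extension of [q0,q1)x[s0,s1) in both directions (match +1,
    mismatch -2, stop when the running score drops xdrop below its best)."""
    # left
    score = best = 0
    bq, bs = q0, s0
    qi, si = q0 - 1, s0 - 1
    while qi >= 0 and si >= 0:
        score += 1 if query[qi] == subject[si] else -2
        if score > best:
            best, bq, bs = score, qi, si
        if score < best - xdrop:
            break
        qi -= 1
        si -= 1
    q0, s0 = bq, bs
    # right
    score = best = 0
    eq, es = q1, s1
    qi, si = q1, s1
    while qi < len(query) and si < len(subject):
        score += 1 if query[qi] == subject[si] else -2
        qi += 1
        si += 1
        if score > best:
            best, eq, es = score, qi, si
        if score < best - xdrop:
            break
    return q0, eq, s0, es


def _ops_of_span(query: str, subject: str, q0: int, q1: int, s0: int, s1: int):
    res = edlib.align(query[q0:q1], subject[s0:s1], task="path", mode="NW")
    return [(int(n), op) for n, op in _CIGAR_RE.findall(res["cigar"])]


def _best_subwindow(
    ops: list[tuple[int, int]],
    q0: int,
    s0: int,
    min_identity_pct: float,
    min_length: int,
) -> tuple[int, int, int, int, int, int, int] | None:
    """Longest window of alignment blocks, starting and ending on a match
    block, that satisfies the identity threshold over all its columns.

    A hit whose full span dips below the threshold may still contain a
    qualifying core (e.g. an element flanked by a few chance-matching
    bases beyond its boundary) — the behaviour expected of a true local
    aligner.
    """
    # prefix sums over blocks: (matches, mismatches, gaps, qlen, slen)
    pm = [0]
    px = [0]
    pg = [0]
    pq = [0]
    ps = [0]
    for n, op in ops:
        pm.append(pm[-1] + (n if op == "=" else 0))
        px.append(px[-1] + (n if op == "X" else 0))
        pg.append(pg[-1] + (n if op in "ID" else 0))
        pq.append(pq[-1] + (n if op in "=XI" else 0))
        ps.append(ps[-1] + (n if op in "=XD" else 0))
    match_blocks = [i for i, (_n, op) in enumerate(ops) if op == "="]
    f = min_identity_pct / 100.0
    # any qualifying window's difference count is bounded by m_total*(1-f)/f;
    # each inter-block gap costs >=1 difference, so the scan per start is short
    # at near-identity thresholds
    diff_cap = pm[-1] * (1.0 - f) / f + 1.0
    best = None
    best_span = min_length - 1
    for a_pos, ii in enumerate(match_blocks):
        if min(pq[-1] - pq[ii], ps[-1] - ps[ii]) <= best_span:
            continue
        for jj in match_blocks[a_pos:]:
            x = px[jj + 1] - px[ii]
            g = pg[jj + 1] - pg[ii]
            if x + g > diff_cap:
                break
            m = pm[jj + 1] - pm[ii]
            span = min(pq[jj + 1] - pq[ii], ps[jj + 1] - ps[ii])
            if span <= best_span:
                continue
            if 100.0 * m / (m + x + g) >= min_identity_pct:
                best = (
                    q0 + pq[ii],
                    q0 + pq[jj + 1],
                    s0 + ps[ii],
                    s0 + ps[jj + 1],
                    m,
                    x,
                    g,
                )
                best_span = span
    return best


def _search_one_strand(
    query: str,
    subject: str,
    min_identity_pct: float,
    min_length: int,
    k: int,
) -> list[tuple[int, int, int, int, int, int, int]]:
    idx = _seed_index(query, k)
    seeds: list[tuple[int, int]] = []
    for i in range(len(subject) - k + 1):
        kmer = subject[i : i + k]
        hits = idx.get(kmer)
        if hits:
            for qp in hits:
                seeds.append((qp, i))
    out = []
    for cl in _cluster_seeds(seeds):
        q0 = min(q for q, _ in cl)
        q1 = max(q for q, _ in cl) + k
        s0 = min(s for _, s in cl)
        s1 = max(s for _, s in cl) + k
        q0, q1, s0, s1 = _xdrop_extend(query, subject, q0, q1, s0, s1)
        if min(q1 - q0, s1 - s0) < min_length:
            continue
        ops = _ops_of_span(query, subject, q0, q1, s0, s1)
        found = _best_subwindow(ops, q0, s0, min_identity_pct, min_length)
        if found:
            out.append(found)
    return out


def _dedupe_hits(hits: list[AlignmentResult]) -> list[AlignmentResult]:
    """Merge hits to the same query span: keep the best-scoring of any pair
    overlapping >=50% in both query and subject on the same contig/strand."""
    kept: list[AlignmentResult] = []
    for h in sorted(hits, key=lambda h: -h.matches):
        dup = False
        for k2 in kept:
            if k2.subject_id != h.subject_id or k2.strand != h.strand:
                continue
            qo = min(k2.query_interval[1], h.query_interval[1]) - max(
                k2.query_interval[0], h.query_interval[0]
            )
            so = min(k2.subject_interval[1], h.subject_interval[1]) - max(
                k2.subject_interval[0], h.subject_interval[0]
            )
            if qo > 0.5 * h.query_span and so > 0.5 * h.subject_span:
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def local_search(
    query: str,
    subject_contigs: Sequence[str] | dict[str, str],
    min_identity_pct: float = 95.0,
    min_length: int = 100,
    seed_size: int = SEED_SIZE,
) -> list[AlignmentResult]:
    """Seeded local alignment of ``query`` against contigs, both strands.

    Exact ``seed_size``-mer seeds are clustered by diagonal, extended
    ungapped with an X-drop, and re-scored end-to-end with edlib. Hits
    shorter than ``min_length`` (on either sequence) or below
    ``min_identity_pct`` are discarded; overlapping hits to the same
    span are merged. Results are sorted by (contig, subject start).
    """
    if not query:
        raise InvalidSequenceError("empty query")
    if min_length < seed_size:
        raise ValueError("min_length must be >= seed size")
    q = canonicalize(query)
    qrc = reverse_complement(q)
    if isinstance(subject_contigs, dict):
        items: Iterable[tuple[str, str]] = subject_contigs.items()
    else:
        items = ((str(i), c) for i, c in enumerate(subject_contigs))
    results: list[AlignmentResult] = []
    for name, contig in items:
        s = canonicalize(contig)
        for strand, qs in (("+", q), ("-", qrc)):
            for q0, q1, s0, s1, m, x, g in _search_one_strand(
                qs, s, min_identity_pct, min_length, seed_size
            ):
                if strand == "-":
                    q0, q1 = len(q) - q1, len(q) - q0
                results.append(
                    AlignmentResult(
                        query_interval=(q0, q1),
                        subject_interval=(s0, s1),
                        strand=strand,
                        matches=m,
                        mismatches=x,
                        gap_columns=g,
                        subject_id=name,
                    )
                )
    results = _dedupe_hits(results)
    results.sort(key=lambda h: (h.subject_id, h.subject_interval))
    return results
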