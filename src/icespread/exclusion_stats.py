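"""Gene-disruption calling, GA co-occurrence tables, and Fisher's exact test.

Strains carrying both a GA1 and a GA2 ICE are rare, and in those that
do, a GA1-encoded methylase-helicase gene (mhgA) is disproportionately
disrupted — suggesting it participates in excluding the second element.
This module detects disruptions (frameshifts, IS insertions,
truncations) against an intact reference ORF, tabulates per-genome GA
combinations, and tests 2x2 associations with an exact hypergeometric
computation written from first principles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import lgamma, exp

import edlib

from .sequence_core import canonicalize
from .t6ss_typing import LocusHit


class InvalidORFError(ValueError):
    pass


@dataclass
class DisruptionCall:
    kind: str  # frameshift | is_insertion | truncation | cargo_replacement | intact
    indel_size: int | None = None
    codon_index: int | None = None  # 1-based from the reference start codon
    codon_length: int | None = None
    nt_offset: int | None = None  # 0-based reference offset of the lesion
    genome_id: str | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "frameshift" and self.indel_size is not None:
            if self.indel_size % 3 == 0:
                raise ValueError("a frameshift indel size cannot be divisible by 3")
        if (
            self.codon_index is not None
            and self.codon_length is not None
            and self.codon_index > self.codon_length
        ):
            raise ValueError("codon index beyond reference length")


_STOPS = {"TAA", "TAG", "TGA"}


def _validate_orf(ref: str) -> None:
    if len(ref) % 3 != 0:
        raise InvalidORFError("reference length not divisible by 3")
    for i in range(0, len(ref) - 3, 3):
        if ref[i : i + 3] in _STOPS:
            raise InvalidORFError(f"internal stop codon at codon {i//3 + 1}")


def detect_disruption(
    observed_gene_seq: str,
    reference_gene_seq: str,
    is_library: list[str] | None = None,
    truncation_coverage: float = 0.80,
    min_indel_report: int = 1,
) -> DisruptionCall:
    """Classify an observed gene copy against an intact reference ORF.

    The lesion is located by exact longest-common-prefix/suffix
    arithmetic, which pins a single indel event without depending on
    where a gap-placing aligner happens to open the gap. The lesion
    offset is the first reference position at which the sequences
    diverge (indel placement is inherently ambiguous when the indel
    borders a repeated base; the leftmost-divergence convention is used,
    the same arithmetic as "frameshifted by 2 bp at codon k of n":
    codon = offset // 3 + 1, 1-based). An insertion matching the IS
    library at >=90% identity is an IS insertion; a very large
    non-IS insertion (>=50% of the gene) is a cargo replacement; a copy
    covering less than ``truncation_coverage`` of the reference is a
    truncation.
    """
    ref = canonicalize(reference_gene_seq)
    obs = canonicalize(observed_gene_seq)
    _validate_orf(ref)
    codon_length = len(ref) // 3
    if obs == ref:
        return DisruptionCall("intact", codon_length=codon_length)
    if len(obs) < truncation_coverage * len(ref):
        return DisruptionCall(
            "truncation",
            indel_size=len(ref) - len(obs),
            codon_length=codon_length,
        )
    net = len(obs) - len(ref)
    p = _lcp(obs, ref)
    codon = min(p // 3 + 1, codon_length)
    if net == 0:
        return DisruptionCall("intact", codon_length=codon_length)
    if net > 0:
        inserted = obs[p : p + net]
        if is_library and _matches_is(inserted, is_library):
            kind = "is_insertion"
        elif net >= 0.5 * len(ref):
            kind = "cargo_replacement"
        elif net % 3 != 0:
            kind = "frameshift"
        else:
            kind = "inframe_indel"
    else:
        kind = "frameshift" if (-net) % 3 != 0 else "inframe_indel"
    if abs(net) < min_indel_report:
        return DisruptionCall("intact", codon_length=codon_length)
    return DisruptionCall(
        kind,
        indel_size=abs(net),
        codon_index=codon,
        codon_length=codon_length,
        nt_offset=p,
    )


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _matches_is(inserted: str, is_library: list[str]) -> bool:
    if len(inserted) < 50:
        return False
    for is_seq in is_library:
        L = min(len(inserted), len(is_seq))
        res = edlib.align(inserted, is_seq, task="distance", mode="NW")
        total = max(len(inserted), len(is_seq))
        if 100.0 * (total - res["editDistance"]) / total >= 90.0:
            return True
    return False


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------

def cooccurrence_counts(
    hits: list[LocusHit],
    clonal_groups: dict[str, str] | None = None,
) -> tuple[dict[str, set[str]], Counter, list[str]]:
    """Per-genome GA label sets and aggregate combination counts.

    ``clonal_groups`` maps genome_id -> clonal group label; when given,
    nearly-clonal genomes with identical GA combinations are counted
    once, and the dropped genomes are returned as flags. A genome with
    several architectures contributes to each marginal tally.
    """
    per_genome: dict[str, set[str]] = {}
    for h in hits:
        per_genome.setdefault(h.genome_id, set()).add(h.ga_label)
    combos: Counter = Counter()
    flagged: list[str] = []
    seen_clonal: set[tuple[str, frozenset]] = set()
    for gid in sorted(per_genome):
        combo = frozenset(per_genome[gid])
        if clonal_groups and gid in clonal_groups:
            key = (clonal_groups[gid], combo)
            if key in seen_clonal:
                flagged.append(gid)
                continue
            seen_clonal.add(key)
        combos[combo] += 1
    return per_genome, combos, flagged


def marginal_counts(combos: Counter) -> Counter:
    out: Counter = Counter()
    for combo, n in combos.items():
        for label in combo:
            out[label] += n
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test (from first principles)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: GA1-only vs GA1+GA2 strains (or any two groups); columns:
    gene disrupted vs intact."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("row margins must be positive")
        if self.a + self.c == 0 or self.b + self.d == 0:
            raise ValueError("column margins must be positive")


def _log_hypergeom(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(A = a) for the conditional (hypergeometric) distribution of the
    top-left cell given margins r1, r2 (rows) and c1 (first column)."""
    n = r1 + r2
    return (
        lgamma(r1 + 1)
        - lgamma(a + 1)
        - lgamma(r1 - a + 1)
        + lgamma(r2 + 1)
        - lgamma(c1 - a + 1)
        - lgamma(r2 - (c1 - a) + 1)
        - (lgamma(n + 1) - lgamma(c1 + 1) - lgamma(n - c1 + 1))
    )


def fisher_exact(
    table: ContingencyTable2x2 | tuple[int, int, int, int],
    alternative: str = "two_sided",
) -> float:
    """Exact p-value for a 2x2 table under fixed margins.

    ``two_sided`` follows the minimum-likelihood convention of
    mainstream statistical software: the sum of probabilities of all
    tables with the same margins whose point probability does not
    exceed that of the observed table (up to a 1e-7 relative
    tolerance). ``greater``/``less`` are one-sided on the top-left cell.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    amin = max(0, c1 - r2)
    amax = min(r1, c1)
    logp = {k: _log_hypergeom(k, r1, r2, c1) for k in range(amin, amax + 1)}
    p_obs = exp(logp[a])
    if alternative == "greater":
        p = sum(exp(lp) for k, lp in logp.items() if k >= a)
    elif alternative == "less":
        p = sum(exp(lp) for k, lp in logp.items() if k <= a)
    elif alternative == "two_sided":
        cutoff = p_obs * (1 + 1e-7)
        included = [exp(lp) for lp in logp.values() if exp(lp) <= cutoff]
        if len(included) == len(logp):
            return 1.0  # the observed table is (one of) the most probable
        p = sum(included)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(1.0, p)
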