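# Methods

`icespread` infers the mobility of integrative and conjugative elements
(ICEs) that carry type VI secretion system (T6SS) loci in human gut
Bacteroidales, from genome assemblies of co-resident isolates. This
note documents the models and conventions behind each stage, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Identity and alignment conventions

All pairwise comparison is built on edlib's unit-cost edit-distance
alignment with traceback. Percent identity is defined over **all**
alignment columns, gap columns included:

    identity = 100 · matches / (matches + mismatches + gap_columns)

This is the whole-element "global DNA percent identity" convention and
differs from BLAST-style identity computed on non-gap columns. The
choice of scoring scheme is immaterial at the regimes the pipeline
operates in — every decision threshold is ≥95% identity, where optimal
alignments are essentially unique — but it is fixed so that reported
identities are reproducible, and the test suite pins the reported
difference count to an independent dynamic-programming oracle.

The seeded local search uses 15-mer exact seeds (sparse seeding is safe
above 95% identity), diagonal clustering (band 100 bp, gap 5 kb),
ungapped X-drop extension (+1/−2, drop 20), and an end-to-end re-scoring
of the candidate span. Two refinements make it behave like a true local
aligner: reported hits always start and end on a match column, and when
a candidate span as a whole falls below the identity threshold, the
longest qualifying sub-window (starting and ending on matches) is
reported instead. Without the second rule, an element flanked by a few
chance-matching bases beyond its boundary would be discarded wholesale
at strict thresholds.

Coordinates are 0-based half-open in memory and 1-based inclusive in
every TSV report. Ambiguity codes other than N are mapped to N with a
warning.

## T6SS typing

Detection queries are *concatemers*: a locus with its variable
effector/immunity regions excised and conserved segments concatenated
(`build_concatemer`, invertible via the stored segment map). A genome is
called positive for an architecture when chained hits reach ≥95%
identity over ≥95% of the query. Chaining operates at two levels:
hits within 50 kb on one contig form a candidate site; residual partial
hits from different contigs are chained greedily (longest first,
non-overlapping in query coordinates) to rescue heavily fragmented
assemblies, and such calls are flagged `fragmented`. Chained identity is
the length-weighted mean over segments; chained coverage is capped at
100%. Multiple qualifying sites in one genome are all reported — a
strain can carry two different GA2 ICEs at different chromosomal sites.

GA2 subtype assignment maximizes global identity against the subtype
reference panel. The best subtype must beat the runner-up by ≥2
percentage points (the margin comfortably exceeds noise when
within-subtype identity is >97% and cross-subtype identity is 80–89%);
closer calls are flagged `ambiguous`, calls below 80% to every reference
`unclassified` (candidate new subtype), and GA2e calls below 90%
identity `provisional`, since that subtype is internally more diverse.

## Transfer, spread and fixation

Within one community (one subject's isolates), copies of an element are
compared over their **complete locus span** — variable regions included,
from the first to the last chained segment. IS elements are removed
before comparison when an IS library is supplied (matches at ≥90%
identity are excised), because insertion sequences hop in and out of
these ICEs on timescales shorter than the transfers being inferred.
Copies are grouped by single linkage at pairwise identity **strictly
above 99.99%**; gap columns count as differences, which resolves the
denominator ambiguity of "99.99% identical" in the presence of indels.
The species count of the best group gives the call: ≥3 species =
multi-species spread, exactly 2 = single-species spread, one carrier =
no transfer.

One practical convention: extracted spans carry a base or two of
boundary jitter (a local hit can begin or end a few bases off the true
element boundary when flanking bases match by chance), and at strict
thresholds on elements of a few tens of kilobases a single spurious
terminal column would flip a call. Up to 10 terminal non-match columns
per alignment end are therefore excluded from the identity denominator;
internal differences are never trimmed.

Fixation is assessed per strain: `complete` when every isolate of the
strain carries the element, `partial` otherwise, `not_assessable` for
single-isolate strains; same-species strain pairs differing in carriage
(one fixed, one free) are flagged. Strain labels come from metadata, or,
when absent, same-species genomes at ≥99.9% genome-wide identity are
grouped as a strain ("near-isogenic"); the threshold is configurable.

## Integration sites

`find_direct_repeats` searches for the longest direct repeat whose left
copy ends, and right copy begins, within 2 bp of the element junctions
(configurable; real assemblies blur junctions), allowing ≤1 mismatch
between the copies. Mismatches must be internal — the first and last
positions of the copies must match exactly. This is the usual
maximal-repeat convention, and it is load-bearing: with a junction
tolerance, *any* L-bp repeat extends to L+1 bp by spending a mismatch on
the boundary, so boundary mismatches cannot be allowed to compete with
length. Ties break longest → fewest mismatches → closest to the
junctions. The search window (200 bp per side) merely bounds runtime;
known Bacteroidales motifs are 7–24 bp.

`map_insertion_by_comparison` anchors an isogenic occupied/empty genome
pair by exact longest common prefix and suffix. For a clean insertion
the prefix covers flank+motif and the suffix motif+flank, so
`lcp + lcs − len(empty)` **is** the duplicated motif length — this
simultaneously verifies that the duplication spans exactly the motif
(flanks outside it align 1:1). The construction requires conserved
sequence immediately around the junctions, which holds for the
near-isogenic comparisons the operation is defined for; divergence far
from the junction is irrelevant. When the "empty" genome carries a
different cargo at the same site, boundaries are instead resolved at the
shared direct repeat, searched with a widened (40 bp) junction
tolerance because the exact anchors can stop short of the junction.

Excision removes the element plus one repeat copy; the **left** copy is
retained (fixed convention — attB biology does not distinguish the
copies). Excision after a mismatch-free plant restores the
pre-insertion genome byte-exactly.

`merge_recognition_patterns` reconciles two overlapping recognition
sequences (exact overlap ≥10 nt required) into one degenerate pattern:
the overlap becomes the uppercase core, single-covered positions become
lowercase soft positions with a 1-mismatch budget. The merged length is
|a| + |b| − overlap by construction. This represents, rather than
resolves, the published discrepancy between the 20-bp observed repeat
and the 18-bp previously reported recognition sequence of the
tRNA-Lys-targeting integrase.

Tandem duplications (e.g. a 445-bp internal duplication inside a sheath
gene) are detected without trusting gap placement: aligners distribute
the gap of a tandem repeat across co-optimal positions, so the shorter
region is anchored chunk-wise (150-mers) in the longer and the offset
jump brackets the event; the longer region is then scanned directly for
a span equal to its immediate successor (≤5% mismatches).

## MGE spread scanning

A spreading MGE is a segment ≥4 kb shared at ≥99.99% identity by
isolates of ≥3 species in one community. "99.99% on an alignment of
length L" uses an integral rule: allowed differences =
⌊L · (1 − 0.9999)⌋ — zero differences at 4 kb, one at 10,001 bp.
The stages mirror a practitioner's BLAST/cd-hit/assembly-join workflow
but are reimplemented so the pipeline is dependency-free and testable:

1. **shared_segments** — all-vs-all local alignment inside the
   community; candidates kept only if found (≥99% of their length, at
   threshold identity) in isolates of ≥3 species. Segments >50%
   covered by a supplied IS library are excluded as transposase noise.
2. **dedupe_segments** — greedy longest-first clustering at 0.99
   identity (identical bases over the shorter sequence), cd-hit-est
   semantics.
3. **join_segments** — suffix–prefix overlap joining (≥4 kb overlap at
   threshold identity), anchored on an exact 32-mer from the start of
   the downstream fragment and verified over the full overlap; forward
   orientation only (the synthetic fragmenter emits forward fragments).
   Overlap graphs with branching keep the branch nodes unjoined and
   flagged; cycles are reported separately as candidate circular
   elements.
4. **reverify** — joined sequences are searched back against the
   community and kept only if full-length in ≥3 species; this is what
   kills join chimeras.
5. **cluster_elements** — across communities, greedy longest-first
   clustering under the 80/80 rule: the smaller element aligned within
   the larger at ≥80% identity with the aligned span covering ≥80% of
   the larger. Clusters sort by the number of communities with spread.

The scan is invariant to genome input order (candidates are
canonicalized and sorted at every stage).

## Disruption calls and the exact test

`detect_disruption` compares an observed gene copy to an intact
reference ORF (validated: length divisible by 3, no internal stops).
The lesion is located by exact longest-common-prefix arithmetic rather
than an aligner's gap placement, which is ambiguous whenever an indel
borders a repeated base; the leftmost-divergence offset `o` gives the
reported codon `o // 3 + 1` (1-based). Net indel sizes not divisible by
3 are frameshifts; insertions matching the IS library at ≥90% are IS
insertions; insertions ≥50% of the gene are cargo replacements; copies
covering <80% of the reference are truncations (the 80% bound is a
package choice; "truncated" has no published number).

`fisher_exact` is written from first principles: the conditional
distribution of the top-left cell under fixed margins is computed via
log-gamma, and the two-sided p-value follows the minimum-likelihood
convention of mainstream statistical software (sum of all tables whose
point probability is ≤ the observed one, with a 1e-7 relative
tolerance); one-sided alternatives are exposed. The implementation is
pinned in tests against both a brute-force enumeration oracle and an
independent reference implementation. Co-occurrence tabulation counts
distinct GA-label combinations per genome, with optional
once-per-clonal-group counting for nearly clonal strains.

## The synthetic-data generator

The generator emulates the observational regimes the thresholds are
specified against: species backbones descending from a common ancestor
at 5–20% substitution divergence (drawn uniformly unless fixed),
near-isogenic strains (10 substitutions between strains, 2 between
isolates of a strain by default), ICEs inserted after a recognition
pattern occurrence with the matched sequence duplicated at the distal
junction, partial-fixation plants, IS insertions and frameshift
lesions, and subtype panels at >97% within / 80–89% cross-subtype
identity. All randomness flows from one seed; outputs are byte-exactly
reproducible, and every planted element is re-locatable by exact search
(audited).

Two generator details matter for exactness. Backbone and isolate
mutation is substitutions-only; indels enter only through explicit
plants, which keeps identity accounting exact. And junctions are
*repaired*: background bases that would extend a planted duplication by
chance (or create a chance repeat at an unduplicated plant) are
resampled, and the guard mutates the background — never the cargo — so
planted copies stay byte-identical across genomes. The plant record
carries the post-repair pre-insertion sequence, making
plant → excise round-trips byte-exact.

What the generator does **not** emulate: real gene content and codon
usage, rearrangements, assembly error, contamination, or within-element
recombination. Passing tests therefore demonstrate the inference logic
under the stated identity regimes, not robustness to assembly artifacts
beyond the boundary-jitter and fragmentation cases explicitly modeled.
Backbone length defaults to 100 kb; real Bacteroidales genomes run to
~5 Mb, but every statistic computed here depends on relative identity
and planted structure, not absolute genome size, so backbone length is
a runtime knob. Tests use 12–40 kb backbones and elements of 4–30 kb
for the same reason; where a criterion needs a given number of
tolerated differences (e.g. one mismatch among shared copies above
99.99%), element lengths are chosen so the arithmetic matches the
regime being emulated (a 1-mismatch pair must span >20 kb to sit above
99.99%).

## Known limitations

- `map_insertion_by_comparison` needs junction-proximal flank
  conservation; heavily diverged pairs raise "no syntenic anchor".
- Overlap joining considers forward-orientation overlaps only.
- The spread classifier compares whole locus spans; it does not model
  partial transfers or within-element recombination.
- The disruption caller assumes at most one indel event per gene copy
  (plus substitutions); multiple independent indels report the first.
- The 2-point subtype ambiguity margin and the 10-column terminal
  trimming cap are package conventions, chosen once and documented
  here, not fitted quantities.
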