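"""Seeded generator of synthetic communities, ICEs and lesions.

Every pipeline stage is testable without downloads: the generator
emits genome FASTA, a metadata table and a full planted-truth manifest
(element coordinates, repeats, expected spread classifications).

The mutation model is substitutions-only for backbones and isolates;
indels enter only through explicit ICE/IS/lesion plants, which keeps
identity accounting exact. Backgrounds are uniform over {A,C,G,T} with
repair sampling near junctions so that a planted target-site
duplication is never extendable by chance and an unduplicated plant
never acquires a chance repeat.

Scale defaults: species backbones default to 100 kb (real Bacteroidales
genomes run to ~5 Mb; every statistic computed here depends on relative
identity and planted structure, not absolute genome size, so the
backbone length is a runtime knob, not a condition). Species diverge at
5-20% from a common ancestor, near-isogenic isolates of a strain differ
by a handful of substitutions, GA2 subtype panels sit at >97% within-
and ~80-89% cross-subtype identity — the regimes the pipeline's
thresholds are specified against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .integration_sites import DirectRepeat, find_direct_repeats
from .io import Genome
from .sequence_core import DegeneratePattern, match_pattern

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_ALPHABET = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate_substitutions(
    seq: str, n_subs: int, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Apply exactly ``n_subs`` substitutions at distinct positions."""
    if n_subs == 0:
        return seq, []
    n_subs = min(n_subs, len(seq))
    positions = sorted(rng.choice(len(seq), size=n_subs, replace=False).tolist())
    arr = list(seq)
    for p in positions:
        choices = [b for b in _ALPHABET if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr), positions


def mutate_rate(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Substitute each position independently with probability ``rate``."""
    n = rng.binomial(len(seq), rate)
    return mutate_substitutions(seq, int(n), rng)


def _pattern_instance(pattern: DegeneratePattern, rng: np.random.Generator) -> str:
    out = []
    for c in pattern.consensus:
        if c in "Nn":
            out.append(_ALPHABET[rng.integers(4)])
        else:
            out.append(c.upper())
    return "".join(out)


def _different_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in _ALPHABET if b != base]
    return choices[rng.integers(3)]


@dataclass
class IcePlantRecord:
    """Planted-truth record for one ICE insertion."""

    element_label: str
    element_interval: tuple[int, int]
    element_sequence: str
    attB_sequence: str  # the matched pattern occurrence (single pre-insertion copy)
    repeat: DirectRepeat | None
    with_duplication: bool
    pattern_inserted: bool  # True if the generator had to create the att site
    #: the genome as it stood before insertion (junction repairs applied);
    #: excising the element restores exactly this sequence
    pre_insertion_sequence: str = ""


def plant_ice(
    genome_seq: str,
    ice_seq: str,
    recognition_pattern: DegeneratePattern | str,
    rng: np.random.Generator,
    with_duplication: bool = True,
    site_index: int | None = None,
    max_repair: int = 60,
) -> tuple[str, IcePlantRecord]:
    """Insert an ICE immediately after a recognition-pattern occurrence,
    duplicating the matched sequence at the distal junction.

    The resulting junctions are screened: a base adjacent to a junction
    that would extend the duplication by chance (or create a chance
    repeat when ``with_duplication`` is off) is repaired to a different
    base, so downstream repeat discovery sees exactly the planted motif.
    """
    if isinstance(recognition_pattern, str):
        recognition_pattern = DegeneratePattern(recognition_pattern)
    seq = genome_seq
    fwd = [m for m in match_pattern(seq, recognition_pattern) if m.strand == "+"]
    pattern_inserted = False
    if not fwd:
        inst = _pattern_instance(recognition_pattern, rng)
        pos = int(rng.integers(len(seq) // 4, 3 * len(seq) // 4))
        seq = seq[:pos] + inst + seq[pos:]
        pattern_inserted = True
        fwd = [m for m in match_pattern(seq, recognition_pattern) if m.strand == "+"]
        assert fwd
    if site_index is None:
        site_index = int(rng.integers(len(fwd)))
    site = fwd[site_index % len(fwd)]
    L = len(recognition_pattern)
    i = site.position
    att = seq[i : i + L]
    ice_s = ice_seq
    # junction guards: the background bases adjacent to the att site must
    # not extend the repeat copies by chance. The background (not the ICE)
    # is adjusted so that planted copies stay byte-identical across genomes.
    if i + L < len(seq) and seq[i + L] == ice_s[0]:
        seq = seq[: i + L] + _different_base(seq[i + L], rng) + seq[i + L + 1 :]
    if i > 0 and seq[i - 1] == ice_s[-1]:
        seq = seq[: i - 1] + _different_base(seq[i - 1], rng) + seq[i:]
    dup = att if with_duplication else ""
    new = seq[: i + L] + ice_s + dup + seq[i + L :]
    elem = (i + L, i + L + len(ice_s))
    new = _repair_junctions(new, elem, L if with_duplication else 0, rng, max_repair)
    repeat = None
    if with_duplication:
        repeat = DirectRepeat((i, i + L), (elem[1], elem[1] + L), new[i : i + L], 0)
    dup_len = L if with_duplication else 0
    pre_insertion = new[: i + L] + new[elem[1] + dup_len :]
    return new, IcePlantRecord(
        element_label="",
        element_interval=elem,
        element_sequence=new[elem[0] : elem[1]],
        attB_sequence=att,
        repeat=repeat,
        with_duplication=with_duplication,
        pattern_inserted=pattern_inserted,
        pre_insertion_sequence=pre_insertion,
    )


def _repair_junctions(
    seq: str,
    elem: tuple[int, int],
    planted_len: int,
    rng: np.random.Generator,
    max_repair: int,
) -> str:
    """Mutate background bases until repeat discovery returns exactly the
    planted motif (or nothing when no duplication was planted)."""
    for _ in range(max_repair):
        found = find_direct_repeats(seq, elem)
        if planted_len == 0:
            if found is None:
                return seq
        elif (
            found is not None
            and found.length == planted_len
            and found.mismatch_count == 0
            and found.left_interval == (elem[0] - planted_len, elem[0])
            and found.right_interval == (elem[1], elem[1] + planted_len)
        ):
            return seq
        # pick a background base implicated in the spurious/extended repeat
        assert found is not None
        if planted_len and found.right_interval[1] > elem[1] + planted_len:
            pos = found.right_interval[1] - 1  # extension beyond the planted copy
        elif planted_len and found.left_interval[0] < elem[0] - planted_len:
            pos = found.left_interval[0]
        elif planted_len == 0:
            pos = min(found.right_interval[1] - 1, len(seq) - 1)
        else:
            # same length but shifted copies: perturb the offending right copy end
            pos = found.right_interval[1] - 1
        if elem[0] - planted_len <= pos < elem[1] + planted_len:
            pos = elem[1] + planted_len  # never touch element or planted copies
            if pos >= len(seq):
                pos = elem[0] - planted_len - 1
        arr = list(seq)
        arr[pos] = _different_base(arr[pos], rng)
        seq = "".join(arr)
    raise RuntimeError("junction repair did not converge")


@dataclass
class LesionRecord:
    gene_id: str
    kind: str  # frameshift | is_insertion | truncation
    indel_size: int
    codon_index: int | None
    codon_length: int


def plant_frameshift(
    gene_seq: str,
    indel_size: int,
    codon_index: int,
    rng: np.random.Generator,
    insertion: bool | None = None,
    gene_id: str = "",
) -> tuple[str, LesionRecord]:
    """Plant an indel of ``indel_size`` nt whose first affected base lies in
    1-based ``codon_index``; sizes not divisible by 3 shift the frame."""
    if insertion is None:
        insertion = bool(rng.integers(2))
    offset = (codon_index - 1) * 3 + int(rng.integers(3))
    if insertion:
        ins = random_sequence(rng, indel_size)
        new = gene_seq[:offset] + ins + gene_seq[offset:]
    else:
        new = gene_seq[:offset] + gene_seq[offset + indel_size :]
    kind = "frameshift" if indel_size % 3 else "inframe_indel"
    return new, LesionRecord(gene_id, kind, indel_size, codon_index, len(gene_seq) // 3)


def plant_is_insertion(
    seq: str,
    is_seq: str,
    rng: np.random.Generator,
    pos: int | None = None,
    gene_id: str = "",
) -> tuple[str, LesionRecord]:
    if pos is None:
        pos = int(rng.integers(1, len(seq)))
    new = seq[:pos] + is_seq + seq[pos:]
    return new, LesionRecord(
        gene_id, "is_insertion", len(is_seq), pos // 3 + 1, len(seq) // 3
    )


# ---------------------------------------------------------------------------
# community simulation
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    label: str
    divergence: float | None = None  # from common ancestor; None -> drawn U(0.05, 0.20)
    n_strains: int = 1
    isolates_per_strain: int = 1
    strain_snvs: int = 10  # substitutions separating strains of a species
    isolate_snvs: int = 2  # substitutions separating isolates of a strain


@dataclass
class IcePlantSpec:
    element_label: str
    recognition_pattern: str
    carrier_species: tuple[str, ...]
    cargo_length: int = 8000
    per_copy_mutations: int = 0
    with_duplication: bool = True
    carrier_fraction: float = 1.0  # fraction of isolates per carrier strain
    #: explicit cargo; lets the same element recur across communities
    cargo_sequence: str | None = None


@dataclass
class SimulationConfig:
    seed: int
    community_id: str = "C1"
    species: Sequence[SpeciesSpec] = ()
    genome_length: int = 100_000
    ice_plants: Sequence[IcePlantSpec] = ()

    def __post_init__(self) -> None:
        if not self.species:
            self.species = tuple(
                SpeciesSpec(label=f"sp{i+1}") for i in range(5)
            )


@dataclass
class TruthManifest:
    """Planted ground truth for one simulated community."""

    community_id: str
    genomes: dict[str, dict] = field(default_factory=dict)
    expected_spread: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _ser(v):
            if isinstance(v, IcePlantRecord):
                return {
                    "element_label": v.element_label,
                    "element_interval": list(v.element_interval),
                    "element_sequence": v.element_sequence,
                    "attB_sequence": v.attB_sequence,
                    "with_duplication": v.with_duplication,
                }
            if isinstance(v, LesionRecord):
                return vars(v)
            return v

        return {
            "community_id": self.community_id,
            "genomes": {
                g: {
                    "species": info["species"],
                    "strain": info["strain"],
                    "elements": [_ser(e) for e in info["elements"]],
                    "lesions": [_ser(l) for l in info["lesions"]],
                }
                for g, info in self.genomes.items()
            },
            "expected_spread": self.expected_spread,
        }


def _expected_classification(n_species: int) -> str:
    if n_species >= 3:
        return "multi_species_spread"
    if n_species == 2:
        return "single_species_spread"
    if n_species == 1:
        return "no_transfer"
    return "absent"


def make_community(
    config: SimulationConfig,
) -> tuple[list[Genome], pd.DataFrame, TruthManifest]:
    """Simulate one community of isolate genomes with planted ICEs.

    Species backbones descend from a common ancestor by substitution at
    the configured divergence; strains within a species differ by a few
    substitutions and isolates within a strain by fewer still. Each ICE
    spec plants one cargo sequence (identical across carriers up to
    ``per_copy_mutations``) after a recognition-pattern occurrence in
    every carrier isolate. Fully deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    ancestor = random_sequence(rng, config.genome_length)
    cargo = {
        sp.element_label: sp.cargo_sequence
        if sp.cargo_sequence is not None
        else random_sequence(rng, sp.cargo_length)
        for sp in config.ice_plants
    }
    manifest = TruthManifest(config.community_id)
    genomes: list[Genome] = []
    rows = []
    for spec in config.species:
        div = (
            spec.divergence
            if spec.divergence is not None
            else float(rng.uniform(0.05, 0.20))
        )
        if div == 0:
            import warnings

            warnings.warn(f"species {spec.label} at zero divergence from ancestor")
        backbone, _ = mutate_rate(ancestor, div, rng)
        for st in range(spec.n_strains):
            strain_label = f"{spec.label}_st{st+1}"
            strain_seq, _ = mutate_substitutions(backbone, spec.strain_snvs, rng)
            for iso in range(spec.isolates_per_strain):
                gid = f"{config.community_id}_{strain_label}_i{iso+1}"
                seq, _ = mutate_substitutions(strain_seq, spec.isolate_snvs, rng)
                elements: list[IcePlantRecord] = []
                for ice in config.ice_plants:
                    if spec.label not in ice.carrier_species:
                        continue
                    if iso >= max(
                        1, round(ice.carrier_fraction * spec.isolates_per_strain)
                    ):
                        continue
                    copy = cargo[ice.element_label]
                    if ice.per_copy_mutations:
                        copy, _ = mutate_substitutions(
                            copy, ice.per_copy_mutations, rng
                        )
                    seq, rec = plant_ice(
                        seq,
                        copy,
                        ice.recognition_pattern,
                        rng,
                        with_duplication=ice.with_duplication,
                        site_index=0,
                    )
                    rec.element_label = ice.element_label
                    elements.append(rec)
                genomes.append(
                    Genome(
                        genome_id=gid,
                        contigs={f"{gid}_c1": seq},
                        species=spec.label,
                        community=config.community_id,
                        strain=strain_label,
                    )
                )
                rows.append(
                    {
                        "genome_id": gid,
                        "species": spec.label,
                        "community": config.community_id,
                        "strain": strain_label,
                    }
                )
                manifest.genomes[gid] = {
                    "species": spec.label,
                    "strain": strain_label,
                    "elements": elements,
                    "lesions": [],
                }
    for ice in config.ice_plants:
        carriers = {
            info["species"]
            for info in manifest.genomes.values()
            if any(e.element_label == ice.element_label for e in info["elements"])
        }
        manifest.expected_spread[ice.element_label] = _expected_classification(
            len(carriers)
        )
    meta = pd.DataFrame(rows, columns=["genome_id", "species", "community", "strain"])
    return genomes, meta, manifest


def audit_manifest(genomes: list[Genome], manifest: TruthManifest) -> bool:
    """Every planted element must be re-locatable by exact search at its
    recorded coordinates in the emitted sequence."""
    by_id = {g.genome_id: g for g in genomes}
    for gid, info in manifest.genomes.items():
        seq = by_id[gid].sequence()
        for rec in info["elements"]:
            s, e = rec.element_interval
            if seq[s:e] != rec.element_sequence:
                return False
            if seq.find(rec.element_sequence) < 0:
                return False
    return True


# ---------------------------------------------------------------------------
# subtype reference panels
# ---------------------------------------------------------------------------

def make_subtype_panel(
    rng: np.random.Generator,
    n_subtypes: int = 5,
    length: int = 5000,
    within_divergence: float = 0.01,
    cross_branch_range: tuple[float, float] = (0.06, 0.10),
    n_test_regions: int = 2,
    labels: Sequence[str] | None = None,
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Emit subtype reference sequences plus labelled test regions.

    References descend independently from one ancestor at per-branch
    divergences drawn from ``cross_branch_range``, which puts pairwise
    cross-subtype identity in the low-80s to high-80s; test regions
    diverge from their reference by ``within_divergence`` (<3%), the
    regime where subtype assignment must be unambiguous.
    """
    if labels is None:
        labels = [f"GA2{c}" for c in "abcde"[:n_subtypes]]
    ancestor = random_sequence(rng, length)
    refs: dict[str, str] = {}
    for lab in labels[:n_subtypes]:
        d = float(rng.uniform(*cross_branch_range))
        refs[lab], _ = mutate_rate(ancestor, d, rng)
    tests: list[tuple[str, str]] = []
    for lab in refs:
        for _ in range(n_test_regions):
            region, _ = mutate_rate(refs[lab], within_divergence, rng)
            tests.append((lab, region))
    return refs, tests
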