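"""Pipeline orchestration: screen -> subtype -> spread -> integrate -> mge-scan.

All tabular outputs are TSV with headers (1-based inclusive
coordinates); nested reports are JSON. Every effective threshold is
logged at startup so a run is reproducible from its log alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import integration_sites, mge_spread, t6ss_typing, transfer_detection
from .io import hits_to_table, load_genomes, read_fasta, read_metadata

log = logging.getLogger("icespread")


@dataclass
class RunConfig:
    genomes_dir: str
    metadata: str
    queries: str | None = None  # FASTA of concatemer queries, ids = GA labels
    out_dir: str = "icespread_out"
    seed: int = 0
    min_identity_pct: float = 95.0
    min_coverage_pct: float = 95.0
    spread_identity_pct: float = 99.99
    mge_min_length: int = 4000
    subtype_margin: float = 2.0
    flank: int = 10_000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("min_identity_pct", 50, 100),
            ("min_coverage_pct", 1, 100),
            ("spread_identity_pct", 90, 100),
            ("subtype_margin", 0, 50),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside allowed range [{lo}, {hi}]")
        if self.mge_min_length < 100:
            raise ValueError("mge_min_length must be >= 100")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _queries_from_fasta(path: str) -> list[t6ss_typing.ConcatemerQuery]:
    seqs = read_fasta(path)
    return [
        t6ss_typing.ConcatemerQuery(
            ga_label=name, sequence=seq,
            segment_map=(((0, len(seq)), (0, len(seq))),),
        )
        for name, seq in seqs.items()
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on one dataset; returns the report bundle
    (also written under ``config.out_dir``)."""
    logging.basicConfig(level=config.log_level)
    log.info("effective thresholds: %s", vars(config))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = read_metadata(config.metadata)
    genomes = load_genomes(config.genomes_dir, meta)
    queries = _queries_from_fasta(config.queries) if config.queries else []

    # screen + subtype
    all_hits: list[t6ss_typing.LocusHit] = []
    ga2_refs = {q.ga_label: q for q in queries if q.ga_label.startswith("GA2")}
    for g in genomes:
        hits = (
            t6ss_typing.screen_genome(
                g, queries, config.min_identity_pct, config.min_coverage_pct
            )
            if queries
            else []
        )
        for h in hits:
            if h.ga_label.startswith("GA2") and len(ga2_refs) > 1:
                contig, s, e, _ = h.primary_segment
                call = t6ss_typing.assign_subtype(
                    g.contigs[contig][s:e], ga2_refs,
                    ambiguity_margin=config.subtype_margin,
                )
                h.subtype = call.subtype
        all_hits.extend(hits)
    hits_df = hits_to_table(all_hits)
    hits_df.to_csv(out / "hits.tsv", sep="\t", index=False)

    # spread per community
    spread_rows = []
    fixation: dict[str, dict] = {}
    for cid, group in meta.groupby("community"):
        members = [g for g in genomes if g.community == cid]
        community = transfer_detection.CommunityDataset(cid, members)
        chits = [h for h in all_hits if h.genome_id in set(group.genome_id)]
        labels = sorted({q.ga_label for q in queries}) or sorted(
            {h.ga_label for h in chits}
        )
        calls = transfer_detection.classify_spread(
            community, chits, config.spread_identity_pct, element_labels=labels
        )
        for call in calls:
            spread_rows.append(
                {
                    "community": call.community_id,
                    "element": call.element_label,
                    "n_species_shared": call.n_species_shared,
                    "classification": call.classification,
                    "min_pairwise_identity": call.min_pairwise_identity_pct,
                }
            )
        for label in labels:
            rep = transfer_detection.assess_fixation(community, label, chits)
            fixation.setdefault(cid, {})[label] = rep.per_strain
    pd.DataFrame(
        spread_rows,
        columns=[
            "community", "element", "n_species_shared", "classification",
            "min_pairwise_identity",
        ],
    ).to_csv(out / "spread.tsv", sep="\t", index=False)
    (out / "fixation.json").write_text(json.dumps(fixation, indent=1))

    # integration sites on detected loci
    integ_rows = []
    by_id = {g.genome_id: g for g in genomes}
    for h in all_hits:
        contig = h.primary_segment[0]
        spans = [(s, e) for c, s, e, _ in h.segments if c == contig]
        s = min(x for x, _ in spans)
        e = max(x for _, x in spans)
        rep = integration_sites.find_direct_repeats(
            by_id[h.genome_id].contigs[contig], (s, e)
        )
        integ_rows.append(
            {
                "genome_id": h.genome_id,
                "element": h.ga_label,
                "contig": contig,
                "start": s + 1,
                "end": e,
                "repeat_length": rep.length if rep else 0,
                "repeat_sequence": rep.repeat_sequence if rep else "",
                "repeat_mismatches": rep.mismatch_count if rep else "",
            }
        )
    pd.DataFrame(
        integ_rows,
        columns=[
            "genome_id", "element", "contig", "start", "end",
            "repeat_length", "repeat_sequence", "repeat_mismatches",
        ],
    ).to_csv(out / "integration.tsv", sep="\t", index=False)

    # MGE scan per community + cross-community clustering
    elements: list[mge_spread.MGEElement] = []
    for cid, group in meta.groupby("community"):
        members = [g for g in genomes if g.community == cid]
        if len(members) < 2:
            continue
        community = transfer_detection.CommunityDataset(cid, members)
        elements.extend(
            mge_spread.scan_community(
                community,
                min_identity_pct=config.spread_identity_pct,
                min_length=config.mge_min_length,
            )
        )
    clusters = mge_spread.cluster_elements(elements)
    cluster_rows = [
        {
            "cluster_id": c.cluster_id,
            "representative_length": c.representative.length,
            "n_occurrences": sum(len(m.occurrences) for m in c.members),
            "communities_with_spread": ",".join(c.communities_with_spread),
            "n_species": max(m.n_species for m in c.members),
        }
        for c in clusters
    ]
    pd.DataFrame(
        cluster_rows,
        columns=[
            "cluster_id", "representative_length", "n_occurrences",
            "communities_with_spread", "n_species",
        ],
    ).to_csv(out / "mge_clusters.tsv", sep="\t", index=False)

    report = {
        "n_genomes": len(genomes),
        "n_hits": len(all_hits),
        "n_mge_elements": len(elements),
        "n_mge_clusters": len(clusters),
    }
    (out / "summary.json").write_text(json.dumps(report, indent=1))
    return {
        "hits": hits_df,
        "spread": spread_rows,
        "fixation": fixation,
        "mge_clusters": cluster_rows,
        "summary": report,
    }
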