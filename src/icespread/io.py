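"""File formats and core containers: genomes, metadata tables, GFF3 features.

Tabular outputs are TSV with headers; coordinates in human-readable
reports are 1-based inclusive, while everything in memory is 0-based
half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence_core import canonicalize

REQUIRED_METADATA_COLUMNS = ("genome_id", "species", "community")


class MetadataError(ValueError):
    """Raised when the metadata table is missing required columns."""


@dataclass
class Genome:
    """One isolate assembly: named contigs plus community/species/strain labels."""

    genome_id: str
    contigs: dict[str, str]
    species: str | None = None
    community: str | None = None
    strain: str | None = None

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs.values())

    def sequence(self) -> str:
        """Contigs concatenated in insertion order (single-contig genomes
        round-trip unchanged)."""
        return "".join(self.contigs.values())


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} dict."""
    recs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        recs[rec.id] = canonicalize(str(rec.seq))
    return recs


def write_fasta(path: str | os.PathLike, seqs: dict[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read the genome metadata TSV (genome_id, species, community[, strain])."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MetadataError(f"cannot parse metadata table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(
            f"metadata table {path} missing required column(s): {', '.join(missing)}"
        )
    if "strain" not in df.columns:
        df["strain"] = pd.NA
    return df


def load_genomes(
    genomes_dir: str | os.PathLike, metadata: pd.DataFrame
) -> list[Genome]:
    """Load one FASTA per metadata row (``<genome_id>.fasta`` or ``.fa``)."""
    genomes = []
    gdir = Path(genomes_dir)
    for row in metadata.itertuples():
        for ext in (".fasta", ".fa", ".fna"):
            p = gdir / f"{row.genome_id}{ext}"
            if p.exists():
                break
        else:
            raise FileNotFoundError(f"no FASTA found for genome {row.genome_id} in {gdir}")
        genomes.append(
            Genome(
                genome_id=row.genome_id,
                contigs=read_fasta(p),
                species=row.species,
                community=row.community,
                strain=None if pd.isna(row.strain) else row.strain,
            )
        )
    return genomes


@dataclass(frozen=True)
class Feature:
    """A minimal genomic feature lifted from GFF3 (0-based half-open)."""

    feature_id: str
    ftype: str
    contig: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)


def read_gff3_features(path: str | os.PathLike) -> list[Feature]:
    """Read GFF3 features via gffutils (in-memory database)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for f in db.all_features():
        attrs = {k: ";".join(v) for k, v in f.attributes.items()}
        feats.append(
            Feature(
                feature_id=f.id,
                ftype=f.featuretype,
                contig=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand or ".",
                attributes=attrs,
            )
        )
    return feats


def hits_to_table(hits: Iterable) -> pd.DataFrame:
    """LocusHit list -> report table (1-based inclusive coordinates)."""
    rows = []
    for h in hits:
        for contig, start, end, strand in h.segments:
            rows.append(
                {
                    "genome_id": h.genome_id,
                    "ga_label": h.ga_label,
                    "subtype": h.subtype or "",
                    "contig": contig,
                    "start": start + 1,
                    "end": end,
                    "strand": strand,
                    "identity": round(h.identity_pct, 4),
                    "coverage": round(h.query_coverage_pct, 4),
                    "fragmented": h.fragmented,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "ga_label",
            "subtype",
            "contig",
            "start",
            "end",
            "strand",
            "identity",
            "coverage",
            "fragmented",
        ],
    )
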