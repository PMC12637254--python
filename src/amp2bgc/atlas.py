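"""Build the phylogeny-informed reference atlas from genome-level inputs.

The atlas links each unique 16S rRNA sequence to the BGC class profiles of
all quality-filtered genomes that carry exactly that sequence.  The pipeline
is: filter genomes on CheckM completeness/contamination, pick one marker
sequence per genome (longest clean 16S within 250-2000 nt), count antiSMASH
regions into the eight classes, collapse identical markers (dereplication),
and pre-compute the four aggregation strategies per entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from amp2bgc.errors import DataError
from amp2bgc.io import format_float, write_fasta
from amp2bgc.profiles import (
    AGGREGATION_STRATEGIES,
    BGC_CLASSES,
    BGCProfile,
    aggregate_profiles,
    map_bgc_classes,
)

logger = logging.getLogger(__name__)

ASSEMBLY_LEVELS = ("complete", "chromosome", "scaffold", "contig")

MIN_MARKER_LEN = 250
MAX_MARKER_LEN = 2000
_DNA = frozenset("ATCG")


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    completeness: float
    contamination: float
    assembly_level: str = "contig"
    lineage: tuple[str, ...] = ()


@dataclass(frozen=True)
class RegionAnnotation:
    genome_id: str
    region_id: str
    products: tuple[str, ...]


@dataclass(frozen=True)
class MarkerSequence:
    genome_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AtlasEntry:
    """One unique marker sequence with its member genomes and their profiles."""

    sequence_id: str
    sequence: str
    member_genomes: list[str]
    member_profiles: list[BGCProfile]
    aggregated: dict[str, BGCProfile] = field(default_factory=dict)

    @property
    def multiplicity(self) -> int:
        return len(self.member_genomes)

    def finalize(self) -> None:
        for strategy in AGGREGATION_STRATEGIES:
            self.aggregated[strategy] = aggregate_profiles(self.member_profiles, strategy)


@dataclass
class ReferenceAtlas:
    entries: list[AtlasEntry]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seqs = [e.sequence for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise DataError("atlas entries must have unique sequences")

    def by_id(self, sequence_id: str) -> AtlasEntry:
        for e in self.entries:
            if e.sequence_id == sequence_id:
                return e
        raise KeyError(sequence_id)

    @property
    def n_genomes(self) -> int:
        return sum(e.multiplicity for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def filter_genomes(
    records: Sequence[GenomeMetadata],
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
) -> list[GenomeMetadata]:
    """Keep genomes with completeness >= min and contamination <= max (bounds inclusive)."""
    for thr in (min_completeness, max_contamination):
        if not (0.0 <= float(thr) <= 100.0):
            raise DataError(f"threshold {thr} outside [0, 100]")
    kept: list[GenomeMetadata] = []
    for rec in records:
        try:
            comp, cont = float(rec.completeness), float(rec.contamination)
            if not (0.0 <= comp <= 100.0 and 0.0 <= cont <= 100.0):
                raise ValueError("percentage out of range")
        except (TypeError, ValueError) as exc:
            logger.warning("genome %s rejected: malformed quality values (%s)", rec.genome_id, exc)
            continue
        if comp >= min_completeness and cont <= max_contamination:
            kept.append(rec)
    return kept


def select_marker(candidates: Sequence[tuple[str, str]]) -> MarkerSequence | None:
    """Pick the longest clean 16S candidate (A/T/C/G only, 250-2000 nt) for one genome."""
    if not candidates:
        logger.debug("no 16S found")
        return None
    genome_ids = {gid for gid, _ in candidates}
    if len(genome_ids) != 1:
        raise DataError(f"marker candidates span multiple genomes: {sorted(genome_ids)}")
    best: tuple[int, str] | None = None
    for _, seq in candidates:
        seq = seq.strip().upper()
        if not seq or set(seq) - _DNA:
            continue
        if not (MIN_MARKER_LEN <= len(seq) <= MAX_MARKER_LEN):
            continue
        if best is None or len(seq) > best[0]:
            best = (len(seq), seq)
    if best is None:
        logger.debug("genome %s: no valid 16S candidate", next(iter(genome_ids)))
        return None
    return MarkerSequence(genome_id=next(iter(genome_ids)), sequence=best[1])


def dereplicate(markers: Sequence[MarkerSequence]) -> dict[str, list[str]]:
    """Group genome ids by exact full-length marker sequence equality."""
    groups: dict[str, list[str]] = {}
    for m in markers:
        groups.setdefault(m.sequence, []).append(m.genome_id)
    return groups


def atlas_from_profiles(
    seq_by_genome: Mapping[str, str],
    profile_by_genome: Mapping[str, BGCProfile],
    provenance: dict | None = None,
) -> ReferenceAtlas:
    """Assemble an atlas from per-genome (sequence, profile) pairs.

    Sequence ids are assigned as ``seq000001``... in order of first appearance,
    so the construction is deterministic for a fixed input order.
    """
    markers = [MarkerSequence(gid, seq) for gid, seq in seq_by_genome.items()]
    groups = dereplicate(markers)
    entries: list[AtlasEntry] = []
    for i, (seq, gids) in enumerate(groups.items()):
        entry = AtlasEntry(
            sequence_id=f"seq{i + 1:06d}",
            sequence=seq,
            member_genomes=list(gids),
            member_profiles=[profile_by_genome[g] for g in gids],
        )
        entry.finalize()
        entries.append(entry)
    if not entries:
        raise DataError("empty atlas: no genome passed all filters")
    return ReferenceAtlas(entries=entries, provenance=provenance or {})


def build_atlas(
    metadata: Sequence[GenomeMetadata],
    region_tables: Sequence[RegionAnnotation],
    marker_candidates: Sequence[tuple[str, str]],
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
    mapping: Mapping[str, str] | None = None,
) -> ReferenceAtlas:
    """Run the full atlas pipeline: filter -> select marker -> count classes -> dereplicate."""
    ids = [m.genome_id for m in metadata]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate genome_id in metadata")
    kept = filter_genomes(metadata, min_completeness, max_contamination)
    kept_ids = {m.genome_id for m in kept}
    dropped = len(metadata) - len(kept)
    if dropped:
        logger.info("%d genomes removed by quality filters", dropped)

    candidates_by_genome: dict[str, list[tuple[str, str]]] = {}
    for gid, seq in marker_candidates:
        candidates_by_genome.setdefault(gid, []).append((gid, seq))
    unknown = set(candidates_by_genome) - set(ids)
    if unknown:
        logger.warning("marker candidates reference unknown genomes, skipped: %s", sorted(unknown))

    regions_by_genome: dict[str, list[Sequence[str]]] = {gid: [] for gid in ids}
    for reg in region_tables:
        if reg.genome_id not in regions_by_genome:
            logger.warning("region %s references unknown genome %s, skipped", reg.region_id, reg.genome_id)
            continue
        regions_by_genome[reg.genome_id].append(reg.products)

    seq_by_genome: dict[str, str] = {}
    profile_by_genome: dict[str, BGCProfile] = {}
    for gid in ids:
        if gid not in kept_ids:
            continue
        marker = select_marker(candidates_by_genome.get(gid, []))
        if marker is None:
            logger.info("genome %s excluded: no valid 16S marker", gid)
            continue
        seq_by_genome[gid] = marker.sequence
        # zero-region genomes are retained as informative all-zero profiles
        profile_by_genome[gid] = map_bgc_classes(regions_by_genome[gid], mapping)

    provenance = {
        "min_completeness": min_completeness,
        "max_contamination": max_contamination,
        "n_input_genomes": len(metadata),
        "n_filtered_genomes": len(seq_by_genome),
    }
    return atlas_from_profiles(seq_by_genome, profile_by_genome, provenance)


# ---------------------------------------------------------------------------
# tabular I/O


def read_metadata_tsv(path: str | Path) -> list[GenomeMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "completeness", "contamination"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing metadata columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        lineage = tuple(str(row["lineage"]).split(";")) if "lineage" in df.columns and pd.notna(row.get("lineage")) else ()
        records.append(
            GenomeMetadata(
                genome_id=str(row["genome_id"]),
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                assembly_level=str(row.get("assembly_level", "contig")),
                lineage=lineage,
            )
        )
    return records


def read_regions_tsv(path: str | Path) -> list[RegionAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "region_id", "products"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing region columns {sorted(missing)}")
    return [
        RegionAnnotation(
            genome_id=str(row["genome_id"]),
            region_id=str(row["region_id"]),
            products=tuple(t for t in str(row["products"]).split(";") if t.strip()),
        )
        for _, row in df.iterrows()
    ]


def marker_candidates_from_fasta(records: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Map FASTA headers to genome ids.

    Header rule: the genome id is the header token up to the first ``|``;
    the suffix (e.g. ``GCF_000001|2``) distinguishes multiple 16S candidates
    of the same genome.
    """
    return [(rid.split("|", 1)[0], seq) for rid, seq in records]


def write_atlas(atlas: ReferenceAtlas, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write the atlas as <prefix>.tsv plus the representative sequences as <prefix>.fasta."""
    out_prefix = Path(out_prefix)
    rows = []
    for e in atlas.entries:
        row: dict[str, object] = {
            "sequence_id": e.sequence_id,
            "sequence": e.sequence,
            "n_genomes": e.multiplicity,
            "member_genome_ids": ";".join(e.member_genomes),
        }
        for strategy in AGGREGATION_STRATEGIES:
            for cls, val in zip(BGC_CLASSES, atlas_entry_strategy(e, strategy)):
                row[f"{strategy}_{cls}"] = format_float(val)
        for ci, cls in enumerate(BGC_CLASSES):
            row[f"member_{cls}"] = ";".join(format_float(p.counts[ci]) for p in e.member_profiles)
        rows.append(row)
    tsv_path = out_prefix.with_suffix(".tsv")
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    fasta_path = out_prefix.with_suffix(".fasta")
    write_fasta(fasta_path, [(e.sequence_id, e.sequence) for e in atlas.entries])
    return tsv_path, fasta_path


def atlas_entry_strategy(entry: AtlasEntry, strategy: str) -> tuple[float, ...]:
    if strategy not in entry.aggregated:
        entry.finalize()
    return entry.aggregated[strategy].counts


def read_atlas(tsv_path: str | Path) -> ReferenceAtlas:
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    entries = []
    for _, row in df.iterrows():
        member_ids = str(row["member_genome_ids"]).split(";")
        member_cols = [str(row[f"member_{cls}"]).split(";") for cls in BGC_CLASSES]
        n = len(member_ids)
        profiles = [
            BGCProfile.from_array([float(member_cols[c][m]) for c in range(len(BGC_CLASSES))])
            for m in range(n)
        ]
        entry = AtlasEntry(
            sequence_id=str(row["sequence_id"]),
            sequence=str(row["sequence"]),
            member_genomes=member_ids,
            member_profiles=profiles,
        )
        entry.aggregated = {
            strategy: BGCProfile.from_array(
                [float(row[f"{strategy}_{cls}"]) for cls in BGC_CLASSES]
            )
            for strategy in AGGREGATION_STRATEGIES
        }
        entries.append(entry)
    if not entries:
        raise DataError(f"{tsv_path}: empty atlas")
    return ReferenceAtlas(entries=entries)
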