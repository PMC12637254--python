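"""Identity search: the BLAST-style top-hit engine.

Queries are matched to atlas reference sequences with a local pairwise
aligner (match +1, mismatch -2; a gap of length L costs 5 + 2L, mirroring
BLASTn's default open/extend penalties).  Percent identity follows the BLAST
``pident`` convention: identical columns divided by alignment length.  A
shared-k-mer prefilter caps how many references are aligned per query;
precomputed BLAST outfmt-6 files are accepted as an alternative engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align

from amp2bgc.atlas import ReferenceAtlas
from amp2bgc.errors import DataError

logger = logging.getLogger(__name__)

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = 5  # charged once per gap, on top of the per-column extend cost
GAP_EXTEND = 2
DEFAULT_K = 11
DEFAULT_MAX_CANDIDATES = 50
DEFAULT_THRESHOLD = 80.0  # lowest identity tier evaluated; below it use the phylo engine

_DNA = frozenset("ATCG")


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    # biopython charges open on the first gap column: open+extend*(L-1);
    # -7/-2 therefore reproduces the 5+2L total used here.
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNER = make_aligner()


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    reference_id: str
    identity: float
    alignment_length: int
    score: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise DataError(f"identity {self.identity} outside [0, 100]")
        if self.alignment_length < 1:
            raise DataError("alignment_length must be >= 1 for a reported hit")


def _validate_dna(seq: str, what: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise DataError(f"{what}: empty sequence")
    if set(seq) - _DNA:
        raise DataError(f"{what}: non-ATCG characters")
    return seq


def align_identity(query: str, reference: str) -> tuple[float, int, int]:
    """Best local alignment of two sequences -> (identity %, alignment length, score)."""
    query = _validate_dna(query, "query")
    reference = _validate_dna(reference, "reference")
    aln = _ALIGNER.align(query, reference)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / length if length else 0.0
    return identity, int(length), int(round(aln.score))


def kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


@dataclass
class SearchIndex:
    """k-mer postings over the atlas reference sequences."""

    k: int
    sequences: dict[str, str]  # reference_id -> sequence
    postings: dict[str, set[str]] = field(default_factory=dict)

    def shared_kmer_counts(self, query: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for kmer in kmer_set(query, self.k):
            for rid in self.postings.get(kmer, ()):
                counts[rid] = counts.get(rid, 0) + 1
        return counts


def index_from_sequences(sequences: Mapping[str, str], k: int = DEFAULT_K) -> SearchIndex:
    if k < 4:
        raise DataError(f"word size k={k} too small (minimum 4)")
    index = SearchIndex(k=k, sequences={})
    for rid, seq in sequences.items():
        if len(seq) < k:
            logger.warning("reference %s shorter than k=%d, excluded from index", rid, k)
            continue
        index.sequences[rid] = seq
        for kmer in kmer_set(seq, k):
            index.postings.setdefault(kmer, set()).add(rid)
    return index


def build_index(atlas: ReferenceAtlas, k: int = DEFAULT_K) -> SearchIndex:
    return index_from_sequences({e.sequence_id: e.sequence for e in atlas.entries}, k)


def top_hit_search(
    query_id: str,
    query: str,
    index: SearchIndex,
    threshold: float = DEFAULT_THRESHOLD,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> AlignmentHit | None:
    """Best-scoring reference above the identity threshold, or None.

    Candidates are the references sharing at least one k-mer with the query,
    capped at ``max_candidates`` by shared-k-mer count.  The best hit has the
    highest score; ties break by higher identity, then by lexicographically
    smallest reference id.  None (a prediction failure downstream) is returned
    when no candidate reaches the threshold.
    """
    if not (0.0 <= threshold <= 100.0):
        raise DataError(f"threshold {threshold} outside [0, 100]")
    shared = index.shared_kmer_counts(query)
    if not shared:
        return None
    candidates = sorted(shared, key=lambda rid: (-shared[rid], rid))[:max_candidates]
    best: AlignmentHit | None = None
    for rid in candidates:
        identity, length, score = align_identity(query, index.sequences[rid])
        hit = AlignmentHit(query_id, rid, identity, length, score)
        if best is None or (hit.score, hit.identity, _neg_id(hit.reference_id)) > (
            best.score,
            best.identity,
            _neg_id(best.reference_id),
        ):
            best = hit
    if best is None or best.identity < threshold:
        return None
    return best


class _neg_id(str):
    """Inverts string ordering so that a smaller reference_id wins a max() comparison."""

    def __lt__(self, other: str) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other: str) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


def parse_external_hits(text: str) -> list[AlignmentHit]:
    """Parse BLAST tabular (outfmt 6, default 12 columns) into AlignmentHits.

    Column mapping: qseqid, sseqid, pident, length, ..., bitscore (rounded to
    an integer score).  Malformed lines are rejected with their line numbers
    logged; well-formed lines are kept.
    """
    hits: list[AlignmentHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 12:
            logger.warning("line %d: expected 12 tab-separated columns, got %d — rejected", lineno, len(fields))
            continue
        try:
            hits.append(
                AlignmentHit(
                    query_id=fields[0],
                    reference_id=fields[1],
                    identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    score=int(round(float(fields[11]))),
                )
            )
        except (ValueError, DataError) as exc:
            logger.warning("line %d: %s — rejected", lineno, exc)
    return hits
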