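"""Validation statistics and the accuracy-assessment protocol.

Covers the position-wise BGC-profile similarity score, greedy identity
clustering with intra-cluster statistics, consistency among genomes sharing
identical 16S sequences, Tukey-fence outlier rates of total BGC counts,
deviation bins for predicted vs true totals, identity-tier stratification,
per-class evaluation, and in-silico V3-V4 extraction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from amp2bgc import align as _align
from amp2bgc.atlas import ReferenceAtlas
from amp2bgc.errors import DataError
from amp2bgc.profiles import BGCProfile, N_CLASSES

logger = logging.getLogger(__name__)

DEVIATION_BINS = ("[0,1]", "(1,5]", "(5,inf)")
IDENTITY_TIERS = ("0-80", "80-90", "90-95", "95-100")
_TIER_EDGES = (80.0, 90.0, 95.0, 100.0)

# 341F / 805R, the standard V3-V4 primer pair; primers are excluded from the
# returned span.
V3V4_FORWARD = "CCTACGGGNGGCWGCAG"
V3V4_REVERSE = "GACTACHVGGGTATCTAATCC"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def bgc_similarity(a: BGCProfile | Sequence[float], b: BGCProfile | Sequence[float]) -> float:
    """Position-wise profile similarity: (1/8) * sum_i 1/(|a_i - b_i| + 1).

    Equals 1 exactly when the two profiles are identical; symmetric; always
    in (0, 1].
    """
    av = a.to_array() if isinstance(a, BGCProfile) else np.asarray(a, dtype=float)
    bv = b.to_array() if isinstance(b, BGCProfile) else np.asarray(b, dtype=float)
    if av.shape != (N_CLASSES,) or bv.shape != (N_CLASSES,):
        raise DataError(f"profiles must have length {N_CLASSES}")
    if not (np.all(np.isfinite(av)) and np.all(np.isfinite(bv))):
        raise DataError("profiles must be finite")
    return float(np.mean(1.0 / (np.abs(av - bv) + 1.0)))


@dataclass
class SimilarityStats:
    cluster_id: str
    n_members: int
    mean: float
    median: float
    std: float  # population standard deviation over the C(n,2) pairs
    min: float
    max: float


def pairwise_stats(profiles: Sequence[BGCProfile], cluster_id: str = "") -> SimilarityStats:
    """Five-number summary of similarity over all unordered profile pairs."""
    if len(profiles) < 2:
        raise DataError("pairwise statistics need at least 2 profiles")
    scores = [bgc_similarity(a, b) for a, b in itertools.combinations(profiles, 2)]
    arr = np.asarray(scores)
    return SimilarityStats(
        cluster_id=cluster_id,
        n_members=len(profiles),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        std=float(arr.std()),  # ddof=0: population std
        min=float(arr.min()),
        max=float(arr.max()),
    )


def greedy_cluster(
    sequences: Sequence[tuple[str, str]],
    threshold: float,
    k: int = _align.DEFAULT_K,
) -> list[list[str]]:
    """CD-HIT-style greedy incremental clustering at a percent-identity threshold.

    Sequences are processed longest-first (ties by id); each joins the first
    existing centroid (in creation order) it matches at >= threshold, else
    seeds a new cluster.  A conservative shared-k-mer screen skips alignments
    that cannot reach the threshold; the greedy semantics are unchanged.
    """
    if not sequences:
        return []
    if not (0.0 < threshold <= 100.0):
        raise DataError(f"threshold {threshold} outside (0, 100]")
    ordered = sorted(sequences, key=lambda item: (-len(item[1]), item[0]))
    centroids: list[tuple[str, str, frozenset[str]]] = []  # (id, seq, kmers)
    clusters: list[list[str]] = []
    miss_frac = 1.0 - threshold / 100.0
    for sid, seq in ordered:
        kmers = _align.kmer_set(seq, k)
        assigned = False
        for ci, (cid, cseq, ckmers) in enumerate(centroids):
            lo, hi = sorted((len(seq), len(cseq)))
            bound = (lo - k + 1) - 2.0 * k * miss_frac * hi
            if bound > 0 and len(kmers & ckmers) < bound:
                continue
            identity, _, _ = _align.align_identity(seq, cseq)
            if identity >= threshold:
                clusters[ci].append(sid)
                assigned = True
                break
        if not assigned:
            centroids.append((sid, seq, kmers))
            clusters.append([sid])
    return clusters


def cluster_similarity_stats(
    clusters: Sequence[Sequence[str]],
    profile_by_id: Mapping[str, BGCProfile],
) -> list[SimilarityStats]:
    """Intra-cluster profile similarity statistics over non-singleton clusters."""
    out = []
    for i, members in enumerate(clusters):
        if len(members) < 2:
            continue
        out.append(pairwise_stats([profile_by_id[m] for m in members], cluster_id=f"cluster{i + 1}"))
    return out


def identical_marker_consistency(atlas: ReferenceAtlas) -> list[SimilarityStats]:
    """Profile-similarity statistics within each multi-genome atlas entry."""
    return [
        pairwise_stats(e.member_profiles, cluster_id=e.sequence_id)
        for e in atlas.entries
        if e.multiplicity >= 2
    ]


def outlier_rate(
    groups: Sequence[Sequence[float]],
    k: float = 1.5,
    min_group_size: int = 4,
) -> float:
    """Pooled Tukey-fence outlier proportion of total BGC counts across groups.

    Within each group of at least ``min_group_size`` values, a value outside
    [Q1 - k*IQR, Q3 + k*IQR] (quartiles by linear interpolation) is an
    outlier; the pooled outlier count over the pooled value count is returned.
    """
    n_outliers = 0
    n_values = 0
    for group in groups:
        vals = np.asarray(group, dtype=float)
        if vals.size < min_group_size:
            logger.warning("group of size %d skipped (< %d)", vals.size, min_group_size)
            continue
        q1, q3 = np.percentile(vals, [25, 75], method="linear")
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        n_outliers += int(np.sum((vals < lo) | (vals > hi)))
        n_values += vals.size
    if n_values == 0:
        raise DataError("no group large enough for outlier analysis")
    return n_outliers / n_values


@dataclass
class EvalSummary:
    """Counts and proportions of |predicted - true| deviations per bin."""

    counts: dict[str, int]
    n_success: int
    n_failures: int = 0

    @property
    def proportions(self) -> dict[str, float]:
        if self.n_success == 0:
            return {b: 0.0 for b in DEVIATION_BINS}
        return {b: c / self.n_success for b, c in self.counts.items()}


def _bin_deviation(d: float) -> str:
    if d <= 1.0:
        return "[0,1]"
    if d <= 5.0:
        return "(1,5]"
    return "(5,inf)"


def deviation_bins(
    predicted_totals: Sequence[float],
    true_totals: Sequence[float],
    n_failures: int = 0,
) -> EvalSummary:
    """Bin absolute total-count deviations into [0,1], (1,5], (5,inf)."""
    pred = np.asarray(predicted_totals, dtype=float)
    true = np.asarray(true_totals, dtype=float)
    if pred.shape != true.shape:
        raise DataError("predicted and true vectors must have equal length")
    counts = {b: 0 for b in DEVIATION_BINS}
    for d in np.abs(pred - true):
        counts[_bin_deviation(float(d))] += 1
    return EvalSummary(counts=counts, n_success=pred.size, n_failures=n_failures)


def identity_tier(identity: float) -> str:
    """Tier for an identity value; tiers are left-open right-closed, 0 joins the first."""
    if not (0.0 <= identity <= 100.0):
        raise DataError(f"identity {identity} outside [0, 100]")
    for label, hi in zip(IDENTITY_TIERS, _TIER_EDGES):
        if identity <= hi:
            return label
    raise AssertionError("unreachable")


def stratify_by_identity(
    predicted_totals: Sequence[float],
    true_totals: Sequence[float],
    identities: Sequence[float],
) -> dict[str, EvalSummary]:
    """Deviation bins computed separately within each identity tier."""
    pred = np.asarray(predicted_totals, dtype=float)
    true = np.asarray(true_totals, dtype=float)
    idents = np.asarray(identities, dtype=float)
    if not (pred.shape == true.shape == idents.shape):
        raise DataError("inputs must have equal length")
    out: dict[str, EvalSummary] = {}
    for tier in IDENTITY_TIERS:
        mask = np.array([identity_tier(i) == tier for i in idents])
        if mask.any():
            out[tier] = deviation_bins(pred[mask], true[mask])
        else:
            out[tier] = EvalSummary(counts={b: 0 for b in DEVIATION_BINS}, n_success=0)
    return out


def per_class_eval(
    predicted: Sequence[BGCProfile],
    true: Sequence[BGCProfile],
) -> dict[str, EvalSummary]:
    """Deviation bins per BGC class over paired profiles."""
    if not predicted or len(predicted) != len(true):
        raise DataError("paired non-empty profile lists required")
    from amp2bgc.profiles import BGC_CLASSES

    P = np.vstack([p.to_array() for p in predicted])
    T = np.vstack([t.to_array() for t in true])
    return {
        cls: deviation_bins(P[:, ci], T[:, ci]) for ci, cls in enumerate(BGC_CLASSES)
    }


def _iupac_mismatches(window: str, primer: str) -> int:
    m = 0
    for base, code in zip(window, primer):
        if base not in IUPAC[code]:
            m += 1
    return m


def _validate_primer(primer: str) -> str:
    primer = primer.strip().upper()
    if not primer or set(primer) - set(IUPAC):
        raise DataError(f"malformed primer {primer!r}")
    return primer


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_v3v4(
    sequence: str,
    fwd_primer: str = V3V4_FORWARD,
    rev_primer: str = V3V4_REVERSE,
    max_mismatches: int = 2,
) -> str | None:
    """In-silico PCR: return the V3-V4 insert between the primer sites, or None.

    The best (fewest-mismatch, then leftmost) forward-primer site is found
    under IUPAC matching; the reverse primer is matched reverse-complemented
    downstream of it.  Primers are excluded from the returned span.
    """
    fwd = _validate_primer(fwd_primer)
    rev = reverse_complement(_validate_primer(rev_primer))
    if max_mismatches < 0:
        raise DataError("max_mismatches must be >= 0")
    seq = sequence.strip().upper()

    def best_site(target: str, primer: str, start: int) -> int | None:
        best: tuple[int, int] | None = None
        for pos in range(start, len(target) - len(primer) + 1):
            m = _iupac_mismatches(target[pos : pos + len(primer)], primer)
            if m <= max_mismatches and (best is None or m < best[0]):
                best = (m, pos)
                if m == 0:
                    break
        return best[1] if best else None

    fpos = best_site(seq, fwd, 0)
    if fpos is None:
        return None
    insert_start = fpos + len(fwd)
    rpos = best_site(seq, rev, insert_start)
    if rpos is None:
        return None
    insert = seq[insert_start:rpos]
    return insert or None
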