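"""Per-sequence prediction orchestration and per-sample class aggregation.

``predict`` runs either engine over a FASTA's worth of query sequences and
returns one :class:`PredictionRecord` per query.  ``aggregate_samples``
multiplies a QIIME2-style feature table into the predicted profiles to give
the total abundance of each BGC class per sample.  ``write_outputs`` emits
the two CSV files: per-sequence predictions and per-sample class abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from amp2bgc import align as _align
from amp2bgc import phylo as _phylo
from amp2bgc.atlas import ReferenceAtlas
from amp2bgc.errors import DataError
from amp2bgc.io import FeatureTable, format_float
from amp2bgc.profiles import AGGREGATION_STRATEGIES, BGC_CLASSES, BGCProfile

logger = logging.getLogger(__name__)

DEFAULT_STRATEGY = "mean_float"


@dataclass
class PredictionRecord:
    query_id: str
    method: str  # "identity" or "phylo"
    strategy: str  # aggregation strategy or HSP method
    best_hit_id: str | None
    identity: float | None
    profile: BGCProfile | None
    status: str  # "ok" or "failed"

    def __post_init__(self) -> None:
        if self.status == "ok" and self.profile is None:
            raise DataError("status=ok requires a profile")
        if self.status == "failed" and self.profile is not None:
            raise DataError("status=failed must not carry a profile")


def predict(
    queries: list[tuple[str, str]],
    atlas: ReferenceAtlas,
    engine: str = "identity",
    strategy: str = DEFAULT_STRATEGY,
    threshold: float = _align.DEFAULT_THRESHOLD,
    tree=None,
    hsp_method: str = "mp",
    index: "_align.SearchIndex | None" = None,
) -> list[PredictionRecord]:
    """Predict one BGC profile per query, in input order.

    The identity engine assigns the aggregated profile of the top hit above
    ``threshold`` (below it the query fails); the phylo engine grafts onto
    ``tree`` and never thresholds.
    """
    if engine not in ("identity", "phylo"):
        raise DataError(f"unknown engine {engine!r}")
    if engine == "identity" and strategy not in AGGREGATION_STRATEGIES:
        raise DataError(f"unknown strategy {strategy!r}")
    if engine == "phylo" and hsp_method not in _phylo.HSP_METHODS:
        raise DataError(f"unknown HSP method {hsp_method!r}")

    records: list[PredictionRecord] = []
    if engine == "identity":
        if index is None:
            index = _align.build_index(atlas)
        entries_by_id = {e.sequence_id: e for e in atlas.entries}
        for qid, seq in queries:
            hit = _align.top_hit_search(qid, seq, index, threshold=threshold)
            if hit is None:
                logger.info("query %s: no hit above %.1f%% identity — failed", qid, threshold)
                records.append(
                    PredictionRecord(qid, "identity", strategy, None, None, None, "failed")
                )
                continue
            profile = entries_by_id[hit.reference_id].aggregated[strategy]
            records.append(
                PredictionRecord(qid, "identity", strategy, hit.reference_id, hit.identity, profile, "ok")
            )
    else:
        if tree is None:
            tree = _phylo.build_nj_tree(atlas)
        for qid, profile, attachment, identity in _phylo.predict_phylo(
            queries, atlas, tree, hsp_method=hsp_method, index=index
        ):
            if profile is None:
                records.append(PredictionRecord(qid, "phylo", hsp_method, None, None, None, "failed"))
            else:
                records.append(
                    PredictionRecord(qid, "phylo", hsp_method, attachment, identity, profile, "ok")
                )
    n_failed = sum(r.status == "failed" for r in records)
    logger.info("%d/%d queries predicted, %d failures", len(records) - n_failed, len(records), n_failed)
    return records


@dataclass
class SampleClassAbundance:
    """Per-sample totals of each BGC class: A[s, c] = sum_f T[f, s] * P[f, c]."""

    abundance: pd.DataFrame  # index = sample ids, columns = BGC_CLASSES
    excluded_fraction: float  # fraction of total table abundance on failed/unmatched features

    def relative(self) -> pd.DataFrame:
        totals = self.abundance.sum(axis=1)
        rel = self.abundance.div(totals.where(totals > 0, 1.0), axis=0)
        rel[totals == 0] = 0.0
        return rel


def aggregate_samples(table: FeatureTable, records: list[PredictionRecord]) -> SampleClassAbundance:
    """Weight predicted profiles by feature abundances to get per-sample class totals."""
    profile_by_feature = {r.query_id: r.profile for r in records if r.status == "ok"}
    usable = [f for f in table.feature_ids if f in profile_by_feature]
    if not usable:
        raise DataError("no overlap between feature table ids and successful predictions")
    P = np.vstack([profile_by_feature[f].to_array() for f in usable])
    T = table.data.loc[usable].to_numpy()  # features x samples
    A = T.T @ P  # samples x classes
    total_abundance = float(table.data.to_numpy().sum())
    used_abundance = float(T.sum())
    excluded = 0.0 if total_abundance == 0 else 1.0 - used_abundance / total_abundance
    if excluded > 0:
        logger.info("%.1f%% of table abundance excluded (failed or unmatched features)", 100 * excluded)
    return SampleClassAbundance(
        abundance=pd.DataFrame(A, index=table.sample_ids, columns=list(BGC_CLASSES)),
        excluded_fraction=excluded,
    )


PER_SEQUENCE_COLUMNS = ["sequence_id", *BGC_CLASSES, "total", "method", "best_hit_id", "identity", "status"]


def write_outputs(
    records: list[PredictionRecord],
    out_prefix: str | Path,
    sample_abundance: SampleClassAbundance | None = None,
) -> list[Path]:
    """Write the per-sequence CSV and, when available, the per-sample CSV."""
    if not records:
        raise DataError("no prediction records to write")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []

    seq_path = out_prefix.parent / (out_prefix.name + "_predictions.csv")
    with seq_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(PER_SEQUENCE_COLUMNS) + "\n")
        for r in records:
            if r.status == "ok":
                cells = [format_float(v) for v in r.profile.counts]
                total = format_float(r.profile.total)  # recomputed sum of the 8 columns
                identity = format_float(r.identity) if r.identity is not None else ""
                hit = r.best_hit_id or ""
            else:
                cells = [""] * len(BGC_CLASSES)
                total, identity, hit = "", "", ""
            fh.write(",".join([r.query_id, *cells, total, r.method, hit, identity, r.status]) + "\n")
    paths.append(seq_path)

    if sample_abundance is not None:
        smp_path = out_prefix.parent / (out_prefix.name + "_samples.csv")
        with smp_path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("sample_id," + ",".join(BGC_CLASSES) + ",total\n")
            for sid, row in sample_abundance.abundance.iterrows():
                vals = [format_float(v) for v in row.to_numpy()]
                fh.write(",".join([str(sid), *vals, format_float(float(row.sum()))]) + "\n")
        paths.append(smp_path)
    return paths


def read_predictions_csv(path: str | Path) -> list[PredictionRecord]:
    """Round-trip reader for the per-sequence CSV."""
    df = pd.read_csv(path, dtype=str)
    records = []
    for _, row in df.iterrows():
        status = row["status"]
        if status == "ok":
            profile = BGCProfile.from_array([float(row[c]) for c in BGC_CLASSES])
            identity = float(row["identity"]) if pd.notna(row["identity"]) and row["identity"] != "" else None
            hit = row["best_hit_id"] if pd.notna(row["best_hit_id"]) else None
        else:
            profile, identity, hit = None, None, None
        records.append(
            PredictionRecord(
                query_id=str(row["sequence_id"]),
                method=str(row["method"]),
                strategy="",
                best_hit_id=hit,
                identity=identity,
                profile=profile,
                status=status,
            )
        )
    return records
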