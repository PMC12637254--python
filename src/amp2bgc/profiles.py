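"""BGC class profiles: the eight-class trait vector and its arithmetic.

Every genome, atlas entry and prediction in this package carries a
:class:`BGCProfile` — a fixed-order vector of non-negative counts over the
eight BiG-SCAPE (v1) BGC classes.  antiSMASH annotates a genome as a set of
"regions", each tagged with one or more product types (``T1PKS``, ``NRPS``,
``terpene``, ...); :func:`map_bgc_classes` collapses those product tags into
the eight classes, one count per region.  :func:`aggregate_profiles` combines
the profiles of several genomes that share an identical 16S sequence under
one of four strategies (mean/median crossed with float/integer output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from amp2bgc.errors import DataError

logger = logging.getLogger(__name__)

#: Fixed class order used in every profile, table column block and CSV output.
BGC_CLASSES: tuple[str, ...] = (
    "PKSI",
    "PKSother",
    "NRPS",
    "PKS-NRPS_Hybrids",
    "RiPPs",
    "Saccharides",
    "Terpene",
    "Others",
)

N_CLASSES = len(BGC_CLASSES)

AGGREGATION_STRATEGIES = ("mean_float", "mean_int", "median_float", "median_int")

# Default antiSMASH-product -> class table, following BiG-SCAPE v1 conventions.
# Keys are compared case-insensitively after trimming; any token not listed
# here routes the whole region to "Others".  Overridable via a two-column TSV
# (product <tab> class), see load_product_class_map.
DEFAULT_PRODUCT_CLASS_MAP: dict[str, str] = {
    # Type I PKS
    "t1pks": "PKSI",
    # other PKS
    "transat-pks": "PKSother",
    "transat-pks-like": "PKSother",
    "transatpks": "PKSother",
    "t2pks": "PKSother",
    "t3pks": "PKSother",
    "hgle-ks": "PKSother",
    "ppys-ks": "PKSother",
    "pks-like": "PKSother",
    "otherks": "PKSother",
    # NRPS
    "nrps": "NRPS",
    "nrps-like": "NRPS",
    "thioamide-nrp": "NRPS",
    # RiPPs
    "lanthipeptide": "RiPPs",
    "lanthipeptide-class-i": "RiPPs",
    "lanthipeptide-class-ii": "RiPPs",
    "lanthipeptide-class-iii": "RiPPs",
    "lanthipeptide-class-iv": "RiPPs",
    "lanthipeptide-class-v": "RiPPs",
    "lanthidin": "RiPPs",
    "lassopeptide": "RiPPs",
    "thiopeptide": "RiPPs",
    "linaridin": "RiPPs",
    "cyanobactin": "RiPPs",
    "glycocin": "RiPPs",
    "lap": "RiPPs",
    "bacteriocin": "RiPPs",
    "ripp-like": "RiPPs",
    "sactipeptide": "RiPPs",
    "bottromycin": "RiPPs",
    "head_to_tail": "RiPPs",
    "microviridin": "RiPPs",
    "proteusin": "RiPPs",
    "guanidinotides": "RiPPs",
    "lipolanthine": "RiPPs",
    "ras-ripp": "RiPPs",
    "fungal-ripp": "RiPPs",
    "thioamitides": "RiPPs",
    "microcin": "RiPPs",
    "epipeptide": "RiPPs",
    "cyclic-lactone-autoinducer": "RiPPs",
    "spliceotide": "RiPPs",
    "ranthipeptide": "RiPPs",
    # saccharides
    "amglyccycl": "Saccharides",
    "oligosaccharide": "Saccharides",
    "cf_saccharide": "Saccharides",
    "saccharide": "Saccharides",
    # terpene
    "terpene": "Terpene",
}

_PKS_CLASSES = frozenset({"PKSI", "PKSother"})


@dataclass(frozen=True)
class BGCProfile:
    """Fixed-order vector of non-negative abundances over the eight BGC classes."""

    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != N_CLASSES:
            raise DataError(
                f"BGC profile must have exactly {N_CLASSES} entries, got {len(self.counts)}"
            )
        arr = np.asarray(self.counts, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise DataError("BGC profile entries must be finite and non-negative")

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "BGCProfile":
        vals = [float(v) for v in values]
        # keep exact ints as ints for clean serialization
        vals = [int(v) if float(v).is_integer() else v for v in vals]
        return cls(tuple(vals))

    @classmethod
    def zeros(cls) -> "BGCProfile":
        return cls(tuple([0] * N_CLASSES))

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @property
    def total(self) -> float:
        return float(sum(self.counts))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(BGC_CLASSES, self.counts))

    def __getitem__(self, cls_name: str) -> float:
        return self.counts[BGC_CLASSES.index(cls_name)]


def load_product_class_map(path: str | Path) -> dict[str, str]:
    """Read a product->class TSV (two columns, no header required, '#' comments)."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DataError(f"{path}:{lineno}: expected 2 tab-separated columns")
        product, cls = parts[0].strip().lower(), parts[1].strip()
        if cls not in BGC_CLASSES:
            raise DataError(f"{path}:{lineno}: unknown BGC class {cls!r}")
        mapping[product] = cls
    if not mapping:
        raise DataError(f"{path}: empty product->class mapping")
    return mapping


def classify_region(products: Iterable[str], mapping: Mapping[str, str] | None = None) -> str:
    """Assign one antiSMASH region (its product token set) to a single class.

    A region whose products span a PKS class and NRPS is a PKS-NRPS hybrid;
    a region whose products all map to one class keeps that class; any other
    multi-class combination, or any unknown token, goes to "Others".
    """
    if mapping is None:
        mapping = DEFAULT_PRODUCT_CLASS_MAP
    tokens = [p.strip().lower() for p in products if p and p.strip()]
    if not tokens:
        raise DataError("region has no product tokens")
    classes = set()
    for tok in tokens:
        cls = mapping.get(tok)
        if cls is None:
            logger.debug("unknown product token %r -> Others", tok)
            return "Others"
        classes.add(cls)
    if classes & _PKS_CLASSES and "NRPS" in classes:
        return "PKS-NRPS_Hybrids"
    if len(classes) == 1:
        return next(iter(classes))
    return "Others"


def map_bgc_classes(
    regions: Sequence[Sequence[str]],
    mapping: Mapping[str, str] | None = None,
) -> BGCProfile:
    """Count one genome's antiSMASH regions into the eight classes.

    ``regions`` is a list of product-token lists, one per region.  Each region
    contributes exactly +1 to exactly one class, so the profile total always
    equals the number of regions.
    """
    counts = np.zeros(N_CLASSES, dtype=int)
    for products in regions:
        cls = classify_region(products, mapping)
        counts[BGC_CLASSES.index(cls)] += 1
    return BGCProfile.from_array(counts)


def round_half_away(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties away from zero (values are >= 0 here)."""
    return np.floor(np.asarray(values, dtype=float) + 0.5)


def aggregate_profiles(members: Sequence[BGCProfile], strategy: str) -> BGCProfile:
    """Combine member-genome profiles into one per-class summary profile.

    Strategies: ``mean_float``/``median_float`` return the per-class mean or
    median; ``mean_int``/``median_int`` round that to the nearest integer with
    ties away from zero.  A single member is returned unchanged by all four.
    """
    if strategy not in AGGREGATION_STRATEGIES:
        raise DataError(f"unknown aggregation strategy {strategy!r}")
    if not members:
        raise DataError("cannot aggregate an empty member list")
    mat = np.vstack([m.to_array() for m in members])
    if strategy.startswith("mean"):
        agg = mat.mean(axis=0)
    else:
        agg = np.median(mat, axis=0)
    if strategy.endswith("_int"):
        agg = round_half_away(agg)
    return BGCProfile.from_array(agg)
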