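"""Synthetic data: phylogenetically coupled 16S-like sequences and BGC traits.

Every fixture used in tests and acceptance runs is generated here, with no
download: a Yule tree rescaled to a chosen mean root-to-tip depth, sequences
evolved under Jukes-Cantor along it, integer BGC profiles evolved as a
reflected +/-1 random walk per class (so traits are phylogenetically
autocorrelated, emulating the observed conservation of BGC repertoires among
close relatives), reference/holdout benchmark splits with optional control
of the query-to-reference identity band, QIIME2-style amplicon fixtures and
atlas-builder input fixtures with known pass/fail edge cases.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from amp2bgc import align as _align
from amp2bgc.atlas import ReferenceAtlas, atlas_from_profiles, write_atlas
from amp2bgc.errors import DataError
from amp2bgc.io import FeatureTable, write_fasta, write_feature_table_biom, write_feature_table_tsv
from amp2bgc.phylo import jc_distance, write_tree
from amp2bgc.profiles import BGC_CLASSES, BGCProfile, DEFAULT_PRODUCT_CLASS_MAP, N_CLASSES

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: Default root profile: a modestly endowed bacterium (7 BGCs across 6 classes).
DEFAULT_ROOT_PROFILE = (1, 0, 2, 0, 2, 0, 1, 1)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    ``step_rate`` is the expected number of +/-1 trait steps per class per
    unit branch length (branch lengths are in substitutions/site).  The
    default of 5 makes tip pairs at ~97 % sequence identity (path length
    ~0.06) expect ~0.3 steps per class, i.e. near-identical profiles among
    close relatives.
    """

    n_tips: int = 40
    seed: int = 0
    seq_length: int = 1200
    rate: float = 1.0  # substitutions per site per unit branch length
    depth: float = 0.1  # mean root-to-tip depth, substitutions/site
    step_rate: float = 5.0
    root_profile: tuple[int, ...] = DEFAULT_ROOT_PROFILE
    holdout_fraction: float = 0.25
    identity_band: tuple[float, float] | None = None
    n_features: int = 12
    n_samples: int = 3

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise DataError("n_tips must be >= 2")
        if self.seq_length < 300:
            raise DataError("seq_length must be >= 300")
        if self.rate < 0 or self.step_rate < 0 or self.depth <= 0:
            raise DataError("rates must be non-negative and depth positive")
        if len(self.root_profile) != N_CLASSES or any(v < 0 for v in self.root_profile):
            raise DataError("root_profile must be 8 non-negative integers")


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_tree(n_tips: int, seed: int, depth: float = 0.1) -> TreeNode:
    """Yule pure-birth tree (unit birth rate) rescaled to mean root-to-tip ``depth``."""
    if n_tips < 2:
        raise DataError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    leaves = [TreeNode(length=0.0), TreeNode(length=0.0)]
    for leaf in leaves:
        root.append(leaf)
    while len(leaves) < n_tips:
        dt = rng.exponential(1.0 / len(leaves))
        for leaf in leaves:
            leaf.length += dt
        split = leaves.pop(int(rng.integers(len(leaves))))
        children = [TreeNode(length=0.0), TreeNode(length=0.0)]
        for c in children:
            split.append(c)
        leaves.extend(children)
    dt = rng.exponential(1.0 / len(leaves))
    for leaf in leaves:
        leaf.length += dt
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"tip{i:04d}"
    mean_depth = float(np.mean([root.distance(t) for t in root.tips()]))
    factor = depth / mean_depth
    for node in root.traverse(include_self=False):
        node.length = (node.length or 0.0) * factor
    return root


def evolve_sequences(
    tree: TreeNode, seq_length: int, rate: float, seed: int
) -> dict[str, str]:
    """Jukes-Cantor sequence evolution: root uniform over ACGT, per-branch substitution.

    Along a branch of length b each site substitutes with probability
    (3/4)(1 - exp(-(4/3) rate b)), to one of the three other bases uniformly.
    """
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_length)
    seqs: dict[int, np.ndarray] = {id(tree): root_seq}
    for node in tree.preorder(include_self=False):
        parent_seq = seqs[id(node.parent)]
        b = node.length or 0.0
        p = 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * rate * b))
        child = parent_seq.copy()
        mask = rng.random(seq_length) < p
        n_mut = int(mask.sum())
        if n_mut:
            child[mask] = (child[mask] + rng.integers(1, 4, size=n_mut)) % 4
        seqs[id(node)] = child
    return {t.name: "".join(_BASES[seqs[id(t)]]) for t in tree.tips()}


def _reflected_walk(start: int, n_steps: int, rng: np.random.Generator) -> int:
    state = start
    for _ in range(n_steps):
        state = abs(state + (1 if rng.random() < 0.5 else -1))
    return state


def evolve_traits(
    tree: TreeNode,
    root_profile: tuple[int, ...],
    step_rate: float,
    seed: int,
) -> dict[str, np.ndarray]:
    """Integer trait evolution: per class a reflected +/-1 random walk along branches.

    The number of steps on a branch of length b is Poisson(step_rate * b);
    reflection at zero keeps all counts non-negative.
    """
    rng = np.random.default_rng(seed)
    root = np.asarray(root_profile, dtype=int)
    states: dict[int, np.ndarray] = {id(tree): root}
    for node in tree.preorder(include_self=False):
        parent = states[id(node.parent)]
        b = node.length or 0.0
        n_steps = rng.poisson(step_rate * b, size=N_CLASSES)
        child = parent.copy()
        for ci in range(N_CLASSES):
            if n_steps[ci]:
                child[ci] = _reflected_walk(int(child[ci]), int(n_steps[ci]), rng)
        states[id(node)] = child
    return {t.name: states[id(t)] for t in tree.tips()}


@dataclass
class Benchmark:
    """A reference atlas plus held-out queries with known true profiles."""

    atlas: ReferenceAtlas
    ref_tree: TreeNode
    queries: list[tuple[str, str]]
    truth: dict[str, BGCProfile]
    identities: dict[str, float]  # query -> best identity to the reference set
    step_rate: float
    config: SimConfig


def _adjust_to_band(
    query: str,
    ref: str,
    target_identity: float,
    rng: np.random.Generator,
) -> str:
    """Move a query toward a target identity to ``ref`` by positional edits.

    Simulated sequences are substitution-only and positionally homologous, so
    identity control reduces to setting the mismatch count: extra mismatches
    are added at random matching positions; excess mismatches are reverted to
    the reference base.
    """
    q = np.array(list(query))
    r = np.array(list(ref))
    L = len(q)
    target_mismatches = int(round(L * (1.0 - target_identity / 100.0)))
    diff = np.flatnonzero(q != r)
    same = np.flatnonzero(q == r)
    if len(diff) < target_mismatches:
        extra = rng.choice(same, size=target_mismatches - len(diff), replace=False)
        for pos in extra:
            choices = [b for b in "ACGT" if b != q[pos]]
            q[pos] = choices[int(rng.integers(3))]
    elif len(diff) > target_mismatches:
        revert = rng.choice(diff, size=len(diff) - target_mismatches, replace=False)
        q[revert] = r[revert]
    return "".join(q)


def make_benchmark(
    config: SimConfig,
    out_dir: str | Path | None = None,
    tune_pendant_steps: float | None = None,
) -> Benchmark:
    """Split simulated tips into a reference atlas and held-out queries.

    With ``tune_pendant_steps`` set, the trait step rate is calibrated so the
    expected number of trait steps summed over the 8 classes along a mean
    query pendant (the Jukes-Cantor distance from a query to its best
    reference) equals that value; otherwise ``config.step_rate`` applies.
    """
    rng_split, rng_band = _spawn_rngs(config.seed, 2)
    tree = simulate_tree(config.n_tips, config.seed + 1, config.depth)
    seqs = evolve_sequences(tree, config.seq_length, config.rate, config.seed + 2)

    tip_names = sorted(seqs)
    n_hold = int(round(config.n_tips * config.holdout_fraction))
    if n_hold < 1:
        raise DataError("holdout fraction leaves no query tips")
    if n_hold >= config.n_tips:
        raise DataError("holdout fraction leaves no reference tips")
    holdout = sorted(str(t) for t in rng_split.choice(tip_names, size=n_hold, replace=False))
    refs = [t for t in tip_names if t not in set(holdout)]

    ref_seqs = {t: seqs[t] for t in refs}
    index = _align.index_from_sequences(ref_seqs)

    query_seqs: dict[str, str] = {}
    identities: dict[str, float] = {}
    for qid in holdout:
        seq = seqs[qid]
        hit = _align.top_hit_search(qid, seq, index, threshold=0.0)
        if config.identity_band is not None and hit is not None:
            lo, hi = config.identity_band
            if not (lo <= hit.identity <= hi):
                target = float(rng_band.uniform(lo, hi))
                seq = _adjust_to_band(seq, ref_seqs[hit.reference_id], target, rng_band)
                hit = _align.top_hit_search(qid, seq, index, threshold=0.0)
        query_seqs[qid] = seq
        identities[qid] = hit.identity if hit is not None else 0.0

    if tune_pendant_steps is not None:
        pendants = [jc_distance(1.0 - i / 100.0) for i in identities.values()]
        mean_pendant = max(float(np.mean(pendants)), 1e-9)
        step_rate = tune_pendant_steps / (N_CLASSES * mean_pendant)
        logger.info("tuned step_rate=%.3f (mean pendant %.4f)", step_rate, mean_pendant)
    else:
        step_rate = config.step_rate

    traits = evolve_traits(tree, config.root_profile, step_rate, config.seed + 3)
    atlas = atlas_from_profiles(
        ref_seqs,
        {t: BGCProfile.from_array(traits[t]) for t in refs},
        provenance={"simulated": True, "seed": config.seed, "step_rate": step_rate},
    )
    ref_tree = tree.shear(refs)
    ref_tree.prune()
    # relabel reference tips with their atlas sequence ids
    tip_to_seqid = {}
    for entry in atlas.entries:
        for gid in entry.member_genomes:
            tip_to_seqid[gid] = entry.sequence_id
    kept_tips = set()
    for tip in list(ref_tree.tips()):
        seqid = tip_to_seqid[tip.name]
        if seqid in kept_tips:  # duplicate sequence: keep one tip per atlas entry
            _remove_tip(ref_tree, tip)
        else:
            tip.name = seqid
            kept_tips.add(seqid)

    bench = Benchmark(
        atlas=atlas,
        ref_tree=ref_tree,
        queries=[(q, query_seqs[q]) for q in holdout],
        truth={q: BGCProfile.from_array(traits[q]) for q in holdout},
        identities=identities,
        step_rate=step_rate,
        config=config,
    )
    if out_dir is not None:
        _write_benchmark(bench, Path(out_dir))
    return bench


def _remove_tip(tree: TreeNode, tip: TreeNode) -> None:
    parent = tip.parent
    parent.remove(tip)
    tree.prune()


def _write_benchmark(bench: Benchmark, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_atlas(bench.atlas, out_dir / "atlas")
    write_fasta(out_dir / "queries.fasta", bench.queries)
    truth_rows = [
        {"query_id": q, **p.as_dict(), "total": p.total} for q, p in bench.truth.items()
    ]
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"query_id": q, "best_identity": i} for q, i in bench.identities.items()]
    ).to_csv(out_dir / "identity_log.tsv", sep="\t", index=False)
    write_tree(bench.ref_tree, out_dir / "ref_tree.nwk")
    cfg = dataclasses.asdict(bench.config)
    cfg["realized_step_rate"] = bench.step_rate
    (out_dir / "config.json").write_text(json.dumps(cfg, indent=1) + "\n")


def make_amplicon_fixture(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[list[tuple[str, str]], FeatureTable, ReferenceAtlas]:
    """Representative sequences plus a per-sample count table, QIIME2-style.

    Features are a mix of reference-identical and lightly mutated sequences;
    counts per sample are negative-binomial (mean 50, dispersion 2).
    """
    rng = np.random.default_rng(config.seed + 17)
    tree = simulate_tree(config.n_tips, config.seed + 1, config.depth)
    seqs = evolve_sequences(tree, config.seq_length, config.rate, config.seed + 2)
    traits = evolve_traits(tree, config.root_profile, config.step_rate, config.seed + 3)
    atlas = atlas_from_profiles(
        dict(sorted(seqs.items())),
        {t: BGCProfile.from_array(v) for t, v in traits.items()},
    )
    tips = sorted(seqs)
    features: list[tuple[str, str]] = []
    for i in range(config.n_features):
        src = tips[int(rng.integers(len(tips)))]
        seq = seqs[src]
        if i % 2 == 1:  # mutate half the features by 1-3 %
            arr = np.array(list(seq))
            n_mut = int(rng.integers(1, max(2, int(0.03 * len(seq)))))
            pos = rng.choice(len(seq), size=n_mut, replace=False)
            for p in pos:
                choices = [b for b in "ACGT" if b != arr[p]]
                arr[p] = choices[int(rng.integers(3))]
            seq = "".join(arr)
        features.append((f"feat{i + 1:03d}", seq))
    mean, dispersion = 50.0, 2.0
    counts = rng.negative_binomial(
        dispersion, dispersion / (dispersion + mean), size=(config.n_features, config.n_samples)
    )
    table = FeatureTable(
        pd.DataFrame(
            counts.astype(float),
            index=[fid for fid, _ in features],
            columns=[f"sample{j + 1}" for j in range(config.n_samples)],
        )
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(out_dir / "rep_seqs.fasta", features)
        write_feature_table_tsv(out_dir / "feature_table.tsv", table)
        write_feature_table_biom(out_dir / "feature_table.biom", table)
        write_atlas(atlas, out_dir / "atlas")
    return features, table, atlas


def make_atlas_input_fixture(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]], dict[str, dict]]:
    """Atlas-builder inputs with deliberate edge cases and a pass/fail manifest.

    The manifest is derived from the construction itself (which rule each
    injected genome violates), independently of the atlas builder.
    """
    rng = np.random.default_rng(config.seed + 29)
    n_clean = max(config.n_tips, 4)
    tree = simulate_tree(n_clean, config.seed + 1, config.depth)
    seqs = evolve_sequences(tree, config.seq_length, config.rate, config.seed + 2)
    clean_ids = sorted(seqs)

    products = sorted(DEFAULT_PRODUCT_CLASS_MAP)
    meta_rows: list[dict] = []
    region_rows: list[dict] = []
    fasta: list[tuple[str, str]] = []
    manifest: dict[str, dict] = {}

    def add_regions(gid: str) -> None:
        for ri in range(int(rng.poisson(4))):
            tok = products[int(rng.integers(len(products)))]
            if rng.random() < 0.15:
                tok = tok + ";" + products[int(rng.integers(len(products)))]
            region_rows.append({"genome_id": gid, "region_id": f"{gid}_r{ri + 1}", "products": tok})

    for i, tip in enumerate(clean_ids):
        gid = f"G{i + 1:03d}"
        meta_rows.append(
            {"genome_id": gid, "completeness": round(float(rng.uniform(92, 100)), 2),
             "contamination": round(float(rng.uniform(0, 4)), 2), "assembly_level": "complete",
             "lineage": "Bacteria;TestPhylum"}
        )
        fasta.append((gid, seqs[tip]))
        add_regions(gid)
        manifest[gid] = {"pass": True, "reason": "clean"}

    base = seqs[clean_ids[0]]
    edge_cases = [
        ("G_LOWCOMP", {"completeness": 85.0, "contamination": 1.0}, base, False, "completeness below 90"),
        ("G_HIGHCONT", {"completeness": 99.0, "contamination": 7.0}, base, False, "contamination above 5"),
        ("G_N16S", {"completeness": 99.0, "contamination": 1.0}, base[:600] + "N" + base[601:], False, "16S contains non-ATCG"),
        ("G_SHORT16S", {"completeness": 99.0, "contamination": 1.0}, base[:249], False, "16S shorter than 250 nt"),
        ("G_DUP", {"completeness": 99.0, "contamination": 1.0}, seqs[clean_ids[1]], True, "duplicate 16S of G002"),
    ]
    for gid, quality, seq, passes, reason in edge_cases:
        meta_rows.append(
            {"genome_id": gid, **quality, "assembly_level": "scaffold", "lineage": "Bacteria;TestPhylum"}
        )
        fasta.append((gid, seq))
        add_regions(gid)
        manifest[gid] = {"pass": passes, "reason": reason}

    metadata = pd.DataFrame(meta_rows)
    regions = pd.DataFrame(region_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
        regions.to_csv(out_dir / "regions.tsv", sep="\t", index=False)
        write_fasta(out_dir / "markers.fasta", fasta)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return metadata, regions, fasta, manifest
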