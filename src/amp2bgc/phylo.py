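"""Phylogenetic prediction engine: grafting plus hidden-state prediction.

A query 16S sequence is grafted next to its nearest reference tip (midpoint
attachment, Jukes-Cantor-corrected pendant branch) and its BGC profile is
inferred from the observed tip profiles by one of three hidden-state
prediction methods:

* ``subtree_average`` — mean profile of the first ancestral subtree that
  contains at least one observed tip;
* ``scp`` — squared-change parsimony: per class, minimise the sum over edges
  of (state change)^2 / branch length with observed tips fixed (the standard
  two-pass weighted-average solution, identical to the maximum-likelihood
  ancestral states under Brownian motion);
* ``mp`` — Sankoff maximum parsimony on integer states 0..max_state with
  linear cost |i-j| per edge, branch lengths ignored, backtrace ties resolved
  toward the smallest state.

This engine never rejects a query on low identity; it is the fallback for
sequences too novel for the identity-search engine.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from amp2bgc import align as _align
from amp2bgc.atlas import ReferenceAtlas
from amp2bgc.errors import DataError
from amp2bgc.profiles import BGCProfile, N_CLASSES

logger = logging.getLogger(__name__)

SCP_EPSILON = 1e-6  # replaces zero branch lengths in scp only
JC_SATURATION_P = 0.74  # beyond this observed difference the JC distance is capped
PENDANT_CAP = 1.0

HSP_METHODS = ("mp", "scp", "subtree_average")


def jc_distance(p: float) -> float:
    """Jukes-Cantor distance for an observed proportion p of differing sites.

    d = -(3/4) ln(1 - (4/3) p), capped at 1.0 substitutions/site; near and
    beyond saturation (p >= 0.74) the cap applies directly.
    """
    if p < 0:
        raise DataError(f"proportion {p} negative")
    if p >= JC_SATURATION_P:
        return PENDANT_CAP
    d = -0.75 * math.log1p(-(4.0 / 3.0) * p)
    return min(d, PENDANT_CAP)


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def graft_query(tree: TreeNode, query_id: str, nearest_ref: str, identity: float) -> TreeNode:
    """Insert the query as a sibling of its nearest reference tip.

    The reference's terminal branch is split at its midpoint; the query hangs
    from the new node on a pendant of JC-corrected length derived from the
    percent identity.  The input tree is not modified.
    """
    if not (0.0 < identity <= 100.0):
        raise DataError(f"identity {identity} outside (0, 100]")
    tree = tree.copy()
    try:
        tip = tree.find(nearest_ref)
    except Exception as exc:
        raise DataError(f"nearest reference {nearest_ref!r} not in tree") from exc
    if not tip.is_tip():
        raise DataError(f"{nearest_ref!r} is not a tip")
    pendant = jc_distance(1.0 - identity / 100.0)
    parent = tip.parent
    if parent is None:
        raise DataError("cannot graft onto a single-node tree")
    half = (tip.length or 0.0) / 2.0
    attachment = TreeNode(length=half)
    parent.remove(tip)
    tip.length = half
    attachment.append(tip)
    attachment.append(TreeNode(name=query_id, length=pendant))
    parent.append(attachment)
    return tree


def _states_matrix(tip_states: Mapping[str, object]) -> dict[str, np.ndarray]:
    out = {}
    for name, state in tip_states.items():
        arr = state.to_array() if isinstance(state, BGCProfile) else np.asarray(state, dtype=float)
        if arr.shape != (N_CLASSES,):
            raise DataError(f"tip state for {name!r} must have length {N_CLASSES}")
        out[name] = arr
    return out


def hsp_subtree_average(tree: TreeNode, tip_states: Mapping[str, object], query_id: str) -> BGCProfile:
    """Mean profile over the first ancestral subtree containing observed tips."""
    states = _states_matrix(tip_states)
    tip = tree.find(query_id)
    node = tip.parent
    while node is not None:
        observed = [states[t.name] for t in node.tips() if t.name in states]
        if observed:
            return BGCProfile.from_array(np.mean(observed, axis=0))
        node = node.parent
    raise DataError("tree has no observed (non-query) tips")


def hsp_scp(tree: TreeNode, tip_states: Mapping[str, object]) -> dict[TreeNode, np.ndarray]:
    """Squared-change parsimony states for every node of the tree.

    Minimises, per class independently, sum over edges of (delta state)^2
    divided by branch length.  Unobserved tips (grafted queries) contribute
    nothing on the downpass and inherit the state inferred at their
    attachment on the uppass.
    """
    states = _states_matrix(tip_states)

    def blen(node: TreeNode) -> float:
        return max(node.length or 0.0, SCP_EPSILON)

    cond: dict[TreeNode, np.ndarray | None] = {}
    efflen: dict[TreeNode, float] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            if node.name in states:
                cond[node] = states[node.name]
                efflen[node] = blen(node)
            else:
                cond[node] = None
        else:
            kids = [c for c in node.children if cond[c] is not None]
            if not kids:
                cond[node] = None
                continue
            prec = np.array([1.0 / efflen[c] for c in kids])
            cond[node] = np.average([cond[c] for c in kids], axis=0, weights=prec)
            efflen[node] = blen(node) + 1.0 / prec.sum()
    if cond[tree] is None:
        raise DataError("tree has no observed tips")

    # uppass: information reaching each node from outside its own subtree
    above: dict[TreeNode, tuple[np.ndarray, float] | None] = {tree: None}
    final: dict[TreeNode, np.ndarray] = {}
    for node in tree.preorder(include_self=True):
        contrib: list[tuple[np.ndarray, float]] = []
        for c in node.children:
            if cond[c] is not None:
                contrib.append((cond[c], efflen[c]))
        if node is not tree and above[node] is not None:
            contrib.append(above[node])
        if node.is_tip():
            if node.name in states:
                final[node] = states[node.name]
            elif contrib:
                w = np.array([1.0 / l for _, l in contrib])
                final[node] = np.average([v for v, _ in contrib], axis=0, weights=w)
            else:
                raise DataError("isolated unobserved tip")
        else:
            w = np.array([1.0 / l for _, l in contrib])
            final[node] = np.average([v for v, _ in contrib], axis=0, weights=w)
        for c in node.children:
            others = [(cond[s], efflen[s]) for s in node.children if s is not c and cond[s] is not None]
            if node is not tree and above[node] is not None:
                others.append(above[node])
            if others:
                w = np.array([1.0 / l for _, l in others])
                val = np.average([v for v, _ in others], axis=0, weights=w)
                above[c] = (val, blen(c) + 1.0 / w.sum())
            else:
                above[c] = None
    return final


def hsp_mp(
    tree: TreeNode,
    tip_states: Mapping[str, object],
    max_state: int | None = None,
) -> dict[TreeNode, np.ndarray]:
    """Sankoff maximum parsimony with linear cost |i-j|, per class independently.

    Returns integer states for every node; ties in the backtrace resolve to
    the smallest state.  Branch lengths are ignored.
    """
    states = _states_matrix(tip_states)
    int_states = {}
    for name, arr in states.items():
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded):
            raise DataError(f"mp requires integer tip states ({name!r} is fractional)")
        int_states[name] = rounded.astype(int)
    observed_max = max((int(v.max()) for v in int_states.values()), default=0)
    if max_state is None:
        max_state = observed_max + 5
    if observed_max > max_state:
        raise DataError(f"observed state {observed_max} exceeds max_state {max_state}")
    K = max_state + 1
    cost = np.abs(np.arange(K)[:, None] - np.arange(K)[None, :]).astype(float)

    S: dict[TreeNode, np.ndarray] = {}
    any_observed = False
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            if node.name in int_states:
                any_observed = True
                mat = np.full((N_CLASSES, K), np.inf)
                mat[np.arange(N_CLASSES), int_states[node.name]] = 0.0
            else:
                mat = np.zeros((N_CLASSES, K))
            S[node] = mat
        else:
            total = np.zeros((N_CLASSES, K))
            for c in node.children:
                # M[cls, i] = min_j (|i-j| + S_c[cls, j])
                total += (S[c][:, None, :] + cost[None, :, :]).min(axis=2)
            S[node] = total
    if not any_observed:
        raise DataError("tree has no observed tips")

    result: dict[TreeNode, np.ndarray] = {}
    result[tree] = np.argmin(S[tree], axis=1)  # argmin picks the smallest tied state
    for node in tree.preorder(include_self=True):
        if node is not tree:
            parent_state = result[node.parent]
            result[node] = np.argmin(cost[parent_state, :] + S[node], axis=1)
    return result


def predict_phylo(
    queries: Sequence[tuple[str, str]],
    atlas: ReferenceAtlas,
    tree: TreeNode,
    hsp_method: str = "mp",
    strategy: str | None = None,
    index: "_align.SearchIndex | None" = None,
) -> list[tuple[str, BGCProfile | None, str | None, float | None]]:
    """Graft each query and infer its profile; returns (id, profile, attachment, identity).

    A profile of None marks a failure (the query shares no k-mers with any
    reference even at the k=6 retry).  Identity never gates this engine.
    """
    if hsp_method not in HSP_METHODS:
        raise DataError(f"unknown HSP method {hsp_method!r}; choose from {HSP_METHODS}")
    if strategy is None:
        strategy = "mean_int" if hsp_method == "mp" else "mean_float"
    tree_tips = {t.name for t in tree.tips()}
    tip_states = {
        e.sequence_id: e.aggregated[strategy]
        for e in atlas.entries
        if e.sequence_id in tree_tips
    }
    if not tip_states:
        raise DataError("no tree tip matches an atlas sequence_id")
    if index is None:
        index = _align.build_index(atlas)
    fallback_index: "_align.SearchIndex | None" = None

    results: list[tuple[str, BGCProfile | None, str | None, float | None]] = []
    for qid, seq in queries:
        hit = _align.top_hit_search(qid, seq, index, threshold=0.0)
        if hit is None:
            if fallback_index is None:
                fallback_index = _align.build_index(atlas, k=6)
            hit = _align.top_hit_search(qid, seq, fallback_index, threshold=0.0)
        if hit is None or hit.reference_id not in tree_tips:
            # also try the nearest reference that is actually in the tree
            if hit is not None and hit.reference_id not in tree_tips:
                hit = _best_hit_in_tree(qid, seq, index, tree_tips)
        if hit is None:
            logger.warning("query %s: no alignable reference, recorded as failure", qid)
            results.append((qid, None, None, None))
            continue
        if hit.identity >= 100.0:
            # exact duplicate of a reference: inherit its state directly
            results.append((qid, BGCProfile.from_array(
                tip_states[hit.reference_id].to_array()
                if isinstance(tip_states[hit.reference_id], BGCProfile)
                else tip_states[hit.reference_id]
            ), hit.reference_id, hit.identity))
            continue
        grafted = graft_query(tree, qid, hit.reference_id, max(hit.identity, 1e-9))
        if hsp_method == "subtree_average":
            profile = hsp_subtree_average(grafted, tip_states, qid)
        elif hsp_method == "scp":
            final = hsp_scp(grafted, tip_states)
            profile = BGCProfile.from_array(np.clip(final[grafted.find(qid)], 0, None))
        else:
            states = hsp_mp(grafted, tip_states)
            profile = BGCProfile.from_array(states[grafted.find(qid)])
        results.append((qid, profile, hit.reference_id, hit.identity))
    return results


def _best_hit_in_tree(qid, seq, index, tree_tips):
    shared = index.shared_kmer_counts(seq)
    candidates = sorted((r for r in shared if r in tree_tips), key=lambda r: (-shared[r], r))[:50]
    best = None
    for rid in candidates:
        identity, length, score = _align.align_identity(seq, index.sequences[rid])
        key = (score, identity, _align._neg_id(rid))
        if best is None or key > best[0]:
            best = (key, _align.AlignmentHit(qid, rid, identity, length, score))
    return best[1] if best else None


def build_nj_tree(atlas: ReferenceAtlas) -> TreeNode:
    """Neighbor-joining tree over atlas sequences from pairwise JC distances.

    Convenience for when no reference tree is supplied; quadratic in the
    number of entries, intended for modest atlas sizes.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids = [e.sequence_id for e in atlas.entries]
    seqs = {e.sequence_id: e.sequence for e in atlas.entries}
    n = len(ids)
    if n < 3:
        raise DataError("neighbor joining needs at least 3 sequences")
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            identity, _, _ = _align.align_identity(seqs[ids[i]], seqs[ids[j]])
            dm[i, j] = dm[j, i] = jc_distance(1.0 - identity / 100.0)
    tree = nj(DistanceMatrix(dm, ids))
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length < 0:
            node.length = 0.0
    return tree
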