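"""Distance-based phylogeny of recovered element sequences.

Pairwise distances use pairwise deletion of gap/ambiguous sites with
either the raw proportion of differing sites (p-distance) or the Kimura
two-parameter correction (K2P, the equal-frequency simplification of
HKY85).  Trees come from an in-package neighbor-joining implementation
with deterministic tie-breaking; branch supports from column-resampling
bootstrap.  Maximum-likelihood inference and aLRT-style supports are
delegated to an optional external tool adapter.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .msa import MultipleAlignment
from .sequence_io import write_fasta

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINES = (0, 2)


def _encode_rows(aln: MultipleAlignment) -> tuple[list[str], np.ndarray]:
    ids = [rid for rid, _ in aln.rows]
    mat = np.full((aln.n_rows, aln.n_cols), 4, dtype=np.uint8)
    for i, (_, row) in enumerate(aln.rows):
        arr = np.frombuffer(row.upper().encode("ascii"), dtype=np.uint8)
        for sym, code in _CODE.items():
            mat[i][arr == ord(sym)] = code
    return ids, mat


def pairwise_distances(aln: MultipleAlignment, correction: str = "k2p",
                       on_saturation: str = "raise") -> DistanceMatrix:
    """Pairwise distances (substitutions/site) with pairwise gap deletion.

    ``correction`` is 'p' or 'k2p'.  A saturated pair (non-positive log
    argument in the K2P formula) raises by default; ``on_saturation='p'``
    substitutes the pair's p-distance instead (used by bootstrap).
    """
    if aln.n_rows < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    if correction not in ("p", "k2p"):
        raise ValueError(f"unknown correction {correction!r}")
    ids, mat = _encode_rows(aln)
    return _distances_from_matrix(ids, mat, correction, on_saturation)


def _distances_from_matrix(ids, mat, correction, on_saturation) -> DistanceMatrix:
    n = mat.shape[0]
    dm = np.zeros((n, n))
    valid = mat < 4
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"pair ({ids[i]!r}, {ids[j]!r}) shares no comparable columns")
            a, b = mat[i][both], mat[j][both]
            diff = a != b
            if correction == "p":
                d = diff.sum() / m
            else:
                is_transition = diff & (
                    (np.isin(a, _PURINES) & np.isin(b, _PURINES))
                    | (~np.isin(a, _PURINES) & ~np.isin(b, _PURINES))
                )
                P = is_transition.sum() / m
                Q = (diff.sum() - is_transition.sum()) / m
                w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
                if w1 <= 0 or w2 <= 0:
                    if on_saturation == "p":
                        d = diff.sum() / m
                    else:
                        raise ValueError(
                            f"K2P saturation for pair ({ids[i]!r}, {ids[j]!r}): "
                            f"P={P:.3f} Q={Q:.3f}"
                        )
                else:
                    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard NJ agglomeration.

    Ties in the Q-criterion break to the lexicographically smallest index
    pair; negative branch lengths are clamped to zero with the remainder
    shifted to the sister branch.  The result is an unrooted tree written
    with a trifurcating root (for >= 3 taxa).
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [TreeNode(name=name) for name in ids]
    D = np.array(dm.data, dtype=float)
    active = list(range(n))
    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.unravel_index(int(np.argmin(q)), q.shape)  # first occurrence: lowest pair
        ai, aj = sorted((best[0], best[1]))
        i, j = active[ai], active[aj]
        dij = D[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2 * (k - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = TreeNode()
        ni, nj = nodes[i], nodes[j]
        ni.length = vi
        nj.length = vj
        parent.append(ni)
        parent.append(nj)
        nodes.append(parent)
        newD = np.zeros((D.shape[0] + 1, D.shape[1] + 1))
        newD[:-1, :-1] = D
        for m_idx in active:
            if m_idx in (i, j):
                continue
            newD[-1, m_idx] = newD[m_idx, -1] = 0.5 * (D[i, m_idx] + D[j, m_idx] - dij)
        D = newD
        active = [a for a in active if a not in (i, j)] + [D.shape[0] - 1]
    root = TreeNode()
    if len(active) == 3:
        i, j, k = active
        vi = max(0.0, (D[i, j] + D[i, k] - D[j, k]) / 2)
        vj = max(0.0, (D[i, j] + D[j, k] - D[i, k]) / 2)
        vk = max(0.0, (D[i, k] + D[j, k] - D[i, j]) / 2)
        for idx, v in zip((i, j, k), (vi, vj, vk)):
            nodes[idx].length = v
            root.append(nodes[idx])
    else:  # exactly 2 taxa
        i, j = active
        for idx in (i, j):
            nodes[idx].length = max(0.0, D[i, j] / 2)
            root.append(nodes[idx])
    return root


def tree_to_newick(tree: TreeNode) -> str:
    import io

    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Canonical internal bipartitions (smaller side, by min name on ties)."""
    leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        parts.add(canon)
    return parts


def bootstrap_support(aln: MultipleAlignment, n_replicates: int = 100, seed: int = 0,
                      correction: str = "k2p") -> TreeNode:
    """NJ tree with bootstrap supports on internal nodes.

    Columns are resampled with replacement; support is the fraction of
    replicate trees containing each internal bipartition, written as the
    internal node name.  Saturated replicate pairs fall back to
    p-distance so every replicate yields a tree.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ids, mat = _encode_rows(aln)
    main = neighbor_joining(_distances_from_matrix(ids, mat, correction, "p"))
    counts: dict[frozenset, int] = {p: 0 for p in _bipartitions(main)}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, mat.shape[1], size=mat.shape[1])
        rep = mat[:, cols]
        try:
            rep_tree = neighbor_joining(_distances_from_matrix(ids, rep, correction, "p"))
        except ValueError:
            continue  # a pair with no comparable columns in this resample
        rep_parts = _bipartitions(rep_tree)
        for p in counts:
            if p in rep_parts:
                counts[p] += 1
    for node in main.non_tips(include_self=False):
        leaves = frozenset(t.name for t in main.tips())
        side = frozenset(t.name for t in node.tips())
        canon = min(side, leaves - side, key=lambda s: (len(s), sorted(s)))
        if canon in counts:
            node.name = f"{counts[canon] / n_replicates:.2f}"
    return main


def phyml_adapter(aln: MultipleAlignment, binary: str = "phyml") -> TreeNode:
    """Optional adapter around an external PhyML binary (HKY85 + aLRT
    supports); raises when the binary is unavailable, never falls back."""
    if shutil.which(binary) is None:
        raise FileNotFoundError(f"external tree tool {binary!r} is not on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        phy = Path(tmp) / "aln.phy"
        with open(phy, "w") as fh:
            fh.write(f" {aln.n_rows} {aln.n_cols}\n")
            for i, (rid, row) in enumerate(aln.rows):
                fh.write(f"t{i:<9} {row}\n")
        subprocess.run([binary, "--input", str(phy), "--datatype", "nt", "-m", "HKY85"],
                       check=True, capture_output=True)
        tree_file = Path(str(phy) + "_phyml_tree.txt")
        tree = TreeNode.read(str(tree_file), format="newick")
    names = {f"t{i}": rid for i, (rid, _) in enumerate(aln.rows)}
    for tip in tree.tips():
        tip.name = names.get(tip.name, tip.name)
    return tree
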