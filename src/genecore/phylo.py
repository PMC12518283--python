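"""Neighbour-joining phylogeny on Tajima-Nei genotype distances.

Diploid SNP genotypes are expanded to two base copies per locus (a
heterozygote contributes one reference and one alternative base); the
mismatch proportion between two accessions averages over the four
copy-pairings at loci called in both (pairwise deletion).  The Tajima-Nei
correction for unequal base composition is then applied:

    d = -b ln(1 - p / b),   b = 1 - sum_i q_i^2 + p^2 / h,
    h = sum_{i<j} x_ij^2 / (2 q_i q_j),

with q_i the base frequencies pooled over the two accessions' copies and
x_ij the relative frequency of the differing-site class with bases {i, j}
(proportions among differing site-pairs).  Saturated pairs (p >= b) get a
missing distance with a warning.

The NJ agglomeration itself is delegated to scikit-bio; branch lengths that
come out negative are floored at zero with the difference moved onto the
sister branch.  Bootstrap support resamples loci with replacement and
counts, for each internal bipartition of the reference tree, the fraction
of replicate trees containing it.
"""

from __future__ import annotations

import logging
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from genecore.containers import GenotypeMatrix

logger = logging.getLogger(__name__)

_BASE_ORDER = ("A", "C", "G", "T")


def tajima_nei_distance(gm: GenotypeMatrix, markers: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Tajima-Nei distance matrix (substitutions per site).

    Returned as a symmetric accessions x accessions DataFrame; saturated
    pairs hold NaN.
    """
    markers = markers.set_index("marker_id").loc[gm.markers].reset_index()
    ref = markers["ref"].to_numpy(dtype=object)
    alt = markers["alt"].to_numpy(dtype=object)
    G = gm.dosage
    n, L = G.shape
    M = (~np.isnan(G)).astype(float)
    A = np.where(np.isnan(G), 0.0, G) / 2.0  # alt-copy probability per call
    AM = A * M
    RM = (1.0 - A) * M

    shared = M @ M.T
    if (shared[np.triu_indices(n, k=1)] == 0).any():
        raise ValueError("some accession pairs share no called loci")

    # expected mismatch count per pair, overall and per base-pair class
    def mismatch(cols: np.ndarray) -> np.ndarray:
        a, r = AM[:, cols], RM[:, cols]
        return a @ r.T + r @ a.T

    all_cols = np.arange(L)
    P = mismatch(all_cols) / shared

    # pooled base counts per pair: copies of base b contributed at shared loci
    q = np.zeros((4, n, n))
    for bi, base in enumerate(_BASE_ORDER):
        w = 2.0 * RM * (ref == base)[None, :] + 2.0 * AM * (alt == base)[None, :]
        q[bi] = w @ M.T + M @ w.T
    q /= np.maximum(4.0 * shared, 1e-12)[None, :, :]

    # differing-site class proportions (among differing pairs)
    total_mm = mismatch(all_cols)
    classes: dict[frozenset, np.ndarray] = {}
    pair_arr = [frozenset((r, a)) for r, a in zip(ref, alt)]
    for cls in set(pair_arr):
        cols = np.flatnonzero([p == cls for p in pair_arr])
        classes[cls] = mismatch(cols)

    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.zeros((n, n))
        for cls, mm in classes.items():
            u, v = sorted(cls)
            ui, vi = _BASE_ORDER.index(u), _BASE_ORDER.index(v)
            x = mm / np.maximum(total_mm, 1e-300)
            h += x**2 / np.maximum(2.0 * q[ui] * q[vi], 1e-300)
        b = 1.0 - (q**2).sum(axis=0) + P**2 / np.maximum(h, 1e-300)
        d = -b * np.log(1.0 - P / b)

    d[P == 0] = 0.0
    saturated = P >= b
    np.fill_diagonal(saturated, False)
    if saturated.any():
        logger.warning(
            "tajima_nei_distance: %d saturated pair(s) (p >= b); distances set missing",
            int(saturated.sum() // 2),
        )
        d[saturated] = np.nan
    d = np.where(d < 0, 0.0, d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return pd.DataFrame(d, index=gm.accessions, columns=gm.accessions)


def _fix_negative_branches(tree: TreeNode) -> TreeNode:
    """Floor negative branch lengths at 0, moving the deficit to the sister."""
    for node in tree.postorder(include_self=False):
        if node.length is not None and node.length < 0:
            deficit = -node.length
            node.length = 0.0
            sibs = [s for s in node.parent.children if s is not node]
            for s in sibs:
                if s.length is not None:
                    s.length += deficit / len(sibs)
    return tree


def nj_tree(dm: pd.DataFrame | DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining; negative branch lengths redistributed."""
    if isinstance(dm, pd.DataFrame):
        data, ids = dm.to_numpy(), list(dm.index)
    else:
        data, ids = dm.data, list(dm.ids)
    if np.isnan(data).any():
        pairs = [
            (ids[i], ids[j]) for i, j in zip(*np.where(np.isnan(data))) if i < j
        ]
        raise ValueError(f"distance matrix incomplete for pairs: {pairs}")
    tree = _skbio_nj(DistanceMatrix(data, ids=ids))
    return _fix_negative_branches(tree)


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    """Non-trivial splits as canonical tip sets (side not holding the anchor)."""
    anchor = min(taxa)
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if anchor in side:
            side = taxa - side
        splits.add(side)
    return splits


def bootstrap_support(
    gm: GenotypeMatrix,
    markers: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> TreeNode:
    """NJ tree with locus-resampling bootstrap support on internal nodes.

    Support (percent of replicates containing each internal bipartition of
    the reference tree) is stored as the internal node name.  ``n_boot=0``
    returns the reference tree with supports absent.
    """
    if gm.n_accessions < 4:
        raise ValueError("bootstrap support requires at least 4 accessions")
    ref_tree = nj_tree(tajima_nei_distance(gm, markers))
    if n_boot == 0:
        return ref_tree
    taxa = frozenset(gm.accessions)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    L = gm.n_markers
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        sub = gm.subset_markers(cols)
        sub.markers = [f"b{i}" for i in range(L)]  # resampled ids must be unique
        msub = markers.set_index("marker_id").loc[[gm.markers[c] for c in cols]].reset_index()
        msub["marker_id"] = sub.markers
        rep = nj_tree(tajima_nei_distance(sub, msub))
        for split in _bipartitions(rep, taxa):
            counts[split] = counts.get(split, 0) + 1
    anchor = min(taxa)
    for node in ref_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if anchor in side:
            side = taxa - side
        node.name = str(int(round(100.0 * counts.get(side, 0) / n_boot)))
    return ref_tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc


def tree_to_newick_string(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()
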