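"""Distance-based haplotype clustering: neighbor-joining with a column bootstrap.

The tree is built from pairwise haplotype mismatch counts over the SNP panel
(missing data resolved through the N policy), which is exactly the structure a
parentage screen needs: clones sharing a transmitted haplotype collapse into
zero-distance clusters, and each paternal lineage forms its own clade.
Neighbor-joining is exact on additive distance matrices and deterministic
here.  Support values come from resampling SNP columns with replacement
(standard phylogenetic bootstrap) and counting how often each internal
bipartition of the full-data tree reappears.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .kinship import haplotype_distance
from .matrix import AS_REFERENCE, GenotypeMatrix


class InsufficientSamplesError(ValueError):
    pass


def distance_matrix(
    matrix: GenotypeMatrix, n_policy: str = AS_REFERENCE, normalize: bool = False
) -> DistanceMatrix:
    """Pairwise haplotype mismatch counts as a symmetric distance matrix.

    With ``normalize=True`` distances are mismatches per compared locus (useful
    under ``pairwise-drop`` where compared-locus counts differ between pairs).
    """
    n = matrix.n_samples
    if n < 2:
        raise InsufficientSamplesError("need at least two samples")
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            n_cmp, mm = haplotype_distance(matrix.cells[i], matrix.cells[j], n_policy)
            d[i, j] = d[j, i] = (mm / n_cmp if n_cmp else 0.0) if normalize else mm
    return DistanceMatrix(d, ids=list(matrix.samples))


def nj_tree(dm: DistanceMatrix, collapse_zero: bool = True) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to zero.

    ``collapse_zero`` merges zero-length internal edges into polytomies, so
    groups of identical haplotypes appear as unresolved clusters rather than
    as arbitrary binary resolutions (an all-zero matrix yields a star tree).
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)  # validates symmetry / hollowness
    if len(dm.ids) < 3:
        raise InsufficientSamplesError("neighbor joining needs >= 3 samples")
    tree = nj(dm, neg_as_zero=True)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    if collapse_zero:
        _collapse_zero_internal(tree)
    return tree


def _collapse_zero_internal(tree: TreeNode) -> None:
    changed = True
    while changed:
        changed = False
        for node in list(tree.traverse()):
            if node.is_tip() or node.is_root():
                continue
            if not node.length:  # None or 0.0
                parent = node.parent
                for child in list(node.children):
                    node.remove(child)
                    parent.append(child)
                parent.remove(node)
                changed = True


def _bipartitions(tree: TreeNode, all_ids: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial splits of the leaf set, canonicalized to the side not
    containing the lexicographically first id."""
    anchor = min(all_ids)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_ids - side
        if 2 <= len(side) <= len(all_ids) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    matrix: GenotypeMatrix,
    n_reps: int = 1000,
    seed: int = 0,
    n_policy: str = AS_REFERENCE,
    collapse_zero: bool = True,
) -> TreeNode:
    """NJ tree of the full panel with column-bootstrap support on internal nodes.

    Loci are resampled with replacement ``n_reps`` times; each internal node of
    the full-data tree is annotated (via its ``name``) with the percentage of
    replicate trees containing the same leaf bipartition, rounded to an integer.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(distance_matrix(matrix, n_policy), collapse_zero)
    all_ids = frozenset(matrix.samples)
    anchor = min(all_ids)
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    m = matrix.n_loci
    for _ in range(n_reps):
        cols = rng.integers(0, m, size=m)
        # distances on resampled columns, computed directly for speed
        cells = matrix.cells[:, cols]
        n = matrix.n_samples
        d = np.zeros((n, n))
        c = cells.copy()
        if n_policy == AS_REFERENCE:
            c[c == "N"] = "-"
        for i in range(n):
            diff = c[i + 1 :] != c[i]
            if n_policy != AS_REFERENCE:
                diff &= (c[i + 1 :] != "N") & (c[i] != "N")
            d[i, i + 1 :] = diff.sum(axis=1)
        d = d + d.T
        rep_tree = nj(DistanceMatrix(d, ids=list(matrix.samples)), neg_as_zero=True)
        for split in _bipartitions(rep_tree, all_ids):
            counts[split] = counts.get(split, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_ids - side
        if 2 <= len(side) <= len(all_ids) - 2:
            node.name = str(round(100.0 * counts.get(side, 0) / n_reps))
    return tree


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Single-line Newick with branch lengths; internal names carry supports."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue().strip()
    if not text.endswith(";"):
        text += ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(source: str | Path) -> TreeNode:
    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    return TreeNode.read(io.StringIO(text), format="newick")


def bipartition_set(tree: TreeNode, ids: Sequence[str] | None = None) -> set[frozenset[str]]:
    """Public helper for topology comparison in round-trip checks."""
    all_ids = frozenset(ids) if ids is not None else frozenset(t.name for t in tree.tips())
    return _bipartitions(tree, all_ids)
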