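"""Display phylogeny: gap-column masking, protein distances, neighbor joining.

The distance is the Kimura-corrected protein distance
``d = -ln(1 - p - 0.2 p^2)`` on the mismatch fraction ``p`` over mutually
ungapped columns, capped when the argument is non-positive (saturation).
Neighbor joining uses the standard Q criterion with a deterministic
lexicographic tie-break and clamps negative branch lengths to zero with a
warning. Trees are returned as :class:`dendropy.Tree` objects, so Newick
round-trips are lossless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

GAP_CHARS = set("-.")
DEFAULT_MAX_GAP_FRAC = 0.75
DEFAULT_MAX_DISTANCE = 10.0


def _as_rows(alignment) -> list[tuple[str, str]]:
    if isinstance(alignment, dict):
        rows = list(alignment.items())
    else:
        rows = [tuple(r) for r in alignment]
    if not rows:
        raise ValueError("empty alignment")
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        raise ValueError(f"alignment is not rectangular: row lengths {sorted(lengths)}")
    return rows


@dataclass
class MaskedAlignment:
    taxa: list[str]
    rows: list[str]  # masked sequences, one per taxon
    kept_column_indices: list[int]

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("masked rows have unequal lengths")


def mask_columns(alignment, max_gap_frac: float = DEFAULT_MAX_GAP_FRAC) -> MaskedAlignment:
    """Drop columns whose gap fraction is >= ``max_gap_frac`` (strict keep rule).

    The boundary follows the removal rule "75% or more": a column at exactly
    the threshold is removed, so kept columns all have gap fraction strictly
    below it.
    """
    rows = _as_rows(alignment)
    taxa = [t for t, _ in rows]
    arr = np.array([list(s) for _, s in rows])
    gap_frac = np.isin(arr, list(GAP_CHARS)).mean(axis=0)
    kept = [int(i) for i in np.where(gap_frac < max_gap_frac)[0]]
    masked = ["".join(arr[r, kept]) for r in range(len(taxa))]
    return MaskedAlignment(taxa=taxa, rows=masked, kept_column_indices=kept)


def protein_distance(a: str, b: str, max_distance: float = DEFAULT_MAX_DISTANCE) -> float:
    """Kimura-corrected distance between two aligned protein rows.

    ``p`` is the mismatch fraction over columns where both rows are ungapped;
    when ``1 - p - 0.2 p^2 <= 0`` the distance is saturated and capped at
    ``max_distance`` (with a warning). Raises on zero comparable columns.
    """
    if len(a) != len(b):
        raise ValueError("rows must have equal aligned length")
    comparable = [(x, y) for x, y in zip(a, b) if x not in GAP_CHARS and y not in GAP_CHARS]
    if not comparable:
        raise ValueError("no mutually ungapped columns between rows")
    p = sum(1 for x, y in comparable if x != y) / len(comparable)
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        warnings.warn(f"saturated distance (p={p:.3f}); capped at {max_distance}")
        return max_distance
    return min(-math.log(arg), max_distance)


def distance_matrix(masked: MaskedAlignment,
                    max_distance: float = DEFAULT_MAX_DISTANCE) -> pd.DataFrame:
    """Symmetric taxon-by-taxon Kimura distance matrix."""
    n = len(masked.taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = protein_distance(masked.rows[i], masked.rows[j], max_distance)
    return pd.DataFrame(D, index=masked.taxa, columns=masked.taxa)


def _nj_newick(labels: list[str], D: np.ndarray) -> str:
    """Canonical neighbor joining; returns an unrooted Newick string.

    Tie-break on equal Q: the pair whose (sorted) tie-label pair is
    lexicographically smallest; an internal node inherits the smaller of its
    children's tie labels.
    """
    nodes = [(lbl, lbl) for lbl in labels]  # (newick fragment, tie label)
    D = D.copy()
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((nodes[i][1], nodes[j][1]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = clamp(0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2)))
        lj = clamp(D[i, j] - (0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))))
        frag = f"({nodes[i][0]}:{li:.10f},{nodes[j][0]}:{lj:.10f})"
        label = min(nodes[i][1], nodes[j][1])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([np.hstack([D[np.ix_(keep, keep)], dnew[keep, None]]),
                       np.hstack([dnew[keep], [0.0]])])
        nodes = [nodes[k] for k in keep] + [(frag, label)]

    # terminal star of three nodes (closed form)
    (f0, _), (f1, _), (f2, _) = nodes
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    b0 = clamp(0.5 * (d01 + d02 - d12))
    b1 = clamp(0.5 * (d01 + d12 - d02))
    b2 = clamp(0.5 * (d02 + d12 - d01))
    if clamped:
        warnings.warn("negative neighbor-joining branch lengths clamped to 0")
    return f"({f0}:{b0:.10f},{f1}:{b1:.10f},{f2}:{b2:.10f});"


def nj_tree(D: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix (>= 3 taxa)."""
    taxa = [str(t) for t in D.index]
    if len(taxa) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    M = np.asarray(D, dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T):
        raise ValueError("distance matrix must be square and symmetric")
    newick = _nj_newick(taxa, M)
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Internal-edge bipartitions as normalized leaf-name sets."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            continue  # trivial bipartitions
        if ref in side:
            side = leaves - side
        out.add(frozenset(side))
    return out


def bootstrap_support(
    alignment,
    n_reps: int,
    seed: int,
    max_gap_frac: float = DEFAULT_MAX_GAP_FRAC,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> dendropy.Tree:
    """NJ tree with internal-node bootstrap supports (percent of replicates).

    Columns of the masked alignment are resampled with replacement; each
    replicate is re-masked implicitly (resampling preserves per-column gap
    structure), distances recomputed and a replicate NJ tree built. Supports
    are bipartition frequencies mapped onto the full-data tree; deterministic
    under a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    masked = mask_columns(alignment, max_gap_frac)
    base = nj_tree(distance_matrix(masked, max_distance))
    ncols = len(masked.rows[0])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rows = ["".join(row[c] for c in cols) for row in masked.rows]
        try:
            rep = nj_tree(distance_matrix(
                MaskedAlignment(masked.taxa, rows, list(cols)), max_distance))
        except ValueError:
            continue  # replicate with no comparable columns for some pair
        for bp in tree_bipartitions(rep):
            counts[bp] = counts.get(bp, 0) + 1

    leaves = set(masked.taxa)
    ref = min(leaves)
    for node in base.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            continue
        if ref in side:
            side = leaves - side
        support = 100.0 * counts.get(frozenset(side), 0) / n_reps
        node.label = f"{support:.0f}"
    return base
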