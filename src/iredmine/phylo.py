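"""Identity-distance matrices and neighbor-joining trees for IRED panels.

"Similarity" between two panel members is their global-alignment percent
identity over aligned columns; the corresponding distance is
``1 - identity``. These identity distances are not guaranteed to be
additive or to satisfy the triangle inequality; neighbor joining is used
as a standard, deterministic agglomeration on them.

Trees are :class:`skbio.TreeNode` objects: unrooted (trifurcating root),
with non-negative branch lengths. Negative lengths arising from the NJ
formulas on non-additive input are clamped to zero and the deficit logged.
"""

from __future__ import annotations

import io
import logging

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .records import ProteinRecord
from .refmap import AlignmentParams, percent_identity

logger = logging.getLogger(__name__)


def distance_matrix(
    records: list, params: AlignmentParams | None = None
):
    """All-pairs identity distances plus the similarity range.

    Returns ``(dm, (min_pct, max_pct))`` where ``dm`` is a
    :class:`skbio.DistanceMatrix` with ``d[i][j] = 1 - identity(i, j)``
    and the range is over off-diagonal percent identities, rounded to
    whole percent.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    labels = [r.id for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    n = len(records)
    d = np.zeros((n, n))
    sims = []
    for i in range(n):
        for j in range(i + 1, n):
            ident = percent_identity(records[i], records[j], params)
            d[i, j] = d[j, i] = 1.0 - ident
            sims.append(100.0 * ident)
    rng = (round(min(sims)), round(max(sims)))
    return DistanceMatrix(d, ids=labels), rng


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard neighbor joining on a distance matrix.

    Agglomerates by the Q criterion with deterministic tie-breaking by
    (i, j) index order; branch lengths come from the canonical NJ
    formulas, with negative lengths clamped to zero.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.data.astype(float).copy()
    nodes = [TreeNode(name=label) for label in dm.ids]

    def clamp(length: float) -> float:
        if length < 0:
            logger.info("clamped negative branch length %.6g to 0", length)
            return 0.0
        return length

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = d.sum(axis=1)
        # Q[i,j] = (m-2) d_ij - r_i - r_j ; pick the (i<j) minimum
        q = (m - 2) * d - row_sums[:, None] - row_sums[None, :]
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or q[i, j] < q[best[0], best[1]] - 1e-12:
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_row[keep]])
        d = np.hstack([d, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal trifurcation: closed-form lengths for the last three nodes
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode(children=[a, b, c])
    a.length, b.length, c.length = clamp(la), clamp(lb), clamp(lc)
    return root


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree to a Newick string with branch lengths."""
    for tip in tree.tips():
        if not tip.name:
            raise ValueError("tree has a tip with an empty label")
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string back into a tree."""
    return TreeNode.read(io.StringIO(text), format="newick")
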