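"""Fast-greedy modularity maximization on individual-resource networks.

The bipartite incidence matrix is treated as an ordinary undirected graph
whose nodes are the individuals plus the food items and whose edges are the
realized interactions.  Modularity follows Newman & Girvan:

    Q = sum_c ( e_c / L - (d_c / 2L)^2 )

with e_c the number of edges inside module c, d_c the total degree of its
nodes and L the number of edges.  The agglomerative search starts from
singleton modules and repeatedly applies the merge of two connected modules
with the largest modularity gain; the partition with the highest Q along
the merge path is returned.  Given the tie rule, the result is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .incidence import IncidenceMatrix

__all__ = ["fast_greedy_modularity", "greedy_modularity_arrays", "ModularityResult"]


@dataclass(frozen=True)
class ModularityResult:
    """Best partition found by the greedy merge path."""

    q: float
    membership: dict[str, int]

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))


def greedy_modularity_arrays(
    biadjacency: np.ndarray, tie_rule: str = "lex"
) -> tuple[float, np.ndarray]:
    """Greedy Q and membership vector for a 0/1 biadjacency array.

    Nodes are numbered rows first then columns.  ``tie_rule`` picks among
    merges of equal gain: ``"lex"`` takes the lowest (module id, module id)
    pair, ``"revlex"`` the highest.  Module ids in the returned membership
    are contiguous from 0 in order of first node appearance.

    This array-level routine is the workhorse behind
    :func:`fast_greedy_modularity` and the Monte-Carlo null ensembles.
    """
    if tie_rule not in ("lex", "revlex"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}; use 'lex' or 'revlex'")
    bi = np.asarray(biadjacency)
    n_rows, n_cols = bi.shape
    k = n_rows + n_cols
    L = float(bi.sum())
    if L == 0:
        raise ValueError("graph has no edges; modularity undefined")

    # E[i, j]: edges between modules i and j (i != j); internal edges via w
    E = np.zeros((k, k))
    E[:n_rows, n_rows:] = bi
    E[n_rows:, :n_rows] = bi.T
    d = E.sum(axis=1)
    w = np.zeros(k)
    active = np.ones(k, dtype=bool)

    inv_L = 1.0 / L
    inv_2L2 = 1.0 / (2.0 * L * L)
    q = float(-np.sum((d / (2.0 * L)) ** 2))
    best_q = q
    merges: list[tuple[int, int]] = []
    best_step = 0

    pair_mask = np.zeros((k, k), dtype=bool)
    iu = np.triu_indices(k, 1)
    pair_mask[iu] = True

    for step in range(1, k):
        dq = E * inv_L - np.outer(d, d) * inv_2L2
        candidates = pair_mask & (E > 0) & active[:, None] & active[None, :]
        if not candidates.any():
            break
        dq = np.where(candidates, dq, -np.inf)
        flat = int(dq.argmax()) if tie_rule == "lex" else int(
            dq.size - 1 - dq[::-1, ::-1].argmax()
        )
        a, b = divmod(flat, k)
        q += float(dq[a, b])
        w[a] += w[b] + E[a, b]
        d[a] += d[b]
        E[a, :] += E[b, :]
        E[:, a] += E[:, b]
        E[a, a] = 0.0
        E[b, :] = 0.0
        E[:, b] = 0.0
        d[b] = 0.0
        active[b] = False
        merges.append((a, b))
        if q > best_q + 1e-12:
            best_q = q
            best_step = step

    labels = np.arange(k)
    for a, b in merges[:best_step]:
        labels[labels == b] = a
    # contiguous ids in order of first appearance
    remap: dict[int, int] = {}
    membership = np.empty(k, dtype=int)
    for node in range(k):
        membership[node] = remap.setdefault(int(labels[node]), len(remap))
    return best_q, membership


def fast_greedy_modularity(
    m: IncidenceMatrix, tie_rule: str = "lex"
) -> ModularityResult:
    """Greedy modularity of the incidence matrix's bipartite graph.

    Returns the best Q found along the agglomerative merge path together
    with the node -> module assignment (individual labels first, then item
    labels).  Raises ``ValueError`` on an edgeless graph.
    """
    q, membership = greedy_modularity_arrays(m.values, tie_rule=tie_rule)
    names = list(m.row_labels) + list(m.col_labels)
    return ModularityResult(q, {name: int(c) for name, c in zip(names, membership)})
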