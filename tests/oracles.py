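"""Independent brute-force oracles used by the test suite.

Deliberately separate code paths from the package: scalar loops, quadrature
and per-cell root-finding instead of the package's closed-form and
vectorized routines, plus exhaustive enumeration where the package
searches.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy.integrate import IntegrationWarning, quad
from scipy.optimize import brentq

U_MAX = 0.04145


def _isocline_p(fill: float) -> float:
    """Solve the isocline exponent by quadrature of the curve itself."""

    def fillfun(x: float, p: float) -> float:
        return 1.0 - (1.0 - (1.0 - x) ** p) ** (1.0 / p)

    def area(p: float) -> float:
        # the curve has a steep corner for extreme p; split the domain and
        # silence quad's slow-convergence chatter (values are accurate)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IntegrationWarning)
            return quad(fillfun, 0.0, 1.0, args=(p,), limit=200)[0]

    return brentq(lambda p: area(p) - fill, 1e-3, 500.0, xtol=1e-10)


def _cell_unexpectedness(m: int, n: int, fill: float) -> tuple[np.ndarray, np.ndarray]:
    """Scalar per-position unexpectedness (presence-beyond, absence-within)."""
    p = _isocline_p(fill)

    def fillfun(x: float) -> float:
        return 1.0 - (1.0 - (1.0 - x) ** p) ** (1.0 / p)

    u_pres = np.zeros((m, n))
    u_abs = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            y = (i + 0.5) / m
            x = (j + 0.5) / n
            a = y - x  # diagonal through the cell: Y = X + a
            x_cross = brentq(lambda t: fillfun(t) - (t + a), 0.0, 1.0, xtol=1e-13)
            y_cross = x_cross + a
            length = 1.0 - abs(a)  # x-extent of the diagonal inside the square
            u = ((y - y_cross) / length) ** 2
            if y > y_cross:  # beyond the isocline: unexpected if presence
                u_pres[i, j] = u
            elif y < y_cross:  # within the nested region: unexpected if absence
                u_abs[i, j] = u
    return u_pres, u_abs


def _ordering_score(arr: np.ndarray, u_pres: np.ndarray, u_abs: np.ndarray) -> float:
    m, n = arr.shape
    total = 0.0
    for i in range(m):
        for j in range(n):
            if arr[i, j] == 1:
                if u_pres[i, j] > 0 and 0 in arr[: i + 1, : j + 1]:
                    total += u_pres[i, j]
            else:
                if u_abs[i, j] > 0 and 1 in arr[i:, j:]:
                    total += u_abs[i, j]
    return total


def exhaustive_temperature(arr: np.ndarray) -> float:
    """Minimum temperature over every row and column ordering."""
    arr = np.asarray(arr, dtype=int)
    m, n = arr.shape
    u_pres, u_abs = _cell_unexpectedness(m, n, arr.mean())
    best = np.inf
    for rows in itertools.permutations(range(m)):
        sub = arr[list(rows)]
        for cols in itertools.permutations(range(n)):
            best = min(best, _ordering_score(sub[:, list(cols)], u_pres, u_abs))
    return min(max(100.0 * best / (m * n) / U_MAX, 0.0), 100.0)


def _partitions(items: list[int]):
    """All set partitions of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in _partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [head]] + part[k + 1 :]
        yield [[head]] + part


def exhaustive_max_modularity(bi: np.ndarray) -> float:
    """Maximum Newman-Girvan Q over all partitions of the bipartite graph."""
    bi = np.asarray(bi, dtype=int)
    m, n = bi.shape
    k = m + n
    adj = np.zeros((k, k), dtype=int)
    adj[:m, m:] = bi
    adj[m:, :m] = bi.T
    L = bi.sum()
    deg = adj.sum(axis=1)
    best = -np.inf
    for part in _partitions(list(range(k))):
        q = 0.0
        for module in part:
            idx = np.array(module)
            e_c = adj[np.ix_(idx, idx)].sum() / 2
            d_c = deg[idx].sum()
            q += e_c / L - (d_c / (2 * L)) ** 2
        best = max(best, q)
    return best
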