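"""Nestedness as matrix temperature.

Matrix temperature measures how far a binary incidence matrix departs from
perfect nestedness, on a 0-100 scale: 0 for a perfectly nested matrix
(every specialist's diet a subset of every broader diet), larger values for
increasingly disordered interaction patterns.

The score of a given row/column ordering follows the isocline construction
of Rodriguez-Girones & Santamaria (2006).  Cell centers are mapped into the
unit square (generalist rows at the top, widely-used items at the left); an
isocline of perfect nestedness for the observed fill separates the expected
presence region (upper-left) from the expected absence region; each
presence beyond the isocline and each absence within it contributes an
"unexpectedness" equal to the squared distance from the isocline along the
cell's 45-degree diagonal, normalized by the diagonal's length.  The
temperature is the total unexpectedness scaled so that a maximally
disordered matrix scores near 100.

Two refinements keep the score faithful to the discrete notion of
nestedness:

* a cell on the geometrically "wrong" side of the isocline only counts if
  it also violates nestedness discretely -- a presence with at least one
  absence in its upper-left rectangle, or an absence with at least one
  presence in its lower-right rectangle.  This makes T exactly 0 for every
  perfectly nested (staircase) matrix, which a smooth isocline alone cannot
  guarantee.
* the reported temperature is the minimum over row/column orderings: tiny
  matrices are solved by exhaustive enumeration; larger ones by a
  degree-sorted start followed by seeded swap hill-climbing with restarts.

The temperature is therefore invariant to the ordering of the input rows
and columns.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .incidence import IncidenceMatrix

__all__ = ["matrix_temperature", "nestedness", "TemperatureResult", "EFFORT_PRESETS"]

#: Atmar & Patterson's normalization constant: expected unexpectedness of a
#: maximally disordered matrix.  T = 100 * U / U_MAX, clamped to [0, 100].
U_MAX = 0.04145

#: exhaustive enumeration is used when n_rows! * n_cols! is at most this
EXHAUSTIVE_LIMIT = 20_000

EFFORT_PRESETS: dict[str, dict[str, int]] = {
    "fast": {"restarts": 2, "iters_per_node": 30},
    "thorough": {"restarts": 8, "iters_per_node": 150},
}


@dataclass(frozen=True)
class TemperatureResult:
    """Minimum temperature found and the packed ordering achieving it."""

    temperature: float
    row_order: tuple[int, ...]
    col_order: tuple[int, ...]
    exhaustive: bool


def _isocline_exponent(fill: float) -> float:
    """Exponent p of the isocline family (1-x)^p + (1-y)^p = 1 for a given fill.

    The presence region {(1-x)^p + (1-y)^p > 1} has area
    1 - Gamma(1+1/p)^2 / Gamma(1+2/p), strictly decreasing in p, so p is
    found by bracketed root-finding on log10(p).  Fill values near 0 or 1
    are clamped to keep p in a numerically safe range.
    """

    def ball_area(log10_p: float) -> float:
        # area of the absence-side region {(1-x)^p + (1-y)^p < 1}; increasing in p
        p = 10.0**log10_p
        return math.exp(2.0 * gammaln(1.0 + 1.0 / p) - gammaln(1.0 + 2.0 / p))

    lo, hi = -2.5, 2.5
    target = 1.0 - fill  # area of the absence-side "ball"
    target = min(max(target, ball_area(lo)), ball_area(hi))
    log10_p = brentq(lambda lp: ball_area(lp) - target, lo, hi, xtol=1e-12)
    return 10.0**log10_p


def _position_unexpectedness(m: int, n: int, fill: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-position geometric unexpectedness grids ``(u_presence, u_absence)``.

    These depend only on matrix shape and fill, not on the arrangement, so
    any ordering of the same matrix can be scored by summing over them.
    ``u_presence[i, j]`` is the contribution of a presence at position
    (i, j) when it lies on the absence side of the isocline (0 otherwise);
    ``u_absence`` is the mirror case.
    """
    p = _isocline_exponent(fill)
    y = (np.arange(m)[:, None] + 0.5) / m  # row centers, top row near 0
    x = (np.arange(n)[None, :] + 0.5) / n
    y = np.broadcast_to(y, (m, n)).copy()
    x = np.broadcast_to(x, (m, n)).copy()

    # g > 0: presence side (toward the origin); g < 0: absence side
    g0 = (1.0 - x) ** p + (1.0 - y) ** p - 1.0

    # diagonal through the cell with direction (1, 1); g(t) decreases in t
    t_lo = -np.minimum(x, y)
    t_hi = np.minimum(1.0 - x, 1.0 - y)
    lo = t_lo.copy()
    hi = t_hi.copy()
    for _ in range(80):  # vectorized bisection for the isocline crossing
        mid = 0.5 * (lo + hi)
        gm = (1.0 - x - mid) ** p + (1.0 - y - mid) ** p - 1.0
        take_hi = gm > 0  # crossing lies beyond mid
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    t_cross = 0.5 * (lo + hi)

    with np.errstate(invalid="ignore", divide="ignore"):
        u_geom = (t_cross / (t_hi - t_lo)) ** 2
    u_geom = np.nan_to_num(u_geom)

    u_presence = np.where(g0 < 0.0, u_geom, 0.0)
    u_absence = np.where(g0 > 0.0, u_geom, 0.0)
    return u_presence, u_absence


def _score(
    arr: np.ndarray, u_presence: np.ndarray, u_absence: np.ndarray
) -> float:
    """Total unexpectedness of one arrangement (rows/cols already ordered)."""
    # presence violated iff an absence exists in its upper-left rectangle
    prefix_min = np.minimum.accumulate(np.minimum.accumulate(arr, axis=0), axis=1)
    # absence violated iff a presence exists in its lower-right rectangle
    suffix_max = np.maximum.accumulate(np.maximum.accumulate(arr[::-1, ::-1], axis=0), axis=1)[
        ::-1, ::-1
    ]
    pres = (arr == 1) & (prefix_min == 0)
    absn = (arr == 0) & (suffix_max == 1)
    return float(u_presence[pres].sum() + u_absence[absn].sum())


def _temperature_from_u(total_u: float, m: int, n: int) -> float:
    t = 100.0 * (total_u / (m * n)) / U_MAX
    return min(max(t, 0.0), 100.0)


def _canonical_start(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree-sorted initial ordering, canonical under input permutations.

    Rows and columns first receive permutation-invariant "colors" by
    iterated neighborhood refinement (degree, then the sorted multiset of
    neighbor colors), then sort by color with remaining ties broken by the
    bit pattern under the refined opposite-side order.  Any permutation of
    the same matrix therefore starts the search from the same arrangement,
    making the reported temperature independent of input row/column order.
    """
    m, n = arr.shape
    row_color: list = [int(d) for d in arr.sum(axis=1)]
    col_color: list = [int(d) for d in arr.sum(axis=0)]
    for _ in range(3):
        row_color_new = [
            (row_color[i], tuple(sorted((col_color[j] for j in np.flatnonzero(arr[i])), reverse=True)))
            for i in range(m)
        ]
        col_color_new = [
            (col_color[j], tuple(sorted((row_color[i] for i in np.flatnonzero(arr[:, j])), reverse=True)))
            for j in range(n)
        ]
        row_color, col_color = row_color_new, col_color_new
    col_keys = sorted(range(n), key=lambda j: col_color[j], reverse=True)
    row_keys = sorted(
        range(m), key=lambda i: (row_color[i], tuple(arr[i, col_keys])), reverse=True
    )
    col_keys = sorted(
        range(n), key=lambda j: (col_color[j], tuple(arr[row_keys, j])), reverse=True
    )
    return np.asarray(row_keys), np.asarray(col_keys)


def matrix_temperature(
    m: IncidenceMatrix,
    seed: int = 0,
    effort: str | dict = "thorough",
) -> TemperatureResult:
    """Minimum matrix temperature over row/column orderings.

    Parameters
    ----------
    m : IncidenceMatrix
        Valid matrix without all-zero rows or columns; at least 2 x 2.
    seed : int
        Seed for the stochastic ordering search (ignored when the matrix is
        small enough for exhaustive enumeration).
    effort : {"fast", "thorough"} or dict
        Search effort: number of restarts and hill-climbing iterations per
        node.  A dict may give ``restarts`` and ``iters_per_node`` directly.

    Returns
    -------
    TemperatureResult
        Temperature in [0, 100] plus the packed row and column orders
        (indices into the input matrix) achieving it.
    """
    arr = np.asarray(m.values, dtype=np.int8)
    n_rows, n_cols = arr.shape
    if n_rows < 2 or n_cols < 2:
        raise ValueError(f"undefined temperature for a {n_rows}x{n_cols} matrix (need >= 2x2)")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("matrix has all-zero rows or columns; prune before scoring")

    fill = arr.mean()
    u_pres, u_abs = _position_unexpectedness(n_rows, n_cols, fill)

    if math.factorial(n_rows) * math.factorial(n_cols) <= EXHAUSTIVE_LIMIT:
        best = (math.inf, None, None)
        for rp in itertools.permutations(range(n_rows)):
            sub = arr[list(rp)]
            for cp in itertools.permutations(range(n_cols)):
                s = _score(sub[:, list(cp)], u_pres, u_abs)
                if s < best[0]:
                    best = (s, rp, cp)
        return TemperatureResult(
            _temperature_from_u(best[0], n_rows, n_cols), best[1], best[2], True
        )

    if isinstance(effort, str):
        try:
            cfg = EFFORT_PRESETS[effort]
        except KeyError:
            raise ValueError(
                f"unknown effort preset {effort!r}; use {sorted(EFFORT_PRESETS)}"
            ) from None
    else:
        cfg = {**EFFORT_PRESETS["fast"], **dict(effort)}
    restarts = int(cfg["restarts"])
    iters = int(cfg["iters_per_node"]) * (n_rows + n_cols)

    rng = np.random.default_rng(seed)
    r0, c0 = _canonical_start(arr)
    best_s = math.inf
    best_orders: tuple[np.ndarray, np.ndarray] | None = None
    for restart in range(max(restarts, 1)):
        if restart == 0:
            rp, cp = r0.copy(), c0.copy()
        else:
            rp, cp = r0[rng.permutation(n_rows)], c0[rng.permutation(n_cols)]
        cur = _score(arr[np.ix_(rp, cp)], u_pres, u_abs)
        for _ in range(iters):
            if rng.random() < 0.5:
                i, j = rng.integers(0, n_rows, 2)
                rp[i], rp[j] = rp[j], rp[i]
                cand = _score(arr[np.ix_(rp, cp)], u_pres, u_abs)
                if cand <= cur:
                    cur = cand
                else:
                    rp[i], rp[j] = rp[j], rp[i]
            else:
                i, j = rng.integers(0, n_cols, 2)
                cp[i], cp[j] = cp[j], cp[i]
                cand = _score(arr[np.ix_(rp, cp)], u_pres, u_abs)
                if cand <= cur:
                    cur = cand
                else:
                    cp[i], cp[j] = cp[j], cp[i]
        if cur < best_s:
            best_s = cur
            best_orders = (rp.copy(), cp.copy())

    assert best_orders is not None
    return TemperatureResult(
        _temperature_from_u(best_s, n_rows, n_cols),
        tuple(int(i) for i in best_orders[0]),
        tuple(int(j) for j in best_orders[1]),
        False,
    )


def nestedness(temperature: float) -> float:
    """Map temperature T in [0, 100] to nestedness N = (100 - T) / 100."""
    if not 0.0 <= temperature <= 100.0:
        raise ValueError(f"temperature {temperature} outside [0, 100]")
    return (100.0 - temperature) / 100.0
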