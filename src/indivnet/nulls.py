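"""Erdos-Renyi null ensembles, Monte-Carlo significance, and SES.

The null hypothesis for any scalar network metric is that links form
independently at random in a matrix of the observed size.  Two variants are
provided: ``bernoulli_half`` (each individual-item link present with
probability 0.5) and ``match_connectance`` (exactly the observed number of
links, placed uniformly at random).  Significance comes from a two-sided
Monte-Carlo test with the plus-one correction; effect magnitude from the
standardized effect size

    SES = (Metric_obs - mean(Metric_sim)) / sd(Metric_sim)

whose null distribution is approximately standard normal, so |SES| > 2 is
read as a significant departure from chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .incidence import IncidenceMatrix
from .modularity import greedy_modularity_arrays
from .temperature import matrix_temperature, nestedness

__all__ = [
    "er_random_matrix",
    "monte_carlo_test",
    "standardized_effect_size",
    "NullTestResult",
    "DegenerateDrawError",
    "metric_evaluator",
]

ALPHA = 0.05  # nominal level of the Monte-Carlo test


class DegenerateDrawError(ValueError):
    """A null draw on which the requested metric is undefined."""


def er_random_matrix(
    n_rows: int,
    n_cols: int,
    mode: str = "bernoulli_half",
    c_obs: float | None = None,
    seed: int | np.random.Generator = 0,
) -> IncidenceMatrix:
    """One Erdos-Renyi random incidence matrix.

    ``bernoulli_half`` sets each cell to 1 independently with probability
    0.5; ``match_connectance`` places exactly ``round(c_obs * n_rows *
    n_cols)`` links uniformly at random.  Draws with empty rows or columns
    are returned as-is; the caller decides whether the metric is defined on
    them.  Passing the same seed yields the identical matrix.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("matrix dimensions must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "bernoulli_half":
        values = (rng.random((n_rows, n_cols)) < 0.5).astype(np.int8)
    elif mode == "match_connectance":
        if c_obs is None:
            raise ValueError("match_connectance mode requires c_obs")
        n_links = int(round(c_obs * n_rows * n_cols))
        if n_links <= 0 or n_links >= n_rows * n_cols:
            raise ValueError(
                f"impossible fill: {n_links} links in a {n_rows}x{n_cols} matrix"
            )
        values = np.zeros(n_rows * n_cols, dtype=np.int8)
        values[rng.choice(n_rows * n_cols, size=n_links, replace=False)] = 1
        values = values.reshape(n_rows, n_cols)
    else:
        raise ValueError(f"unknown null mode {mode!r}")
    rows = tuple(f"i{k:03d}" for k in range(n_rows))
    cols = tuple(f"r{k:03d}" for k in range(n_cols))
    return IncidenceMatrix(rows, cols, values)


def metric_evaluator(
    name: str, seed: int = 0, effort: str | dict = "fast", tie_rule: str = "lex"
) -> Callable[[IncidenceMatrix], float]:
    """Scalar metric function by name, hardened for degenerate null draws.

    ``"nestedness"`` and ``"temperature"`` prune empty rows/columns before
    scoring and raise :class:`DegenerateDrawError` when fewer than 2 rows
    or columns survive; ``"modularity"`` raises it on edgeless draws;
    ``"connectance"`` is always defined.
    """

    def _temperature(m: IncidenceMatrix) -> float:
        try:
            pruned = m.prune()
        except ValueError as exc:
            raise DegenerateDrawError(str(exc)) from exc
        if min(pruned.shape) < 2:
            raise DegenerateDrawError("pruned matrix smaller than 2x2")
        return matrix_temperature(pruned, seed=seed, effort=effort).temperature

    if name == "temperature":
        return _temperature
    if name == "nestedness":
        return lambda m: nestedness(_temperature(m))
    if name == "modularity":

        def _modularity(m: IncidenceMatrix) -> float:
            if m.n_links == 0:
                raise DegenerateDrawError("edgeless draw")
            return greedy_modularity_arrays(m.values, tie_rule=tie_rule)[0]

        return _modularity
    if name == "connectance":
        return lambda m: m.n_links / (m.shape[0] * m.shape[1])
    raise ValueError(f"unknown metric {name!r}")


@dataclass(frozen=True)
class NullTestResult:
    """Observed metric against an Erdos-Renyi null ensemble."""

    metric_name: str
    observed: float
    null_values: tuple[float, ...] = field(repr=False)
    n_sim: int
    p_value: float
    ses: float
    significant: bool
    mode: str
    seed: int
    n_redraws: int = 0

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1))


def standardized_effect_size(observed: float, null_values: Sequence[float]) -> float:
    """SES = (observed - mean(null)) / sd(null), with sample (n-1) sd.

    Values above 2 (below -2) indicate a metric significantly higher
    (lower) than expected under the null, by the normal approximation.
    """
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size < 2:
        raise ValueError("SES requires at least 2 null values")
    sd = float(np.std(nulls, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate null ensemble: zero standard deviation")
    return (float(observed) - float(nulls.mean())) / sd


def monte_carlo_test(
    observed: float,
    metric_fn: Callable[[IncidenceMatrix], float],
    template: IncidenceMatrix,
    n_sim: int = 1000,
    mode: str = "bernoulli_half",
    seed: int = 0,
    metric_name: str = "metric",
    redraw_limit: int = 100,
) -> NullTestResult:
    """Two-sided Monte-Carlo test of an observed metric against ER draws.

    ``n_sim`` random matrices of the template's shape (and, for
    ``match_connectance``, its connectance) are scored with ``metric_fn``.
    The two-sided p-value uses the plus-one correction:

        p = min(1, 2 * min( (#{sim >= obs} + 1) / (n_sim + 1),
                            (#{sim <= obs} + 1) / (n_sim + 1) ))

    Draws on which the metric is undefined (:class:`DegenerateDrawError`)
    are redrawn, up to ``redraw_limit`` times in total.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    n_rows, n_cols = template.shape
    c_obs = template.n_links / (n_rows * n_cols)
    rng = np.random.default_rng(seed)
    nulls: list[float] = []
    redraws = 0
    while len(nulls) < n_sim:
        draw = er_random_matrix(n_rows, n_cols, mode=mode, c_obs=c_obs, seed=rng)
        try:
            nulls.append(float(metric_fn(draw)))
        except DegenerateDrawError:
            redraws += 1
            if redraws > redraw_limit:
                raise RuntimeError(
                    f"metric {metric_name!r} undefined on more than "
                    f"{redraw_limit} null draws"
                )
    arr = np.asarray(nulls)
    p_high = (int((arr >= observed).sum()) + 1) / (n_sim + 1)
    p_low = (int((arr <= observed).sum()) + 1) / (n_sim + 1)
    p = min(1.0, 2.0 * min(p_high, p_low))
    sd = float(np.std(arr, ddof=1))
    ses = (observed - float(arr.mean())) / sd if sd > 0 else math.nan
    return NullTestResult(
        metric_name=metric_name,
        observed=float(observed),
        null_values=tuple(arr.tolist()),
        n_sim=n_sim,
        p_value=p,
        ses=ses,
        significant=p < ALPHA,
        mode=mode,
        seed=seed,
        n_redraws=redraws,
    )
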