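"""Descriptors of individual-resource networks.

Connectance, per-individual degree distribution, Chao1 sampling coverage,
nestedness (via matrix temperature) and fast-greedy modularity, with a
convenience wrapper gathering them into one record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .incidence import IncidenceMatrix
from .modularity import fast_greedy_modularity
from .temperature import matrix_temperature, nestedness

__all__ = [
    "connectance",
    "degree_distribution",
    "chao1",
    "Chao1Result",
    "NetworkMetrics",
    "compute_network_metrics",
]


def connectance(m: IncidenceMatrix) -> float:
    """Realized fraction of possible links: L / (rows * cols)."""
    n_rows, n_cols = m.shape
    return m.n_links / (n_rows * n_cols)


def degree_distribution(m: IncidenceMatrix) -> dict[int, float]:
    """Proportion of individuals interacting with each number of food items.

    Keys are observed row degrees (>= 1 on a pruned matrix); values sum
    to 1.
    """
    degrees = m.values.sum(axis=1)
    counts: dict[int, int] = {}
    for deg in degrees:
        counts[int(deg)] = counts.get(int(deg), 0) + 1
    total = sum(counts.values())
    return {deg: counts[deg] / total for deg in sorted(counts)}


@dataclass(frozen=True)
class Chao1Result:
    """Chao1 richness estimate and the implied sampling coverage."""

    s_obs: int
    f1: int
    f2: int
    s_est: float
    coverage: float


def chao1(item_frequencies: Mapping[str, int]) -> Chao1Result:
    """Chao1 estimator of food-item richness from occurrence frequencies.

    ``item_frequencies`` maps each observed item to the number of
    individuals consuming it.  With f1 singletons and f2 doubletons,

        S_est = S_obs + f1^2 / (2 f2)            if f2 > 0
        S_est = S_obs + f1 (f1 - 1) / 2          if f2 = 0 (bias-corrected)

    Coverage ``S_obs / S_est`` equals 1 exactly when no item is a
    singleton: the inventory is then judged complete.
    """
    if not item_frequencies:
        raise ValueError("chao1 requires at least one observed item")
    freqs = list(item_frequencies.values())
    if any(f < 1 for f in freqs):
        raise ValueError("item frequencies must be >= 1")
    s_obs = len(freqs)
    f1 = sum(1 for f in freqs if f == 1)
    f2 = sum(1 for f in freqs if f == 2)
    if f2 > 0:
        s_est = s_obs + f1 * f1 / (2.0 * f2)
    else:
        s_est = s_obs + f1 * (f1 - 1) / 2.0
    return Chao1Result(s_obs, f1, f2, float(s_est), s_obs / s_est)


@dataclass(frozen=True)
class NetworkMetrics:
    """All network descriptors of one site x season incidence matrix."""

    connectance: float
    degree_distribution: dict[int, float] = field(repr=False)
    temperature: float
    nestedness: float
    modularity: float
    module_assignment: dict[str, int] = field(repr=False)
    chao1: Chao1Result


def compute_network_metrics(
    m: IncidenceMatrix,
    seed: int = 0,
    effort: str | dict = "thorough",
    tie_rule: str = "lex",
) -> NetworkMetrics:
    """Compute every descriptor of one incidence matrix in one pass."""
    temp = matrix_temperature(m, seed=seed, effort=effort)
    mod = fast_greedy_modularity(m, tie_rule=tie_rule)
    item_freq = {
        label: int(count)
        for label, count in zip(m.col_labels, np.asarray(m.values).sum(axis=0))
    }
    return NetworkMetrics(
        connectance=connectance(m),
        degree_distribution=degree_distribution(m),
        temperature=temp.temperature,
        nestedness=nestedness(temp.temperature),
        modularity=mod.q,
        module_assignment=mod.membership,
        chao1=chao1(item_freq),
    )
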