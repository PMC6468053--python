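"""Environmental predictors and metric ~ environment regressions.

Food-resource availability enters as three predictors per site x season:
the exponential Shannon diversity of arthropod dry mass across orders (a
Hill number: the effective number of equally common orders), the total
arthropod dry mass, and the log-transformed fruit count.  Habitat
structure is summarized by a PCA of eight Z-scored structural variables
measured at sampling stations; the mean PC1 and PC2 station scores per
site x season act as two further predictors.  Network metrics are then
regressed on each predictor with ordinary least squares, one simple
regression per (predictor, metric) pair, and predictor collinearity is
screened with Spearman rank correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HABITAT_VARIABLES",
    "shannon_exp_diversity",
    "fruit_predictor",
    "habitat_pca",
    "HabitatPCA",
    "fit_metric_regression",
    "RegressionResult",
    "collinearity_screen",
    "build_env_predictors",
]

#: the eight habitat-structure variables measured at each station
HABITAT_VARIABLES: tuple[str, ...] = (
    "understory_obstruction",
    "herbaceous_obstruction",
    "canopy_openness",
    "canopy_connectivity",
    "litter_depth",
    "tree_dbh",
    "tree_distance",
    "tree_height",
)


def shannon_exp_diversity(mass_by_order: Mapping[str, float]) -> float:
    """Exponential Shannon diversity exp(H') of arthropod dry mass.

    Proportions are dry masses over the total; zero-mass orders are
    dropped.  Returns the Hill number of order 1: between 1 (a single
    order) and the number of orders (perfectly even masses).
    """
    masses = np.asarray([v for v in mass_by_order.values()], dtype=float)
    if (masses < 0).any():
        raise ValueError("arthropod masses must be non-negative")
    masses = masses[masses > 0]
    if masses.size == 0:
        raise ValueError("diversity undefined: no positive mass")
    p = masses / masses.sum()
    return float(np.exp(-np.sum(p * np.log(p))))


def fruit_predictor(count: int, base: str = "log10") -> float:
    """Log-transformed fruit count, ``log(count + 1)``.

    The +1 offset keeps zero counts defined; ``base`` may be ``"log10"``
    (default) or ``"ln"``.
    """
    if count < 0:
        raise ValueError("fruit count must be non-negative")
    if base == "log10":
        return math.log10(count + 1)
    if base == "ln":
        return math.log(count + 1)
    raise ValueError(f"unknown log base {base!r}; use 'log10' or 'ln'")


@dataclass(frozen=True)
class HabitatPCA:
    """PCA of Z-scored habitat variables pooled over sites and seasons."""

    loadings: pd.DataFrame = field(repr=False)  # variables x components
    variance_fractions: tuple[float, ...]
    scores: pd.DataFrame = field(repr=False)  # stations x (site, season, PCs)
    site_season_means: pd.DataFrame = field(repr=False)  # per site x season PC1/PC2


def habitat_pca(
    samples: pd.DataFrame, variables: Sequence[str] = HABITAT_VARIABLES
) -> HabitatPCA:
    """Principal components of habitat structure across stations.

    Parameters
    ----------
    samples : DataFrame
        One row per station with ``site`` and ``season`` columns plus the
        habitat variables (station values already averaged over quadrants).
        Stations from all sites and seasons are pooled into a single PCA.
    variables : sequence of str
        Habitat variable columns to use.

    Notes
    -----
    Each variable is Z-scored over the pooled stations, the correlation
    matrix is eigen-decomposed, and the sign of each axis is fixed so its
    largest-magnitude loading is positive.  Returns loadings, the variance
    fraction of every axis, per-station scores, and the mean PC1/PC2 score
    per site x season (the regression predictors).
    """
    variables = list(variables)
    missing = [v for v in variables if v not in samples.columns]
    if missing:
        raise ValueError(f"habitat table lacks variables: {missing}")
    if len(samples) <= len(variables):
        raise ValueError(
            f"need more stations ({len(samples)}) than variables ({len(variables)})"
        )
    x = samples[variables].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant habitat variable: {variables[constant[0]]!r}")
    z = (x - mean) / sd

    corr = (z.T @ z) / (len(z) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for axis in range(eigvecs.shape[1]):  # sign convention
        lead = np.argmax(np.abs(eigvecs[:, axis]))
        if eigvecs[lead, axis] < 0:
            eigvecs[:, axis] *= -1
    fractions = tuple(float(v) for v in eigvals / eigvals.sum())

    pc_names = [f"PC{k + 1}" for k in range(len(variables))]
    loadings = pd.DataFrame(eigvecs, index=variables, columns=pc_names)
    score_values = z @ eigvecs
    scores = samples[["site", "season"]].copy().reset_index(drop=True)
    scores[pc_names] = score_values
    means = (
        scores.groupby(["site", "season"], sort=True, observed=True)[["PC1", "PC2"]]
        .mean()
        .rename(columns={"PC1": "pc1_score", "PC2": "pc2_score"})
        .reset_index()
    )
    return HabitatPCA(loadings, fractions, scores, means)


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS fit of one network metric on one predictor."""

    predictor: str
    response: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def fit_metric_regression(
    x: Sequence[float],
    y: Sequence[float],
    predictor: str = "x",
    response: str = "y",
) -> RegressionResult:
    """Ordinary least squares ``y = a + b x`` with a two-sided p for b.

    One point per site x season; trend lines are reported as significant
    at p < 0.05.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        predictor=predictor,
        response=response,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def collinearity_screen(
    predictors: pd.DataFrame, columns: Sequence[str] | None = None, flag_p: float = 0.1
) -> pd.DataFrame:
    """Pairwise Spearman correlations between predictors.

    Returns one row per unordered pair with rho, the p-value, and a
    ``flagged`` column marking pairs with p <= ``flag_p`` (candidate
    collinearity).  Constant predictors yield an undefined (NaN) rho,
    reported as such.
    """
    cols = list(columns) if columns is not None else [
        c for c in predictors.columns if pd.api.types.is_numeric_dtype(predictors[c])
    ]
    if len(predictors) < 4:
        raise ValueError("collinearity screen needs at least 4 rows")
    out = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            xa = predictors[a].to_numpy(dtype=float)
            xb = predictors[b].to_numpy(dtype=float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                rho, p = math.nan, math.nan
            else:
                rho, p = stats.spearmanr(xa, xb)
            out.append(
                {
                    "var_a": a,
                    "var_b": b,
                    "rho": float(rho),
                    "p_value": float(p),
                    "flagged": bool(p <= flag_p) if not math.isnan(p) else False,
                }
            )
    return pd.DataFrame(out)


def build_env_predictors(
    resources: pd.DataFrame,
    habitat: HabitatPCA,
    fruit_log_base: str = "log10",
) -> pd.DataFrame:
    """Assemble the per-site x season predictor table.

    ``resources`` needs one row per site x season with ``site``, ``season``,
    ``fruit_count`` and one ``mass_<order>`` column per arthropod order.
    Returns columns: site, season, arthropod_diversity, arthropod_total_mass,
    log_fruit, pc1_score, pc2_score.
    """
    mass_cols = [c for c in resources.columns if c.startswith("mass_")]
    if not mass_cols:
        raise ValueError("resource table has no mass_<order> columns")
    rows = []
    for _, rec in resources.iterrows():
        masses = {c: float(rec[c]) for c in mass_cols}
        rows.append(
            {
                "site": rec["site"],
                "season": rec["season"],
                "arthropod_diversity": shannon_exp_diversity(masses),
                "arthropod_total_mass": float(sum(masses.values())),
                "log_fruit": fruit_predictor(int(rec["fruit_count"]), base=fruit_log_base),
            }
        )
    table = pd.DataFrame(rows)
    return table.merge(habitat.site_season_means, on=["site", "season"], how="left")
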