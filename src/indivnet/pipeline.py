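"""Whole-study orchestration: matrices -> metrics -> nulls -> regressions.

``run_study`` drives the complete site x season analysis from a single
YAML (or dict) configuration: build or simulate the incidence matrices,
compute network descriptors, test nestedness and modularity against
Erdos-Renyi null ensembles, assemble environmental predictors, and regress
each metric on each predictor.  Every source of randomness flows from the
manifest seed, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diet import Season, build_incidence, dedupe_one_per_season, read_diet_records
from .envstats import build_env_predictors, collinearity_screen, fit_metric_regression, habitat_pca
from .incidence import IncidenceMatrix
from .metrics import chao1, connectance, degree_distribution
from .modularity import fast_greedy_modularity
from .nulls import metric_evaluator, monte_carlo_test
from .simulate import EnvironmentDesign, StudyDesign, generate_study
from .temperature import matrix_temperature, nestedness

__all__ = ["run_study", "sampling_effort", "StudyReport", "DEFAULT_CONFIG"]

log = logging.getLogger("indivnet")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "null": {"mode": "bernoulli_half", "n_sim": 1000, "metrics": ["nestedness", "modularity"]},
    "metrics": {"effort": "thorough", "tie_rule": "lex"},
    "report": {"regress_connectance": False, "fruit_log_base": "log10"},
}

#: predictors entering the metric regressions
PREDICTORS = ("arthropod_diversity", "arthropod_total_mass", "log_fruit", "pc1_score", "pc2_score")


@dataclasses.dataclass(frozen=True)
class StudyReport:
    """Result of one full study run."""

    rows: pd.DataFrame = dataclasses.field(repr=False)
    regressions: pd.DataFrame = dataclasses.field(repr=False)
    collinearity: pd.DataFrame = dataclasses.field(repr=False)
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        """Write report.csv, regressions.csv and report.json under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "report.csv", index=False)
        self.regressions.to_csv(out / "regressions.csv", index=False)
        payload = {
            "manifest": self.manifest,
            "rows": self.rows.to_dict(orient="records"),
            "regressions": self.regressions.to_dict(orient="records"),
            "collinearity": self.collinearity.to_dict(orient="records"),
        }
        (out / "report.json").write_text(json.dumps(payload, sort_keys=True, indent=1))


def sampling_effort(
    grids: int,
    traps_per_night: int,
    nights_per_session: int,
    sessions_per_season: int,
    seasons: int,
) -> int:
    """Total trapping effort in trap-nights: the product of design constants."""
    values = (grids, traps_per_night, nights_per_session, sessions_per_season, seasons)
    if any(int(v) != v or v < 1 for v in values):
        raise ValueError("all design constants must be positive integers")
    return int(np.prod([int(v) for v in values]))


def _load_config(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in dict(config).items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _matrices_from_data(cfg: Mapping[str, Any]) -> dict[tuple[str, str], IncidenceMatrix]:
    data = cfg["data"]
    records = read_diet_records(
        data["records"],
        delimiter=data.get("delimiter", "\t"),
        season_aliases=data.get("season_aliases"),
    )
    records = dedupe_one_per_season(records, rule=data.get("dedupe_rule", "first"))
    sites = data.get("sites") or sorted({r.site for r in records})
    out: dict[tuple[str, str], IncidenceMatrix] = {}
    for site in sites:
        for season in Season:
            out[(site, season.value)] = build_incidence(records, site, season)
    return out


def run_study(config: str | Path | Mapping[str, Any]) -> StudyReport:
    """Run the full analysis described by a configuration.

    The configuration holds either a ``simulate`` block (a
    :class:`~indivnet.simulate.StudyDesign` as nested mappings) or a
    ``data`` block naming the record and covariate files, plus ``null``,
    ``metrics`` and ``report`` sections.  Returns a :class:`StudyReport`
    with one row per site x season, the regression table, the predictor
    collinearity screen, and the run manifest.
    """
    cfg = _load_config(config)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    null_cfg = cfg["null"]
    met_cfg = cfg["metrics"]
    rep_cfg = cfg["report"]

    stage = "inputs"
    try:
        if "simulate" in cfg:
            sim_cfg = dict(cfg["simulate"] or {})
            env = EnvironmentDesign(**{
                k: _tupled(v) for k, v in sim_cfg.pop("environment", {}).items()
            })
            design = StudyDesign(**{k: _tupled(v) for k, v in sim_cfg.items()}, environment=env)
            study = generate_study(design, seed=int(rng.integers(2**31)))
            matrices = study.matrices
            resources, habitat = study.resources, study.habitat
            sim_manifest = study.manifest
        elif "data" in cfg:
            matrices = _matrices_from_data(cfg)
            resources = pd.read_csv(cfg["data"]["resources"])
            habitat = pd.read_csv(cfg["data"]["habitat"])
            sim_manifest = None
        else:
            raise ValueError("config needs a 'simulate' or a 'data' section")

        stage = "habitat_pca"
        pca = habitat_pca(habitat)
        stage = "env_predictors"
        predictors = build_env_predictors(
            resources, pca, fruit_log_base=rep_cfg.get("fruit_log_base", "log10")
        )

        rows = []
        for (site, season), matrix in sorted(matrices.items()):
            stage = f"metrics[{site}/{season}]"
            matrix = matrix.prune()
            n_ind, n_item = matrix.shape
            temp_seed = int(rng.integers(2**31))
            null_seeds = {m: int(rng.integers(2**31)) for m in ("nestedness", "modularity")}
            temp = matrix_temperature(matrix, seed=temp_seed, effort=met_cfg["effort"])
            mod = fast_greedy_modularity(matrix, tie_rule=met_cfg["tie_rule"])
            cov = chao1(
                {c: int(k) for c, k in zip(matrix.col_labels, matrix.values.sum(axis=0))}
            )
            row = {
                "site": site,
                "season": season,
                "n_individuals": n_ind,
                "n_items": n_item,
                "n_links": matrix.n_links,
                "connectance": connectance(matrix),
                "temperature": temp.temperature,
                "nestedness": nestedness(temp.temperature),
                "modularity": mod.q,
                "n_modules": mod.n_modules,
                "chao1_coverage": cov.coverage,
                "degree_distribution": json.dumps(
                    {str(k): v for k, v in degree_distribution(matrix).items()}
                ),
            }
            observed = {"nestedness": row["nestedness"], "modularity": row["modularity"]}
            for metric in null_cfg["metrics"]:
                stage = f"null[{metric}][{site}/{season}]"
                result = monte_carlo_test(
                    observed[metric],
                    metric_evaluator(metric, seed=temp_seed, effort=met_cfg["effort"],
                                     tie_rule=met_cfg["tie_rule"]),
                    matrix,
                    n_sim=int(null_cfg["n_sim"]),
                    mode=null_cfg["mode"],
                    seed=null_seeds[metric],
                    metric_name=metric,
                )
                row[f"{metric}_p"] = result.p_value
                row[f"{metric}_ses"] = result.ses
                row[f"{metric}_null_mean"] = result.null_mean
                row[f"{metric}_null_sd"] = result.null_sd
                row[f"{metric}_redraws"] = result.n_redraws
                log.info(
                    "%s/%s %s: obs=%.4f p=%.4f ses=%.2f (redraws=%d)",
                    site, season, metric, observed[metric], result.p_value,
                    result.ses, result.n_redraws,
                )
            rows.append(row)

        stage = "report"
        table = pd.DataFrame(rows).merge(predictors, on=["site", "season"], how="left")

        responses = list(null_cfg["metrics"]) or ["nestedness", "modularity"]
        if rep_cfg.get("regress_connectance"):
            responses = responses + ["connectance"]
        fits = []
        for response in responses:
            for predictor in PREDICTORS:
                fit = fit_metric_regression(
                    table[predictor], table[response], predictor=predictor, response=response
                )
                fits.append(dataclasses.asdict(fit) | {"significant": fit.significant})
        regressions = pd.DataFrame(fits)
        screen = collinearity_screen(table, columns=list(PREDICTORS))

        manifest = {
            "indivnet_version": __version__,
            "seed": seed,
            "null": null_cfg,
            "metrics": met_cfg,
            "report": rep_cfg,
            "simulation": sim_manifest,
        }
        return StudyReport(table, regressions, screen, manifest)
    except Exception as exc:
        raise RuntimeError(f"study failed at stage {stage!r}: {exc}") from exc


def _tupled(value: Any) -> Any:
    return tuple(value) if isinstance(value, list) else value
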