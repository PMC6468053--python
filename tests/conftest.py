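"""Shared fixtures: small matrices and a field-study-shaped record set."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from indivnet import DietRecord, IncidenceMatrix, Season

#: per-site (cool_dry, warm_wet) retained-sample counts of the study design
#: the record fixture emulates; 374 samples of 319 individuals in total.
SITE_SEASON_COUNTS = {
    "FAL": (44, 72),
    "EEJBB1": (36, 52),
    "EEJBB2": (48, 58),
    "EEJBB3": (37, 27),
}
#: individuals sampled in both seasons at each site (374 - 319 = 55 total)
RECAPTURED_ACROSS_SEASONS = {"FAL": 17, "EEJBB1": 13, "EEJBB2": 15, "EEJBB3": 10}

FOOD_ITEMS = [
    "Coleoptera", "Hymenoptera", "Isoptera", "Orthoptera", "Araneae",
    "Hemiptera", "Lepidoptera", "Diptera", "Blattodea", "Scorpiones",
    "Miconia_pulp", "Miconia_seeds", "Solanum_pulp", "Solanum_seeds",
    "Cecropia_fiber", "fruit_fiber_A", "fruit_fiber_B", "fruit_fiber_C",
    "bird_feathers", "bird_bones",
]


def random_incidence(n_rows: int, n_cols: int, fill: float, seed: int) -> IncidenceMatrix:
    """Random matrix without empty rows/columns (redrawn until valid)."""
    rng = np.random.default_rng(seed)
    while True:
        arr = (rng.random((n_rows, n_cols)) < fill).astype(np.int8)
        if (arr.sum(1) > 0).all() and (arr.sum(0) > 0).all():
            return IncidenceMatrix(
                tuple(f"i{k}" for k in range(n_rows)),
                tuple(f"r{k}" for k in range(n_cols)),
                arr,
            )


@pytest.fixture(scope="session")
def study_records() -> list[DietRecord]:
    """Diet records shaped like the field study.

    Each site x season has the target number of retained individuals; about
    15% of them carry a second within-season capture (which deduplication
    must drop), and a fixed number of individuals per site appear in both
    seasons (recaptures across seasons are retained once per season).
    """
    rng = np.random.default_rng(20090501)
    records: list[DietRecord] = []
    base_date = {Season.COOL_DRY: dt.date(2009, 6, 1), Season.WARM_WET: dt.date(2009, 11, 1)}
    for site, (n_dry, n_wet) in SITE_SEASON_COUNTS.items():
        n_both = RECAPTURED_ACROSS_SEASONS[site]
        ids_dry = [f"{site}_ind{k:03d}" for k in range(n_dry)]
        # the first n_both dry-season individuals reappear in the wet season
        ids_wet = ids_dry[:n_both] + [
            f"{site}_ind{k:03d}" for k in range(n_dry, n_dry + n_wet - n_both)
        ]
        for season, ids in ((Season.COOL_DRY, ids_dry), (Season.WARM_WET, ids_wet)):
            for ind in ids:
                n_caps = 2 if rng.random() < 0.15 else 1  # within-season recapture
                for cap in range(n_caps):
                    date = base_date[season] + dt.timedelta(days=int(rng.integers(0, 60)) + cap)
                    items = rng.choice(FOOD_ITEMS, size=int(rng.integers(1, 5)), replace=False)
                    for item in items:
                        records.append(
                            DietRecord(ind, site, season, str(item), capture_date=date)
                        )
    return records
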