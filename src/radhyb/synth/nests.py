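"""Synthetic nest records with group-dependent clutch outcomes.

Clutch size is a rounded normal draw (minimum 1 egg); hatched eggs are a
binomial draw at the group hatch probability; a small fraction of hatched
individuals is found dead at excavation, so that the excavation counts
(eggshells, dead, unhatched) reconstruct the clutch exactly:
live = eggshells - dead and clutch = unhatched + dead + live.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .config import SimConfig

SEASON_START = dt.date(2019, 9, 1)
DEAD_FRACTION = 0.03


def simulate_nests(
    config: SimConfig, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate one season of nest records for all configured groups."""
    config.validate()
    if isinstance(seed, np.random.Generator):
        rng = seed
    elif seed is not None:
        rng = np.random.default_rng(seed)
    else:
        rng = config.rng("nests")

    rows = []
    nest_no = 0
    for group in sorted(config.nest_params):
        params = config.nest_params[group]
        for _ in range(params.n_nests):
            nest_no += 1
            clutch = max(1, int(round(rng.normal(params.clutch_mean, params.clutch_sd))))
            hatched = int(rng.binomial(clutch, params.hatch_prob))
            dead = int(rng.binomial(hatched, DEAD_FRACTION))
            incubation = max(40, int(round(rng.normal(params.incubation_mean, params.incubation_sd))))
            ovip = SEASON_START + dt.timedelta(days=int(rng.integers(0, 120)))
            rows.append(
                {
                    "nest_id": f"N{nest_no:03d}",
                    "group": group,
                    "oviposition_date": ovip.isoformat(),
                    "emergence_date": (ovip + dt.timedelta(days=incubation)).isoformat(),
                    "eggshells": hatched,
                    "dead_hatchlings": dead,
                    "unhatched_eggs": clutch - hatched,
                    "female_id": "",
                    "true_clutch": clutch,
                    "true_hatch_prob": params.hatch_prob,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "nest_id", "group", "oviposition_date", "emergence_date",
            "eggshells", "dead_hatchlings", "unhatched_eggs", "female_id",
            "true_clutch", "true_hatch_prob",
        ],
    )
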