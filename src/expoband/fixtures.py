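"""Packaged validation datasets for the styrene FRP-lamination study.

The package ships the study's situation-level data as plain-text fixtures:

* ``factor_table`` — the default modifying-factor score table (YAML)
* ``category_bands`` — the four exposure-category score bands (YAML)
* ``frp_ship_profile`` — the worked-example situation profile: FRP
  lamination (UPR spraying/coating) for ship manufacturing (YAML)
* ``measurement_summaries`` — per-company styrene measurement summaries
  (n, AM, GM, GSD, min, max in ppm; 22 lamination + 14 inspection rows,
  160 personal 8h-TWA samples in total)
* ``measurement_totals`` — the published per-task pooled summary rows
* ``model_estimates`` — per-company external model estimates
  (daily average / 50th / 90th percentile, ppm) alongside the new model's
  exposure score and category

Individual measurement values were never published; ``expoband.simulate``
generates synthetic stand-ins from the summaries.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .factors import (
    CategoryBands,
    FactorTable,
    SituationProfile,
    load_category_bands,
    load_factor_table,
)
from .stats import MeasurementSummary

__all__ = ["FIXTURE_NAMES", "load_fixture", "summaries_from_frame", "load_profiles"]

FIXTURE_NAMES = (
    "factor_table",
    "category_bands",
    "frp_ship_profile",
    "measurement_summaries",
    "measurement_totals",
    "model_estimates",
)


def _read_csv(name: str) -> pd.DataFrame:
    with (resources.files("expoband.data") / name).open() as fh:
        return pd.read_csv(fh)


def profile_from_dict(doc: dict) -> SituationProfile:
    return SituationProfile(
        situation_id=str(doc["situation_id"]),
        task_label=str(doc.get("task_label", "")),
        phase=str(doc["phase"]),
        selections={str(k): str(v) for k, v in doc["selections"].items()},
    )


def load_profiles(path) -> list[SituationProfile]:
    """Situation profiles from a YAML file (single mapping or a list)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    docs = doc if isinstance(doc, list) else [doc]
    return [profile_from_dict(d) for d in docs]


def load_fixture(
    name: str,
) -> FactorTable | CategoryBands | SituationProfile | pd.DataFrame:
    """Load one packaged dataset by name (see FIXTURE_NAMES)."""
    if name == "factor_table":
        return load_factor_table()
    if name == "category_bands":
        return load_category_bands()
    if name == "frp_ship_profile":
        with (resources.files("expoband.data") / "frp_ship_profile.yaml").open() as fh:
            return profile_from_dict(yaml.safe_load(fh))
    if name == "measurement_summaries":
        return _read_csv("measurement_summaries.csv")
    if name == "measurement_totals":
        return _read_csv("measurement_totals.csv")
    if name == "model_estimates":
        return _read_csv("model_estimates.csv")
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")


def summaries_from_frame(df: pd.DataFrame) -> list[MeasurementSummary]:
    """MeasurementSummary objects from a summary-format DataFrame.

    Expects columns situation_id, n, am_ppm (or am), gm_ppm (or gm), gsd,
    min_ppm, max_ppm; a missing/NaN GSD marks a singleton group.
    """
    def col(row, *names, default=np.nan):
        for c in names:
            if c in row:
                return row[c]
        return default

    out = []
    for _, row in df.iterrows():
        gsd = col(row, "gsd")
        gm = float(col(row, "gm_ppm", "gm"))
        out.append(
            MeasurementSummary(
                situation_id=str(row["situation_id"]),
                n=int(row["n"]),
                am=float(col(row, "am_ppm", "am", default=gm)),
                gm=gm,
                gsd=None if pd.isna(gsd) else float(gsd),
                vmin=float(col(row, "min_ppm", "min", default=gm)),
                vmax=float(col(row, "max_ppm", "max", default=gm)),
            )
        )
    return out
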