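"""Monitoring-table I/O: CSV schemas, validation, harvest conventions, metadata.

The canonical tidy layout has one row per (population, year):

====================  =======================================================
column                meaning
====================  =======================================================
population            optional label when a file holds several populations
year                  survey year (strictly increasing within population)
pre_calves, pre_fy    early-summer structure counts (calves / FY composite)
post_calves,          autumn post-harvest structure counts
post_females,
post_males
harvest_cF .. adM     six-class harvest off-take (complete, no missing values)
tot                   optional winter total count
====================  =======================================================

Alternatively harvest may come in the three classes hunters report —
``harvest_calves``, ``harvest_females``, ``harvest_males`` — which are expanded
to six classes by splitting calves 50:50 by sex (odd animal to the male class)
and assigning the composite yearling+older off-take per sex to the adult class.
The model's likelihood depends only on within-sex yearling+adult sums, so this
allocation does not alter the fit.

Missing survey values are empty cells (NaN), never zeroes. A ``schema_map``
(our name -> file's column name) adapts files with different headers without
editing them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .demography import CLASSES
from .simulate import SimulationTruth, SurveyDataset

__all__ = [
    "MonitoringTable",
    "SchemaError",
    "ValidationError",
    "read_monitoring_csv",
    "dataset_from_dataframe",
    "write_dataset_csv",
    "read_dataset_csv",
    "write_truth_csv",
    "write_run_metadata",
]

SURVEY_COLUMNS = ("pre_calves", "pre_fy", "post_calves", "post_females", "post_males")
HARVEST_COLUMNS = tuple(f"harvest_{name}" for name in CLASSES)
HARVEST3_COLUMNS = ("harvest_calves", "harvest_females", "harvest_males")


class SchemaError(ValueError):
    """A mandatory column is missing after applying the schema map."""


class ValidationError(ValueError):
    """A row-level data problem (negative or non-integer count, bad year order)."""


def _expand_three_class_harvest(df: pd.DataFrame) -> pd.DataFrame:
    """Expand hunter-reported three-class harvest to the six model classes."""
    df = df.copy()
    calves = df["harvest_calves"].to_numpy()
    df["harvest_cF"] = calves // 2
    df["harvest_cM"] = calves - calves // 2
    df["harvest_yF"] = 0
    df["harvest_adF"] = df["harvest_females"].to_numpy()
    df["harvest_yM"] = 0
    df["harvest_adM"] = df["harvest_males"].to_numpy()
    return df.drop(columns=list(HARVEST3_COLUMNS))


@dataclass
class MonitoringTable:
    """A validated monitoring table, possibly covering several populations."""

    frame: pd.DataFrame
    extra_columns: tuple[str, ...] = ()

    @property
    def populations(self) -> list[str]:
        if "population" in self.frame.columns:
            return list(pd.unique(self.frame["population"]))
        return ["default"]

    def dataset(self, population: Optional[str] = None) -> SurveyDataset:
        """Extract one population's series as a model-ready SurveyDataset."""
        df = self.frame
        if "population" in df.columns:
            if population is None:
                if df["population"].nunique() > 1:
                    raise ValueError(
                        f"several populations present {self.populations}; pick one"
                    )
                population = df["population"].iloc[0]
            df = df[df["population"] == population]
        harvest = df[list(HARVEST_COLUMNS)].to_numpy(dtype=np.int64)
        tot = df["tot"].to_numpy(dtype=float) if "tot" in df.columns else None
        if tot is not None and np.all(np.isnan(tot)):
            tot = None
        return SurveyDataset(
            years=df["year"].to_numpy(np.int64),
            pre_calves=df["pre_calves"].to_numpy(float),
            pre_fy=df["pre_fy"].to_numpy(float),
            post_calves=df["post_calves"].to_numpy(float),
            post_females=df["post_females"].to_numpy(float),
            post_males=df["post_males"].to_numpy(float),
            harvest=harvest,
            tot=tot,
        )


def _validate(df: pd.DataFrame) -> None:
    count_cols = [c for c in df.columns if c in SURVEY_COLUMNS + HARVEST_COLUMNS + ("tot",)]
    for col in count_cols:
        values = df[col]
        bad = values.notna() & (values < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"negative count in column {col!r} at row {row + 2}")
        finite = values.dropna()
        if not np.allclose(finite, np.round(finite)):
            row = int(np.flatnonzero((values.notna() & (values != np.round(values))).to_numpy())[0])
            raise ValidationError(f"non-integer count in column {col!r} at row {row + 2}")
    for col in HARVEST_COLUMNS:
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
            raise ValidationError(f"missing harvest value in column {col!r} at row {row + 2}")
    group_key = df["population"] if "population" in df.columns else np.zeros(len(df))
    for _, sub in df.groupby(group_key):
        years = sub["year"].to_numpy()
        if np.any(np.diff(years) <= 0):
            raise ValidationError("years must be strictly increasing within a population")


def _apply_schema(df: pd.DataFrame, schema_map: Optional[dict[str, str]]) -> pd.DataFrame:
    if schema_map:
        rename = {v: k for k, v in schema_map.items()}
        df = df.rename(columns=rename)
    return df


def monitoring_from_dataframe(
    df: pd.DataFrame, schema_map: Optional[dict[str, str]] = None
) -> MonitoringTable:
    df = _apply_schema(df, schema_map)
    if all(c in df.columns for c in HARVEST3_COLUMNS):
        df = _expand_three_class_harvest(df)
    mandatory = ("year",) + SURVEY_COLUMNS + HARVEST_COLUMNS
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns after mapping: {missing}")
    known = set(mandatory) | {"tot", "population"}
    extra = tuple(c for c in df.columns if c not in known)
    _validate(df)
    return MonitoringTable(frame=df.reset_index(drop=True), extra_columns=extra)


def read_monitoring_csv(
    path: str | Path, schema_map: Optional[dict[str, str]] = None
) -> MonitoringTable:
    """Read and validate a monitoring CSV; ``schema_map`` bridges foreign headers."""
    return monitoring_from_dataframe(pd.read_csv(path), schema_map=schema_map)


def dataset_from_dataframe(
    df: pd.DataFrame,
    schema_map: Optional[dict[str, str]] = None,
    population: Optional[str] = None,
) -> SurveyDataset:
    return monitoring_from_dataframe(df, schema_map=schema_map).dataset(population)


def write_dataset_csv(dataset: SurveyDataset, path: str | Path) -> None:
    dataset.to_dataframe().to_csv(path, index=False)


def read_dataset_csv(
    path: str | Path, schema_map: Optional[dict[str, str]] = None
) -> SurveyDataset:
    return read_monitoring_csv(path, schema_map=schema_map).dataset()


def write_truth_csv(truth: SimulationTruth, path: str | Path) -> None:
    truth.to_dataframe().to_csv(path, index=False)


def load_scenario_config(path: str | Path):
    """Read a sensitivity-scenario config (YAML or JSON).

    Recognised keys: ``scenario`` (required), ``grid``, ``n_replicates``,
    ``n_years``, ``include_tot``, ``p_range``, and an optional ``mcmc`` block
    with :class:`~cirpop.model.MCMCConfig` fields. Returns
    ``(BiasScenario, MCMCConfig | None)``.
    """
    import yaml

    from .model import MCMCConfig
    from .sensitivity import BiasScenario

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "scenario" not in raw:
        raise SchemaError("scenario config needs a 'scenario' key")
    mcmc_raw = raw.pop("mcmc", None)
    kwargs = {
        "name": raw["scenario"],
        **{
            k: raw[k]
            for k in ("n_replicates", "n_years", "include_tot")
            if k in raw
        },
    }
    if "grid" in raw:
        kwargs["grid"] = tuple(raw["grid"])
    if "p_range" in raw:
        kwargs["p_range"] = tuple(raw["p_range"])
    scenario = BiasScenario(**kwargs)
    mcmc = MCMCConfig(**mcmc_raw) if mcmc_raw else None
    return scenario, mcmc


def write_run_metadata(path: str | Path, seed: int, **settings) -> None:
    """JSON sidecar with the seed, software version and run settings."""
    from . import __version__

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return str(obj)

    payload = {"seed": int(seed), "cirpop_version": __version__, **settings}
    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
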