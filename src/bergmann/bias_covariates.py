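"""Geographic- and time-specific fossil sampling metric.

Tetrapod fossil-bearing formations and occurrences are counted per cell of a
grid of nine 20-degree latitudinal zones crossed with the three Mesozoic
periods, and each taxon is assigned the counts of the cell containing its
mean palaeolatitude and mean age.  The counts act as covariates so that
regression results can be checked against spatial/temporal sampling bias.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .phylo_data import TraitDataset

__all__ = [
    "PERIODS",
    "PERIOD_BOUNDS",
    "ZONE_EDGES",
    "assign_zone",
    "period_from_age",
    "build_counts",
    "BiasCovariateTable",
    "attach_covariates",
]

PERIODS = ("Triassic", "Jurassic", "Cretaceous")
# ICS numeric bounds in Ma, (older, younger); configurable via arguments
PERIOD_BOUNDS = {
    "Triassic": (251.9, 201.4),
    "Jurassic": (201.4, 145.0),
    "Cretaceous": (145.0, 66.0),
}
N_ZONES = 9
ZONE_EDGES = np.linspace(-90.0, 90.0, N_ZONES + 1)


def assign_zone(palaeolat: float) -> int:
    """Zone index 0 (southernmost, [-90, -70)) .. 8 (northernmost).

    Bins are half-open [lo, hi) except the top one, which is closed so that
    +90 maps to zone 8.
    """
    if not -90.0 <= palaeolat <= 90.0:
        raise ValueError(f"palaeolatitude {palaeolat} outside [-90, 90]")
    if palaeolat == 90.0:
        return N_ZONES - 1
    return int(np.floor((palaeolat + 90.0) / 20.0))


def period_from_age(age_ma: float,
                    bounds: dict | None = None) -> str:
    """Geologic period containing ``age_ma``; boundary ages go to the
    younger period.  Raises outside the Mesozoic."""
    bounds = bounds or PERIOD_BOUNDS
    for period in PERIODS:
        older, younger = bounds[period]
        if younger < age_ma <= older:
            return period
    # exact base of the Cretaceous (66.0) belongs to the Cretaceous
    if age_ma == bounds["Cretaceous"][1]:
        return "Cretaceous"
    raise ValueError(f"age {age_ma} Ma falls outside the Mesozoic")


@dataclass(frozen=True)
class BiasCovariateTable:
    """Per-(zone, period) unique-formation and occurrence counts."""

    counts: pd.DataFrame  # index: zone 0..8; columns: MultiIndex-free layout

    def formation_count(self, zone: int, period: str) -> int:
        return int(self.counts.loc[zone, f"formations_{period}"])

    def occurrence_count(self, zone: int, period: str) -> int:
        return int(self.counts.loc[zone, f"occurrences_{period}"])

    def matrix(self, what: str = "formations") -> pd.DataFrame:
        """9 x 3 count matrix (zones x periods)."""
        return self.counts[[f"{what}_{p}" for p in PERIODS]].rename(
            columns={f"{what}_{p}": p for p in PERIODS})

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)


def build_counts(formation_table: pd.DataFrame,
                 bounds: dict | None = None) -> BiasCovariateTable:
    """Count formations and occurrences per (zone, period) cell.

    ``formation_table`` rows are occurrences with columns ``formation``,
    ``palaeolatitude``, and either ``period`` or ``age`` (the stated label
    wins when both are present).  Optional boolean columns ``identifiable``
    and ``body_fossil`` drive the two stated exclusions, which apply to the
    occurrence count only: a formation exists in a cell regardless of
    whether its occurrences are identifiable.
    """
    df = formation_table.copy()
    required = {"formation", "palaeolatitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"formation table missing columns {sorted(missing)}")

    if "period" not in df.columns and "age" not in df.columns:
        raise ValueError("formation table needs a 'period' or 'age' column")

    def row_period(row):
        label = row.get("period")
        if pd.notna(label) and label is not None:
            if str(label) not in PERIODS:
                raise ValueError(f"unknown period labels: [{label!r}]")
            return str(label)
        return period_from_age(float(row["age"]), bounds)

    periods = df.apply(row_period, axis=1) if len(df) else pd.Series(
        [], dtype=object)
    df["_period"] = periods
    df["_zone"] = df["palaeolatitude"].map(assign_zone)

    keep = pd.Series(True, index=df.index)
    if "identifiable" in df.columns:
        keep &= df["identifiable"].astype(bool)
    if "body_fossil" in df.columns:
        keep &= df["body_fossil"].astype(bool)

    out = pd.DataFrame(index=pd.Index(range(N_ZONES), name="zone"))
    for period in PERIODS:
        in_cell = df["_period"] == period
        formations = df[in_cell].groupby("_zone")["formation"].nunique()
        occurrences = df[in_cell & keep].groupby("_zone").size()
        out[f"formations_{period}"] = formations.reindex(
            range(N_ZONES), fill_value=0).astype(int)
        out[f"occurrences_{period}"] = occurrences.reindex(
            range(N_ZONES), fill_value=0).astype(int)
    return BiasCovariateTable(counts=out)


def attach_covariates(dataset: TraitDataset, table: BiasCovariateTable,
                      bounds: dict | None = None) -> TraitDataset:
    """Attach each species the (formation, occurrence) counts of the cell of
    its mean palaeolatitude and mean age.

    A stated period label on the species takes precedence over the numeric
    mean age.  Species whose mean age falls outside the Mesozoic (and that
    carry no period label) are reported as an error.  Idempotent: existing
    counts are recomputed, not accumulated.
    """
    mean_lat = dataset.mean_latitude()
    mean_age = dataset.mean_age()
    formation = np.zeros(len(dataset))
    occurrence = np.zeros(len(dataset))
    problems = []
    for i, sp in enumerate(dataset.species):
        zone = assign_zone(float(mean_lat[i]))
        if dataset.period[i] in PERIODS:
            period = dataset.period[i]
        elif np.isfinite(mean_age[i]):
            try:
                period = period_from_age(float(mean_age[i]), bounds)
            except ValueError:
                problems.append(f"{sp} (mean age {mean_age[i]:.1f} Ma)")
                continue
        else:
            problems.append(f"{sp} (no period label and no age)")
            continue
        formation[i] = table.formation_count(zone, period)
        occurrence[i] = table.occurrence_count(zone, period)
    if problems:
        raise ValueError("species outside the Mesozoic grid: "
                         + "; ".join(problems))
    return TraitDataset(
        species=list(dataset.species),
        response=dataset.response.copy(),
        occurrences=[list(o) for o in dataset.occurrences],
        period=list(dataset.period),
        clade=list(dataset.clade),
        tip_age=None if dataset.tip_age is None else dataset.tip_age.copy(),
        formation_count=formation,
        occurrence_count=occurrence,
    )
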