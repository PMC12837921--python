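"""Camera-trap record ingestion, validation and summary statistics.

A *detection* is a photograph separated from the previous retained photograph
of the same species at the same station by more than a small gap (1 min by
convention); an *independent capture* uses a 30 min gap.  Paired cameras at a
station are collapsed to the station level before filtering, so that the two
cameras of a pair never generate duplicate events.

Effort is counted in trap nights: one station (or camera) active during one
calendar night; partial first/last days count as one night if the unit was
active at any point during them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_DETECTION_COLUMNS = ("station_id", "timestamp", "species")


class ValidationError(ValueError):
    """Raised when input records fail schema or referential checks."""


@dataclass
class EffortTable:
    """Per-station survey effort.

    Attributes
    ----------
    table:
        DataFrame with columns ``station_id``, ``trap_nights_station``,
        ``trap_nights_camera``.
    """

    table: pd.DataFrame

    @property
    def total_station_nights(self) -> float:
        return float(self.table["trap_nights_station"].sum())

    @property
    def total_camera_nights(self) -> float:
        return float(self.table["trap_nights_camera"].sum())

    def station_nights(self, station_id) -> float:
        row = self.table.loc[self.table["station_id"] == station_id]
        if row.empty:
            raise KeyError(f"unknown station {station_id!r}")
        return float(row["trap_nights_station"].iloc[0])


def parse_detections(records: pd.DataFrame, stations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate and normalize a raw detection table.

    Timestamps are parsed to pandas datetimes; unparseable rows and rows whose
    ``station_id`` is absent from the station registry are rejected with their
    row indices named in the error.
    """
    missing = [c for c in REQUIRED_DETECTION_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"detection table missing columns: {missing}")
    out = records.copy()
    ts = pd.to_datetime(out["timestamp"], errors="coerce")
    bad = list(out.index[ts.isna()])
    if bad:
        raise ValidationError(f"unparseable timestamps at record indices {bad}")
    out["timestamp"] = ts
    if stations is not None:
        known = set(stations["station_id"])
        unknown = out.loc[~out["station_id"].isin(known)]
        if not unknown.empty:
            raise ValidationError(
                f"unknown station_id at record indices {list(unknown.index)}: "
                f"{sorted(unknown['station_id'].unique())}"
            )
    return out


def filter_events(
    records: pd.DataFrame,
    gap_minutes: float,
    stations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Greedy minimum-gap filter producing independent events.

    Per (species, station), records are scanned in time order; the first is
    retained and each subsequent record is retained iff it falls at least
    ``gap_minutes`` after the last *retained* record.  Cameras within a
    station are pooled before filtering.

    Returns the retained rows with an added ``event_id`` column.
    """
    if gap_minutes <= 0:
        raise ValueError("gap_minutes must be positive")
    records = parse_detections(records, stations)
    records = records.sort_values("timestamp", kind="mergesort")
    gap = pd.Timedelta(minutes=gap_minutes)
    keep_idx: list = []
    for (_, _), grp in records.groupby(["species", "station_id"], sort=False):
        last = None
        for idx, t in zip(grp.index, grp["timestamp"]):
            if last is None or t - last >= gap:
                keep_idx.append(idx)
                last = t
    events = records.loc[sorted(keep_idx, key=lambda i: (records.at[i, "timestamp"], i))].copy()
    events = events.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    events.insert(0, "event_id", np.arange(1, len(events) + 1))
    return events


def _active_nights(start, end) -> int:
    """Calendar nights between two timestamps, partial days counting as 1."""
    d0 = pd.Timestamp(start).normalize()
    d1 = pd.Timestamp(end).normalize()
    if d1 < d0:
        raise ValueError("active_end precedes active_start")
    return int((d1 - d0).days) + 1


def effort_from_stations(stations: pd.DataFrame, cameras_per_station: int = 2) -> EffortTable:
    """Build an :class:`EffortTable` from per-station active date ranges.

    ``stations`` needs ``station_id``, ``active_start`` and ``active_end``
    columns.  Camera-level nights assume ``cameras_per_station`` cameras with
    the station's activity window (per-camera windows, when known, can be
    supplied by calling this per camera and summing).
    """
    nights = [
        _active_nights(s, e)
        for s, e in zip(stations["active_start"], stations["active_end"])
    ]
    table = pd.DataFrame(
        {
            "station_id": stations["station_id"].to_numpy(),
            "trap_nights_station": nights,
            "trap_nights_camera": [n * cameras_per_station for n in nights],
        }
    )
    return EffortTable(table)


def capture_rate(events: pd.DataFrame, effort: EffortTable, species: str) -> float:
    """Independent captures per 100 station-level trap nights."""
    nights = effort.total_station_nights
    if nights <= 0:
        raise ValueError("total station-level trap nights must be positive")
    n = int((events["species"] == species).sum())
    return 100.0 * n / nights


def naive_occupancy(events: pd.DataFrame, stations: pd.DataFrame, species: str) -> float:
    """Proportion of stations with at least one event of ``species``."""
    all_stations = stations["station_id"].unique()
    if len(all_stations) == 0:
        raise ValueError("station list is empty")
    occupied = events.loc[events["species"] == species, "station_id"].unique()
    return len(np.intersect1d(all_stations, occupied)) / len(all_stations)


def rai(
    events: pd.DataFrame,
    effort: EffortTable,
    species: str,
    per_station: bool = False,
):
    """Relative abundance index: events per 100 trap days.

    Global by default; with ``per_station=True`` returns a DataFrame with one
    RAI per station (``rai`` is NaN and ``undefined`` is flagged where a
    station has zero effort).  Per-station values feed the occupancy model's
    prey-availability covariate.
    """
    sub = events.loc[events["species"] == species]
    if not per_station:
        nights = effort.total_station_nights
        if nights <= 0:
            raise ValueError("total trap days must be positive")
        return 100.0 * len(sub) / nights
    counts = sub.groupby("station_id").size()
    rows = []
    for _, r in effort.table.iterrows():
        n = int(counts.get(r["station_id"], 0))
        nights = r["trap_nights_station"]
        undefined = nights <= 0
        rows.append(
            {
                "station_id": r["station_id"],
                "events": n,
                "trap_nights": nights,
                "rai": np.nan if undefined else 100.0 * n / nights,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)


def scale_covariates(
    covariates: pd.DataFrame, corr_threshold: float = 0.6
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center and scale covariate columns; report pairwise correlations.

    Each numeric column is transformed to mean 0, sample standard deviation 1
    (denominator n−1).  Returns ``(scaled, report)`` where ``report`` lists
    every column pair with its Pearson correlation and a ``flagged`` boolean
    when |r| exceeds ``corr_threshold``.
    """
    if len(covariates) < 2:
        raise ValueError("need at least two rows to standardize")
    scaled = covariates.copy()
    for col in covariates.columns:
        x = covariates[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance covariate column: {col!r}")
        scaled[col] = (x - x.mean()) / sd
    cols = list(covariates.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = float(np.corrcoef(scaled[cols[i]], scaled[cols[j]])[0, 1])
            rows.append(
                {
                    "var1": cols[i],
                    "var2": cols[j],
                    "pearson_r": r,
                    "flagged": abs(r) > corr_threshold,
                }
            )
    report = pd.DataFrame(rows, columns=["var1", "var2", "pearson_r", "flagged"])
    return scaled, report


def write_events(events: pd.DataFrame, path) -> None:
    """Write an event table (detections schema plus ``event_id``)."""
    events.to_csv(path, index=False)
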