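"""Survey effort and sighting records: schemas, I/O, filtering, encounter rates.

Effort is organised as primary sampling units (PSUs, contiguous 20 km coastal
sections) containing four 5 km inshore segments (< 1500 m from shore) and one
diagonal offshore segment of variable length.  Whale counts and observation
conditions (Beaufort sea state, sightability) are aggregated per segment;
sightings carry visually estimated perpendicular distances and group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SIGHTABILITY_LEVELS = ["poor", "fair", "good", "excellent"]

SEGMENT_COLUMNS = [
    "segment_id", "psu_id", "kind", "date", "region",
    "length_km", "lat", "lon", "bss", "sightability", "n_whales",
]
SIGHTING_COLUMNS = [
    "sighting_id", "segment_id", "date", "lat", "lon",
    "perp_distance_m", "group_size", "bss", "sightability",
]


@dataclass
class Segment:
    segment_id: str
    psu_id: str
    kind: str
    date: pd.Timestamp
    region: int
    length_km: float
    lat: float
    lon: float
    bss: int
    sightability: str
    n_whales: int


@dataclass
class Sighting:
    sighting_id: str
    segment_id: str
    date: pd.Timestamp
    lat: float
    lon: float
    perp_distance_m: float  # NaN when the observer did not record distance
    group_size: int
    bss: int
    sightability: str

    @property
    def distance_missing(self) -> bool:
        return not np.isfinite(self.perp_distance_m)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")


def _segment_row_errors(row) -> list[str]:
    errs = []
    if not row["length_km"] > 0:
        errs.append("length_km must be > 0")
    if not row["n_whales"] >= 0:
        errs.append("n_whales must be >= 0")
    if row["region"] not in (1, 2, 3):
        errs.append("region must be 1, 2 or 3")
    if row["kind"] not in ("inshore", "offshore"):
        errs.append("kind must be inshore or offshore")
    if pd.isna(row["date"]) or not (5 <= row["date"].month <= 8):
        errs.append("date must fall in the May-August survey window")
    return errs


def _sighting_row_errors(row) -> list[str]:
    errs = []
    if np.isfinite(row["perp_distance_m"]) and row["perp_distance_m"] < 0:
        errs.append("perp_distance_m must be >= 0 when present")
    if not row["group_size"] >= 1:
        errs.append("group_size must be >= 1")
    return errs


def _read_validated(path, required, checker, numeric):
    df = pd.read_csv(path)
    _require_columns(df, required, path)
    df["date"] = pd.to_datetime(df["date"], errors="coerce")
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    rejects = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        errs = checker(row)
        if errs:
            keep[i] = False
            # +2: header line plus 1-based numbering
            rejects.append({"line": i + 2, "errors": "; ".join(errs)})
    return (
        df[keep].reset_index(drop=True),
        pd.DataFrame(rejects, columns=["line", "errors"]),
    )


def read_segments(path):
    """Read and validate a segments CSV.

    Returns ``(segments, rejects)``: rows violating invariants are removed
    and reported with their file line numbers.
    """
    return _read_validated(
        path, SEGMENT_COLUMNS, _segment_row_errors,
        ["length_km", "lat", "lon", "bss", "n_whales", "region"],
    )


def read_sightings(path):
    """Read and validate a sightings CSV.

    Sightings with missing perpendicular distance are accepted and flagged
    ``distance_missing`` (they still contribute whales to segment counts,
    just not to the detection function).
    """
    df, rejects = _read_validated(
        path, SIGHTING_COLUMNS, _sighting_row_errors,
        ["lat", "lon", "perp_distance_m", "group_size", "bss"],
    )
    df["distance_missing"] = ~np.isfinite(df["perp_distance_m"])
    return df, rejects


def write_segments(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in SEGMENT_COLUMNS if c in df]
              + [c for c in df.columns if c not in SEGMENT_COLUMNS])


def write_sightings(df: pd.DataFrame, path) -> None:
    cols = [c for c in SIGHTING_COLUMNS if c in df]
    df.to_csv(path, index=False, columns=cols)


def filter_conditions(segments: pd.DataFrame, max_bss: int = 3,
                      log: list | None = None) -> pd.DataFrame:
    """Drop segments surveyed in Beaufort sea state above ``max_bss``.

    The detection function cannot be applied in BSS >= 4 (no sightings were
    made there), so those segments are removed; the removal fraction is
    appended to ``log`` when given.
    """
    n0 = len(segments)
    out = segments[segments["bss"] <= max_bss].reset_index(drop=True)
    if log is not None and n0 > 0:
        log.append(
            f"filter_conditions: removed {n0 - len(out)}/{n0} segments "
            f"({100.0 * (n0 - len(out)) / n0:.2f}%) with BSS > {max_bss}"
        )
    return out


def encounter_rate(
    segments: pd.DataFrame,
    by: str = "year",
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Whales per km of effort, grouped by year, latitude bin, or both.

    Counts are individual whales (group sizes already summed into the
    per-segment ``n_whales``).  Grouping keys: ``"year"``, ``"lat_bin"`` or
    ``"year_lat"``; the latitude bin width defaults to 0.1 degrees and is
    configurable (1-degree summaries are also standard).  Cells with zero
    effort do not appear (no-data, not zero).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    seg = segments.copy()
    seg["date"] = pd.to_datetime(seg["date"])
    seg["year"] = seg["date"].dt.year
    seg["lat_bin"] = (np.floor(seg["lat"] / bin_width) + 0.5) * bin_width
    keys = {"year": ["year"], "lat_bin": ["lat_bin"],
            "year_lat": ["year", "lat_bin"]}
    if by not in keys:
        raise ValueError(f"unknown grouping {by!r}")
    grp = seg.groupby(keys[by], as_index=False).agg(
        effort_km=("length_km", "sum"), n_whales=("n_whales", "sum")
    )
    grp = grp[grp["effort_km"] > 0].reset_index(drop=True)
    grp["rate"] = grp["n_whales"] / grp["effort_km"]
    return grp
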