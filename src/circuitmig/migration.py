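"""Net-squared displacement (NSD) migration delimitation.

For a migratory animal with two seasonal ranges, the squared straight-line
displacement from the first fix is near zero during pre-migration residency,
rises steeply during the directed migratory movement, and plateaus on the
destination range.  The start and end of that rise delimit the migration and
give the source/ground endpoints used by the circuit stage.

Endpoints here are picked by a deterministic plateau-fraction rule (first
crossings of configurable low/high fractions of the plateau level) rather
than by visual inspection, so runs are reproducible; the fractions are
exposed and default to 5% / 95%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TelemetryTrack",
    "MigrationWindow",
    "NoMigrationError",
    "nsd_series",
    "detect_migration",
    "detect_track_migration",
    "read_tracks_csv",
    "write_tracks_csv",
]


class NoMigrationError(ValueError):
    """Raised when an NSD series shows no migratory plateau."""


@dataclass
class TelemetryTrack:
    """Ordered GPS fixes for one animal-season-year.

    ``fixes`` holds (x_km, y_km) rows; ``timestamps`` the matching
    observation times (strictly increasing).
    """

    animal_id: str
    season: str
    year: int
    timestamps: pd.DatetimeIndex
    fixes: np.ndarray  # (n, 2) projected km

    def __post_init__(self) -> None:
        self.fixes = np.asarray(self.fixes, dtype=float)
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if self.fixes.ndim != 2 or self.fixes.shape[1] != 2:
            raise ValueError("fixes must be an (n, 2) array")
        if len(self.timestamps) != len(self.fixes):
            raise ValueError("timestamps and fixes length mismatch")
        if len(self.fixes) < 3:
            raise ValueError("a track needs at least 3 fixes")
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def label(self) -> str:
        return f"{self.animal_id}-{self.season}-{self.year}"


@dataclass
class MigrationWindow:
    """Detected migration bounds on a track's NSD series."""

    start_index: int
    end_index: int
    nsd: np.ndarray
    start_point: tuple[float, float] | None = None
    end_point: tuple[float, float] | None = None
    plateau: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if not (0 <= self.start_index < self.end_index < len(self.nsd)):
            raise ValueError("migration window indices out of order")


def nsd_series(track: TelemetryTrack) -> np.ndarray:
    """Squared displacement (km^2) of every fix from the first fix."""
    d = track.fixes - track.fixes[0]
    return d[:, 0] ** 2 + d[:, 1] ** 2


def detect_migration(
    nsd: np.ndarray,
    low_frac: float = 0.05,
    high_frac: float = 0.95,
) -> MigrationWindow:
    """Delimit the migratory rise of an NSD series.

    The plateau level ``P`` is the median of the top quartile of the series.
    Migration starts at the last index before the series first exceeds
    ``low_frac * P`` and ends at the first index reaching ``high_frac * P``.

    Raises
    ------
    NoMigrationError
        If the series lacks a plateau: the maximum over the trailing window
        must exceed four times the leading-window median plus 1 km^2.
    """
    nsd = np.asarray(nsd, dtype=float)
    if not 0 < low_frac < high_frac <= 1:
        raise ValueError("need 0 < low_frac < high_frac <= 1")
    n = len(nsd)
    if n < 3:
        raise ValueError("NSD series too short")
    w = max(3, n // 10)
    lead = float(np.median(nsd[:w]))
    trail = float(np.max(nsd[-w:]))
    if trail <= 4.0 * lead + 1.0:
        raise NoMigrationError(
            f"no migration detected: trailing max {trail:.3g} km^2 does not "
            f"exceed 4 x leading median {lead:.3g} + 1 km^2"
        )
    top_quartile = np.sort(nsd)[-max(1, n // 4):]
    plateau = float(np.median(top_quartile))

    above_low = np.nonzero(nsd > low_frac * plateau)[0]
    first_rise = int(above_low[0])
    start = max(first_rise - 1, 0)
    reach_high = np.nonzero(nsd >= high_frac * plateau)[0]
    end = int(reach_high[0])
    if end <= start:  # degenerate: series starts on the plateau
        raise NoMigrationError("no pre-migration residency phase found")
    return MigrationWindow(start_index=start, end_index=end, nsd=nsd, plateau=plateau)


def detect_track_migration(
    track: TelemetryTrack,
    low_frac: float = 0.05,
    high_frac: float = 0.95,
) -> MigrationWindow:
    """`detect_migration` on a track, attaching endpoint fix coordinates.

    Endpoints always coincide with recorded fixes, never interpolated
    positions.
    """
    win = detect_migration(nsd_series(track), low_frac=low_frac, high_frac=high_frac)
    win.start_point = tuple(track.fixes[win.start_index])
    win.end_point = tuple(track.fixes[win.end_index])
    return win


# -- track CSV interchange ----------------------------------------------

_COLUMNS = ["animal_id", "season", "year", "timestamp_iso8601", "x_km", "y_km"]


def write_tracks_csv(tracks: list[TelemetryTrack], path: str | Path) -> None:
    frames = []
    for t in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": t.animal_id,
                    "season": t.season,
                    "year": t.year,
                    "timestamp_iso8601": t.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                    "x_km": t.fixes[:, 0],
                    "y_km": t.fixes[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True)[_COLUMNS].to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> list[TelemetryTrack]:
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    tracks = []
    for (animal, season, year), grp in df.groupby(
        ["animal_id", "season", "year"], sort=False
    ):
        tracks.append(
            TelemetryTrack(
                animal_id=str(animal),
                season=str(season),
                year=int(year),
                timestamps=pd.DatetimeIndex(pd.to_datetime(grp["timestamp_iso8601"])),
                fixes=grp[["x_km", "y_km"]].to_numpy(),
            )
        )
    return tracks
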