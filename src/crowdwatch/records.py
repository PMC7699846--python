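"""Geotagged check-in records and their CSV serialization.

A check-in is a microblog post carrying explicit WGS84 coordinates and a
timestamp with a fixed UTC offset (Shanghai local time, +08:00, by default).
The text is consumed pre-tokenized: tokens are atomic strings, joined by a
configurable delimiter (default space) in the CSV ``tokens`` field.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Sequence

CST = timezone(timedelta(hours=8))
"""China Standard Time, the default offset for timestamps."""

CSV_HEADER = ["id", "timestamp", "lon", "lat", "tokens"]


class RecordError(ValueError):
    """Raised for records violating basic coordinate/timestamp invariants."""


@dataclass(frozen=True)
class CheckInRecord:
    """One geotagged post.

    Attributes
    ----------
    id : str
        Stable record identifier.
    timestamp : datetime
        Timezone-aware instant (a fixed UTC offset, +08:00 by default).
    lon, lat : float
        WGS84 degrees.
    tokens : tuple of str
        Ordered token sequence; may be empty.
    user : str or None
        Optional author identifier.
    """

    id: str
    timestamp: datetime
    lon: float
    lat: float
    tokens: tuple[str, ...] = field(default_factory=tuple)
    user: str | None = None

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise RecordError(f"longitude {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise RecordError(f"latitude {self.lat} outside [-90, 90]")
        if self.timestamp.tzinfo is None:
            raise RecordError("timestamp must carry an explicit UTC offset")
        if not isinstance(self.tokens, tuple):
            object.__setattr__(self, "tokens", tuple(self.tokens))


def write_records_csv(
    records: Iterable[CheckInRecord],
    path: str | Path,
    token_delimiter: str = " ",
) -> None:
    """Write records as CSV with header ``id,timestamp,lon,lat,tokens``.

    Timestamps are ISO-8601 with offset; tokens are joined by
    ``token_delimiter``.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for rec in records:
            writer.writerow(
                [
                    rec.id,
                    rec.timestamp.isoformat(),
                    repr(rec.lon),
                    repr(rec.lat),
                    token_delimiter.join(rec.tokens),
                ]
            )


def read_records_csv(
    path: str | Path, token_delimiter: str = " "
) -> list[CheckInRecord]:
    """Read a check-in CSV written by :func:`write_records_csv`."""
    out: list[CheckInRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_HEADER) - set(reader.fieldnames or ())
        if missing:
            raise RecordError(f"check-in CSV missing columns: {sorted(missing)}")
        for row in reader:
            tokens = tuple(t for t in row["tokens"].split(token_delimiter) if t)
            out.append(
                CheckInRecord(
                    id=row["id"],
                    timestamp=datetime.fromisoformat(row["timestamp"]),
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    tokens=tokens,
                    user=row.get("user") or None,
                )
            )
    return out


def sort_records(records: Sequence[CheckInRecord]) -> list[CheckInRecord]:
    """Records sorted by timestamp (stable: equal instants keep input order)."""
    return sorted(records, key=lambda r: r.timestamp)
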