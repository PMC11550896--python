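"""Domain types and I/O for thermosensitive-spot tables.

Coordinate convention: ``x_px`` runs along the proximodistal axis with 0 at
the wrist, increasing toward the elbow; ``y_px`` is mediolateral. Segment 1
is therefore the most distal (wrist-adjacent) quarter of the search region.
All coordinates are standardized post-alignment pixels; ``px_to_mm`` is a
display-only conversion factor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

__all__ = [
    "CATEGORIES",
    "StudyRegion",
    "SpotRecord",
    "SpotTable",
    "SpotValidationError",
    "SpotParseError",
    "read_spot_table",
    "write_spot_table",
    "assign_segment",
    "px_to_mm_distance",
]

#: Five-way spot taxonomy. ``unconfirmed`` means a positive identification
#: followed by no positive confirmation sweep.
CATEGORIES = ("cold", "warm", "inconsistent", "incongruous", "unconfirmed")

_CSV_FIELDS = (
    "participant_id",
    "session_id",
    "x_px",
    "y_px",
    "stimulus_blocks",
    "delta_t_c",
    "category",
    "response_log_id",
)

#: Stimulus amplitude (degC offset from baseline) paired with each session:
#: sessions 1-2 use +/-2 degC, sessions 3-4 use +/-4 degC.
SESSION_DELTA_T = {1: 2.0, 2: 2.0, 3: 4.0, 4: 4.0}


class SpotValidationError(ValueError):
    """A record violates a domain invariant."""


class SpotParseError(ValueError):
    """A CSV row could not be parsed; message names row and field."""


@dataclass(frozen=True)
class StudyRegion:
    """Rectangular search region on the dorsal forearm.

    Parameters
    ----------
    length_px
        Proximodistal extent in pixels (wrist at 0, elbow at ``length_px``).
    width_px
        Mediolateral extent in pixels.
    px_to_mm
        Millimetres per pixel, used only to convert distances for display.
    n_segments
        Number of equal proximodistal search segments.
    """

    length_px: float = 1200.0
    width_px: float = 300.0
    px_to_mm: float = 0.33
    n_segments: int = 4

    def __post_init__(self) -> None:
        if self.length_px <= 0 or self.width_px <= 0:
            raise SpotValidationError("region extents must be positive")
        if self.px_to_mm <= 0:
            raise SpotValidationError("px_to_mm must be positive")
        if self.n_segments < 1:
            raise SpotValidationError("n_segments must be >= 1")

    @property
    def area_px2(self) -> float:
        return self.length_px * self.width_px

    @property
    def perimeter_px(self) -> float:
        return 2.0 * (self.length_px + self.width_px)

    def segment_edges(self) -> list[float]:
        """Boundaries partitioning [0, L] into ``n_segments`` equal parts."""
        step = self.length_px / self.n_segments
        return [k * step for k in range(self.n_segments + 1)]

    def contains(self, x_px: float, y_px: float) -> bool:
        return 0.0 <= x_px <= self.length_px and 0.0 <= y_px <= self.width_px

    def to_dict(self) -> dict:
        return {
            "length_px": self.length_px,
            "width_px": self.width_px,
            "px_to_mm": self.px_to_mm,
            "n_segments": self.n_segments,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyRegion":
        return cls(
            length_px=float(d.get("length_px", 1200.0)),
            width_px=float(d.get("width_px", 300.0)),
            px_to_mm=float(d.get("px_to_mm", 0.33)),
            n_segments=int(d.get("n_segments", 4)),
        )


@dataclass(frozen=True)
class SpotRecord:
    """One confirmed-or-unconfirmed thermosensitive spot."""

    participant_id: str
    session_id: int
    x_px: float
    y_px: float
    stimulus_blocks: frozenset[str]
    delta_t_c: float
    category: str
    response_log_id: str = ""

    def validate(self, region: StudyRegion) -> None:
        if self.session_id not in (1, 2, 3, 4):
            raise SpotValidationError(
                f"session_id must be 1-4, got {self.session_id!r}"
            )
        if self.delta_t_c not in (2.0, 4.0):
            raise SpotValidationError(
                f"delta_t_c must be 2 or 4, got {self.delta_t_c!r}"
            )
        if SESSION_DELTA_T[self.session_id] != self.delta_t_c:
            raise SpotValidationError(
                f"session {self.session_id} pairs with "
                f"delta_t {SESSION_DELTA_T[self.session_id]}, got {self.delta_t_c}"
            )
        if self.category not in CATEGORIES:
            raise SpotValidationError(f"unknown category {self.category!r}")
        if not self.stimulus_blocks or not self.stimulus_blocks <= {"cold", "warm"}:
            raise SpotValidationError(
                f"stimulus_blocks must be a nonempty subset of "
                f"{{cold, warm}}, got {set(self.stimulus_blocks)!r}"
            )
        if not region.contains(self.x_px, self.y_px):
            raise SpotValidationError(
                f"coordinate ({self.x_px}, {self.y_px}) outside region "
                f"[0,{region.length_px}] x [0,{region.width_px}]"
            )

    @property
    def confirmed(self) -> bool:
        return self.category != "unconfirmed"


@dataclass
class SpotTable:
    """Ordered collection of validated spot records plus the study region."""

    records: list[SpotRecord]
    region: StudyRegion
    provenance: str = ""

    def validate(self) -> None:
        seen: set[tuple] = set()
        for i, rec in enumerate(self.records):
            try:
                rec.validate(self.region)
            except SpotValidationError as exc:
                raise SpotValidationError(f"record {i}: {exc}") from exc
            key = (rec.participant_id, rec.session_id, rec.x_px, rec.y_px)
            if key in seen:
                raise SpotValidationError(f"record {i}: duplicate spot {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def confirmed(self) -> "SpotTable":
        """Subtable of confirmed spots (all categories but unconfirmed)."""
        return SpotTable(
            [r for r in self.records if r.confirmed], self.region, self.provenance
        )

    def for_participant(self, participant_id: str) -> "SpotTable":
        return SpotTable(
            [r for r in self.records if r.participant_id == participant_id],
            self.region,
            self.provenance,
        )

    def participants(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.participant_id not in out:
                out.append(r.participant_id)
        return out

    def with_categories(self, categories: dict[str, str]) -> "SpotTable":
        """Return a copy with categories reassigned by response_log_id."""
        recs = [
            replace(r, category=categories.get(r.response_log_id, r.category))
            for r in self.records
        ]
        return SpotTable(recs, self.region, self.provenance)


def _serialize_blocks(blocks: frozenset[str]) -> str:
    return "|".join(b for b in ("cold", "warm") if b in blocks)


def _parse_blocks(s: str) -> frozenset[str]:
    parts = frozenset(p for p in s.split("|") if p)
    if not parts or not parts <= {"cold", "warm"}:
        raise ValueError(f"bad stimulus_blocks {s!r}")
    return parts


def read_spot_table(path, region: StudyRegion) -> SpotTable:
    """Read a spot CSV into a validated :class:`SpotTable`.

    Raises :class:`SpotParseError` naming the offending row and field on a
    malformed row, and :class:`SpotValidationError` on invariant violations
    (out-of-region coordinate, bad session, unknown category).
    """
    records: list[SpotRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != list(_CSV_FIELDS):
            raise SpotParseError(
                f"{path}: expected header {','.join(_CSV_FIELDS)}, "
                f"got {reader.fieldnames}"
            )
        for rownum, row in enumerate(reader, start=2):
            rec = _parse_row(row, rownum)
            records.append(rec)
    table = SpotTable(records, region, provenance=f"read from {path}")
    table.validate()
    return table


def _parse_row(row: dict, rownum: int) -> SpotRecord:
    def get(fieldname: str, conv):
        raw = row.get(fieldname)
        if raw is None or raw == "" and fieldname != "response_log_id":
            raise SpotParseError(f"row {rownum}: missing field {fieldname!r}")
        try:
            return conv(raw)
        except (ValueError, TypeError) as exc:
            raise SpotParseError(
                f"row {rownum}: bad value {raw!r} for field {fieldname!r}"
            ) from exc

    return SpotRecord(
        participant_id=get("participant_id", str),
        session_id=get("session_id", int),
        x_px=get("x_px", float),
        y_px=get("y_px", float),
        stimulus_blocks=get("stimulus_blocks", _parse_blocks),
        delta_t_c=get("delta_t_c", float),
        category=get("category", str),
        response_log_id=row.get("response_log_id", "") or "",
    )


def write_spot_table(table: SpotTable, path) -> None:
    """Write a spot CSV; inverse of :func:`read_spot_table`.

    Floats are written with ``repr`` so the round trip is exact; output is
    byte-stable for a given table.
    """
    table.validate()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_CSV_FIELDS)
        for rec in table.records:
            writer.writerow(
                [
                    rec.participant_id,
                    rec.session_id,
                    repr(rec.x_px),
                    repr(rec.y_px),
                    _serialize_blocks(rec.stimulus_blocks),
                    repr(rec.delta_t_c),
                    rec.category,
                    rec.response_log_id,
                ]
            )


def assign_segment(x_px: float, region: StudyRegion) -> int:
    """Map a proximodistal coordinate to its search segment (1..n_segments).

    Segments are half-open ``[(k-1)L/n, kL/n)`` with the top boundary
    ``x = L`` closed into segment ``n`` so no in-region point is lost.
    """
    if not 0.0 <= x_px <= region.length_px:
        raise SpotValidationError(
            f"x_px={x_px} outside [0, {region.length_px}]"
        )
    step = region.length_px / region.n_segments
    return min(int(x_px // step) + 1, region.n_segments)


def px_to_mm_distance(d_px: float, region: StudyRegion) -> float:
    """Convert a pixel distance to millimetres (display only)."""
    if d_px < 0:
        raise SpotValidationError(f"distance must be >= 0, got {d_px}")
    return d_px * region.px_to_mm
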