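"""96-well harvesting arrays, sample identifiers and specimen metadata.

Pinned specimens are arrayed in an 8x12 grid (rows A-H, columns 1-12)
mirroring a 96-well microplate; 95 squares hold specimens and one square is
reserved for a negative control.  Each square gets a unique sample ID of the
form ``CCDB-31120-A01``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

from .taxonomy import RANK_COLUMNS, Taxonomy

ROWS = "ABCDEFGH"
N_COLUMNS = 12
N_WELLS = len(ROWS) * N_COLUMNS

#: year the study's specimen ages are measured against
DEFAULT_ANALYSIS_YEAR = 2017

_PLATE_CODE_RE = re.compile(r"^CCDB-\d+$")
_WELL_RE = re.compile(r"^([A-H])(\d{1,2})$")


class PlateError(ValueError):
    """Validation failure in plate/sample-ID handling."""


@dataclass(frozen=True, order=True)
class WellAddress:
    """A single square: row letter A-H, column 1-12. Row-major ordering."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise PlateError(f"well row must be one of {ROWS!r}, got {self.row!r}")
        if not 1 <= self.column <= N_COLUMNS:
            raise PlateError(f"well column must be 1..{N_COLUMNS}, got {self.column}")

    @property
    def index(self) -> int:
        """Row-major index 0..95 (A01=0, A12=11, H12=95)."""
        return ROWS.index(self.row) * N_COLUMNS + (self.column - 1)

    @classmethod
    def from_index(cls, i: int) -> "WellAddress":
        if not 0 <= i < N_WELLS:
            raise PlateError(f"well index out of range: {i}")
        return cls(ROWS[i // N_COLUMNS], i % N_COLUMNS + 1)

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        m = _WELL_RE.match(text.strip())
        if not m:
            raise PlateError(f"cannot parse well address {text!r}")
        return cls(m.group(1), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column:02d}"


def all_wells() -> list[WellAddress]:
    """The 96 wells in row-major order A01..H12."""
    return [WellAddress.from_index(i) for i in range(N_WELLS)]


@dataclass(frozen=True)
class SampleID:
    plate_code: str
    well: WellAddress

    def __post_init__(self) -> None:
        if not _PLATE_CODE_RE.match(self.plate_code):
            raise PlateError(
                f"plate code must match 'CCDB-<digits>', got {self.plate_code!r}"
            )

    def __str__(self) -> str:
        return f"{self.plate_code}-{self.well}"


def format_sample_id(plate_code: str, well: WellAddress) -> str:
    """Canonical sample ID, e.g. ``CCDB-31120-A01`` (zero-padded column)."""
    return str(SampleID(plate_code, well))


def parse_sample_id(text: str) -> SampleID:
    """Inverse of :func:`format_sample_id`."""
    parts = text.strip().rsplit("-", 1)
    if len(parts) != 2:
        raise PlateError(f"cannot parse sample ID {text!r}")
    return SampleID(parts[0], WellAddress.parse(parts[1]))


@dataclass
class SpecimenRecord:
    """Per-specimen metadata captured during databasing."""

    sample_id: SampleID
    taxonomy: Taxonomy = field(default_factory=Taxonomy)
    catalogue_number: str = ""
    collection_year: int | None = None
    country: str = ""
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.collection_year is not None and self.collection_year > DEFAULT_ANALYSIS_YEAR:
            # collection cannot postdate processing
            raise PlateError(
                f"collection year {self.collection_year} is after the analysis year "
                f"{DEFAULT_ANALYSIS_YEAR} for {self.sample_id}"
            )

    def age(self, analysis_year: int = DEFAULT_ANALYSIS_YEAR) -> int | None:
        """Specimen age in years at analysis time, or None if year unknown."""
        if self.collection_year is None:
            return None
        return analysis_year - self.collection_year


CONTROL_MARKER = "negative_control"


@dataclass
class PlateArray:
    """One 95-specimen array plus its reserved negative-control square.

    The control square defaults to H12 (the 96th square in row-major order)
    but is configurable; no specimen may occupy it.
    """

    plate_code: str
    control_well: WellAddress = field(default_factory=lambda: WellAddress("H", 12))
    wells: dict[WellAddress, SpecimenRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not _PLATE_CODE_RE.match(self.plate_code):
            raise PlateError(f"plate code must match 'CCDB-<digits>', got {self.plate_code!r}")
        for well, rec in self.wells.items():
            self._check(well, rec)

    def _check(self, well: WellAddress, rec: SpecimenRecord) -> None:
        if well == self.control_well:
            raise PlateError(f"well {well} is the negative control; cannot hold a specimen")
        if rec.sample_id.plate_code != self.plate_code or rec.sample_id.well != well:
            raise PlateError(
                f"sample ID {rec.sample_id} does not match plate {self.plate_code} well {well}"
            )

    def add(self, rec: SpecimenRecord) -> None:
        well = rec.sample_id.well
        self._check(well, rec)
        if well in self.wells:
            raise PlateError(f"duplicate sample ID {rec.sample_id}")
        self.wells[well] = rec

    @property
    def specimens(self) -> list[SpecimenRecord]:
        return [self.wells[w] for w in sorted(self.wells)]

    def __len__(self) -> int:
        return len(self.wells)


_BASE_COLUMNS = ("sample_id", "role", "catalogue_number") + RANK_COLUMNS + (
    "collection_year",
    "country",
    "flags",
)


def _record_row(rec: SpecimenRecord) -> list[str]:
    return (
        [str(rec.sample_id), "specimen", rec.catalogue_number]
        + list(rec.taxonomy.as_tuple())
        + [
            "" if rec.collection_year is None else str(rec.collection_year),
            rec.country,
            ";".join(sorted(rec.flags)),
        ]
    )


def write_submission_table(plates: list[PlateArray], path) -> None:
    """Write the submission spreadsheet: one TSV row per specimen plus one
    marker row per plate naming the negative-control well."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_BASE_COLUMNS)
        for plate in plates:
            ctrl = [format_sample_id(plate.plate_code, plate.control_well), CONTROL_MARKER]
            w.writerow(ctrl + [""] * (len(_BASE_COLUMNS) - 2))
            for rec in plate.specimens:
                w.writerow(_record_row(rec))


def _rows_to_plates(rows: list[dict]) -> list[PlateArray]:
    plates: dict[str, PlateArray] = {}
    controls: dict[str, WellAddress] = {}
    pending: dict[str, list[SpecimenRecord]] = {}
    for row in rows:
        sid = parse_sample_id(row["sample_id"])
        code = sid.plate_code
        if row.get("role", "specimen") == CONTROL_MARKER:
            controls[code] = sid.well
            continue
        year = row.get("collection_year", "")
        rec = SpecimenRecord(
            sample_id=sid,
            taxonomy=Taxonomy.from_mapping(row),
            catalogue_number=row.get("catalogue_number", ""),
            collection_year=int(year) if str(year).strip() else None,
            country=row.get("country", ""),
            flags=set(f for f in row.get("flags", "").split(";") if f),
        )
        pending.setdefault(code, []).append(rec)
    out: list[PlateArray] = []
    for code in dict.fromkeys(list(controls) + list(pending)):
        plate = PlateArray(code, control_well=controls.get(code, WellAddress("H", 12)))
        for rec in pending.get(code, []):
            plate.add(rec)
        out.append(plate)
    return out


def read_submission_table(path) -> list[PlateArray]:
    """Inverse of :func:`write_submission_table`."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return _rows_to_plates(rows)


def read_plate_metadata(path) -> PlateArray:
    """Read a single-plate metadata TSV (header: sample_id, role,
    catalogue_number, taxonomy ranks, collection_year, country, flags)."""
    plates = read_submission_table(path)
    if not plates:
        # an empty file still denotes one (empty) array, but the plate code
        # is unknowable; give the conventional empty plate
        return PlateArray("CCDB-0")
    if len(plates) > 1:
        raise PlateError(
            f"expected one plate, found codes {[p.plate_code for p in plates]}"
        )
    return plates[0]
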