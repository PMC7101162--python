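"""Record types and CSV table I/O for SEM and light-microscope measurements.

Measurement tables are plain CSV (UTF-8, ``.`` decimal separator) with the
canonical headers below; header matching is case-insensitive.

SEM table
    ``sample_id, morphotype, length_um, width_um, ct_left_um, ct_right_um``
    (the two central-tube columns are optional and may be empty)
LM table
    ``sample_id, length_um, mass_pg, mean_thickness_um, central_area``
    (``central_area`` is optional; absent values default to ``unknown``)
Metadata table
    ``sample_id, station, month, depth_m, cell_density_per_l``

All lengths are in micrometres, masses in picograms, cell densities in
cells per litre.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("coccomix")

#: Closed morphotype vocabulary: Type A, "Overcalcified" Type A,
#: Group B (Types B/C/B-C pooled) and malformed coccoliths.
MORPHOTYPES = ("A", "OA", "B", "M")

#: Central-area classes distinguishable in the light microscope.
CENTRAL_AREA_CLASSES = ("open", "overcalcified", "unknown")


class TableFormatError(ValueError):
    """Raised when a measurement table cannot be parsed.

    Carries one ``(row, message)`` diagnostic per rejected row, with
    1-based data-row indices (the header is row 0).
    """

    def __init__(self, path, diagnostics: list[tuple[int, str]]):
        self.path = str(path)
        self.diagnostics = diagnostics
        lines = "; ".join(f"row {i}: {msg}" for i, msg in diagnostics)
        super().__init__(f"{path}: {lines}")


@dataclass(frozen=True)
class SemRecord:
    """One SEM-measured coccolith.

    ``length`` is the distal-shield long axis, ``width`` the perpendicular
    short axis (so ``length >= width`` always). ``ct_left``/``ct_right``
    are the central-tube widths measured on both sides along the length
    axis; they are recorded for Type A only and may be absent.
    """

    sample_id: str
    morphotype: str
    length: float
    width: float
    ct_left: float | None = None
    ct_right: float | None = None

    def __post_init__(self):
        if self.morphotype not in MORPHOTYPES:
            raise ValueError(
                f"unknown morphotype code {self.morphotype!r}; "
                f"expected one of {MORPHOTYPES}"
            )
        for name in ("length", "width"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if self.length < self.width:
            raise ValueError(
                f"length ({self.length}) < width ({self.width}): the distal "
                "shield long axis is the length axis"
            )
        for name in ("ct_left", "ct_right"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class LmRecord:
    """One light-microscope-measured coccolith (CPR-method output)."""

    sample_id: str
    length: float
    mass: float
    mean_thickness: float
    central_area: str = "unknown"

    def __post_init__(self):
        if self.central_area not in CENTRAL_AREA_CLASSES:
            raise ValueError(
                f"unknown central-area class {self.central_area!r}; "
                f"expected one of {CENTRAL_AREA_CLASSES}"
            )
        for name in ("length", "mass", "mean_thickness"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.length <= 0:
            raise ValueError(f"length must be > 0, got {self.length}")
        if self.mass < 0:
            raise ValueError(f"mass must be >= 0, got {self.mass}")
        if self.mean_thickness <= 0:
            raise ValueError(
                f"mean_thickness must be > 0, got {self.mean_thickness}"
            )
        if self.mean_thickness >= self.length:
            raise ValueError(
                f"mean_thickness ({self.mean_thickness}) must be smaller "
                f"than length ({self.length})"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample station metadata and cell density (cells/L)."""

    sample_id: str
    station: str
    month: str
    depth: float
    cell_density: float

    def __post_init__(self):
        if not (math.isfinite(self.cell_density) and self.cell_density >= 0):
            raise ValueError(
                f"cell_density must be finite and >= 0, got {self.cell_density}"
            )


_SEM_COLUMNS = ("sample_id", "morphotype", "length_um", "width_um",
                "ct_left_um", "ct_right_um")
_LM_COLUMNS = ("sample_id", "length_um", "mass_pg", "mean_thickness_um",
               "central_area")
_META_COLUMNS = ("sample_id", "station", "month", "depth_m",
                 "cell_density_per_l")


def _open_reader(path, required: Sequence[str]):
    path = Path(path)
    handle = path.open(newline="", encoding="utf-8")
    reader = csv.DictReader(handle)
    if reader.fieldnames is None:
        handle.close()
        raise TableFormatError(path, [(0, "empty file, no header")])
    # case-insensitive canonical headers
    mapping = {name.strip().lower(): name for name in reader.fieldnames}
    missing = [c for c in required if c not in mapping]
    if missing:
        handle.close()
        raise TableFormatError(
            path, [(0, f"missing required column(s): {', '.join(missing)}")]
        )
    return handle, reader, mapping


def _float_or_none(text: str | None):
    if text is None or text.strip() == "":
        return None
    return float(text)


def read_sem_table(path) -> list[SemRecord]:
    """Read an SEM morphometric table into :class:`SemRecord` rows.

    Raises :class:`TableFormatError` listing every rejected row with its
    1-based row index; absent central-tube fields are allowed.
    """
    handle, reader, cols = _open_reader(path, _SEM_COLUMNS[:4])
    records, bad = [], []
    with handle:
        for i, row in enumerate(reader, start=1):
            try:
                records.append(SemRecord(
                    sample_id=row[cols["sample_id"]].strip(),
                    morphotype=row[cols["morphotype"]].strip(),
                    length=float(row[cols["length_um"]]),
                    width=float(row[cols["width_um"]]),
                    ct_left=_float_or_none(row.get(cols.get("ct_left_um", ""))),
                    ct_right=_float_or_none(row.get(cols.get("ct_right_um", ""))),
                ))
            except (ValueError, TypeError, KeyError) as exc:
                bad.append((i, str(exc)))
    if bad:
        raise TableFormatError(path, bad)
    logger.info("read %d SEM records from %s", len(records), path)
    return records


def read_lm_table(path) -> list[LmRecord]:
    """Read a light-microscope measurement table into :class:`LmRecord` rows.

    ``central_area`` defaults to ``"unknown"`` when the column is absent
    or empty. Raises :class:`TableFormatError` with per-row diagnostics.
    """
    handle, reader, cols = _open_reader(path, _LM_COLUMNS[:4])
    records, bad = [], []
    with handle:
        for i, row in enumerate(reader, start=1):
            try:
                area = row.get(cols.get("central_area", ""))
                records.append(LmRecord(
                    sample_id=row[cols["sample_id"]].strip(),
                    length=float(row[cols["length_um"]]),
                    mass=float(row[cols["mass_pg"]]),
                    mean_thickness=float(row[cols["mean_thickness_um"]]),
                    central_area=(area.strip() if area and area.strip()
                                  else "unknown"),
                ))
            except (ValueError, TypeError, KeyError) as exc:
                bad.append((i, str(exc)))
    if bad:
        raise TableFormatError(path, bad)
    logger.info("read %d LM records from %s", len(records), path)
    return records


def read_meta_table(path) -> list[SampleMeta]:
    """Read per-sample metadata (station, month, depth, cell density)."""
    handle, reader, cols = _open_reader(path, _META_COLUMNS)
    records, bad = [], []
    with handle:
        for i, row in enumerate(reader, start=1):
            try:
                records.append(SampleMeta(
                    sample_id=row[cols["sample_id"]].strip(),
                    station=row[cols["station"]].strip(),
                    month=row[cols["month"]].strip(),
                    depth=float(row[cols["depth_m"]]),
                    cell_density=float(row[cols["cell_density_per_l"]]),
                ))
            except (ValueError, TypeError, KeyError) as exc:
                bad.append((i, str(exc)))
    if bad:
        raise TableFormatError(path, bad)
    return records


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return repr(float(value))


def write_sem_table(path, records: Iterable[SemRecord]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(_SEM_COLUMNS)
        for r in records:
            writer.writerow([r.sample_id, r.morphotype, _fmt(r.length),
                             _fmt(r.width), _fmt(r.ct_left), _fmt(r.ct_right)])


def write_lm_table(path, records: Iterable[LmRecord]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(_LM_COLUMNS)
        for r in records:
            writer.writerow([r.sample_id, _fmt(r.length), _fmt(r.mass),
                             _fmt(r.mean_thickness), r.central_area])


def write_meta_table(path, records: Iterable[SampleMeta]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(_META_COLUMNS)
        for r in records:
            writer.writerow([r.sample_id, r.station, r.month,
                             _fmt(r.depth), _fmt(r.cell_density)])
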