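"""The per-comet characterization record and its CSV serialization."""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence


@dataclass
class CometRecord:
    """Full characterization of one comet.

    Geometry uses 0-based (row, col) coordinates; ``bbox`` is half-open on
    its max edges.  ``cph`` (center position of head) is the absolute column
    of the intensity-profile peak; ``head_radius_r`` the distance from CPH
    to the first column whose profile value drops below HT x peak.  ``dna``
    is the summed intensity of the comet, ``tdna`` the fraction of it lying
    in the tail.  The three moments follow the standard definitions:
    extent = TDNA x tail length, Olive = TDNA x tail distance, and the
    moment of inertia is the DNA-normalized intensity-weighted squared
    distance of tail columns from the CPH.
    """

    id: int
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    cph: int
    head_radius_r: float
    tail_length: float
    tail_distance: float
    dna: float
    tdna: float
    extent_moment: float
    olive_moment: float
    inertia_moment: float
    class_label: str = "unclassified"
    flags: str = ""

    def validate(self) -> None:
        if not 0.0 <= self.tdna <= 1.0:
            raise ValueError(f"tdna out of [0,1]: {self.tdna}")
        if self.head_radius_r < 0 or self.tail_length < 0:
            raise ValueError("head radius and tail length must be >= 0")


_SCALAR_COLUMNS = (
    "id", "row_min", "col_min", "row_max", "col_max",
    "centroid_row", "centroid_col", "cph", "head_radius_r",
    "tail_length", "tail_distance", "dna", "tdna",
    "extent_moment", "olive_moment", "inertia_moment",
    "class_label", "flags",
)

_FLOAT_FIELDS = {
    "centroid_row", "centroid_col", "head_radius_r", "tail_length",
    "tail_distance", "dna", "tdna", "extent_moment", "olive_moment",
    "inertia_moment",
}


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def write_records(records: Iterable[CometRecord], path: str | Path) -> None:
    """Write comet records as a CSV table (header + one row per comet).

    Floats are serialized at 6 significant digits and round-trip at that
    precision through :func:`read_records`.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCALAR_COLUMNS)
        for rec in records:
            r0, c0, r1, c1 = rec.bbox
            row = [rec.id, r0, c0, r1, c1,
                   _fmt(rec.centroid[0]), _fmt(rec.centroid[1]), rec.cph,
                   _fmt(rec.head_radius_r), _fmt(rec.tail_length),
                   _fmt(rec.tail_distance), _fmt(rec.dna), _fmt(rec.tdna),
                   _fmt(rec.extent_moment), _fmt(rec.olive_moment),
                   _fmt(rec.inertia_moment), rec.class_label, rec.flags]
            writer.writerow(row)


def read_records(path: str | Path) -> list[CometRecord]:
    """Read a CSV written by :func:`write_records`."""
    out: list[CometRecord] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != _SCALAR_COLUMNS:
            raise ValueError(f"unexpected comet-record header in {path}")
        for row in reader:
            out.append(CometRecord(
                id=int(row["id"]),
                bbox=(int(row["row_min"]), int(row["col_min"]),
                      int(row["row_max"]), int(row["col_max"])),
                centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
                cph=int(row["cph"]),
                head_radius_r=float(row["head_radius_r"]),
                tail_length=float(row["tail_length"]),
                tail_distance=float(row["tail_distance"]),
                dna=float(row["dna"]),
                tdna=float(row["tdna"]),
                extent_moment=float(row["extent_moment"]),
                olive_moment=float(row["olive_moment"]),
                inertia_moment=float(row["inertia_moment"]),
                class_label=row["class_label"],
                flags=row["flags"],
            ))
    return out
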