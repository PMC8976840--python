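"""Traced-membrane contour model and file I/O.

The morphometry arm starts from membrane traces, not raster micrographs:
closed mitochondrial outlines, open ER membrane polylines, and open cristae
polylines, with vertex coordinates in nanometres.  This mirrors the manual
workflow in which organelle membranes are outlined on high-magnification TEM
images and the traces exported for quantification.

Two on-disk dialects are supported:

* JSON -- ``{"field_id", "pixel_size_nm", "contours": [{"id", "label",
  "closed", "parent_mito", "vertices": [[x, y], ...]}, ...]}``; a file may
  hold a single field object or a list of them.
* flat CSV -- one vertex per row with columns
  ``field_id, contour_id, label, closed, parent, x_nm, y_nm``.

All coordinates are nanometres.  Closed contours are normalized to
counter-clockwise orientation on read.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import LinearRing, Polygon

LABELS = ("mitochondrion", "er", "crista")

__all__ = [
    "Contour",
    "MitochondrionProfile",
    "ContactSegment",
    "MorphometryRecord",
    "ContourField",
    "ContourSchemaError",
    "ContourGeometryError",
    "read_contour_fields",
    "write_contour_fields",
]


class ContourSchemaError(ValueError):
    """Raised when a contour record violates the documented schema."""


class ContourGeometryError(ValueError):
    """Raised when a contour is geometrically invalid (degenerate,
    self-intersecting, or containment-violating)."""


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area of a closed vertex loop (nm^2); positive if CCW."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polyline_length(vertices: np.ndarray, closed: bool = False) -> float:
    """Total arc length of a polyline (nm); includes the closing edge if closed."""
    pts = np.vstack([vertices, vertices[:1]]) if closed else vertices
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


@dataclass
class Contour:
    """An ordered membrane trace in nanometres.

    Closed contours (organelle outlines) must be simple polygons and are
    stored counter-clockwise; open contours (ER membranes, cristae) need at
    least two vertices.
    """

    vertices: np.ndarray
    closed: bool
    label: str
    id: str = ""
    parent_mito: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ContourSchemaError(f"contour {self.id!r}: vertices must be (n, 2)")
        if not np.all(np.isfinite(v)):
            raise ContourSchemaError(f"contour {self.id!r}: non-finite coordinates")
        if self.label not in LABELS:
            raise ContourSchemaError(
                f"contour {self.id!r}: unknown label {self.label!r}"
            )
        if self.closed:
            # drop an explicitly repeated closing vertex
            if len(v) > 1 and np.allclose(v[0], v[-1]):
                v = v[:-1]
            if len(v) < 3:
                raise ContourGeometryError(
                    f"contour {self.id!r}: closed contour needs >=3 vertices"
                )
            if abs(signed_area(v)) <= 0.0:
                raise ContourGeometryError(f"contour {self.id!r}: zero-area polygon")
            if not LinearRing(v).is_simple:
                raise ContourGeometryError(
                    f"contour {self.id!r}: self-intersecting closed contour"
                )
            if signed_area(v) < 0:  # normalize to counter-clockwise
                v = v[::-1].copy()
        else:
            if len(v) < 2:
                raise ContourGeometryError(
                    f"contour {self.id!r}: open contour needs >=2 vertices"
                )
        self.vertices = v

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def length(self) -> float:
        """Perimeter for closed contours, arc length for open ones (nm)."""
        return polyline_length(self.vertices, closed=self.closed)

    def area(self) -> float:
        """Enclosed (shoelace) area in nm^2; only defined for closed contours."""
        if not self.closed:
            raise ContourGeometryError("area is defined only for closed contours")
        return signed_area(self.vertices)

    def polygon(self) -> Polygon:
        if not self.closed:
            raise ContourGeometryError("polygon() requires a closed contour")
        return Polygon(self.vertices)


@dataclass
class MitochondrionProfile:
    """One mitochondrion section: its closed outline plus traced cristae."""

    outline: Contour
    cristae: list[Contour] = field(default_factory=list)
    id: str = ""
    field_id: str = ""

    def __post_init__(self) -> None:
        if not (self.outline.closed and self.outline.label == "mitochondrion"):
            raise ContourSchemaError(
                f"profile {self.id!r}: outline must be a closed mitochondrion contour"
            )
        for c in self.cristae:
            if c.closed or c.label != "crista":
                raise ContourSchemaError(
                    f"profile {self.id!r}: cristae must be open 'crista' contours"
                )


@dataclass
class ContactSegment:
    """A maximal arc of a mitochondrial outline lying in the ER gap band.

    Arc positions are arc lengths (nm) along the counter-clockwise outline,
    measured from its first vertex.  ``thickness_samples`` holds the in-band
    OMM-to-ER distances at the resampled outline positions of the segment.
    """

    arc_start: float
    arc_end: float
    thickness_samples: np.ndarray
    er_id: str = ""

    @property
    def length(self) -> float:
        return self.arc_end - self.arc_start


@dataclass
class MorphometryRecord:
    """Per-mitochondrion measurement panel.

    Units follow the TEM-morphometry convention: areas in um^2, cristae
    abundance in um/um^2, contact coverage in percent of perimeter, cleft
    thickness in nm.
    """

    mito_id: str
    field_id: str
    area_um2: float
    perimeter_um: float
    circularity: float
    aspect_ratio: float
    cristae_abundance: float
    merc_coverage: float
    merc_mean_thickness: float | None
    merc_lengths: list[float]
    age_group: str | None = None
    tissue: str | None = None

    def to_dict(self) -> dict:
        d = {
            "mito_id": self.mito_id,
            "field_id": self.field_id,
            "area_um2": self.area_um2,
            "perimeter_um": self.perimeter_um,
            "circularity": self.circularity,
            "aspect_ratio": self.aspect_ratio,
            "cristae_abundance": self.cristae_abundance,
            "merc_coverage": self.merc_coverage,
            "merc_mean_thickness": self.merc_mean_thickness,
            "n_contacts": len(self.merc_lengths),
            "merc_total_length_nm": float(sum(self.merc_lengths)),
            "age_group": self.age_group,
            "tissue": self.tissue,
        }
        return d


@dataclass
class ContourField:
    """All traces of one imaged field: mitochondrion profiles and ER polylines."""

    field_id: str
    profiles: list[MitochondrionProfile]
    er: list[Contour]
    pixel_size_nm: float = 1.0
    # ER traces are assumed already curated to be ribosome-free; the flag is
    # carried through so downstream outputs can record the assumption.
    assume_ribosome_free: bool = True


def _field_from_records(field_id: str, pixel: float, records: list[dict]) -> ContourField:
    mitos: dict[str, Contour] = {}
    cristae: dict[str, list[Contour]] = {}
    er: list[Contour] = []
    for rec in records:
        label = rec.get("label")
        closed = bool(rec.get("closed"))
        cid = str(rec.get("id", ""))
        try:
            contour = Contour(
                vertices=np.asarray(rec["vertices"], dtype=float),
                closed=closed,
                label=label,
                id=cid,
                parent_mito=rec.get("parent_mito"),
            )
        except KeyError as exc:
            raise ContourSchemaError(
                f"field {field_id!r} contour {cid!r}: missing key {exc}"
            ) from exc
        if label == "mitochondrion":
            if not closed:
                raise ContourSchemaError(
                    f"field {field_id!r}: mitochondrion contour {cid!r} must be closed"
                )
            mitos[cid] = contour
        elif label == "crista":
            parent = rec.get("parent_mito")
            if parent is None:
                raise ContourSchemaError(
                    f"field {field_id!r}: crista {cid!r} lacks parent_mito"
                )
            cristae.setdefault(str(parent), []).append(contour)
        elif label == "er":
            if closed:
                raise ContourSchemaError(
                    f"field {field_id!r}: er contour {cid!r} must be open"
                )
            er.append(contour)
        else:
            raise ContourSchemaError(
                f"field {field_id!r}: contour {cid!r} has unknown label {label!r}"
            )
    orphans = set(cristae) - set(mitos)
    if orphans:
        raise ContourSchemaError(
            f"field {field_id!r}: cristae reference unknown mitochondria {sorted(orphans)}"
        )
    profiles = [
        MitochondrionProfile(
            outline=mitos[mid],
            cristae=cristae.get(mid, []),
            id=mid,
            field_id=field_id,
        )
        for mid in sorted(mitos)
    ]
    er.sort(key=lambda c: c.id)
    return ContourField(field_id=field_id, profiles=profiles, er=er, pixel_size_nm=pixel)


def read_contour_fields(path: str | Path) -> list[ContourField]:
    """Read a contour file (JSON or flat CSV, by extension) into fields.

    Enforces all contour invariants; closed outlines come back
    counter-clockwise regardless of stored orientation.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ContourSchemaError(f"{path}: not valid JSON ({exc})") from exc
    if isinstance(payload, dict):
        payload = [payload]
    fields = []
    for obj in payload:
        if "field_id" not in obj or "contours" not in obj:
            raise ContourSchemaError(f"{path}: field object needs field_id and contours")
        fields.append(
            _field_from_records(
                str(obj["field_id"]),
                float(obj.get("pixel_size_nm", 1.0)),
                obj["contours"],
            )
        )
    return fields


def _read_csv(path: Path) -> list[ContourField]:
    rows_by_field: dict[str, dict[str, dict]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        needed = {"field_id", "contour_id", "label", "closed", "parent", "x_nm", "y_nm"}
        if reader.fieldnames is None or not needed <= set(reader.fieldnames):
            raise ContourSchemaError(f"{path}: CSV header must contain {sorted(needed)}")
        for i, row in enumerate(reader, start=2):
            fid = row["field_id"]
            if fid not in rows_by_field:
                rows_by_field[fid] = {}
                order.append(fid)
            recs = rows_by_field[fid]
            cid = row["contour_id"]
            if cid not in recs:
                recs[cid] = {
                    "id": cid,
                    "label": row["label"],
                    "closed": row["closed"].strip().lower() in ("1", "true", "yes"),
                    "parent_mito": row["parent"] or None,
                    "vertices": [],
                }
            try:
                recs[cid]["vertices"].append([float(row["x_nm"]), float(row["y_nm"])])
            except ValueError as exc:
                raise ContourSchemaError(f"{path} line {i}: bad coordinate") from exc
    return [
        _field_from_records(fid, 1.0, list(rows_by_field[fid].values())) for fid in order
    ]


def write_contour_fields(fields: Iterable[ContourField], path: str | Path) -> None:
    """Write fields as contour JSON (deterministic key order and formatting)."""
    payload = []
    for f in fields:
        contours = []
        for p in f.profiles:
            contours.append(_contour_obj(p.outline))
            contours.extend(_contour_obj(c) for c in p.cristae)
        contours.extend(_contour_obj(c) for c in f.er)
        payload.append(
            {
                "field_id": f.field_id,
                "pixel_size_nm": f.pixel_size_nm,
                "assume_ribosome_free": f.assume_ribosome_free,
                "contours": contours,
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _contour_obj(c: Contour) -> dict:
    return {
        "id": c.id,
        "label": c.label,
        "closed": c.closed,
        "parent_mito": c.parent_mito,
        "vertices": [[float(x), float(y)] for x, y in c.vertices],
    }
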