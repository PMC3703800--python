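"""Domain model for expert lesion annotations and their XML serialization.

An annotation dataset consists of one document per (image, expert) pair. Each
document carries a list of *markings*: a lesion-type label, a spatial region
(polygon, circle or ellipse), at least one representative point (the cue
location that drew the expert's attention), and a three-level subjective
confidence. The on-disk format is a light-weight XML dialect described by the
DTD in :data:`ANNOTATION_DTD`; the writer emits a canonical form (fixed element
order, fixed numeric formatting) that :func:`parse_annotation_xml` inverts
exactly.

Coordinate convention: 0-based pixel coordinates, origin at the top-left pixel
corner, ``x`` rightward (columns), ``y`` downward (rows).
"""

from __future__ import annotations

import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "ANNOTATION_DTD",
    "CANONICAL_LESION_TYPES",
    "AnnotationParseError",
    "AnnotationValidationError",
    "ConfidenceLevel",
    "Geometry",
    "RepresentativePoint",
    "Marking",
    "ExpertAnnotationSet",
    "parse_annotation_xml",
    "write_annotation_xml",
    "validate_dataset",
]

#: Reconstructed document type definition for the annotation format. The
#: original kit's DTD body is not public; this schema covers the same
#: information (image/expert identity, regions, representative points,
#: three-level confidence) and is what this package reads and writes.
ANNOTATION_DTD = """\
<!ELEMENT imageannotation (imagename, expert, imagesize, markinglist)>
<!ELEMENT imagename (#PCDATA)>
<!ELEMENT expert (#PCDATA)>
<!ELEMENT imagesize (height, width)>
<!ELEMENT height (#PCDATA)>
<!ELEMENT width (#PCDATA)>
<!ELEMENT markinglist (marking*)>
<!ELEMENT marking (lesiontype, (polygonregion | circleregion | ellipseregion),
                   representativepoint+, confidencelevel)>
<!ELEMENT lesiontype (#PCDATA)>
<!ELEMENT polygonregion (point, point, point+)>
<!ELEMENT circleregion (center, radius)>
<!ELEMENT ellipseregion (center, radiusx, radiusy, orientation)>
<!ELEMENT point (x, y)>
<!ELEMENT center (x, y)>
<!ELEMENT representativepoint (center, radius)>
<!ELEMENT confidencelevel (#PCDATA)>
<!ELEMENT x (#PCDATA)>
<!ELEMENT y (#PCDATA)>
<!ELEMENT radius (#PCDATA)>
<!ELEMENT radiusx (#PCDATA)>
<!ELEMENT radiusy (#PCDATA)>
<!ELEMENT orientation (#PCDATA)>
"""

#: Lesion labels agreed beforehand for diabetic retinopathy; arbitrary labels
#: are nevertheless accepted, since experts may define their own classes.
CANONICAL_LESION_TYPES = (
    "hard_exudates",
    "soft_exudates",
    "microaneurysms",
    "haemorrhages",
    "neovascularisation",
)


class AnnotationParseError(ValueError):
    """Malformed XML or a document not matching the annotation schema."""


class AnnotationValidationError(ValueError):
    """A structurally valid document violating a domain invariant."""


class ConfidenceLevel(Enum):
    """Three-level subjective confidence of an expert marking.

    The numeric scale maps low -> 1/3, moderate -> 2/3, high -> 1. The only
    hard requirement on the scale is strict monotonicity; these defaults give
    an evenly spaced increasing three-point scale in (0, 1].
    """

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"

    @property
    def numeric(self) -> float:
        return _CONFIDENCE_NUMERIC[self]

    @classmethod
    def from_numeric(cls, value: float) -> "ConfidenceLevel":
        for level, num in _CONFIDENCE_NUMERIC.items():
            if math.isclose(num, value, rel_tol=0, abs_tol=1e-9):
                return level
        raise ValueError(f"no confidence level with numeric value {value!r}")


_CONFIDENCE_NUMERIC = {
    ConfidenceLevel.LOW: 1.0 / 3.0,
    ConfidenceLevel.MODERATE: 2.0 / 3.0,
    ConfidenceLevel.HIGH: 1.0,
}


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise AnnotationValidationError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class Geometry:
    """Spatial region of a marking: polygon, circle area or ellipse area.

    Exactly one variant's fields are populated:

    * ``polygon`` — ``vertices``: ordered (x, y) pairs, at least 3;
    * ``circle_area`` — ``center`` and ``radius`` (> 0 pixels);
    * ``ellipse_area`` — ``center``, ``radii`` = (rx, ry) and ``orientation``
      in radians (counter-clockwise rotation of the rx axis).
    """

    variant: str
    vertices: tuple[tuple[float, float], ...] | None = None
    center: tuple[float, float] | None = None
    radius: float | None = None
    radii: tuple[float, float] | None = None
    orientation: float | None = None

    def __post_init__(self) -> None:
        if self.variant == "polygon":
            if self.vertices is None or len(self.vertices) < 3:
                raise AnnotationValidationError("polygon requires >=3 vertices")
            if any(v is not None for v in (self.center, self.radius, self.radii, self.orientation)):
                raise AnnotationValidationError("polygon carries only vertices")
            for x, y in self.vertices:
                _check_finite("polygon vertex", x, y)
        elif self.variant == "circle_area":
            if self.center is None or self.radius is None:
                raise AnnotationValidationError("circle_area requires center and radius")
            if self.vertices is not None or self.radii is not None or self.orientation is not None:
                raise AnnotationValidationError("circle_area carries only center and radius")
            _check_finite("circle", *self.center, self.radius)
            if self.radius < 0:
                raise AnnotationValidationError("circle radius must be >= 0")
        elif self.variant == "ellipse_area":
            if self.center is None or self.radii is None or self.orientation is None:
                raise AnnotationValidationError(
                    "ellipse_area requires center, radii and orientation"
                )
            if self.vertices is not None or self.radius is not None:
                raise AnnotationValidationError("ellipse_area carries no polygon/circle fields")
            _check_finite("ellipse", *self.center, *self.radii, self.orientation)
            if self.radii[0] <= 0 or self.radii[1] <= 0:
                raise AnnotationValidationError("ellipse radii must be > 0")
        else:
            raise AnnotationValidationError(f"unknown geometry variant {self.variant!r}")

    @classmethod
    def polygon(cls, vertices: Iterable[tuple[float, float]]) -> "Geometry":
        return cls(variant="polygon", vertices=tuple((float(x), float(y)) for x, y in vertices))

    @classmethod
    def circle(cls, center: tuple[float, float], radius: float) -> "Geometry":
        return cls(
            variant="circle_area",
            center=(float(center[0]), float(center[1])),
            radius=float(radius),
        )

    @classmethod
    def ellipse(
        cls,
        center: tuple[float, float],
        radii: tuple[float, float],
        orientation: float,
    ) -> "Geometry":
        return cls(
            variant="ellipse_area",
            center=(float(center[0]), float(center[1])),
            radii=(float(radii[0]), float(radii[1])),
            orientation=float(orientation),
        )


@dataclass(frozen=True)
class RepresentativePoint:
    """A cue location: the most salient spot of evidence for the lesion."""

    center: tuple[float, float]
    radius: float = 0.0

    def __post_init__(self) -> None:
        _check_finite("representative point", *self.center, self.radius)
        if self.radius < 0:
            raise AnnotationValidationError("representative point radius must be >= 0")


@dataclass(frozen=True)
class Marking:
    """One expert's annotation of one lesion."""

    lesion_type: str
    region: Geometry
    rep_points: tuple[RepresentativePoint, ...]
    confidence: ConfidenceLevel
    #: Unknown XML child elements preserved verbatim for lossless round-trips.
    extras: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.lesion_type or not self.lesion_type.strip():
            raise AnnotationValidationError("lesion_type must be a non-empty token")
        if len(self.rep_points) < 1:
            raise AnnotationValidationError(
                f"marking of type {self.lesion_type!r} requires >=1 representative point"
            )


@dataclass(frozen=True)
class ExpertAnnotationSet:
    """All markings of one expert on one image.

    ``image_size`` is (height, width) in pixels; geometry extending beyond the
    bounds is accepted here and clipped at rasterization time.
    """

    image_id: str
    expert_id: str
    image_size: tuple[int, int]
    markings: tuple[Marking, ...] = ()

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise AnnotationValidationError("image_size must be positive")
        if not self.image_id or not self.expert_id:
            raise AnnotationValidationError("image_id and expert_id must be non-empty")

    def lesion_types(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for m in self.markings:
            seen.setdefault(m.lesion_type, None)
        return tuple(seen)


# ---------------------------------------------------------------------------
# canonical numeric formatting: up to 6 decimal places, trailing zeros
# stripped, negative zero normalized.  Idempotent under parse -> write.

def _fmt(value: float) -> str:
    s = f"{float(value):.6f}".rstrip("0").rstrip(".")
    if s in ("-0", ""):
        s = "0"
    return s


def _parse_float(text: str | None, where: str) -> float:
    if text is None or not text.strip():
        raise AnnotationParseError(f"missing numeric value in {where}")
    try:
        return float(text.strip())
    except ValueError as exc:
        raise AnnotationParseError(f"bad numeric value {text!r} in {where}") from exc


def _child(elem: ET.Element, tag: str, where: str) -> ET.Element:
    found = elem.find(tag)
    if found is None:
        raise AnnotationParseError(f"missing <{tag}> in {where}")
    return found


def _text(elem: ET.Element, tag: str, where: str) -> str:
    return (_child(elem, tag, where).text or "").strip()


_KNOWN_MARKING_TAGS = frozenset(
    {
        "lesiontype",
        "polygonregion",
        "circleregion",
        "ellipseregion",
        "representativepoint",
        "confidencelevel",
    }
)


def parse_annotation_xml(document: str | bytes) -> ExpertAnnotationSet:
    """Parse one annotation document into an :class:`ExpertAnnotationSet`.

    Raises :class:`AnnotationParseError` for malformed XML (with the line
    number) or schema deviations, and :class:`AnnotationValidationError` for
    domain-invariant violations (e.g. a polygon with fewer than 3 vertices),
    naming the offending marking.
    """
    if isinstance(document, bytes):
        document = document.decode("utf-8")
    # strip DOCTYPE: stdlib ElementTree does not process external DTDs
    body = re.sub(r"<!DOCTYPE[^>]*>", "", document, count=1)
    try:
        root = ET.fromstring(body)
    except ET.ParseError as exc:
        line, col = exc.position
        raise AnnotationParseError(f"malformed XML at line {line}, column {col}: {exc}") from exc
    if root.tag != "imageannotation":
        raise AnnotationParseError(f"root element must be <imageannotation>, got <{root.tag}>")

    image_id = _text(root, "imagename", "document")
    expert_id = _text(root, "expert", "document")
    size_el = _child(root, "imagesize", "document")
    height = int(_parse_float(_text(size_el, "height", "imagesize"), "imagesize/height"))
    width = int(_parse_float(_text(size_el, "width", "imagesize"), "imagesize/width"))

    markings: list[Marking] = []
    mlist = _child(root, "markinglist", "document")
    for idx, mel in enumerate(mlist.findall("marking")):
        where = f"marking #{idx}"
        lesion_type = _text(mel, "lesiontype", where)

        region = _parse_region(mel, where)
        rep_points = tuple(
            RepresentativePoint(center=_parse_xy(_child(rp, "center", where), where),
                                radius=_parse_float(_text(rp, "radius", where), where))
            for rp in mel.findall("representativepoint")
        )
        if not rep_points:
            raise AnnotationParseError(f"{where}: requires >=1 <representativepoint>")
        conf_text = _text(mel, "confidencelevel", where)
        try:
            confidence = ConfidenceLevel(conf_text)
        except ValueError as exc:
            raise AnnotationParseError(
                f"{where}: unknown confidence level {conf_text!r}"
            ) from exc
        extras = tuple(
            ET.tostring(ch, encoding="unicode").strip()
            for ch in mel
            if ch.tag not in _KNOWN_MARKING_TAGS
        )
        try:
            markings.append(
                Marking(
                    lesion_type=lesion_type,
                    region=region,
                    rep_points=rep_points,
                    confidence=confidence,
                    extras=extras,
                )
            )
        except AnnotationValidationError as exc:
            raise AnnotationValidationError(f"{where}: {exc}") from exc

    return ExpertAnnotationSet(
        image_id=image_id,
        expert_id=expert_id,
        image_size=(height, width),
        markings=tuple(markings),
    )


def _parse_xy(elem: ET.Element, where: str) -> tuple[float, float]:
    return (
        _parse_float(_text(elem, "x", where), where),
        _parse_float(_text(elem, "y", where), where),
    )


def _parse_region(mel: ET.Element, where: str) -> Geometry:
    poly = mel.find("polygonregion")
    circ = mel.find("circleregion")
    ell = mel.find("ellipseregion")
    present = [e for e in (poly, circ, ell) if e is not None]
    if len(present) != 1:
        raise AnnotationParseError(f"{where}: exactly one region element required")
    try:
        if poly is not None:
            vertices = [_parse_xy(p, where) for p in poly.findall("point")]
            if len(vertices) < 3:
                raise AnnotationValidationError(f"{where}: polygon requires >=3 vertices")
            return Geometry.polygon(vertices)
        if circ is not None:
            return Geometry.circle(
                _parse_xy(_child(circ, "center", where), where),
                _parse_float(_text(circ, "radius", where), where),
            )
        assert ell is not None
        return Geometry.ellipse(
            _parse_xy(_child(ell, "center", where), where),
            (
                _parse_float(_text(ell, "radiusx", where), where),
                _parse_float(_text(ell, "radiusy", where), where),
            ),
            _parse_float(_text(ell, "orientation", where), where),
        )
    except AnnotationValidationError as exc:
        if str(exc).startswith(where):
            raise
        raise AnnotationValidationError(f"{where}: {exc}") from exc


def write_annotation_xml(aset: ExpertAnnotationSet) -> str:
    """Serialize to the canonical XML form (inverse of the parser).

    Element order is fixed, numbers are printed with up to 6 decimal places
    (trailing zeros stripped), and unknown preserved elements are re-emitted
    verbatim after the known children of their marking, so
    ``write(parse(write(s))) == write(s)`` byte for byte.
    """
    out: list[str] = ['<?xml version="1.0" encoding="UTF-8"?>', "<imageannotation>"]
    out.append(f"  <imagename>{_escape(aset.image_id)}</imagename>")
    out.append(f"  <expert>{_escape(aset.expert_id)}</expert>")
    out.append("  <imagesize>")
    out.append(f"    <height>{aset.image_size[0]}</height>")
    out.append(f"    <width>{aset.image_size[1]}</width>")
    out.append("  </imagesize>")
    out.append("  <markinglist>")
    for m in aset.markings:
        out.append("    <marking>")
        out.append(f"      <lesiontype>{_escape(m.lesion_type)}</lesiontype>")
        out.extend(_region_lines(m.region))
        for rp in m.rep_points:
            out.append("      <representativepoint>")
            out.append(_xy_lines(rp.center, indent=8))
            out.append(f"        <radius>{_fmt(rp.radius)}</radius>")
            out.append("      </representativepoint>")
        out.append(f"      <confidencelevel>{m.confidence.value}</confidencelevel>")
        for extra in m.extras:
            out.append("      " + extra)
        out.append("    </marking>")
    out.append("  </markinglist>")
    out.append("</imageannotation>")
    return "\n".join(out) + "\n"


def _escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def _xy_lines(xy: tuple[float, float], indent: int) -> str:
    pad = " " * indent
    return (
        f"{pad}<center>\n{pad}  <x>{_fmt(xy[0])}</x>\n"
        f"{pad}  <y>{_fmt(xy[1])}</y>\n{pad}</center>"
    )


def _region_lines(g: Geometry) -> list[str]:
    lines: list[str] = []
    if g.variant == "polygon":
        assert g.vertices is not None
        lines.append("      <polygonregion>")
        for x, y in g.vertices:
            lines.append(
                f"        <point>\n          <x>{_fmt(x)}</x>\n"
                f"          <y>{_fmt(y)}</y>\n        </point>"
            )
        lines.append("      </polygonregion>")
    elif g.variant == "circle_area":
        assert g.center is not None and g.radius is not None
        lines.append("      <circleregion>")
        lines.append(_xy_lines(g.center, indent=8))
        lines.append(f"        <radius>{_fmt(g.radius)}</radius>")
        lines.append("      </circleregion>")
    else:
        assert g.center is not None and g.radii is not None and g.orientation is not None
        lines.append("      <ellipseregion>")
        lines.append(_xy_lines(g.center, indent=8))
        lines.append(f"        <radiusx>{_fmt(g.radii[0])}</radiusx>")
        lines.append(f"        <radiusy>{_fmt(g.radii[1])}</radiusy>")
        lines.append(f"        <orientation>{_fmt(g.orientation)}</orientation>")
        lines.append("      </ellipseregion>")
    return lines


@dataclass(frozen=True)
class DatasetViolation:
    """One cross-document inconsistency found by :func:`validate_dataset`."""

    kind: str  # "duplicate_pair" | "size_conflict"
    image_id: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind}: image {self.image_id!r}: {self.detail}"


def validate_dataset(sets: Sequence[ExpertAnnotationSet]) -> list[DatasetViolation]:
    """Check cross-document consistency; an empty result means a clean dataset.

    Reported violations: duplicate (image_id, expert_id) pairs, and
    conflicting declared image sizes for the same image_id. Violations are
    data, not exceptions.
    """
    violations: list[DatasetViolation] = []
    seen_pairs: set[tuple[str, str]] = set()
    sizes: dict[str, tuple[int, int]] = {}
    for s in sets:
        pair = (s.image_id, s.expert_id)
        if pair in seen_pairs:
            violations.append(
                DatasetViolation(
                    kind="duplicate_pair",
                    image_id=s.image_id,
                    detail=f"duplicate annotation set for expert {s.expert_id!r}",
                )
            )
        seen_pairs.add(pair)
        if s.image_id in sizes and sizes[s.image_id] != s.image_size:
            violations.append(
                DatasetViolation(
                    kind="size_conflict",
                    image_id=s.image_id,
                    detail=f"image_size {s.image_size} conflicts with {sizes[s.image_id]}",
                )
            )
        sizes.setdefault(s.image_id, s.image_size)
    return violations
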