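"""Readers and writers for slices, masks and nodule annotations.

DICOM intensities are converted to Hounsfield units via the rescale
slope/intercept tags; NIfTI and PNG pass grayscale values through.  All grids
are row-major with 0-based (row, col) coordinates.  Masks are {0, 1} in
memory and 0/255 in PNG files for viewer friendliness.

Annotations arrive either in the simplified JSON dialect used throughout the
test fixtures::

    {"readers": [{"id": "R1",
                  "contours": [{"slice": 0, "points": [[r, c], ...]}]}]}

or, best effort, in LIDC-style XML (readingSession / unblindedReadNodule /
roi / edgeMap elements, namespace-agnostic).  Contours smaller than 3 mm
equivalent diameter are retained but flagged; filtering happens downstream
at rasterization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class AnnotationError(ValueError):
    """Malformed annotation source."""


@dataclass
class Contour:
    """Closed nodule outline on one slice; points are (row, col) vertices."""

    slice_index: int
    points: list[tuple[float, float]]
    pixel_spacing_mm: float = 1.0

    def __post_init__(self):
        pts = [tuple(map(float, p)) for p in self.points]
        if len(pts) >= 2 and pts[0] == pts[-1]:
            pts = pts[:-1]
        if len(pts) < 3:
            raise AnnotationError(
                "unclosed polygon: a contour needs at least 3 distinct vertices"
            )
        self.points = pts

    @property
    def area_mm2(self) -> float:
        """Shoelace polygon area scaled by the pixel spacing."""
        pts = np.asarray(self.points)
        r, c = pts[:, 0], pts[:, 1]
        area_px = 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))
        return area_px * self.pixel_spacing_mm**2

    @property
    def equivalent_diameter_mm(self) -> float:
        """Diameter of the circle with the contour's area."""
        return 2.0 * float(np.sqrt(self.area_mm2 / np.pi))

    @property
    def meets_size_rule(self) -> bool:
        """True when the nodule reaches the 3 mm full-annotation threshold."""
        return self.equivalent_diameter_mm >= 3.0


@dataclass
class ReaderAnnotation:
    reader_id: str
    contours: list[Contour] = field(default_factory=list)


@dataclass
class AnnotationSet:
    readers: list[ReaderAnnotation] = field(default_factory=list)

    def reader(self, reader_id: str) -> ReaderAnnotation:
        for r in self.readers:
            if r.reader_id == reader_id:
                return r
        raise KeyError(f"unknown reader id {reader_id!r}")

    def for_slice(self, slice_index: int) -> "AnnotationSet":
        return AnnotationSet([
            ReaderAnnotation(r.reader_id,
                             [c for c in r.contours if c.slice_index == slice_index])
            for r in self.readers
        ])


@dataclass
class SliceRecord:
    image: np.ndarray
    patient_id: str = ""
    series_id: str = ""
    slice_index: int = 0
    pixel_spacing_mm: float | None = None
    source_format: str = ""

    def __post_init__(self):
        if self.pixel_spacing_mm is not None and self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")


_FORMATS = ("dicom", "nifti", "png")
_EXT_FORMAT = {".dcm": "dicom", ".dicom": "dicom", ".nii": "nifti",
               ".png": "png"}


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return "nifti"
    fmt = _EXT_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"unsupported file extension: {path.suffix!r} ({path})")
    return fmt


def read_slice(path: str | Path, format: str | None = None,
               slice_index: int = 0) -> SliceRecord:
    """Read one grayscale slice from DICOM, NIfTI or PNG."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(f"cannot read slice: {path}")
    try:
        if fmt == "dicom":
            return _read_dicom(path, slice_index)
        if fmt == "nifti":
            return _read_nifti(path, slice_index)
        return _read_png(path, slice_index)
    except (FileNotFoundError, ValueError):
        raise
    except Exception as exc:
        raise ValueError(f"unreadable or corrupt {fmt} file {path}: {exc}") from exc


def _read_dicom(path: Path, slice_index: int) -> SliceRecord:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = getattr(ds, "RescaleSlope", None)
    intercept = getattr(ds, "RescaleIntercept", None)
    if slope is None or intercept is None:
        warnings.warn(f"{path}: missing rescale tags; using raw stored values")
    else:
        arr = arr * float(slope) + float(intercept)
    spacing = None
    ps = getattr(ds, "PixelSpacing", None)
    if ps is not None:
        spacing = float(ps[0])
    return SliceRecord(
        image=arr,
        patient_id=str(getattr(ds, "PatientID", "")),
        series_id=str(getattr(ds, "SeriesInstanceUID", "")),
        slice_index=slice_index,
        pixel_spacing_mm=spacing,
        source_format="dicom",
    )


def _read_nifti(path: Path, slice_index: int) -> SliceRecord:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 3:
        data = data[:, :, slice_index]
    zooms = img.header.get_zooms()
    spacing = float(zooms[0]) if zooms and zooms[0] > 0 else None
    return SliceRecord(image=data, slice_index=slice_index,
                       pixel_spacing_mm=spacing, source_format="nifti")


def _read_png(path: Path, slice_index: int) -> SliceRecord:
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("F"), dtype=np.float64)
    return SliceRecord(image=arr, slice_index=slice_index, source_format="png")


def write_mask(mask: np.ndarray, path: str | Path, format: str | None = None) -> None:
    """Write a binary mask as PNG (0/255) or NIfTI (0/1); lossless round trip."""
    path = Path(path)
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    fmt = format or _infer_format(path)
    if fmt == "png":
        from PIL import Image

        Image.fromarray((m.astype(np.uint8) * 255)).save(path)
    elif fmt == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(m.astype(np.uint8), affine=np.eye(4)), str(path))
    else:
        raise ValueError("mask format must be png or nifti")


def read_mask(path: str | Path, format: str | None = None) -> np.ndarray:
    """Read a mask written by :func:`write_mask` back to {0, 1}."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "png":
        from PIL import Image

        with Image.open(path) as im:
            return (np.asarray(im) > 0).astype(np.uint8)
    if fmt == "nifti":
        import nibabel as nib

        return (np.asanyarray(nib.load(str(path)).dataobj) > 0).astype(np.uint8)
    raise ValueError("mask format must be png or nifti")


# --------------------------------------------------------------------------
# annotation parsing
# --------------------------------------------------------------------------
def parse_annotations(source: str | Path, dialect: str = "json",
                      pixel_spacing_mm: float = 1.0) -> AnnotationSet:
    """Parse nodule contours from simplified JSON or LIDC-style XML."""
    if dialect == "json":
        return _parse_json(Path(source), pixel_spacing_mm)
    if dialect == "lidc-xml":
        return _parse_lidc_xml(Path(source), pixel_spacing_mm)
    raise ValueError("dialect must be 'json' or 'lidc-xml'")


def _parse_json(path: Path, spacing: float) -> AnnotationSet:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"malformed JSON at {path}:{exc.lineno}: {exc.msg}") from exc
    readers = []
    for rd in payload.get("readers", []):
        contours = [
            Contour(slice_index=int(c.get("slice", 0)), points=c["points"],
                    pixel_spacing_mm=spacing)
            for c in rd.get("contours", [])
        ]
        readers.append(ReaderAnnotation(str(rd["id"]), contours))
    return AnnotationSet(readers)


def _parse_lidc_xml(path: Path, spacing: float) -> AnnotationSet:
    from lxml import etree

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise AnnotationError(f"malformed XML at {path}: {exc}") from exc

    def local(el, name):
        return el.findall(f".//{{*}}{name}") or el.findall(f".//{name}")

    readers = []
    for i, session in enumerate(local(tree.getroot(), "readingSession")):
        rid_el = local(session, "servicingRadiologistID")
        rid = rid_el[0].text.strip() if rid_el and rid_el[0].text else f"reader{i}"
        contours = []
        for nodule in local(session, "unblindedReadNodule"):
            for roi in local(nodule, "roi"):
                incl = local(roi, "inclusion")
                if incl and incl[0].text and incl[0].text.strip().upper() == "FALSE":
                    continue
                pts = []
                for edge in local(roi, "edgeMap"):
                    x = local(edge, "xCoord")
                    y = local(edge, "yCoord")
                    if x and y:
                        pts.append((float(y[0].text), float(x[0].text)))
                if len(pts) >= 3:
                    contours.append(Contour(0, pts, spacing))
        readers.append(ReaderAnnotation(rid, contours))
    return AnnotationSet(readers)
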