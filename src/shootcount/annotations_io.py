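"""Annotation and image I/O plus single-tree crop extraction.

Coordinate conventions
----------------------
Everything in this package is 0-based.  Boxes are half-open pixel
rectangles ``[xmin, xmax) x [ymin, ymax)`` so that width = xmax - xmin and
area arithmetic (IoU, cropping) is unambiguous.  Pascal-VOC XML files, as
written by LabelImg, store 1-based *inclusive* indices; they are converted
on read (``xmin-1, ymin-1, xmax, ymax``) and converted back on write.

Point annotations (one dot per shoot) travel as CSV with a metadata header
or as JSON; both carry the image id and dimensions so a file is
self-describing.  Density maps are persisted as 32-bit single-channel TIFF
with a JSON sidecar holding the count and stride.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image

__all__ = [
    "PointAnnotation",
    "BoxAnnotation",
    "Box",
    "AnnotationFormatError",
    "read_voc_boxes",
    "write_voc_boxes",
    "read_points",
    "write_points",
    "crop_single_trees",
    "CropRecord",
    "load_image",
    "save_image",
    "save_density",
    "load_density",
]


class AnnotationFormatError(ValueError):
    """Raised when an annotation file parses but violates the format contract."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in 0-based, half-open pixel coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    label: str = "tree"
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise AnnotationFormatError(
                f"degenerate box ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise AnnotationFormatError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)


@dataclass
class BoxAnnotation:
    """All crown boxes of one image (ground truth or detector output)."""

    image_id: str
    boxes: list[Box] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass
class PointAnnotation:
    """Shoot dot annotations of one image: one (x, y) per shoot.

    ``points`` is an (n, 2) float array of x, y pixel coordinates; every
    point must lie inside ``[0, width) x [0, height)``.
    """

    image_id: str
    width: int
    height: int
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.width <= 0 or self.height <= 0:
            raise AnnotationFormatError("image dimensions must be positive")
        ok_x = (pts[:, 0] >= 0) & (pts[:, 0] < self.width)
        ok_y = (pts[:, 1] >= 0) & (pts[:, 1] < self.height)
        bad = np.flatnonzero(~(ok_x & ok_y))
        if bad.size:
            i = int(bad[0])
            raise AnnotationFormatError(
                f"point {i} at ({pts[i, 0]}, {pts[i, 1]}) outside "
                f"[0, {self.width}) x [0, {self.height})"
            )
        object.__setattr__(self, "points", pts)

    @property
    def count(self) -> int:
        return int(self.points.shape[0])

    def __len__(self) -> int:
        return self.count


# ---------------------------------------------------------------------------
# Pascal-VOC boxes
# ---------------------------------------------------------------------------

_VOC_FIELDS = ("xmin", "ymin", "xmax", "ymax")


def read_voc_boxes(path: str | Path) -> BoxAnnotation:
    """Read a Pascal-VOC XML file (LabelImg dialect) into a :class:`BoxAnnotation`.

    VOC's 1-based inclusive pixel indices become this package's 0-based
    half-open convention: ``(xmin-1, ymin-1, xmax, ymax)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise AnnotationFormatError(f"{path}: not well-formed XML: {exc}") from exc
    root = tree.getroot()
    image_id = root.findtext("filename") or path.stem
    boxes: list[Box] = []
    for idx, obj in enumerate(root.iter("object"), start=1):
        bnd = obj.find("bndbox")
        if bnd is None:
            raise AnnotationFormatError(f"{path}: object {idx} has no <bndbox>")
        vals = {}
        for name in _VOC_FIELDS:
            text = bnd.findtext(name)
            if text is None:
                raise AnnotationFormatError(
                    f"{path}: object {idx} missing <{name}> in <bndbox>"
                )
            try:
                vals[name] = float(text)
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"{path}: object {idx} has non-numeric <{name}>: {text!r}"
                ) from exc
        label = obj.findtext("name") or "object"
        conf_text = obj.findtext("confidence") or obj.findtext("score")
        conf = float(conf_text) if conf_text is not None else None
        boxes.append(
            Box(
                xmin=vals["xmin"] - 1.0,
                ymin=vals["ymin"] - 1.0,
                xmax=vals["xmax"],
                ymax=vals["ymax"],
                label=label,
                confidence=conf,
            )
        )
    return BoxAnnotation(image_id=str(image_id), boxes=boxes)


def write_voc_boxes(
    ann: BoxAnnotation, path: str | Path, width: int = 0, height: int = 0
) -> None:
    """Write boxes back to Pascal-VOC XML, undoing the convention shift."""
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = ann.image_id
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(width)
    etree.SubElement(size, "height").text = str(height)
    etree.SubElement(size, "depth").text = "3"
    for box in ann.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = box.label
        if box.confidence is not None:
            etree.SubElement(obj, "confidence").text = repr(float(box.confidence))
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = repr(float(box.xmin) + 1.0)
        etree.SubElement(bnd, "ymin").text = repr(float(box.ymin) + 1.0)
        etree.SubElement(bnd, "xmax").text = repr(float(box.xmax))
        etree.SubElement(bnd, "ymax").text = repr(float(box.ymax))
    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=False)
    )


# ---------------------------------------------------------------------------
# Point files (CSV with metadata header, or JSON)
# ---------------------------------------------------------------------------


def read_points(path: str | Path) -> PointAnnotation:
    """Read shoot dot annotations from CSV or JSON.

    CSV dialect: first line ``# image_id=<id> width=<w> height=<h>``, then a
    ``x,y`` header row, then one row per point.  JSON dialect: an object with
    keys ``image_id``, ``width``, ``height``, ``points`` (list of [x, y]).
    Out-of-bounds points are rejected with the offending row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        for key in ("image_id", "width", "height", "points"):
            if key not in payload:
                raise AnnotationFormatError(f"{path}: missing key {key!r}")
        return PointAnnotation(
            image_id=str(payload["image_id"]),
            width=int(payload["width"]),
            height=int(payload["height"]),
            points=np.asarray(payload["points"], dtype=float).reshape(-1, 2),
        )
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise AnnotationFormatError(f"{path}: missing '# image_id=... width=... height=...' header")
    meta = {}
    for tok in lines[0].lstrip("#").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    for key in ("image_id", "width", "height"):
        if key not in meta:
            raise AnnotationFormatError(f"{path}: header missing {key!r}")
    pts: list[tuple[float, float]] = []
    for row_no, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.lower().startswith("x,"):
            continue
        parts = line.split(",")
        if len(parts) < 2:
            raise AnnotationFormatError(f"{path}: row {row_no}: expected 'x,y'")
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise AnnotationFormatError(
                f"{path}: row {row_no}: non-numeric coordinate"
            ) from exc
        pts.append((x, y))
    width, height = int(meta["width"]), int(meta["height"])
    arr = np.asarray(pts, dtype=float).reshape(-1, 2)
    if arr.size:
        bad = np.flatnonzero(
            ~((arr[:, 0] >= 0) & (arr[:, 0] < width) & (arr[:, 1] >= 0) & (arr[:, 1] < height))
        )
        if bad.size:
            # +3: header line, column header line, 1-based rows
            raise AnnotationFormatError(
                f"{path}: row {int(bad[0]) + 3}: point outside [0, {width}) x [0, {height})"
            )
    return PointAnnotation(meta["image_id"], width, height, arr)


def write_points(ann: PointAnnotation, path: str | Path) -> None:
    """Write a :class:`PointAnnotation` as CSV (the package's native dialect)."""
    lines = [
        f"# image_id={ann.image_id} width={ann.width} height={ann.height}",
        "x,y",
    ]
    lines += [f"{float(x)!r},{float(y)!r}" for x, y in ann.points]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Crop extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CropRecord:
    """Offset bookkeeping mapping a crop back into its parent image.

    A crop-local coordinate ``(x, y)`` corresponds to parent coordinate
    ``(x + x_off, y + y_off)``.
    """

    box_index: int
    x_off: int
    y_off: int
    width: int
    height: int

    def to_parent(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float).reshape(-1, 2) + [self.x_off, self.y_off]

    def to_crop(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float).reshape(-1, 2) - [self.x_off, self.y_off]


def crop_single_trees(
    image: np.ndarray, boxes: BoxAnnotation, pad: int = 0
) -> tuple[list[np.ndarray], list[CropRecord]]:
    """Extract one padded crop per detected crown box.

    Each box is expanded by ``pad`` pixels on every side, clamped to the
    image bounds, and cut out of ``image`` (H x W x C or H x W).  The
    returned :class:`CropRecord` offsets map crop-local shoot coordinates
    back to the parent frame exactly.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    img = np.asarray(image)
    H, W = img.shape[:2]
    crops: list[np.ndarray] = []
    records: list[CropRecord] = []
    for i, box in enumerate(boxes.boxes):
        x0 = max(0, int(np.floor(box.xmin)) - pad)
        y0 = max(0, int(np.floor(box.ymin)) - pad)
        x1 = min(W, int(np.ceil(box.xmax)) + pad)
        y1 = min(H, int(np.ceil(box.ymax)) + pad)
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"box {i} lies outside the image after clamping")
        crops.append(img[y0:y1, x0:x1].copy())
        records.append(CropRecord(i, x0, y0, x1 - x0, y1 - y0))
    return crops, records


# ---------------------------------------------------------------------------
# Images and density maps on disk
# ---------------------------------------------------------------------------


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG into an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def save_density(grid: np.ndarray, stride: int, source_id: str, path: str | Path) -> None:
    """Persist a density map as float32 TIFF plus a JSON sidecar with metadata."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(grid, dtype=np.float32))
    sidecar = {
        "source_id": source_id,
        "stride": int(stride),
        "count": float(np.asarray(grid).sum()),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_density(path: str | Path) -> tuple[np.ndarray, dict]:
    import tifffile

    path = Path(path)
    grid = tifffile.imread(path).astype(np.float64)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return grid, sidecar
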