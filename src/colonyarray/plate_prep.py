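"""Preparation of single-plate images from scanner output.

Flatbed scanners capture up to four agar plates per image.  This module
splits such composites into single-plate rasters, corrects for the
mirror reflection a scanner introduces about the vertical axis, applies
quarter-turn rotations and resizing, and tracks set/plate identity
through a systematic file-naming scheme::

    <base>_set-<s>.jpg            composite; segmentation yields plates 1..4
    <base>_set-<s>_[<k>].jpg      composite with plate-number offset k
    <base>_set-<s>_plate-<p>.jpg  single plate

The separators ``-``, ``_`` or nothing are all accepted between the
``set``/``plate`` token and its number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "FileNameInfo",
    "CompositeMapping",
    "PlateNameError",
    "parse_plate_filename",
    "format_plate_filename",
    "split_composite",
    "prepare_plate_image",
    "segment_file",
    "batch_segment",
]

IMAGE_EXTENSIONS = (".jpg", ".jpeg", ".png", ".tif", ".tiff")


class PlateNameError(ValueError):
    """Raised when a file name does not follow a recognized template."""


@dataclass(frozen=True)
class FileNameInfo:
    """Identity tokens parsed from a plate-image file name."""

    base_name: str
    set_number: int
    plate_number: int | None = None
    plate_offset: int = 0
    extension: str = ".jpg"

    def __post_init__(self) -> None:
        if not self.base_name:
            raise PlateNameError("empty base name")
        if self.set_number < 1:
            raise PlateNameError("set number must be >= 1")
        if self.plate_number is not None and self.plate_number < 1:
            raise PlateNameError("plate number must be >= 1")
        if self.plate_offset < 0:
            raise PlateNameError("plate offset must be >= 0")


@dataclass(frozen=True)
class CompositeMapping:
    """How quadrants of a composite scan map to plate numbers.

    ``positions[i]`` is the plate number of quadrant ``i`` in reading
    order (left-to-right, top-to-bottom) of the *corrected* image.  When
    ``mirrored`` is true the scan is assumed reflected about its
    vertical axis, so quadrant columns are swapped before numbering.
    """

    positions: tuple[int, ...] = (1, 2, 3, 4)
    mirrored: bool = True

    def __post_init__(self) -> None:
        n = len(self.positions)
        if n not in (1, 2, 4):
            raise ValueError(f"quadrant count must be 1, 2 or 4, got {n}")
        if len(set(self.positions)) != n:
            raise ValueError("plate numbers must be unique within a mapping")

    @property
    def layout(self) -> tuple[int, int]:
        """(rows, cols) of the quadrant grid."""
        return {1: (1, 1), 2: (1, 2), 4: (2, 2)}[len(self.positions)]


# set / plate tokens: "set-3", "set_3", "set3" (case-insensitive)
_TOKEN = r"[-_]?(\d+)"
_NAME_RE = re.compile(
    r"^(?P<base>.+?)_set" + _TOKEN.replace("(", "(?P<set>", 1)
    + r"(?:_plate" + _TOKEN.replace("(", "(?P<plate>", 1) + r")?"
    + r"(?:_\[(?P<offset>\d+)\])?"
    + r"(?P<ext>\.[A-Za-z]+)$",
    re.IGNORECASE,
)


def parse_plate_filename(name: str) -> FileNameInfo:
    """Parse a systematically named plate-image file.

    Parameters
    ----------
    name:
        File name (with extension), e.g. ``"Yfg1_G418_set-1.jpg"`` or
        ``"a_set1_plate2.png"``.  An offset token ``[k]`` immediately
        before the extension shifts the plate numbering of segmented
        outputs by *k*.

    Raises
    ------
    PlateNameError
        If the name does not match any recognized template.
    """
    name = Path(name).name
    ext = Path(name).suffix.lower()
    if ext not in IMAGE_EXTENSIONS:
        raise PlateNameError(
            f"{name!r}: unrecognized image extension {ext!r} "
            f"(expected one of {', '.join(IMAGE_EXTENSIONS)})"
        )
    m = _NAME_RE.match(name)
    if m is None:
        raise PlateNameError(
            f"{name!r} does not match the expected templates "
            "'screen_setx.jpg' or 'screen_setx_platey.jpg'"
        )
    plate = m.group("plate")
    offset = m.group("offset")
    return FileNameInfo(
        base_name=m.group("base"),
        set_number=int(m.group("set")),
        plate_number=int(plate) if plate is not None else None,
        plate_offset=int(offset) if offset is not None else 0,
        extension=m.group("ext").lower(),
    )


def format_plate_filename(base: str, set_number: int, plate_number: int,
                          extension: str = ".jpg") -> str:
    """Canonical single-plate output file name."""
    return f"{base}_set-{set_number}_plate-{plate_number}{extension}"


def split_composite(
    image: np.ndarray, mapping: CompositeMapping | None = None
) -> list[tuple[int, np.ndarray]]:
    """Split a composite scan into single-plate sub-images.

    The image is divided into equal quadrants per ``mapping.layout``.
    If the mapping is mirrored, quadrant columns are swapped before
    plate numbers are assigned (the pixel data of each sub-image is not
    flipped; only the quadrant-to-plate assignment changes).  Pixel
    values are preserved bit-exactly.

    Returns
    -------
    list of (plate_number, raster), sorted by plate number.
    """
    if mapping is None:
        mapping = CompositeMapping()
    qrows, qcols = mapping.layout
    h, w = image.shape[:2]
    if h % qrows or w % qcols:
        raise ValueError(
            f"image shape {image.shape[:2]} not divisible into "
            f"{qrows}x{qcols} quadrants"
        )
    sh, sw = h // qrows, w // qcols
    out: list[tuple[int, np.ndarray]] = []
    for qi, plate in enumerate(mapping.positions):
        r, c = divmod(qi, qcols)
        if mapping.mirrored:
            c = qcols - 1 - c
        sub = image[r * sh:(r + 1) * sh, c * sw:(c + 1) * sw].copy()
        out.append((plate, sub))
    out.sort(key=lambda t: t[0])
    return out


def prepare_plate_image(
    raster: np.ndarray,
    rotate_quarter_turns: int = 0,
    resize_factor: float = 1.0,
    to_greyscale: bool = True,
) -> np.ndarray:
    """Orient and format a single-plate raster for measurement.

    Rotation is by exact quarter turns (lossless, counter-clockwise);
    resizing uses bilinear interpolation via Pillow; greyscale
    conversion uses the ITU-R 601 luma transform, so an RGB raster with
    equal channels maps to that channel value.
    """
    if raster.size == 0:
        raise ValueError("empty raster")
    if resize_factor <= 0:
        raise ValueError(f"resize_factor must be > 0, got {resize_factor}")
    out = np.asarray(raster)
    if to_greyscale and out.ndim == 3:
        img = Image.fromarray(out.astype(np.uint8))
        out = np.asarray(img.convert("L"))
    out = np.rot90(out, k=rotate_quarter_turns % 4)
    if resize_factor != 1.0:
        img = Image.fromarray(out)
        new_size = (
            max(1, round(out.shape[1] * resize_factor)),
            max(1, round(out.shape[0] * resize_factor)),
        )
        out = np.asarray(img.resize(new_size, Image.BILINEAR))
    return np.ascontiguousarray(out)


@dataclass
class SegmentResult:
    """Outcome of segmenting one composite file."""

    source: str
    outputs: list[str] = field(default_factory=list)


def segment_file(
    path: str | Path,
    out_dir: str | Path,
    mapping: CompositeMapping | None = None,
    extra_offset: int = 0,
    rotate_quarter_turns: int = 0,
    resize_factor: float = 1.0,
) -> SegmentResult:
    """Segment one composite image file into single-plate files.

    Output files follow the canonical naming scheme so that
    :func:`parse_plate_filename` round-trips base/set/plate.  A file
    already carrying a plate number is passed through (prepared but not
    split).
    """
    path = Path(path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    info = parse_plate_filename(path.name)
    raster = np.asarray(Image.open(path))
    result = SegmentResult(source=str(path))
    offset = info.plate_offset + extra_offset

    def _write(plate: int, arr: np.ndarray) -> None:
        arr = prepare_plate_image(arr, rotate_quarter_turns, resize_factor)
        name = format_plate_filename(info.base_name, info.set_number,
                                     plate + offset, info.extension)
        Image.fromarray(arr).save(out_dir / name)
        result.outputs.append(name)

    if info.plate_number is not None:
        _write(info.plate_number, raster)
    else:
        for plate, sub in split_composite(raster, mapping):
            _write(plate, sub)
    return result


def batch_segment(
    in_dir: str | Path,
    out_dir: str | Path,
    mapping: CompositeMapping | None = None,
    **kwargs,
) -> list[SegmentResult]:
    """Segment every recognizable image in a folder, in lexicographic
    order, writing a ``manifest.log`` of outputs alongside the results."""
    in_dir = Path(in_dir)
    out_dir = Path(out_dir)
    results = []
    for path in sorted(in_dir.iterdir()):
        if path.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        try:
            results.append(segment_file(path, out_dir, mapping, **kwargs))
        except PlateNameError as exc:
            results.append(SegmentResult(source=f"{path} [SKIPPED: {exc}]"))
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.log", "w") as fh:
        for res in results:
            fh.write(f"{res.source}\t{','.join(res.outputs)}\n")
    return results
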