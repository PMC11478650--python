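"""File formats: CSV box tables and YOLO darknet txt annotations.

Truth CSV has the header ``x_min,y_min,x_max,y_max``; detection CSV adds
``score,tile_row,tile_col``.  YOLO txt lines are
``class cx cy w h [score]`` with centre/size normalised by the image (or
tile) dimensions and written as 6-decimal fixed point.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from .boxes import Box


class FormatError(ValueError):
    """A file failed to parse; the message carries file and line context."""


# ---------------------------------------------------------------------------
# YOLO darknet txt
# ---------------------------------------------------------------------------


def box_to_yolo_line(
    box: Box,
    image_width: float,
    image_height: float,
    class_id: int = 0,
    score: Optional[float] = None,
) -> str:
    cx, cy = box.center
    fields = [
        str(class_id),
        f"{cx / image_width:.6f}",
        f"{cy / image_height:.6f}",
        f"{box.width / image_width:.6f}",
        f"{box.height / image_height:.6f}",
    ]
    if score is not None:
        fields.append(f"{score:.6f}")
    return " ".join(fields)


def yolo_line_to_box(
    line: str,
    image_width: float,
    image_height: float,
    path: Optional[Path] = None,
    lineno: Optional[int] = None,
) -> Tuple[int, Box, Optional[float]]:
    """Parse one YOLO line into (class_id, box, score-or-None)."""

    def _fail(msg: str) -> FormatError:
        where = f"{path}:{lineno}: " if path is not None else ""
        return FormatError(f"{where}{msg}: {line.strip()!r}")

    parts = line.split()
    if len(parts) not in (5, 6):
        raise _fail("expected 5 or 6 whitespace-separated fields")
    try:
        class_id = int(parts[0])
        cx, cy, w, h = (float(p) for p in parts[1:5])
        score = float(parts[5]) if len(parts) == 6 else None
    except ValueError:
        raise _fail("non-numeric field") from None
    for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
        if not (0.0 <= v <= 1.0):
            raise _fail(f"normalized coordinate {name}={v} outside [0, 1]")
    if w <= 0 or h <= 0:
        raise _fail("zero-size box")
    box = Box(
        (cx - w / 2) * image_width,
        (cy - h / 2) * image_height,
        (cx + w / 2) * image_width,
        (cy + h / 2) * image_height,
    )
    return class_id, box, score


def write_yolo_txt(
    boxes: Sequence[Box],
    path: Path,
    image_width: float,
    image_height: float,
    scores: Optional[Sequence[float]] = None,
) -> None:
    path = Path(path)
    lines = []
    for i, box in enumerate(boxes):
        score = None if scores is None else scores[i]
        lines.append(box_to_yolo_line(box, image_width, image_height, score=score))
    path.write_text("".join(line + "\n" for line in lines))


def read_yolo_txt(
    path: Path, image_width: float, image_height: float
) -> List[Tuple[int, Box, Optional[float]]]:
    path = Path(path)
    out = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        out.append(yolo_line_to_box(line, image_width, image_height, path=path, lineno=lineno))
    return out


# ---------------------------------------------------------------------------
# CSV box tables
# ---------------------------------------------------------------------------

TRUTH_HEADER = ["x_min", "y_min", "x_max", "y_max"]
DETECTION_HEADER = ["x_min", "y_min", "x_max", "y_max", "score", "tile_row", "tile_col"]


def _num(s: str) -> float:
    v = float(s)
    return int(v) if v.is_integer() else v


def write_truth_csv(boxes: Sequence[Box], path: Path) -> None:
    path = Path(path)
    try:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(TRUTH_HEADER)
            for b in boxes:
                writer.writerow([_num(str(b.x_min)), _num(str(b.y_min)),
                                 _num(str(b.x_max)), _num(str(b.y_max))])
    except OSError as exc:
        raise OSError(f"cannot write truth CSV {path}: {exc}") from exc


def read_truth_csv(path: Path) -> List[Box]:
    path = Path(path)
    try:
        with path.open(newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header] != TRUTH_HEADER:
                raise FormatError(f"{path}: expected header {','.join(TRUTH_HEADER)}")
            boxes = []
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
                try:
                    boxes.append(Box(*(float(v) for v in row)))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
            return boxes
    except OSError as exc:
        raise OSError(f"cannot read truth CSV {path}: {exc}") from exc


def write_detection_csv(rows: Sequence[Tuple[Box, float, int, int]], path: Path) -> None:
    """Write global detections as (box, score, tile_row, tile_col) rows."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DETECTION_HEADER)
        for box, score, tile_row, tile_col in rows:
            writer.writerow(
                [box.x_min, box.y_min, box.x_max, box.y_max, score, tile_row, tile_col]
            )


def read_detection_csv(path: Path) -> List[Tuple[Box, float, int, int]]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != DETECTION_HEADER:
            raise FormatError(f"{path}: expected header {','.join(DETECTION_HEADER)}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(row)}")
            try:
                box = Box(*(float(v) for v in row[:4]))
                rows.append((box, float(row[4]), int(row[5]), int(row[6])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
        return rows
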