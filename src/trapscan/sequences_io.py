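"""Deployment I/O: read image folders, group frames into bursts by
timestamp, and write annotated images, reports and filtered copies.

A deployment is everything one camera recorded at one site.  Frames are
grouped into sequences with the chained 60-second rule: a frame joins the
current sequence iff its gap to the *previous* frame is at most 60 s,
matching camera-trap burst semantics.  Timestamps come from EXIF
DateTimeOriginal, a ``YYYYMMDD_HHMMSS`` filename pattern, or file mtime.
"""

from __future__ import annotations

import logging
import re
import shutil
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

logger = logging.getLogger(__name__)

MAX_GAP_S = 60.0
IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png"}

# EXIF tags
_EXIF_IFD = 0x8769
_DATETIME_ORIGINAL = 36867
_DATETIME = 306

_FILENAME_TS = re.compile(r"(\d{8})_(\d{6})")

BOX_COLORS = {"human": (0, 0, 255), "animal": (255, 0, 0)}  # blue / red


@dataclass
class Frame:
    image_path: Path
    pixels: np.ndarray          # HxW or HxWx3 uint8
    timestamp: float            # seconds since epoch
    frame_index: int = 0

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class SequenceRecord:
    sequence_id: str
    frames: list[Frame]
    deployment_id: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class SequenceResult:
    """One processed sequence: its label and per-frame detections."""

    sequence_id: str
    label: str
    frames: list[Frame]
    detections_per_frame: list[list] = field(default_factory=list)

    def count_boxes(self, cls: str) -> int:
        return sum(1 for dets in self.detections_per_frame for d in dets if d.cls == cls)


@dataclass
class DeploymentReport:
    deployment_id: str
    results: list[SequenceResult]

    def totals(self) -> dict[str, int]:
        out = {"human": 0, "animal": 0, "background": 0}
        for r in self.results:
            out[r.label] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sequence_id": r.sequence_id,
                "label": r.label,
                "n_frames": len(r.frames),
                "n_human_boxes": r.count_boxes("human"),
                "n_animal_boxes": r.count_boxes("animal"),
            }
            for r in self.results
        ]
        return pd.DataFrame(rows, columns=["sequence_id", "label", "n_frames", "n_human_boxes", "n_animal_boxes"])


# ---------------------------------------------------------------------------
# timestamp resolution


def _exif_timestamp(path: Path) -> float | None:
    try:
        with Image.open(path) as img:
            exif = img.getexif()
    except Exception:
        return None
    raw = exif.get_ifd(_EXIF_IFD).get(_DATETIME_ORIGINAL) or exif.get(_DATETIME)
    if not raw:
        return None
    try:
        dt = datetime.strptime(str(raw), "%Y:%m:%d %H:%M:%S")
    except ValueError:
        return None
    return dt.replace(tzinfo=timezone.utc).timestamp()


def _filename_timestamp(path: Path) -> float | None:
    m = _FILENAME_TS.search(path.stem)
    if not m:
        return None
    try:
        dt = datetime.strptime(m.group(1) + m.group(2), "%Y%m%d%H%M%S")
    except ValueError:
        return None
    return dt.replace(tzinfo=timezone.utc).timestamp()


def resolve_timestamp(path: Path, source: str = "auto") -> float | None:
    """Timestamp in epoch seconds, or None if unresolvable under ``source``.

    ``auto`` tries exif, then the filename pattern, then mtime.
    """
    if source == "exif":
        return _exif_timestamp(path)
    if source == "filename":
        return _filename_timestamp(path)
    if source == "mtime":
        return path.stat().st_mtime
    if source == "auto":
        for fn in (_exif_timestamp, _filename_timestamp):
            ts = fn(path)
            if ts is not None:
                return ts
        return path.stat().st_mtime
    raise ValueError(f"unknown timestamp source: {source!r}")


# ---------------------------------------------------------------------------
# loading and grouping


def load_deployment(
    folder: str | Path, timestamp_source: str = "auto"
) -> list[Frame]:
    """Read every readable image in ``folder`` into Frames sorted by time.

    Unreadable files and files with no resolvable timestamp are skipped
    with a warning.  Raises if the folder holds no images at all.
    """
    folder = Path(folder)
    paths = sorted(p for p in folder.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not paths:
        raise FileNotFoundError(f"no images in {folder}")
    frames = []
    for p in paths:
        try:
            with Image.open(p) as img:
                pixels = np.asarray(img.convert("RGB") if img.mode not in ("L", "RGB") else img)
        except Exception as exc:
            logger.warning("skipping unreadable image %s: %s", p.name, exc)
            continue
        ts = resolve_timestamp(p, timestamp_source)
        if ts is None:
            logger.warning("skipping %s: no timestamp under source %r", p.name, timestamp_source)
            continue
        frames.append(Frame(image_path=p, pixels=pixels, timestamp=ts))
    if not frames:
        raise FileNotFoundError(f"no readable, timestamped images in {folder}")
    frames.sort(key=lambda f: (f.timestamp, f.image_path.name))
    return frames


def group_into_sequences(
    frames: list[Frame], max_gap_s: float = MAX_GAP_S, deployment_id: str = ""
) -> list[SequenceRecord]:
    """Partition time-sorted frames into sequences by the chained gap rule.

    A frame joins the current sequence iff its gap to the previous frame
    is <= ``max_gap_s``; otherwise it starts a new sequence.
    """
    sequences: list[SequenceRecord] = []
    current: list[Frame] = []
    for frame in frames:
        if current and frame.timestamp - current[-1].timestamp > max_gap_s:
            sequences.append(_finish_sequence(current, len(sequences), deployment_id))
            current = []
        current.append(frame)
    if current:
        sequences.append(_finish_sequence(current, len(sequences), deployment_id))
    return sequences


def _finish_sequence(frames: list[Frame], index: int, deployment_id: str) -> SequenceRecord:
    for i, f in enumerate(frames):
        f.frame_index = i
    return SequenceRecord(
        sequence_id=f"seq{index:04d}", frames=list(frames), deployment_id=deployment_id
    )


# ---------------------------------------------------------------------------
# outputs


def write_annotated(
    sequence: SequenceRecord, detections_per_frame: list[list], out_dir: str | Path
) -> list[Path]:
    """Write one JPEG per frame with colored boxes: blue for humans, red
    for animals, none for background frames."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for frame in sequence.frames:
        dest = out_dir / (frame.image_path.stem + "_annotated.jpg")
        dets = detections_per_frame[frame.frame_index]
        if not dets:
            # background frame: copied byte-identically, no re-encoding
            shutil.copyfile(frame.image_path, dest)
            written.append(dest)
            continue
        img = Image.fromarray(frame.pixels).convert("RGB")
        draw = ImageDraw.Draw(img)
        for det in dets:
            x0, y0, x1, y1 = det.bbox
            # PIL rectangles are inclusive; boxes are half-open
            draw.rectangle([x0, y0, x1 - 1, y1 - 1], outline=BOX_COLORS[det.cls], width=3)
        img.save(dest, quality=95)
        written.append(dest)
    return written


def write_report(report: DeploymentReport, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``report.csv`` (one row per sequence) and a text summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = report.to_frame()
    csv_path = out_dir / "report.csv"
    df.to_csv(csv_path, index=False)
    totals = report.totals()
    txt_path = out_dir / "report.txt"
    lines = [
        f"Deployment: {report.deployment_id}",
        f"Sequences: {len(report.results)}",
        f"  animal:     {totals['animal']}",
        f"  human:      {totals['human']}",
        f"  background: {totals['background']}",
        "",
    ]
    for r in report.results:
        lines.append(
            f"{r.sequence_id}: {r.label} ({len(r.frames)} frames, "
            f"{r.count_boxes('human')} human boxes, {r.count_boxes('animal')} animal boxes)"
        )
    txt_path.write_text("\n".join(lines) + "\n")
    return csv_path, txt_path


def filter_deployment(
    report: DeploymentReport, drop: set[str], dest: str | Path
) -> list[str]:
    """Copy sequences whose label is not in ``drop`` into ``dest``.

    Copies are byte-identical (no re-encoding).  Returns the kept
    sequence ids.  ``dest`` must not sit inside the source folder.
    """
    bad = drop - {"human", "background", "animal"}
    if bad:
        raise ValueError(f"unknown labels in drop set: {sorted(bad)}")
    dest = Path(dest)
    sources = {r.frames[0].image_path.parent.resolve() for r in report.results if r.frames}
    dest_res = dest.resolve()
    for src in sources:
        if dest_res == src or src in dest_res.parents:
            raise ValueError(f"destination {dest} is inside the source folder {src}")
    dest.mkdir(parents=True, exist_ok=True)
    kept = []
    for r in report.results:
        if r.label in drop:
            continue
        kept.append(r.sequence_id)
        seq_dir = dest / r.sequence_id
        seq_dir.mkdir(exist_ok=True)
        for frame in r.frames:
            shutil.copyfile(frame.image_path, seq_dir / frame.image_path.name)
    return kept
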