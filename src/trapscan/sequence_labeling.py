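"""Pool per-frame detections into a sequence label.

A real animal or person persists across several frames of a burst, while
vegetation flicker and intensity artifacts come and go.  Cross-frame
verification links same-class detections whose boxes overlap across
different frames and discards links supported by too few frames.  The
surviving detections determine the sequence label: background when empty,
human when every detection is human, animal as soon as any animal is
detected.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluation import iou

DEFAULT_MIN_SUPPORT = 2
DEFAULT_LINK_IOU = 0.3


@dataclass
class Detection:
    """A classified foreground box; class is never 'background'."""

    frame_index: int
    bbox: tuple[int, int, int, int]
    cls: str            # "human" | "animal"
    score: float        # max class probability

    def __post_init__(self):
        if self.cls not in ("human", "animal"):
            raise ValueError(f"detection class must be human or animal, got {self.cls!r}")


@dataclass
class SequenceLabel:
    label: str                      # "background" | "human" | "animal"
    detections: list[Detection]


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cross_frame_verify(
    detections: list[Detection],
    n_frames: int,
    min_support: int = DEFAULT_MIN_SUPPORT,
    link_iou: float = DEFAULT_LINK_IOU,
) -> list[Detection]:
    """Keep detections supported by overlapping same-class boxes in
    ``min_support`` or more distinct frames.

    Two detections link when they share a class, sit in different frames,
    and their boxes overlap with IoU >= ``link_iou``; links are transitive
    (connected components).  Sequences shorter than ``min_support`` frames
    keep all detections — there is nothing to corroborate against.
    """
    if n_frames < min_support:
        return list(detections)
    uf = _UnionFind(len(detections))
    for i in range(len(detections)):
        for j in range(i + 1, len(detections)):
            a, b = detections[i], detections[j]
            if a.cls != b.cls or a.frame_index == b.frame_index:
                continue
            if iou(a.bbox, b.bbox) >= link_iou:
                uf.union(i, j)
    frames_per_root: dict[int, set[int]] = {}
    for i, det in enumerate(detections):
        frames_per_root.setdefault(uf.find(i), set()).add(det.frame_index)
    return [
        det
        for i, det in enumerate(detections)
        if len(frames_per_root[uf.find(i)]) >= min_support
    ]


def label_sequence(verified: list[Detection]) -> SequenceLabel:
    """Background if empty; animal if any animal detection; else human."""
    if not verified:
        return SequenceLabel(label="background", detections=[])
    if any(d.cls == "animal" for d in verified):
        return SequenceLabel(label="animal", detections=list(verified))
    return SequenceLabel(label="human", detections=list(verified))
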