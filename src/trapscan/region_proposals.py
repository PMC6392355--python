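"""Region proposals: connect foreground blocks and reject low-texture
false positives with the Shrinked Histogram Length (SHL).

Foreground blocks are merged into 8-connected components, mapped back to
original-image bounding boxes, and each cropped patch is screened by SHL:
the number of intensity levels whose relative frequency exceeds a small
threshold.  Intensity artifacts (dark corners, sunspots, flash-lit gray
regions) concentrate their mass on a handful of levels and score a small
SHL; textured animals and people span many levels and score big.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .block_features import BlockGrid, to_grayscale

logger = logging.getLogger(__name__)

DEFAULT_TH_HS = 0.01
DEFAULT_SHL_MIN = 12
DEFAULT_MIN_BLOCKS = 2

N_LEVELS = 256


@dataclass
class RegionProposal:
    """A connected set of foreground blocks hypothesized to be an object."""

    frame_index: int
    blocks: list[tuple[int, int]]          # (row, col) block coordinates
    bbox: tuple[int, int, int, int]        # original-image px, half-open, 0-based
    patch: np.ndarray | None = None        # original-resolution crop

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def connect_blocks(
    fg_frame: np.ndarray,
    grid: BlockGrid,
    frame_index: int = 0,
    min_blocks: int = DEFAULT_MIN_BLOCKS,
) -> list[RegionProposal]:
    """8-connected components of the foreground block mask for one frame.

    ``fg_frame`` may be flat (n_blocks,) or shaped (rows, cols).
    Components with fewer than ``min_blocks`` blocks are dropped.  The
    bounding box is the tight union of member blocks, mapped to
    original-image coordinates rounding outward.
    """
    mask = np.asarray(fg_frame, dtype=bool).reshape(grid.rows, grid.cols)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    proposals: list[RegionProposal] = []
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labels == comp)
        if rows.size < min_blocks:
            continue
        x0w = cols.min() * grid.block_w
        y0w = rows.min() * grid.block_h
        x1w = (cols.max() + 1) * grid.block_w
        y1w = (rows.max() + 1) * grid.block_h
        bbox = grid.to_original(x0w, y0w, x1w, y1w)
        proposals.append(
            RegionProposal(
                frame_index=frame_index,
                blocks=list(zip(rows.tolist(), cols.tolist())),
                bbox=bbox,
            )
        )
    return proposals


def crop_patch(pixels: np.ndarray, bbox: tuple[int, int, int, int]) -> np.ndarray:
    x0, y0, x1, y1 = bbox
    return np.asarray(pixels)[y0:y1, x0:x1]


def compute_shl(patch: np.ndarray, th_hs: float = DEFAULT_TH_HS) -> int:
    """Shrinked Histogram Length of a patch.

    With n_i the count of intensity level i in a w x h patch,
    SHL = #{i : n_i / (w*h) > th_hs} over the 256 8-bit levels.  Color
    patches are converted to luma first.
    """
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("empty patch")
    if not 0 < th_hs < 1:
        raise ValueError(f"th_hs must be in (0, 1), got {th_hs}")
    gray = to_grayscale(patch)
    counts = np.bincount(gray.ravel(), minlength=N_LEVELS)
    return int(np.count_nonzero(counts / gray.size > th_hs))


def verify_proposal(
    proposal: RegionProposal,
    th_hs: float = DEFAULT_TH_HS,
    shl_min: int = DEFAULT_SHL_MIN,
) -> bool:
    """Keep a proposal iff its patch SHL reaches ``shl_min``."""
    if proposal.patch is None:
        raise ValueError("proposal has no patch to verify")
    shl = compute_shl(proposal.patch, th_hs)
    keep = shl >= shl_min
    if not keep:
        logger.info(
            "rejected proposal frame=%d bbox=%s SHL=%d < %d",
            proposal.frame_index, proposal.bbox, shl, shl_min,
        )
    return keep
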