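"""Block-grid feature extraction for camera-trap frames.

Every frame is rescaled to a canonical working resolution and partitioned
into a fixed 32 x 23 grid of 736 square blocks.  Per-block feature
histograms (HOG by default) are the unit of comparison for background
modeling: moving objects reveal themselves as blocks whose histogram
drifts away from the co-located blocks in the other frames of the burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern

GRID_COLS = 32
GRID_ROWS = 23
N_BLOCKS = GRID_COLS * GRID_ROWS  # 736
BLOCK_SIZE = 16
WORKING_W = GRID_COLS * BLOCK_SIZE  # 512
WORKING_H = GRID_ROWS * BLOCK_SIZE  # 368

HOG_BINS = 9
INTENSITY_BINS = 32
LBP_BINS = 256

FEATURE_TYPES = ("hog", "intensity", "lbp", "glcm")


@dataclass(frozen=True)
class BlockGrid:
    """Geometry of the 32 x 23 working-resolution block grid.

    ``scale_x``/``scale_y`` map working-pixel coordinates back to the
    original image (original = working * scale).
    """

    cols: int = GRID_COLS
    rows: int = GRID_ROWS
    block_w: int = BLOCK_SIZE
    block_h: int = BLOCK_SIZE
    working_w: int = WORKING_W
    working_h: int = WORKING_H
    orig_w: int = WORKING_W
    orig_h: int = WORKING_H

    @property
    def n_blocks(self) -> int:
        return self.cols * self.rows

    @property
    def scale_x(self) -> float:
        return self.orig_w / self.working_w

    @property
    def scale_y(self) -> float:
        return self.orig_h / self.working_h

    def block_bbox_working(self, row: int, col: int) -> tuple[int, int, int, int]:
        """Half-open (x0, y0, x1, y1) of one block in working pixels."""
        return (
            col * self.block_w,
            row * self.block_h,
            (col + 1) * self.block_w,
            (row + 1) * self.block_h,
        )

    def to_original(self, x0: float, y0: float, x1: float, y1: float) -> tuple[int, int, int, int]:
        """Map a working-resolution box to original pixels, rounding outward."""
        ox0 = int(np.floor(x0 * self.scale_x))
        oy0 = int(np.floor(y0 * self.scale_y))
        ox1 = int(np.ceil(x1 * self.scale_x))
        oy1 = int(np.ceil(y1 * self.scale_y))
        ox1 = min(ox1, self.orig_w)
        oy1 = min(oy1, self.orig_h)
        return max(ox0, 0), max(oy0, 0), ox1, oy1


@dataclass
class BlockFeatureStack:
    """Per-frame, per-block feature histograms for one sequence.

    ``hists`` has shape (n_frames, n_blocks, hist_len); every histogram is
    L1-normalized (or all-zero, e.g. HOG of a constant block).
    """

    hists: np.ndarray
    feature_type: str
    grid: BlockGrid = field(default_factory=BlockGrid)

    @property
    def n_frames(self) -> int:
        return self.hists.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.hists.shape[1]


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma of a color image; grayscale passes through. uint8 out."""
    arr = np.asarray(pixels)
    if arr.ndim == 3:
        arr = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def rescale_to_working(pixels: np.ndarray) -> tuple[np.ndarray, BlockGrid]:
    """Rescale a frame to the 512 x 368 grayscale working image.

    Returns the working image (uint8) and the :class:`BlockGrid` that maps
    blocks back to original-image coordinates.
    """
    arr = np.asarray(pixels)
    if arr.size == 0:
        raise ValueError("empty image")
    h, w = arr.shape[:2]
    if h < 32 or w < 32:
        raise ValueError(f"image too small for block analysis: {w}x{h}")
    gray = to_grayscale(arr)
    if (w, h) != (WORKING_W, WORKING_H):
        img = Image.fromarray(gray).resize((WORKING_W, WORKING_H), Image.BILINEAR)
        gray = np.asarray(img)
    grid = BlockGrid(orig_w=w, orig_h=h)
    return gray, grid


def _block_view(image: np.ndarray, grid: BlockGrid) -> np.ndarray:
    """(rows, cols, block_h, block_w) view of the working image."""
    return image.reshape(grid.rows, grid.block_h, grid.cols, grid.block_w).transpose(0, 2, 1, 3)


def _hog_histograms(image: np.ndarray, grid: BlockGrid) -> np.ndarray:
    img = image.astype(np.float64)
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    # unsigned orientation in [0, 180), 9 bins of 20 degrees; votes are
    # magnitude-weighted and linearly interpolated between the two nearest
    # bins so that sensor noise cannot flip a vote wholesale at a bin edge
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0
    pos = ang / (180.0 / HOG_BINS)
    lo = np.floor(pos)
    frac = pos - lo
    b0 = lo.astype(np.intp) % HOG_BINS
    b1 = (b0 + 1) % HOG_BINS
    row = np.arange(grid.working_h)[:, None] // grid.block_h
    col = np.arange(grid.working_w)[None, :] // grid.block_w
    block = (row * grid.cols + col).astype(np.intp)
    n = grid.n_blocks * HOG_BINS
    hist = np.bincount(
        (block * HOG_BINS + b0).ravel(), weights=(mag * (1 - frac)).ravel(), minlength=n
    )
    hist += np.bincount(
        (block * HOG_BINS + b1).ravel(), weights=(mag * frac).ravel(), minlength=n
    )
    return hist.reshape(grid.n_blocks, HOG_BINS)


def _intensity_histograms(image: np.ndarray, grid: BlockGrid) -> np.ndarray:
    levels = (image.astype(np.intp) * INTENSITY_BINS) // 256
    row = np.arange(grid.working_h)[:, None] // grid.block_h
    col = np.arange(grid.working_w)[None, :] // grid.block_w
    block = (row * grid.cols + col).astype(np.intp)
    flat_idx = block * INTENSITY_BINS + levels
    hist = np.bincount(flat_idx.ravel(), minlength=grid.n_blocks * INTENSITY_BINS)
    return hist.reshape(grid.n_blocks, INTENSITY_BINS).astype(np.float64)


def _lbp_histograms(image: np.ndarray, grid: BlockGrid) -> np.ndarray:
    codes = local_binary_pattern(image, P=8, R=1, method="default").astype(np.intp)
    row = np.arange(grid.working_h)[:, None] // grid.block_h
    col = np.arange(grid.working_w)[None, :] // grid.block_w
    block = (row * grid.cols + col).astype(np.intp)
    flat_idx = block * LBP_BINS + codes
    hist = np.bincount(flat_idx.ravel(), minlength=grid.n_blocks * LBP_BINS)
    return hist.reshape(grid.n_blocks, LBP_BINS).astype(np.float64)


def _glcm_features(image: np.ndarray, grid: BlockGrid) -> np.ndarray:
    blocks = _block_view(image, grid).reshape(grid.n_blocks, grid.block_h, grid.block_w)
    out = np.empty((grid.n_blocks, 4))
    for b in range(grid.n_blocks):
        # 32 gray levels keep the co-occurrence matrix small per 16x16 block
        quant = (blocks[b] // 8).astype(np.uint8)
        glcm = graycomatrix(quant, distances=[1], angles=[0], levels=32, symmetric=False, normed=True)
        out[b, 0] = graycoprops(glcm, "contrast")[0, 0]
        # correlation lies in [-1, 1]; shift to keep the stack non-negative
        out[b, 1] = (graycoprops(glcm, "correlation")[0, 0] + 1.0) / 2.0
        out[b, 2] = graycoprops(glcm, "energy")[0, 0]
        out[b, 3] = graycoprops(glcm, "homogeneity")[0, 0]
    return out


def block_histograms(image: np.ndarray, grid: BlockGrid, feature_type: str = "hog") -> np.ndarray:
    """Per-block L1-normalized feature histograms of a working image.

    Parameters
    ----------
    image : uint8 working image matching ``grid``.
    feature_type : one of ``hog`` (9-bin unsigned gradient-orientation
        histogram), ``intensity`` (32 levels), ``lbp`` (256 raw 8-neighbor
        codes), ``glcm`` (contrast / shifted correlation / energy /
        homogeneity at offset (1, 0)).

    Returns
    -------
    (n_blocks, hist_len) array; rows sum to 1, or to 0 for a constant
    block under HOG (no gradient anywhere).
    """
    if image.shape != (grid.working_h, grid.working_w):
        raise ValueError("working image does not match grid")
    if feature_type == "hog":
        hist = _hog_histograms(image, grid)
    elif feature_type == "intensity":
        hist = _intensity_histograms(image, grid)
    elif feature_type == "lbp":
        hist = _lbp_histograms(image, grid)
    elif feature_type == "glcm":
        hist = _glcm_features(image, grid)
    else:
        raise ValueError(f"unknown feature type: {feature_type!r}")
    totals = hist.sum(axis=1, keepdims=True)
    nonzero = totals[:, 0] > 0
    hist[nonzero] /= totals[nonzero]
    return hist


def histogram_distance(h1: np.ndarray, h2: np.ndarray) -> float:
    """L1 distance between two feature histograms."""
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    if h1.shape != h2.shape:
        raise ValueError(f"histogram length mismatch: {h1.shape} vs {h2.shape}")
    return float(np.abs(h1 - h2).sum())


def compute_stack(frames, feature_type: str = "hog") -> BlockFeatureStack:
    """Build the :class:`BlockFeatureStack` for a sequence of frames.

    ``frames`` is an iterable of pixel arrays or objects with a ``pixels``
    attribute; all frames share one grid (taken from the first frame).
    """
    hists = []
    grid = None
    for f in frames:
        pixels = getattr(f, "pixels", f)
        working, g = rescale_to_working(pixels)
        if grid is None:
            grid = g
        hists.append(block_histograms(working, g, feature_type))
    if not hists:
        raise ValueError("no frames")
    return BlockFeatureStack(hists=np.stack(hists), feature_type=feature_type, grid=grid)
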