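"""Background modeling via minimum feature distance (MFD).

For each of the 736 block positions, the block whose feature histogram is
closest to some other co-located block is taken as the background
exemplar; the minimum pairwise distance itself (the MFD) calibrates a
per-block foreground threshold.  Two methods are offered: ``composite``
uses the whole sequence to assemble a per-block composite background,
``three_frame`` restricts the comparison to a sliding 3-frame window, for
cameras that record only 3 images per trigger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .block_features import BlockFeatureStack

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 2.0
# Absolute floor on the foreground threshold (L1 on unit-sum histograms,
# range [0, 2]).  The MFD is a minimum over few pairwise distances and so
# underestimates the typical frame-to-frame jitter; the floor covers the
# jitter tail of static textured blocks under sensor noise and JPEG
# re-encoding (empirically < 0.2), while a genuine object re-textures a
# block and pushes the distance toward 1-2.
TAU_MIN = 0.25

BG_METHODS = ("composite", "three_frame")


@dataclass
class BackgroundAssignment:
    """Per-block background exemplar and the derived foreground mask."""

    bg: np.ndarray          # (n_blocks,) background frame index per block
    mfd: np.ndarray         # (n_blocks,) minimum feature distance per block
    fg: np.ndarray          # (n_frames, n_blocks) bool foreground flags
    method: str
    alpha: float


def _pairwise_l1(hists: np.ndarray) -> np.ndarray:
    """(F, F, B) matrix of L1 distances between co-located block histograms."""
    # hists: (F, B, D)
    return np.abs(hists[:, None, :, :] - hists[None, :, :, :]).sum(axis=3)


def _mfd_all(hists: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized MFD over all blocks: returns (bg index, mfd) arrays."""
    n_frames = hists.shape[0]
    if n_frames < 2:
        raise ValueError("background modeling needs >=2 frames")
    d = _pairwise_l1(hists)
    np.einsum("ffb->fb", d)[:] = np.inf  # exclude self-distance
    score = d.min(axis=1)                # (F, B): nearest co-located neighbor
    bg = score.argmin(axis=0)            # argmin ties -> lowest frame index
    mfd = score[bg, np.arange(hists.shape[1])]
    return bg, mfd


def mfd_background(stack: BlockFeatureStack, block: int) -> tuple[int, float]:
    """Background frame index and MFD for one block position.

    For each candidate frame f the score is the minimum distance to any
    other co-located block; the background is the frame minimizing that
    score (ties broken by lowest frame index).
    """
    bg, mfd = _mfd_all(stack.hists[:, [block], :])
    return int(bg[0]), float(mfd[0])


def _threshold(mfd: np.ndarray, alpha: float) -> np.ndarray:
    return np.maximum(alpha * mfd, TAU_MIN)


def foreground_mask_composite(
    stack: BlockFeatureStack, alpha: float = DEFAULT_ALPHA
) -> BackgroundAssignment:
    """Composite-background method over the whole sequence.

    A block in frame f is foreground iff its distance to the per-block
    composite background (the MFD frame's histogram) exceeds
    max(alpha * MFD, tau_min).
    """
    if alpha <= 1:
        logger.warning("alpha=%.3g <= 1 gives a degenerate threshold (<= MFD)", alpha)
    bg, mfd = _mfd_all(stack.hists)
    blocks = np.arange(stack.n_blocks)
    bg_hist = stack.hists[bg, blocks, :]                     # (B, D)
    dist = np.abs(stack.hists - bg_hist[None, :, :]).sum(axis=2)  # (F, B)
    fg = dist > _threshold(mfd, alpha)[None, :]
    return BackgroundAssignment(bg=bg, mfd=mfd, fg=fg, method="composite", alpha=alpha)


def foreground_mask_three_frame(
    stack: BlockFeatureStack, alpha: float = DEFAULT_ALPHA
) -> BackgroundAssignment:
    """3-frame sliding-window method.

    For frame f the MFD rule is applied within the window of the nearest
    three frames (clamped at sequence ends).  Sequences shorter than 3
    frames fall back to the composite method.
    """
    n = stack.n_frames
    if n < 3:
        logger.info("sequence has %d frames; falling back to composite background", n)
        out = foreground_mask_composite(stack, alpha)
        return BackgroundAssignment(
            bg=out.bg, mfd=out.mfd, fg=out.fg, method="three_frame", alpha=alpha
        )
    fg = np.zeros((n, stack.n_blocks), dtype=bool)
    bg_full = np.zeros(stack.n_blocks, dtype=np.intp)
    mfd_full = np.zeros(stack.n_blocks)
    blocks = np.arange(stack.n_blocks)
    for f in range(n):
        lo = min(max(f - 1, 0), n - 3)
        window = stack.hists[lo : lo + 3]
        bg, mfd = _mfd_all(window)
        bg_hist = window[bg, blocks, :]
        dist = np.abs(window[f - lo] - bg_hist).sum(axis=1)
        fg[f] = dist > _threshold(mfd, alpha)
        if f == n // 2:  # representative assignment for reporting
            bg_full, mfd_full = bg + lo, mfd
    return BackgroundAssignment(
        bg=bg_full, mfd=mfd_full, fg=fg, method="three_frame", alpha=alpha
    )


def foreground_mask(
    stack: BlockFeatureStack, method: str = "composite", alpha: float = DEFAULT_ALPHA
) -> BackgroundAssignment:
    """Dispatch to the selected background-subtraction method."""
    if method == "composite":
        return foreground_mask_composite(stack, alpha)
    if method == "three_frame":
        return foreground_mask_three_frame(stack, alpha)
    raise ValueError(f"unknown background method: {method!r}")
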