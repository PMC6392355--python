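"""MFD background selection and foreground masking."""

import numpy as np
import pytest

from trapscan import background_model as bm
from trapscan import block_features as bf
from trapscan import region_proposals as rp
from trapscan import sequences_io as sio


def make_stack(hists: np.ndarray) -> bf.BlockFeatureStack:
    return bf.BlockFeatureStack(hists=hists, feature_type="hog", grid=bf.BlockGrid())


def brute_force_mfd(hists: np.ndarray, block: int) -> tuple[int, float]:
    """Exhaustive O(F^2) pairwise search, lowest-index tie-break."""
    n = hists.shape[0]
    best_f, best_score = None, None
    for f in range(n):
        score = min(
            np.abs(hists[f, block] - hists[g, block]).sum() for g in range(n) if g != f
        )
        if best_score is None or score < best_score:
            best_f, best_score = f, score
    return best_f, best_score


class TestMFD:
    def test_identical_blocks_tie_break_lowest_index(self):
        hists = np.tile(np.full((1, 9), 1 / 9), (10, 1, 1))
        bg, mfd = bm.mfd_background(make_stack(hists), 0)
        assert bg == 0 and mfd == 0.0

    def test_single_outlier_is_never_background(self, rng):
        hists = np.tile(np.full((1, 9), 1 / 9), (10, 1, 1))
        hists[7, 0] = np.r_[1.0, np.zeros(8)]
        bg, mfd = bm.mfd_background(make_stack(hists), 0)
        assert bg == 0 and mfd == 0.0

    def test_needs_two_frames(self, rng):
        hists = rng.random((1, 4, 9))
        with pytest.raises(ValueError, match=">=2 frames"):
            bm.mfd_background(make_stack(hists), 0)

    def test_matches_brute_force_on_random_stacks(self, rng):
        """Vectorized MFD equals the exhaustive pairwise oracle,
        including tie-breaks (histograms drawn on a coarse lattice so
        exact ties occur)."""
        for _ in range(50):
            hists = rng.integers(0, 3, (10, 5, 9)).astype(float)
            hists /= np.maximum(hists.sum(-1, keepdims=True), 1)
            stack = make_stack(hists)
            for b in range(5):
                assert bm.mfd_background(stack, b) == pytest.approx(
                    brute_force_mfd(hists, b)
                )


class TestForegroundMask:
    def test_bg_frame_never_foreground_composite(self, rng):
        hists = rng.random((8, 20, 9))
        hists /= hists.sum(-1, keepdims=True)
        a = bm.foreground_mask_composite(make_stack(hists))
        assert not a.fg[a.bg, np.arange(20)].any()

    def test_alpha_monotonicity(self, rng):
        hists = rng.random((10, 50, 9))
        hists /= hists.sum(-1, keepdims=True)
        stack = make_stack(hists)
        counts = [
            bm.foreground_mask_composite(stack, alpha).fg.sum()
            for alpha in [1.1, 1.5, 2.0, 3.0, 5.0]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_frame_permutation_permutes_rows(self, rng):
        """Order independence up to tie-breaking: when the closest
        co-located pair is an exact duplicate, the exemplar histogram is
        the same whichever endpoint wins the index tie-break, so the
        foreground rows must permute exactly with the frames."""
        hists = rng.random((6, 30, 9))
        hists /= hists.sum(-1, keepdims=True)
        hists[1] = hists[0]  # duplicated background pair per block
        perm = rng.permutation(6)
        a = bm.foreground_mask_composite(make_stack(hists))
        b = bm.foreground_mask_composite(make_stack(hists[perm]))
        np.testing.assert_array_equal(a.fg[perm], b.fg)
        np.testing.assert_allclose(a.mfd, b.mfd)

    def test_low_alpha_warns(self, rng, caplog):
        hists = rng.random((4, 5, 9))
        hists /= hists.sum(-1, keepdims=True)
        with caplog.at_level("WARNING"):
            bm.foreground_mask_composite(make_stack(hists), alpha=0.5)
        assert any("degenerate" in r.message for r in caplog.records)

    def test_unknown_method(self, rng):
        hists = rng.random((4, 5, 9))
        with pytest.raises(ValueError):
            bm.foreground_mask(make_stack(hists), "vibe")


class TestThreeFrame:
    def test_identical_frames_no_foreground(self):
        hists = np.tile(np.full((1, 10, 9), 1 / 9), (3, 1, 1))
        a = bm.foreground_mask_three_frame(make_stack(hists))
        assert not a.fg.any()

    def test_middle_frame_sprite_flagged(self):
        hists = np.tile(np.full((1, 10, 9), 1 / 9), (3, 1, 1))
        hists[1, 4] = np.r_[1.0, np.zeros(8)]  # object in the middle frame
        a = bm.foreground_mask_three_frame(make_stack(hists))
        assert a.fg[1, 4]
        assert not a.fg[0].any() and not a.fg[2].any()

    def test_short_sequence_falls_back_to_composite(self, rng, caplog):
        hists = rng.random((2, 10, 9))
        hists /= hists.sum(-1, keepdims=True)
        with caplog.at_level("INFO"):
            a = bm.foreground_mask_three_frame(make_stack(hists))
        assert a.method == "three_frame"
        b = bm.foreground_mask_composite(make_stack(hists))
        np.testing.assert_array_equal(a.fg, b.fg)
        assert any("falling back" in r.message for r in caplog.records)

    def test_static_sequence_agrees_with_composite(self, static_deployment):
        folder, _ = static_deployment
        frames = sio.load_deployment(folder, "exif")
        stack = bf.compute_stack(frames)
        a = bm.foreground_mask_three_frame(stack)
        b = bm.foreground_mask_composite(stack)
        assert not a.fg.any() and not b.fg.any()


class TestOnFixtures:
    def test_static_scene_is_all_background(self, static_deployment):
        folder, _ = static_deployment
        frames = sio.load_deployment(folder, "exif")
        stack = bf.compute_stack(frames)
        a = bm.foreground_mask_composite(stack)
        assert a.fg.sum() == 0

    def test_sprite_blocks_recovered(self, deployment):
        """Block-level recall and precision >= 0.8 on the moving-sprite
        sequences: flagged blocks concentrate on the sprite's box."""
        folder, manifest = deployment
        frames = sio.load_deployment(folder, "exif")
        sequences = sio.group_into_sequences(frames)
        grid = bf.BlockGrid(orig_w=512, orig_h=384)
        for spec, seq in zip(manifest["sequences"], sequences):
            if spec["label"] == "background":
                continue
            stack = bf.compute_stack(seq.frames)
            a = bm.foreground_mask_composite(stack)
            core_tp = core_fn = hit_any = n_flagged = 0
            # block centers at working resolution, mapped to original px
            cx = (np.arange(32)[None, :] * 16 + 8) * grid.scale_x
            cy = (np.arange(23)[:, None] * 16 + 8) * grid.scale_y
            for frame in seq.frames:
                boxes = spec["boxes"].get(frame.image_path.name, [])
                x0, y0, x1, y1, _ = boxes[0]
                # core blocks: center inside the sprite box (recall target)
                core = (cx >= x0) & (cx < x1) & (cy >= y0) & (cy < y1)
                # touching blocks: any overlap with the box (not false alarms)
                c0, r0 = int(x0 / grid.scale_x) // 16, int(y0 / grid.scale_y) // 16
                c1 = int(np.ceil(x1 / grid.scale_x / 16))
                r1 = int(np.ceil(y1 / grid.scale_y / 16))
                touching = np.zeros((23, 32), dtype=bool)
                touching[r0:r1, c0:c1] = True
                fg = a.fg[frame.frame_index].reshape(23, 32)
                core_tp += (fg & core).sum()
                core_fn += (~fg & core).sum()
                hit_any += (fg & touching).sum()
                n_flagged += fg.sum()
            assert core_tp / (core_tp + core_fn) >= 0.8, spec["sequence_id"]
            assert hit_any / n_flagged >= 0.8, spec["sequence_id"]
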