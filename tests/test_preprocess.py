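"""Preprocessing operator contracts, each checked against an independent
oracle: brute-force loops for projection and the rolling ball, ground-truth
drift for registration."""

import inspect

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from colonykymo import SimulationConfig, simulate_colony
from colonykymo.preprocess import (RigidTransform, apply_rigid,
                                   apply_transforms, max_projection,
                                   register_series, rolling_ball_background,
                                   stitch_tiles, transforms_from_csv,
                                   transforms_to_csv)
from colonykymo.simulate import TileSet, emit_tiles


# --------------------------------------------------------------- projection

class TestMaxProjection:
    def test_single_slice_identity(self, rng):
        z = rng.uniform(size=(1, 12, 12))
        assert np.array_equal(max_projection(z), z[0])

    def test_zero_slice_ignored(self, rng):
        a = rng.uniform(size=(12, 12))
        z = np.stack([np.zeros_like(a), a])
        assert np.array_equal(max_projection(z), a)

    def test_matches_elementwise_loop_oracle(self, rng):
        z = rng.uniform(size=(4, 9, 7))
        out = max_projection(z)
        for i in range(9):
            for j in range(7):
                assert out[i, j] == max(z[k, i, j] for k in range(4))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_projection(np.empty((0, 5, 5)))


# ---------------------------------------------------------------- stitching

class TestStitchTiles:
    def test_single_tile_identity(self, rng):
        frame = rng.uniform(size=(40, 40))
        assert np.abs(stitch_tiles(emit_tiles(frame, (1, 1))) - frame).max() < 1e-12

    def test_constant_image_stays_constant(self):
        frame = np.full((60, 60), 7.25)
        out = stitch_tiles(emit_tiles(frame, (2, 2), overlap=0.2))
        assert np.abs(out - 7.25).max() < 1e-12

    def test_inconsistent_tile_sizes_rejected(self, rng):
        ts = emit_tiles(rng.uniform(size=(60, 60)), (2, 2), overlap=0.2)
        ts.tiles[1] = ts.tiles[1][:-1]
        with pytest.raises(ValueError, match="inconsistent"):
            stitch_tiles(ts)

    def test_missing_positions_rejected(self, rng):
        ts = emit_tiles(rng.uniform(size=(60, 60)), (2, 2), overlap=0.2)
        ts.positions = ts.positions[:-1]
        with pytest.raises(ValueError, match="position"):
            stitch_tiles(ts)

    def test_blend_weights_linear_in_two_tile_overlap(self):
        """In a pure two-tile overlap the cross-fade weight varies linearly
        and sums to one: stitching a horizontal ramp reproduces it exactly,
        and stitching tiles from images c and 0 gives a linear transition."""
        h, w = 20, 60
        left = np.ones((h, w))
        right = np.zeros((h, w))
        ts = emit_tiles(np.empty((h, w)), (1, 2), overlap=0.3)
        th, tw = ts.tiles[0].shape
        ts.tiles = [left[:, :tw].copy(), right[:, -tw:].copy()]
        out = stitch_tiles(ts)
        (r0, c0), (r1, c1) = ts.positions
        lo, hi = c1, c0 + tw  # overlap columns
        assert np.allclose(out[:, :lo], 1.0)
        assert np.allclose(out[:, hi:], 0.0)
        prof = out[h // 2, lo:hi]
        # linear: second differences vanish
        assert np.abs(np.diff(prof, 2)).max() < 1e-9
        assert prof[0] > prof[-1]


# ------------------------------------------------------------- rolling ball

def _ball(radius):
    ax = np.arange(-radius, radius + 1)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    return d2 <= radius * radius, np.sqrt(np.maximum(radius * radius - d2, 0))


def rolling_ball_oracle(frame, radius):
    """Brute-force sliding ball: min-then-max with the ball structuring
    element (explicit loops, edge padding)."""
    fp, s = _ball(radius)
    h, w = frame.shape
    pad = np.pad(frame, radius, mode="edge")
    er = np.empty_like(frame, dtype=float)
    for i in range(h):
        for j in range(w):
            win = pad[i:i + 2 * radius + 1, j:j + 2 * radius + 1]
            er[i, j] = np.min((win - s)[fp])
    pad = np.pad(er, radius, mode="edge")
    bg = np.empty_like(er)
    for i in range(h):
        for j in range(w):
            win = pad[i:i + 2 * radius + 1, j:j + 2 * radius + 1]
            bg[i, j] = np.max((win + s)[fp])
    return bg


class TestRollingBall:
    def test_constant_image_residual_zero(self):
        frame = np.full((16, 16), 123.0)
        bg, res = rolling_ball_background(frame, radius_px=4)
        assert np.abs(res).max() == 0
        assert np.allclose(bg, frame)

    def test_bright_pixel_isolated_and_matches_oracle(self):
        frame = np.full((16, 16), 10.0)
        frame[7, 9] = 500.0
        bg, res = rolling_ball_background(frame, radius_px=4)
        oracle_bg = rolling_ball_oracle(frame, 4)
        assert np.allclose(bg, oracle_bg)
        assert res[7, 9] > 400
        assert np.count_nonzero(res > 1) == 1

    def test_matches_oracle_on_random_fixture(self, rng):
        frame = rng.uniform(0, 100, size=(24, 24))
        bg, _ = rolling_ball_background(frame, radius_px=5, exact=True)
        assert np.allclose(bg, rolling_ball_oracle(frame, 5))

    def test_default_radius_is_1000px(self):
        sig = inspect.signature(rolling_ball_background)
        assert sig.parameters["radius_px"].default == 1000

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            rolling_ball_background(np.ones((8, 8)), radius_px=0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 8))
    def test_residual_bounds_invariant(self, seed, radius):
        """Residual is >= 0 and <= the original frame everywhere."""
        frame = np.random.default_rng(seed).uniform(0, 500, size=(20, 20))
        bg, res = rolling_ball_background(frame, radius_px=radius)
        assert res.min() >= 0
        assert np.all(res <= frame + 1e-9)
        assert np.all(bg <= frame + 1e-9)

    def test_idempotent_on_own_residual(self):
        """A second pass removes <1% additional signal."""
        yy, xx = np.mgrid[0:48, 0:48]
        frame = (50 + 0.5 * xx
                 + 3000 * (np.hypot(yy - 24, xx - 24) < 10)).astype(float)
        _, res1 = rolling_ball_background(frame, radius_px=12, exact=True)
        _, res2 = rolling_ball_background(res1, radius_px=12, exact=True)
        assert (res1 - res2).sum() < 0.01 * res1.sum()

    def test_approximation_preserves_wide_plateau(self):
        """The large-radius approximate path removes offset + tilt but keeps
        a colony-scale plateau (the signal of interest)."""
        yy, xx = np.mgrid[0:128, 0:128]
        plateau = 3000.0 * (np.hypot(yy - 64, xx - 64) < 40)
        frame = 100 + 0.2 * xx + plateau
        bg, res = rolling_ball_background(frame, radius_px=1000)
        inside = plateau > 0
        assert res[inside].mean() > 2800
        assert res[~inside].mean() < 150


# ------------------------------------------------------------- registration

def _textured(rng, n=128):
    from scipy import ndimage as ndi
    return ndi.gaussian_filter(rng.uniform(0, 100, (n, n)), 2)


class TestRegistration:
    def test_identity_on_identical_frames(self, rng):
        frame = _textured(rng)
        res = register_series(np.stack([frame] * 4))
        for tr in res.transforms:
            assert abs(tr.dy) < 0.1 and abs(tr.dx) < 0.1
            assert abs(tr.theta) < 0.1

    def test_single_frame_identity(self, rng):
        res = register_series(_textured(rng)[None])
        assert len(res.transforms) == 1
        assert res.transforms[0].is_identity

    def test_blank_frames_flagged(self, rng):
        frames = np.stack([_textured(rng), np.zeros((128, 128))])
        with pytest.warns(UserWarning, match="blank"):
            res = register_series(frames)
        assert res.transforms[1].degenerate

    # fixed-reference mode: the static-scene estimation contract
    # (0.5 px / 0.5 deg); sequential mode re-registers each frame to the
    # aligned previous frame, so its error random-walks along the chain —
    # the price of staying robust when frame content changes (colony growth)
    @pytest.mark.parametrize("policy,tol_px,tol_deg", [
        ("first", 0.5, 0.5), ("previous", 1.0, 0.5)])
    def test_recovers_injected_drift(self, rng, policy, tol_px, tol_deg):
        base = _textured(rng)
        truth = [(0.0, 0.0, 0.0), (1.2, -0.8, 0.4), (2.0, 0.5, 0.9),
                 (1.4, 1.6, 1.3), (0.3, 2.2, 1.7)]
        frames = np.stack([apply_rigid(base, dy, dx, th, order=3)
                           for dy, dx, th in truth])
        # a smooth static texture has no sharp edges: register on intensity
        res = register_series(frames, reference_policy=policy,
                              edge_sigma=None)
        for tr, (dy, dx, th) in zip(res.transforms, truth):
            # the correction undoes the drift
            assert tr.dy == pytest.approx(-dy, abs=tol_px)
            assert tr.dx == pytest.approx(-dx, abs=tol_px)
            assert tr.theta == pytest.approx(-th, abs=tol_deg)

    def test_already_aligned_series_unchanged(self, rng):
        base = _textured(rng)
        drift = [(0, 0, 0), (1.5, -1.0, 0.6), (0.5, 2.0, 1.1)]
        frames = np.stack([apply_rigid(base, *d, order=3) for d in drift])
        aligned = register_series(frames, reference_policy="first",
                                  edge_sigma=None).aligned
        res2 = register_series(aligned, reference_policy="first",
                               edge_sigma=None)
        for tr in res2.transforms:
            assert np.hypot(tr.dy, tr.dx) <= 0.5
            assert abs(tr.theta) <= 0.5

    def test_transforms_applied_identically_to_second_channel(self, rng):
        base = _textured(rng)
        frames = np.stack([base, apply_rigid(base, 2.0, -1.0, 0.0)])
        res = register_series(frames)
        other = apply_transforms(frames, res.transforms)
        assert np.abs(other - res.aligned).max() < 1e-5

    def test_transform_csv_roundtrip(self, tmp_path):
        trs = [RigidTransform(), RigidTransform(dy=1.5, dx=-2.25, theta=0.75,
                                                reference_frame_index=0)]
        transforms_to_csv(trs, tmp_path / "t.csv")
        back = transforms_from_csv(tmp_path / "t.csv")
        assert back == trs


def test_simulated_drift_recovered_from_ground_truth():
    """End-to-end: the registration stage undoes the generator's recorded
    translational drift on a noisy colony series (the colony is isotropic,
    so only translation is observable)."""
    cfg = SimulationConfig(image_size=128, pixel_size=0.06, t_end=8.0,
                           p1_window=None, p2_onset=None,
                           drift_max_translation=1.5,
                           drift_max_rotation=0.4, seed=5)
    stack, truth = simulate_colony(cfg)
    res = register_series(stack.live)
    for tr, (dy, dx, theta) in zip(res.transforms, truth.drift):
        assert tr.dy == pytest.approx(-dy, abs=0.5)
        assert tr.dx == pytest.approx(-dx, abs=0.5)
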