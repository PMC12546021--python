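"""Sharpness scoring, perceptual hashing, and speed-zone categorization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from PIL import Image
from scipy import ndimage

from coloqc.frame_analysis import (
    DEFAULT_BLUR_THRESHOLD,
    FrameHash,
    SpeedZone,
    assess_blur,
    hamming_distance,
    is_blurred,
    laplacian_variance,
    perceptual_hash,
    speed_zone,
    to_grayscale,
)

# ---------------------------------------------------------------------------
# independent oracles


def laplacian_variance_oracle(gray: np.ndarray) -> float:
    """Explicit double-loop 3x3 Laplacian with edge replication."""
    h, w = gray.shape
    g = gray.astype(float)
    resp = np.empty_like(g)
    for y in range(h):
        for x in range(w):
            up = g[max(y - 1, 0), x]
            down = g[min(y + 1, h - 1), x]
            left = g[y, max(x - 1, 0)]
            right = g[y, min(x + 1, w - 1)]
            resp[y, x] = up + down + left + right - 4 * g[y, x]
    return float(resp.var())


def phash_oracle(frame: np.ndarray) -> int:
    """DCT perceptual hash via an explicit cosine-matrix transform."""
    img = Image.fromarray(frame).convert("L").resize((32, 32), Image.Resampling.LANCZOS)
    p = np.asarray(img, dtype=float)
    N = 32
    n = np.arange(N)
    # DCT-II, unnormalized: X_k = 2 * sum_n x_n cos(pi k (2n+1) / (2N))
    C = 2 * np.cos(np.pi * np.outer(n, 2 * n + 1) / (2 * N))
    coeffs = C @ p @ C.T
    block = coeffs[:8, :8]
    bits = (block > np.median(block)).ravel()
    out = 0
    for b in bits:
        out = (out << 1) | int(b)
    return out


def hamming_oracle(a: int, b: int) -> int:
    return sum((a >> i) & 1 != (b >> i) & 1 for i in range(64))


# ---------------------------------------------------------------------------
# Laplacian variance


def test_constant_frame_has_zero_variance():
    assert laplacian_variance(np.full((16, 16), 128, np.uint8)) == 0.0


def test_offset_invariance():
    rng = np.random.default_rng(0)
    base = rng.uniform(50, 150, size=(24, 24))
    assert laplacian_variance(base + 37.0) == pytest.approx(
        laplacian_variance(base), abs=1e-9
    )


def test_checkerboard_matches_brute_force_value():
    board = np.indices((8, 8)).sum(axis=0) % 2 * 255
    board = board.astype(np.uint8)
    expected = laplacian_variance_oracle(board.astype(float))
    assert expected == pytest.approx(820940.625)  # closed-form count of edge cases
    assert laplacian_variance(board) == pytest.approx(expected, rel=1e-12)


def test_amplitude_scaling_is_quadratic():
    rng = np.random.default_rng(1)
    pattern = rng.uniform(-1, 1, size=(32, 32))
    pattern -= pattern.mean()
    v1 = laplacian_variance(100 + 40 * pattern)
    for a in (0.25, 0.5, 1.0):
        va = laplacian_variance(100 + 40 * a * pattern)
        assert va == pytest.approx(a**2 * v1, rel=0.01)


def test_gaussian_blur_monotonically_lowers_variance(texture_frame):
    variances = [
        laplacian_variance(ndimage.gaussian_filter(texture_frame.astype(float), s))
        if s else laplacian_variance(texture_frame)
        for s in (0, 1, 2, 4)
    ]
    assert all(a >= b for a, b in zip(variances, variances[1:]))


def test_oracle_equivalence_on_random_frames(rng):
    for _ in range(50):
        frame = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        assert laplacian_variance(frame) == pytest.approx(
            laplacian_variance_oracle(frame.astype(float)), rel=1e-9
        )


def test_color_frames_use_luminance_weighting():
    rgb = np.zeros((8, 8, 3), np.uint8)
    rgb[..., 0] = 200
    gray = to_grayscale(rgb)
    assert gray == pytest.approx(np.full((8, 8), 0.299 * 200))


def test_empty_frame_rejected():
    with pytest.raises(ValueError):
        laplacian_variance(np.empty((0, 0)))


# ---------------------------------------------------------------------------
# blur decision


@pytest.mark.parametrize(
    "variance, expected",
    [(49.999, True), (50.0, False), (0.0, True), (50.001, False)],
)
def test_blur_threshold_is_strict(variance, expected):
    assert is_blurred(variance, 50.0) is expected


def test_negative_variance_rejected():
    with pytest.raises(ValueError):
        is_blurred(-1.0)


def test_assess_blur_bundles_consistent_fields(texture_frame):
    a = assess_blur(texture_frame)
    assert a.threshold_used == DEFAULT_BLUR_THRESHOLD
    assert a.is_blurred == (a.variance < a.threshold_used)


# ---------------------------------------------------------------------------
# perceptual hash


def test_hash_deterministic_and_hex_roundtrip(texture_frame):
    h1 = perceptual_hash(texture_frame)
    h2 = perceptual_hash(texture_frame.copy())
    assert h1 == h2
    assert FrameHash.from_hex(h1.hex) == h1
    assert len(h1.hex) == 16


def test_brightness_offset_leaves_hash_unchanged(texture_frame):
    clipped = np.clip(texture_frame, 0, 235)  # headroom so +20 cannot clip
    h0 = perceptual_hash(clipped)
    h1 = perceptual_hash(clipped + 20)
    assert hamming_distance(h0, h1) == 0


def test_hash_matches_cosine_matrix_oracle(texture_frame, rng):
    frames = [texture_frame] + [
        rng.integers(0, 256, size=(64, 64)).astype(np.uint8) for _ in range(10)
    ]
    for frame in frames:
        assert perceptual_hash(frame).bits == phash_oracle(frame)


def test_translation_distance_agrees_with_oracle(texture_frame):
    h, w = texture_frame.shape[:2]
    shifted = np.roll(texture_frame, w // 2, axis=1)  # 50% translation
    mine = hamming_distance(perceptual_hash(texture_frame), perceptual_hash(shifted))
    ref = hamming_oracle(phash_oracle(texture_frame), phash_oracle(shifted))
    assert mine == ref
    assert mine > 0


# ---------------------------------------------------------------------------
# Hamming distance


def test_hamming_identity_and_complement():
    h = FrameHash(0x0F0F_1234_ABCD_5678)
    comp = FrameHash(h.bits ^ 0xFFFF_FFFF_FFFF_FFFF)
    assert hamming_distance(h, h) == 0
    assert hamming_distance(h, comp) == 64


@given(
    st.integers(0, 2**64 - 1), st.integers(0, 2**64 - 1), st.integers(0, 2**64 - 1)
)
@settings(max_examples=200, deadline=None)
def test_hamming_is_a_metric(a, b, c):
    ha, hb, hc = FrameHash(a), FrameHash(b), FrameHash(c)
    dab = hamming_distance(ha, hb)
    assert dab == hamming_distance(hb, ha)
    assert (dab == 0) == (a == b)
    assert dab <= hamming_distance(ha, hc) + hamming_distance(hc, hb)


def test_hamming_agrees_with_bit_loop_oracle(rng):
    for _ in range(50):
        a, b = (int(x) for x in rng.integers(0, 2**63, size=2))
        assert hamming_distance(FrameHash(a), FrameHash(b)) == hamming_oracle(a, b)


# ---------------------------------------------------------------------------
# speed zones


@pytest.mark.parametrize(
    "distance, zone",
    [(0, "normal"), (20, "normal"), (21, "warning"), (30, "warning"),
     (31, "danger"), (64, "danger")],
)
def test_zone_boundaries(distance, zone):
    assert speed_zone(distance) is SpeedZone(zone)


def test_zones_partition_the_distance_range():
    zones = [speed_zone(d) for d in range(65)]
    assert all(isinstance(z, SpeedZone) for z in zones)
    assert [z for z in zones].count(SpeedZone.NORMAL) == 21
    assert zones.count(SpeedZone.WARNING) == 10
    assert zones.count(SpeedZone.DANGER) == 34


def test_out_of_range_distance_rejected():
    with pytest.raises(ValueError):
        speed_zone(65)
    with pytest.raises(ValueError):
        speed_zone(-1)
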