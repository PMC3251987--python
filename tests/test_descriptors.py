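import numpy as np
import pytest

from veinline.descriptors import (
    CodeMap,
    code_geometry,
    code_to_grayscale,
    lbp,
    llbp,
    llbp_concat,
    llbp_h,
    llbp_magnitude,
    llbp_v,
    load_codemap,
    save_codemap,
    step,
)

# ---------------------------------------------------------------- oracles


def naive_llbp_h(image, N):
    """Per-pixel nested-loop horizontal line codes (pixel order, center
    excluded)."""
    m = (N - 1) // 2
    h, w = image.shape
    img = image.astype(np.int64)
    bits = np.zeros((h - 2 * m, w - 2 * m, N - 1), dtype=bool)
    for r in range(m, h - m):
        for c in range(m, w - m):
            k = 0
            for off in list(range(-m, 0)) + list(range(1, m + 1)):
                bits[r - m, c - m, k] = img[r, c + off] >= img[r, c]
                k += 1
    return bits


def naive_llbp_v(image, N):
    m = (N - 1) // 2
    h, w = image.shape
    img = image.astype(np.int64)
    bits = np.zeros((h - 2 * m, w - 2 * m, N - 1), dtype=bool)
    for r in range(m, h - m):
        for c in range(m, w - m):
            k = 0
            for off in list(range(-m, 0)) + list(range(1, m + 1)):
                bits[r - m, c - m, k] = img[r + off, c] >= img[r, c]
                k += 1
    return bits


def naive_lbp(image, P, R):
    """Per-pixel loop with explicit bilinear sampling on the circle."""
    h, w = image.shape
    img = image.astype(np.float64)
    bits = np.zeros((h - 2 * R, w - 2 * R, P), dtype=bool)
    for r in range(R, h - R):
        for c in range(R, w - R):
            for k in range(P):
                angle = 2.0 * np.pi * k / P
                dy = -R * np.sin(angle)
                dx = R * np.cos(angle)
                oy, ox = int(np.floor(dy)), int(np.floor(dx))
                fy, fx = dy - oy, dx - ox
                # sample positions within 1e-9 of a pixel are exact
                if fy < 1e-9:
                    fy = 0.0
                elif fy > 1 - 1e-9:
                    oy, fy = oy + 1, 0.0
                if fx < 1e-9:
                    fx = 0.0
                elif fx > 1 - 1e-9:
                    ox, fx = ox + 1, 0.0
                y0, x0 = r + oy, c + ox
                val = (1 - fy) * (1 - fx) * img[y0, x0]
                if fx > 0:
                    val += (1 - fy) * fx * img[y0, x0 + 1]
                if fy > 0:
                    val += fy * (1 - fx) * img[y0 + 1, x0]
                if fy > 0 and fx > 0:
                    val += fy * fx * img[y0 + 1, x0 + 1]
                bits[r - R, c - R, k] = val >= img[r, c]
    return bits


# ----------------------------------------------------------------- tests


def test_step_boundary_and_signs():
    assert step(0) == 1
    assert step(-1) == 0
    assert step(13) == 1
    assert np.array_equal(step(np.array([-5, 0, 5])), [0, 1, 1])


class TestLlbpComponents:
    def test_constant_image_all_ones(self):
        img = np.full((9, 9), 42, dtype=np.uint8)
        assert llbp_h(img, 5).bits.all()
        assert llbp_v(img, 5).bits.all()

    def test_horizontal_ramp_code(self):
        # strictly increasing left->right: left neighbors below center,
        # right neighbors above -> bits 0011 in pixel order
        img = np.tile(np.arange(0, 90, 10, dtype=np.uint8), (9, 1))
        cmap = llbp_h(img, 5)
        assert all(
            cmap.code_string(r, c) == "0011"
            for r in range(cmap.valid_height)
            for c in range(cmap.valid_width)
        )

    def test_ramp_decimal_value_matches_weighted_sums(self):
        # bits 0011 with c=3: left weights 2,1 -> 0; right weights 1,2 -> 3
        img = np.tile(np.arange(0, 90, 10, dtype=np.uint8), (9, 1))
        cmap = llbp_h(img, 5)
        assert np.all(cmap.values == 3)

    def test_matches_naive_loops(self, random_image):
        img = random_image((32, 32))
        assert np.array_equal(llbp_h(img, 7).bits, naive_llbp_h(img, 7))
        assert np.array_equal(llbp_v(img, 7).bits, naive_llbp_v(img, 7))

    def test_transpose_duality(self, random_image):
        img = random_image((24, 40))
        direct = llbp_v(img, 5)
        via_transpose = llbp_h(np.ascontiguousarray(img.T), 5)
        assert np.array_equal(direct.bits, via_transpose.bits.transpose(1, 0, 2))

    def test_even_or_tiny_line_rejected(self, random_image):
        with pytest.raises(ValueError):
            llbp_h(random_image((16, 16)), 6)
        with pytest.raises(ValueError):
            llbp_h(random_image((16, 16)), 1)

    def test_image_too_narrow(self, random_image):
        with pytest.raises(ValueError):
            llbp_h(random_image((30, 5)), 7)


class TestConcat:
    def test_worked_example_bitstring(self):
        h_bits = np.array(
            [[[int(b) for b in "010111001111"]]], dtype=bool
        )
        v_bits = np.array(
            [[[int(b) for b in "101001011101"]]], dtype=bool
        )
        h_map = CodeMap(h_bits, (6, 6, 6, 6), "llbp_h")
        v_map = CodeMap(v_bits, (6, 6, 6, 6), "llbp_v")
        combined = llbp_concat(h_map, v_map)
        assert combined.code_string(0, 0) == "010111001111101001011101"
        assert combined.bits_per_pixel == 24

    def test_concat_length_is_sum(self, random_image):
        img = random_image((20, 20))
        cmap = llbp(img, 5)
        assert cmap.bits_per_pixel == 2 * (5 - 1)
        assert np.array_equal(cmap.bits[..., :4], llbp_h(img, 5).bits)
        assert np.array_equal(cmap.bits[..., 4:], llbp_v(img, 5).bits)

    def test_geometry_mismatch_rejected(self, random_image):
        h_map = llbp_h(random_image((20, 20)), 5)
        v_map = llbp_v(random_image((22, 22)), 5)
        with pytest.raises(ValueError):
            llbp_concat(h_map, v_map)

    def test_wrong_component_tags_rejected(self, random_image):
        h_map = llbp_h(random_image((20, 20)), 5)
        with pytest.raises(ValueError):
            llbp_concat(h_map, h_map)


def test_magnitude_pythagorean_cases():
    assert llbp_magnitude(3, 4) == pytest.approx(5.0)
    assert llbp_magnitude(0, 0) == 0.0
    assert llbp_magnitude(7, 0) == 7.0


class TestLbp:
    def test_constant_image_all_ones(self):
        img = np.full((10, 10), 9, dtype=np.uint8)
        assert lbp(img, 8, 1).bits.all()

    def test_matches_naive_loop(self, random_image):
        img = random_image((32, 32))
        for P, R in [(8, 1), (8, 2), (4, 1)]:
            assert np.array_equal(lbp(img, P, R).bits, naive_lbp(img, P, R))

    def test_axial_neighbors_exact(self):
        # samples 0 and 4 lie exactly on integer pixels (right and left)
        img = np.array(
            [[5, 5, 5], [4, 5, 9], [5, 5, 5]], dtype=np.uint8
        )
        cmap = lbp(img, 8, 1)
        bits = cmap.bits[0, 0]
        assert bits[0] == True  # right neighbor 9 >= 5  # noqa: E712
        assert bits[4] == False  # left neighbor 4 < 5  # noqa: E712

    def test_too_small_image(self, random_image):
        with pytest.raises(ValueError):
            lbp(random_image((2, 2)), 8, 1)


class TestGeometry:
    @pytest.mark.parametrize(
        "descriptor,kwargs,expected",
        [
            ("llbp", dict(N=21), (44, 172, 40, 302720)),
            ("llbp_v", dict(N=17), (48, 176, 16, 135168)),
            ("llbp_h", dict(N=21), (44, 172, 20, 151360)),
            ("lbp", dict(P=8, R=1), (62, 190, 8, 94240)),
            ("lbp", dict(P=8, R=2), (60, 188, 8, 90240)),
        ],
    )
    def test_closed_form_template_sizes(self, descriptor, kwargs, expected):
        geom = code_geometry(64, 192, descriptor, **kwargs)
        assert (
            geom.valid_height,
            geom.valid_width,
            geom.bits_per_pixel,
            geom.total_bits,
        ) == expected

    def test_closed_form_matches_actual_maps(self, random_image):
        img = random_image((64, 192))
        for cmap, geom in [
            (llbp(img, 21), code_geometry(64, 192, "llbp", N=21)),
            (llbp_v(img, 17), code_geometry(64, 192, "llbp_v", N=17)),
            (lbp(img, 8, 1), code_geometry(64, 192, "lbp", P=8, R=1)),
        ]:
            assert (cmap.valid_height, cmap.valid_width, cmap.bits_per_pixel) == (
                geom.valid_height,
                geom.valid_width,
                geom.bits_per_pixel,
            )
            assert cmap.total_bits == geom.total_bits
            assert (
                cmap.total_bits
                == cmap.valid_height * cmap.valid_width * cmap.bits_per_pixel
            )

    def test_descriptor_does_not_fit(self):
        with pytest.raises(ValueError):
            code_geometry(10, 10, "llbp", N=21)


class TestMonotoneInvariance:
    @pytest.mark.parametrize("offset", [1, 40, -25])
    def test_constant_shift_leaves_codes_unchanged(self, random_image, offset):
        img = random_image((24, 24)).astype(np.int64)
        img = np.clip(img, 40, 215).astype(np.uint8)  # room for the offset
        shifted = (img.astype(np.int64) + offset).astype(np.uint8)
        assert np.array_equal(llbp(img, 7).bits, llbp(shifted, 7).bits)
        assert np.array_equal(lbp(img, 8, 1).bits, lbp(shifted, 8, 1).bits)


class TestVisualization:
    def test_extreme_values_map_to_0_and_255(self):
        cmap = CodeMap(
            np.zeros((1, 2, 4), dtype=bool),
            (0, 0, 0, 0),
            "lbp",
            values=np.array([[0.0, 15.0]]),
        )
        assert np.array_equal(code_to_grayscale(cmap), [[0, 255]])

    def test_constant_map_renders_mid_gray(self):
        cmap = CodeMap(
            np.ones((2, 2, 4), dtype=bool),
            (0, 0, 0, 0),
            "lbp",
            values=np.full((2, 2), 9.0),
        )
        assert np.all(code_to_grayscale(cmap) == 128)

    def test_three_value_linear_normalization(self):
        cmap = CodeMap(
            np.zeros((1, 3, 4), dtype=bool),
            (0, 0, 0, 0),
            "lbp",
            values=np.array([[0.0, 50.0, 100.0]]),
        )
        assert np.array_equal(code_to_grayscale(cmap), [[0, 128, 255]])


def test_codemap_serialization_round_trip(tmp_path, random_image):
    cmap = llbp(random_image((20, 30)), 5)
    path = tmp_path / "template.vlcm"
    save_codemap(cmap, path)
    loaded = load_codemap(path)
    assert loaded.descriptor_tag == "llbp"
    assert loaded.margin == cmap.margin
    assert np.array_equal(loaded.bits, cmap.bits)
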