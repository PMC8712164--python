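import numpy as np
import pytest

from osteotex.config import EdgeConfig
from osteotex.segmentation import (
    EdgeMap,
    NoROIError,
    ROIBox,
    crop,
    detect_edges,
    extract_roi,
)

from conftest import make_image


def edge_map(mask):
    return EdgeMap(mask=np.asarray(mask, bool), detector="canny", params={})


def brute_force_components(mask):
    """Independent 8-connected component labelling by flood fill."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], []
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < mask.shape[0]
                                    and 0 <= cc < mask.shape[1]
                                    and mask[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


class TestDetectEdges:
    @pytest.mark.parametrize("method", ["canny", "sobel", "prewitt"])
    def test_constant_image_has_no_edges(self, constant_image, method):
        edges = detect_edges(constant_image, method=method)
        assert not edges.mask.any()
        assert edges.detector == method

    def test_sobel_finds_vertical_step(self):
        arr = np.zeros((12, 12))
        arr[:, 6:] = 255.0
        edges = detect_edges(make_image(arr), method="sobel")
        cols = np.nonzero(edges.mask)[1]
        assert edges.mask.any()
        assert set(cols) <= {5, 6}  # gradient mass concentrated at the step

    def test_canny_outlines_filled_rectangle(self):
        arr = np.zeros((30, 30))
        arr[8:22, 5:25] = 255.0
        edges = detect_edges(make_image(arr), method="canny")
        rows, cols = np.nonzero(edges.mask)
        assert edges.mask.any()
        # all edge pixels near the rectangle perimeter, none deep inside
        near_row = (np.abs(rows - 8) <= 2) | (np.abs(rows - 21) <= 2)
        near_col = (np.abs(cols - 5) <= 2) | (np.abs(cols - 24) <= 2)
        assert np.all(near_row | near_col)

    def test_unknown_method_rejected(self, constant_image):
        with pytest.raises(ValueError, match="unknown edge detector"):
            detect_edges(constant_image, method="roberts")

    def test_bad_hysteresis_rejected(self, constant_image):
        cfg = EdgeConfig(low=0.5, high=0.2)
        with pytest.raises(ValueError, match="low < high"):
            detect_edges(constant_image, method="canny", config=cfg)

    def test_deterministic(self, random_image):
        a = detect_edges(random_image, method="canny")
        b = detect_edges(random_image, method="canny")
        np.testing.assert_array_equal(a.mask, b.mask)


class TestExtractROI:
    def test_single_pixel(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 7] = True
        box = extract_roi(edge_map(mask))
        assert box == ROIBox(5, 6, 7, 8)

    def test_largest_of_two_components(self):
        mask = np.zeros((20, 20), bool)
        mask[2, 3:13] = True  # 10 pixels
        mask[15, 1:4] = True  # 3 pixels
        box = extract_roi(edge_map(mask))
        assert box == ROIBox(2, 3, 3, 13)

    def test_rectangle_outline_tight_bbox(self):
        mask = np.zeros((20, 20), bool)
        mask[2, 3:13] = mask[8, 3:13] = True
        mask[2:9, 3] = mask[2:9, 12] = True
        box = extract_roi(edge_map(mask))
        assert box == ROIBox(2, 9, 3, 13)

    def test_empty_mask_raises(self):
        with pytest.raises(NoROIError, match="full image"):
            extract_roi(edge_map(np.zeros((5, 5), bool)))

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(25):
            mask = rng.random((12, 12)) < 0.2
            if not mask.any():
                continue
            comps = brute_force_components(mask)
            largest = max(len(c) for c in comps)
            box = extract_roi(edge_map(mask))
            # box must contain every pixel of some largest component
            winners = [c for c in comps if len(c) == largest]
            assert any(
                all(box.row_min <= r < box.row_max
                    and box.col_min <= c_ < box.col_max for r, c_ in comp)
                for comp in winners
            )


class TestCrop:
    def test_full_image_box_is_identity(self, random_image):
        box = ROIBox(0, random_image.height, 0, random_image.width)
        out = crop(random_image, box)
        np.testing.assert_array_equal(out.pixels, random_image.pixels)

    def test_single_pixel_box(self, random_image):
        out = crop(random_image, ROIBox(3, 4, 5, 6))
        assert out.shape == (1, 1)
        assert out.pixels[0, 0] == random_image.pixels[3, 5]
        assert out.offset == (3, 5)

    def test_shape_arithmetic(self, rng):
        img = make_image(rng.integers(0, 256, (20, 20)).astype(float))
        out = crop(img, ROIBox(2, 9, 3, 13))
        assert out.shape == (7, 10)

    def test_out_of_bounds_rejected(self, random_image):
        with pytest.raises(ValueError, match="exceeds image bounds"):
            crop(random_image, ROIBox(0, random_image.height + 1, 0, 2))
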