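"""US segmentation and medium construction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oxylight import (
    Grid3D,
    OpticalProperties,
    USImage,
    mask_to_medium,
    make_tube_phantom,
    segment_tissue,
    synth_us_image,
)
from oxylight.phantoms import boundary_truth_rows
from oxylight.segmentation import BinaryMask


def _us(pixels, pitch=0.074):
    return USImage(np.asarray(pixels, dtype=float), pixel_pitch_mm=pitch)


class TestSegmentTissue:
    def test_noiseless_rectangle_recovered_exactly(self):
        img = np.zeros((64, 64))
        img[20:40, 10:50] = 1.0
        mask = segment_tissue(_us(img), threshold=0.5, median_kernel=1)
        assert np.array_equal(mask.pixels, (img > 0.5).astype(np.uint8))

    def test_largest_component_kept(self):
        img = np.zeros((64, 64))
        img[5:10, 5:10] = 1.0  # 25 px blob
        img[30:50, 30:55] = 1.0  # 500 px blob
        mask = segment_tissue(_us(img), threshold=0.5, median_kernel=1)
        assert mask.pixels[35, 40] == 1
        assert mask.pixels[7, 7] == 0

    def test_holes_are_filled(self):
        img = np.zeros((64, 64))
        img[10:50, 10:50] = 1.0
        img[25:30, 25:30] = 0.0  # speckle hole
        mask = segment_tissue(_us(img), threshold=0.5, median_kernel=1)
        assert mask.pixels[27, 27] == 1

    def test_empty_mask_raises_with_suggestion(self):
        img = np.random.default_rng(0).uniform(0, 0.2, (32, 32))
        with pytest.raises(ValueError, match="Otsu"):
            segment_tissue(_us(img), threshold=float(img.max()), median_kernel=1)

    def test_threshold_outside_range_rejected(self):
        img = np.ones((16, 16)) * 0.5
        with pytest.raises(ValueError, match="outside"):
            segment_tissue(_us(img), threshold=2.0)

    def test_water_above_row_forced_to_zero(self):
        img = np.ones((32, 32))
        img[0, 0] = 0.0
        mask = segment_tissue(_us(img), threshold=0.5, water_above_row=10)
        assert not mask.pixels[:10].any()
        assert mask.pixels[10:].all()

    def test_speckled_slab_boundary_recovered_within_two_pixels(self):
        """Generator's ground-truth interface is the oracle."""
        spec = make_tube_phantom(
            [],
            medium_kind="two_slab",
            interface_depth_mm=8.0,
            image_shape=(128, 96),
            pixel_pitch_mm=0.148,
            grid_shape=(96, 64, 128),
        )
        us = synth_us_image(spec, seed=5)
        mask = segment_tissue(us, threshold=0.35, median_kernel=5)
        truth = boundary_truth_rows(spec)
        assert np.all(np.abs(mask.boundary_rows - truth) <= 2)

    @given(st.integers(0, 2**32 - 1))
    def test_idempotence_on_binary_images(self, seed):
        """Segmenting an already-binary image returns its filled largest
        component for any threshold in (0, 1)."""
        rng = np.random.default_rng(seed)
        img = (rng.uniform(size=(24, 24)) > 0.6).astype(float)
        img[10:14, 10:14] = 1.0  # guarantee non-empty
        first = segment_tissue(_us(img), threshold=0.5, median_kernel=1)
        second = segment_tissue(
            _us(first.pixels.astype(float)), threshold=0.5, median_kernel=1
        )
        assert np.array_equal(first.pixels, second.pixels)

    @given(st.floats(0.1, 0.8), st.floats(0.05, 0.15))
    def test_threshold_monotonicity(self, t, dt):
        """Raising the threshold never grows the thresholded foreground."""
        rng = np.random.default_rng(99)
        img = rng.uniform(size=(48, 48))
        img[16:32, 16:32] += 1.0
        lo = segment_tissue(_us(img), threshold=t, median_kernel=3)
        hi = segment_tissue(_us(img), threshold=min(t + dt, 1.7), median_kernel=3)
        # the high-threshold largest component is contained in the
        # low-threshold filled foreground
        grown = np.logical_and(hi.pixels, np.logical_not(lo.pixels))
        # allow only pixels that were hole-filled at the lower threshold
        assert grown.sum() == 0 or lo.pixels[grown].all()


class TestMaskToMedium:
    def _props(self):
        tissue = {750: OpticalProperties(0.101, 10.5, 0.9)}
        water = {750: OpticalProperties(0.026, 0.0, 0.0)}
        return tissue, water

    def test_full_mask_fills_grid_width(self):
        mask = BinaryMask(np.ones((16, 20), dtype=np.uint8), pixel_pitch_mm=0.1)
        grid = Grid3D(shape=(32, 8, 16), spacing_mm=0.1)
        tissue, water = self._props()
        medium = mask_to_medium(mask, tissue, water, grid)
        assert medium.labels.shape == (32, 8, 16)
        assert (medium.labels == 1).all()

    def test_edge_replication_semantics(self):
        """Tissue touching the left mask edge replicates as tissue; the
        background right edge replicates as background."""
        m = np.zeros((10, 12), dtype=np.uint8)
        m[:, :6] = 1
        mask = BinaryMask(m, pixel_pitch_mm=0.1)
        grid = Grid3D(shape=(24, 4, 10), spacing_mm=0.1)
        tissue, water = self._props()
        medium = mask_to_medium(mask, tissue, water, grid)
        assert (medium.labels[0, :, :] == 1).all()  # left pad = tissue
        assert (medium.labels[-1, :, :] == 0).all()  # right pad = background

    def test_in_footprint_pixels_transferred_exactly(self):
        rng = np.random.default_rng(2)
        m = (rng.uniform(size=(20, 30)) > 0.5).astype(np.uint8)
        mask = BinaryMask(m, pixel_pitch_mm=0.1)
        grid = Grid3D(shape=(40, 6, 20), spacing_mm=0.1)
        tissue, water = self._props()
        medium = mask_to_medium(mask, tissue, water, grid)
        pad = (40 - 30) // 2
        assert np.array_equal(medium.labels[pad : pad + 30, 3, :], m.T)

    def test_elevational_extrusion_uniform(self):
        rng = np.random.default_rng(3)
        m = (rng.uniform(size=(12, 16)) > 0.4).astype(np.uint8)
        mask = BinaryMask(m, pixel_pitch_mm=0.1)
        grid = Grid3D(shape=(20, 5, 12), spacing_mm=0.1)
        tissue, water = self._props()
        medium = mask_to_medium(mask, tissue, water, grid)
        for iy in range(1, 5):
            assert np.array_equal(
                medium.labels[:, iy, :], medium.labels[:, 0, :]
            )

    def test_instrument_rasters_produce_full_volume_shape(self):
        mask = BinaryMask(
            np.ones((512, 545), dtype=np.uint8), pixel_pitch_mm=0.074
        )
        grid = Grid3D(shape=(744, 8, 512), spacing_mm=0.074)
        tissue, water = self._props()
        medium = mask_to_medium(mask, tissue, water, grid)
        assert medium.labels.shape == (744, 8, 512)

    def test_mask_larger_than_grid_rejected(self):
        mask = BinaryMask(np.ones((16, 50), dtype=np.uint8), pixel_pitch_mm=0.1)
        grid = Grid3D(shape=(40, 4, 16), spacing_mm=0.1)
        tissue, water = self._props()
        with pytest.raises(ValueError, match="exceeds"):
            mask_to_medium(mask, tissue, water, grid)

    def test_pitch_mismatch_rejected(self):
        mask = BinaryMask(np.ones((8, 8), dtype=np.uint8), pixel_pitch_mm=0.2)
        grid = Grid3D(shape=(16, 4, 8), spacing_mm=0.1)
        tissue, water = self._props()
        with pytest.raises(ValueError, match="pitch"):
            mask_to_medium(mask, tissue, water, grid)
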