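import numpy as np
import pytest

from lpscreen import images, simulate
from lpscreen.errors import BackgroundUndefinedError, OvercrowdedFieldError


def blank_field(shape=(64, 64), value=0.0):
    z = np.full(shape, value, dtype=float)
    return images.ImageField(z.copy(), z.copy(), z.copy())


def disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestSegmentNuclei:
    def test_blank_image_zero_nuclei(self):
        labels = images.segment_nuclei(blank_field())
        assert labels.max() == 0

    def test_bright_square_single_nucleus(self):
        f = blank_field()
        f.nuclear_stain[10:19, 10:19] = 100.0
        labels = images.segment_nuclei(f, min_area_px=10)
        assert labels.max() == 1
        assert (labels == 1).sum() == 81

    def test_two_discs_recovered_with_areas(self):
        f = blank_field((128, 128))
        m1 = disc_mask((128, 128), 30, 30, 8)
        m2 = disc_mask((128, 128), 90, 90, 6)
        f.nuclear_stain[m1 | m2] = 200.0
        labels = images.segment_nuclei(f)
        assert labels.max() == 2
        areas = sorted(np.bincount(labels.ravel())[1:])
        assert abs(areas[0] - m2.sum()) <= 1 and abs(areas[1] - m1.sum()) <= 1

    def test_min_area_filters_specks(self):
        f = blank_field()
        f.nuclear_stain[5, 5] = 100.0
        f.nuclear_stain[20:29, 20:29] = 100.0
        labels = images.segment_nuclei(f, min_area_px=20)
        assert labels.max() == 1

    def test_fixed_threshold_method(self):
        f = blank_field(value=10.0)
        f.nuclear_stain[10:19, 10:19] = 50.0
        labels = images.segment_nuclei(f, threshold_method="fixed", fixed_threshold=30)
        assert labels.max() == 1


class TestEstimateBackground:
    def test_uniform_image_background_is_value(self):
        f = blank_field(value=7.0)
        f.nuclear_stain[10:19, 10:19] += 100.0
        labels = images.segment_nuclei(f, min_area_px=10)
        bg = images.estimate_background(f, labels)
        assert bg.green == 7.0 and bg.red == 7.0 and bg.nuclear_stain == 7.0

    def test_constant_offset_recovered(self):
        f = blank_field((96, 96), value=12.5)
        m = disc_mask((96, 96), 40, 40, 9)
        f.nuclear_stain[m] += 300.0
        f.green[m] += 80.0
        labels = images.segment_nuclei(f)
        assert images.estimate_background(f, labels).green == 12.5

    def test_shift_raises_background_exactly(self):
        field, _ = simulate.generate_image_field(n_cells=6, shape=(160, 160), seed=3)
        labels = images.segment_nuclei(field)
        bg1 = images.estimate_background(field, labels)
        shifted = images.ImageField(
            field.nuclear_stain, field.green + 11.0, field.red
        )
        bg2 = images.estimate_background(shifted, labels)
        assert bg2.green == pytest.approx(bg1.green + 11.0, abs=1e-12)

    def test_no_intercell_pixels_is_error(self):
        f = blank_field((16, 16))
        f.nuclear_stain[:, :] = 100.0
        f.nuclear_stain[0, 0] = 0.0
        labels = np.ones((16, 16), dtype=np.int32)
        with pytest.raises(BackgroundUndefinedError):
            images.estimate_background(f, labels, halo_px=8)


class TestMeasureCells:
    def test_uniform_green_ratio_one(self):
        f = blank_field((64, 64))
        m = disc_mask((64, 64), 32, 32, 6)
        f.nuclear_stain[m] = 200.0
        f.green[:, :] = 10.0
        labels = images.segment_nuclei(f)
        cells = images.measure_cells(f, labels, images.Background(0, 0, 0))
        assert len(cells) == 1
        assert cells[0].nc_ratio == pytest.approx(1.0)

    def test_piecewise_constant_ratio_four(self):
        f = blank_field((64, 64))
        m = disc_mask((64, 64), 32, 32, 7)
        f.nuclear_stain[m] = 200.0
        f.green[:, :] = 5.0
        f.green[m] = 20.0
        labels = images.segment_nuclei(f)
        cells = images.measure_cells(f, labels, images.Background(0, 0, 0))
        assert cells[0].nc_ratio == pytest.approx(4.0)

    def test_geometry_invariants(self):
        field, _ = simulate.generate_image_field(n_cells=9, shape=(224, 224), seed=4)
        labels = images.segment_nuclei(field)
        bg = images.estimate_background(field, labels)
        for c in images.measure_cells(field, labels, bg):
            nucleus = labels == c.label
            core = np.zeros_like(nucleus)
            core[c.core_pixels] = True
            ring = np.zeros_like(nucleus)
            ring[c.ring_pixels] = True
            assert (core & ~nucleus).sum() == 0  # core inside nucleus
            assert (ring & nucleus).sum() == 0  # ring outside nucleus
            # ring starts exactly 1 px outside: no ring pixel touches the
            # nucleus (Chebyshev distance >= 2) but some lie at distance 2
            from scipy import ndimage

            d1 = ndimage.binary_dilation(nucleus, np.ones((3, 3), bool))
            assert (ring & d1).sum() == 0
            d2 = ndimage.binary_dilation(d1, np.ones((3, 3), bool))
            assert (ring & d2).sum() > 0

    def test_matches_bruteforce_mask_arithmetic(self):
        """Pixel-by-pixel oracle built from shifted-mask min/max filters."""
        rng = np.random.default_rng(5)
        f = blank_field((96, 96))
        m = disc_mask((96, 96), 48, 48, 8)
        f.nuclear_stain[m] = 300.0
        yy, xx = np.mgrid[:96, :96]
        f.green = 10.0 + 20.0 * np.exp(-(((yy - 48) ** 2 + (xx - 48) ** 2) / 60.0))
        f.red = rng.uniform(5, 15, (96, 96))
        labels = images.segment_nuclei(f)
        bg = images.Background(0.0, 2.0, 1.0)
        (cell,) = images.measure_cells(f, labels, bg)

        def cheb_window(mask, r, op):
            acc = None
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    sh = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
                    acc = sh if acc is None else op(acc, sh)
            return acc

        nucleus = labels == 1
        core = cheb_window(nucleus, 2, np.logical_and)
        ring = cheb_window(nucleus, 3, np.logical_or) & ~cheb_window(
            nucleus, 1, np.logical_or
        )
        g = np.clip(f.green - bg.green, 0, None)
        r = np.clip(f.red - bg.red, 0, None)
        assert cell.nuclear_green == pytest.approx(g[core].mean(), abs=1e-9)
        assert cell.cyto_green == pytest.approx(g[ring].mean(), abs=1e-9)
        assert cell.nc_ratio == pytest.approx(
            g[core].mean() / g[ring].mean(), abs=1e-9
        )
        assert cell.nuclear_red == pytest.approx(r[core].mean(), abs=1e-9)

    def test_neighbor_nucleus_pixels_removed_from_ring(self):
        f = blank_field((64, 64))
        m1 = disc_mask((64, 64), 30, 26, 6)
        m2 = disc_mask((64, 64), 30, 41, 6)  # 15 px apart: rings would touch
        f.nuclear_stain[m1 | m2] = 200.0
        f.green[:, :] = 10.0
        labels = images.segment_nuclei(f)
        assert labels.max() == 2
        cells = images.measure_cells(f, labels, images.Background(0, 0, 0))
        for c in cells:
            ring = np.zeros((64, 64), bool)
            ring[c.ring_pixels] = True
            assert (ring & (labels > 0)).sum() == 0


class TestSummarizeWell:
    def test_zero_cells(self):
        s = images.summarize_well([[]])
        assert s.cell_count == 0
        assert np.isnan(s.mean_nc_ratio) and np.isnan(s.mean_nuclear_red)

    def test_mean_of_ratios(self):
        cells = [
            images.CellMeasurement(i, ((), ()), ((), ()), 1, 1, r, 5.0)
            for i, r in enumerate((1.0, 2.0, 3.0))
        ]
        s = images.summarize_well([cells[:2], cells[2:]])
        assert s.cell_count == 3
        assert s.mean_nc_ratio == pytest.approx(2.0)

    def test_two_fields_pool_counts(self):
        fields = []
        for seed, n in ((1, 12), (2, 15)):
            field, _ = simulate.generate_image_field(
                n_cells=n, shape=(288, 288), seed=seed
            )
            fields.append(images.measure_field(field))
        s = images.summarize_well(fields)
        assert s.cell_count == 27


class TestGeneratedFields:
    def test_translocation_monotone(self):
        means = []
        for t in (1.0, 1.5, 2.5):
            field, _ = simulate.generate_image_field(n_cells=15, translocation=t, seed=9)
            s = images.summarize_well([images.measure_field(field)])
            means.append(s.mean_nc_ratio)
        assert means[0] < means[1] < means[2]

    def test_overcrowding_rejected(self):
        with pytest.raises(OvercrowdedFieldError):
            simulate.generate_image_field(n_cells=500, shape=(128, 128))

    def test_scale_equivariance(self):
        field, _ = simulate.generate_image_field(n_cells=8, shape=(192, 192), seed=2)
        labels = images.segment_nuclei(field)
        bg = images.estimate_background(field, labels)
        m0 = images.measure_cells(field, labels, bg)
        f2 = images.ImageField(field.nuclear_stain, field.green * 2.5, field.red)
        bg2 = images.estimate_background(f2, labels)
        m2 = images.measure_cells(f2, labels, bg2)
        for a, b in zip(m0, m2):
            assert b.nc_ratio == pytest.approx(a.nc_ratio, abs=1e-9)
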