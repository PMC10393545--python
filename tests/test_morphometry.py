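import numpy as np
import pytest
from scipy.spatial.distance import cdist

from gammatail.morphometry import (
    Circle,
    analyze_labels,
    analyze_mask,
    circular_fraction,
    decompose_body_shmoo,
    largest_inscribed_circle,
    read_mask,
    shmoo_length,
    shmoo_width,
    write_mask,
)
from gammatail.errors import InvalidInputError
from gammatail.simulate import ShmooGroundTruth, make_shmoo_mask, random_blob_mask


def brute_force_inscribed_circle(mask):
    """Exhaustive oracle: per foreground pixel, min distance to any
    background pixel centre (frame border counts as background)."""
    arr = np.pad(np.asarray(mask) != 0, 1, constant_values=False)
    fg = np.argwhere(arr)
    bg = np.argwhere(~arr)
    d = cdist(fg.astype(float), bg.astype(float)).min(axis=1)
    order = np.lexsort((fg[:, 1], fg[:, 0], -d))  # max distance, then (row, col)
    best = order[0]
    row, col = fg[best] - 1
    return Circle(int(row), int(col), float(d[best]))


def disc_mask(n, r, center=None):
    c = (n - 1) / 2.0 if center is None else center
    rows, cols = np.indices((n, n), dtype=float)
    return np.hypot(rows - c, cols - c) <= r


class TestInscribedCircle:
    def test_single_pixel_has_radius_one(self):
        mask = np.zeros((5, 5), dtype=int)
        mask[2, 3] = 1
        c = largest_inscribed_circle(mask)
        assert (c.row, c.col, c.radius) == (2, 3, 1.0)

    def test_three_by_three_block_centres(self):
        mask = np.zeros((5, 5), dtype=int)
        mask[1:4, 1:4] = 1
        c = largest_inscribed_circle(mask)
        assert (c.row, c.col) == (2, 2)
        assert c.radius == 2.0  # distance from the middle to the nearest background

    def test_centered_disc(self):
        mask = disc_mask(41, 15.0, center=20.0)
        c = largest_inscribed_circle(mask)
        assert abs(c.radius - 15.0) <= 1.0
        assert abs(c.row - 20) <= 1 and abs(c.col - 20) <= 1

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidInputError):
            largest_inscribed_circle(np.zeros((4, 4), dtype=int))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle_on_random_blobs(self, seed):
        mask = random_blob_mask(44, seed)
        got = largest_inscribed_circle(mask)
        exp = brute_force_inscribed_circle(mask)
        assert (got.row, got.col) == (exp.row, exp.col)
        assert got.radius == pytest.approx(exp.radius, abs=1e-9)


class TestDecomposition:
    def test_pure_disc_has_no_meaningful_shmoo(self):
        mask = disc_mask(61, 20.0)
        body, shmoo = decompose_body_shmoo(mask)
        assert shmoo is None or shmoo.radius <= 1.0

    def test_shmoo_lands_in_the_protrusion(self):
        mask, rec = make_shmoo_mask(ShmooGroundTruth(18.0, 18.0, 7.0, angle=0.0))
        body, shmoo = decompose_body_shmoo(mask)
        assert shmoo is not None
        c = rec.truth["center_col"]
        assert shmoo.col > c + body.radius - 1  # protrusion points along +col
        # body and shmoo circles never overlap by construction
        gap = np.hypot(shmoo.row - body.row, shmoo.col - body.col)
        assert gap > body.radius

    def test_two_lobes_larger_one_wins(self):
        mask, _ = make_shmoo_mask(ShmooGroundTruth(15.0, 18.0, 9.0, angle=0.0, grid_size=96))
        small, _ = make_shmoo_mask(ShmooGroundTruth(15.0, 8.0, 5.0, angle=np.pi, grid_size=96))
        both = mask | small
        body, shmoo = decompose_body_shmoo(both)
        assert shmoo.col > body.col  # sits in the larger (rightward) lobe


class TestLengthAndWidth:
    def test_protrusion_length_recovered(self):
        mask, _ = make_shmoo_mask(ShmooGroundTruth(20.0, 15.0, 7.0, angle=0.0))
        body, shmoo = decompose_body_shmoo(mask)
        length, degenerate = shmoo_length(mask, body, shmoo)
        assert not degenerate
        assert length == pytest.approx(15.0, abs=2.0)

    def test_width_recovered(self):
        mask, _ = make_shmoo_mask(ShmooGroundTruth(20.0, 18.0, 7.0, angle=1.1))
        m = analyze_mask(mask)
        assert m.width == pytest.approx(7.0, abs=2.0)

    def test_degenerate_axis_flagged(self):
        mask = disc_mask(31, 10.0)
        body = largest_inscribed_circle(mask)
        length, degenerate = shmoo_length(mask, body, Circle(body.row, body.col, 1.0))
        assert degenerate and length == 0.0

    def test_scaling_the_mask_scales_the_length(self):
        small, _ = make_shmoo_mask(ShmooGroundTruth(16.0, 16.0, 6.0, angle=0.4, grid_size=80))
        big, _ = make_shmoo_mask(ShmooGroundTruth(32.0, 32.0, 12.0, angle=0.4, grid_size=160))
        l_small = analyze_mask(small).length
        l_big = analyze_mask(big).length
        assert l_big == pytest.approx(2.0 * l_small, rel=0.05)

    def test_rotation_by_quarter_turn_changes_little(self):
        a, _ = make_shmoo_mask(ShmooGroundTruth(16.0, 14.0, 7.0, angle=0.0, grid_size=80))
        b, _ = make_shmoo_mask(ShmooGroundTruth(16.0, 14.0, 7.0, angle=np.pi / 2, grid_size=80))
        ma, mb = analyze_mask(a), analyze_mask(b)
        assert abs(ma.length - mb.length) < 1.0
        assert abs(ma.width - mb.width) < 1.0


class TestCircularFraction:
    def test_disc_is_nearly_all_inside(self):
        mask = disc_mask(61, 20.0)
        body = largest_inscribed_circle(mask)
        assert circular_fraction(mask, body) >= 0.95

    def test_area_ratio_for_disc_plus_protrusion(self):
        gt = ShmooGroundTruth(20.0, 20.0, 7.0, angle=0.0)
        mask, rec = make_shmoo_mask(gt)
        body = largest_inscribed_circle(mask)
        frac = circular_fraction(mask, body)
        disc_area = np.pi * gt.body_radius**2
        assert frac == pytest.approx(disc_area / rec.truth["foreground_area"], abs=0.03)

    def test_monotone_nonincreasing_in_protrusion_length(self):
        fracs = []
        for L in (5.0, 12.0, 20.0, 28.0):
            mask, _ = make_shmoo_mask(ShmooGroundTruth(18.0, L, 7.0, angle=0.8))
            fracs.append(analyze_mask(mask).circular_fraction)
        assert all(b <= a + 1e-9 for a, b in zip(fracs, fracs[1:]))


class TestBatch:
    def _labels(self):
        img = np.zeros((200, 96), dtype=int)
        for k, (gt_r, gt_l) in enumerate([(14.0, 12.0), (12.0, 20.0)], start=1):
            mask, _ = make_shmoo_mask(ShmooGroundTruth(gt_r, gt_l, 6.0, angle=0.3))
            img[k * 96 - 96 : k * 96, :][mask] = k
        img[5, 5] = 3  # debris: below the size filter
        return img

    def test_batch_rows_match_per_mask_calls(self):
        img = self._labels()
        table = analyze_labels(img)
        assert list(table["label"]) == [1, 2]
        for _, row in table.iterrows():
            single = analyze_mask(img == row["label"])
            assert row["length_px"] == pytest.approx(single.length)
            assert row["circular_fraction"] == pytest.approx(single.circular_fraction)

    def test_label_permutation_permutes_rows_only(self):
        img = self._labels()
        permuted = np.where(img == 1, 9, img)
        t1 = analyze_labels(img).set_index("label")
        t2 = analyze_labels(permuted).set_index("label")
        assert t1.loc[1, "length_px"] == pytest.approx(t2.loc[9, "length_px"])
        assert t1.loc[2, "width_px"] == pytest.approx(t2.loc[2, "width_px"])


def test_mask_text_and_png_round_trip(tmp_path):
    mask, _ = make_shmoo_mask(ShmooGroundTruth(10.0, 8.0, 5.0, grid_size=48))
    txt = tmp_path / "mask.txt"
    png = tmp_path / "mask.png"
    write_mask(mask, txt)
    write_mask(mask, png)
    assert np.array_equal(read_mask(txt), mask)
    assert np.array_equal(read_mask(png), mask)
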