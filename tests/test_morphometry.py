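"""Mask-based spike traits against analytic shapes and renderer ground truth."""

import numpy as np
import pytest
from skimage import draw
from scipy.ndimage import rotate

from spikesplit import (
    SpikeMaskPair,
    SyntheticSpikeSpec,
    basic_traits,
    build_trait_table,
    fit_quadrilateral_model,
    render_spike,
)
from spikesplit.io import read_mask_pairs, write_mask_pair


def disk_mask(radius=50, pad=50):
    size = 2 * (radius + pad) + 1
    body = np.zeros((size, size), bool)
    rr, cc = draw.disk((size // 2, size // 2), radius)
    body[rr, cc] = True
    return body


def rect_mask(a=200, b=40, pad=30):
    body = np.zeros((a + 2 * pad, b + 2 * pad), bool)
    body[pad : pad + a, pad : pad + b] = True
    return body


def rhombus_mask(d1=300, d2=80, pad=30):
    h, w = d1 + 2 * pad + 1, d2 + 2 * pad + 1
    y, x = np.mgrid[0:h, 0:w]
    return (np.abs(y - h // 2) / (d1 / 2) + np.abs(x - w // 2) / (d2 / 2)) <= 1


def pair_of(body, awns=None, scale=0.1, spike_id="s", projection=1):
    if awns is None:
        awns = np.zeros_like(body)
    return SpikeMaskPair(body=body, awns=awns, scale=scale, spike_id=spike_id, projection=projection)


class TestBasicTraits:
    def test_circle_analytic(self):
        t = basic_traits(pair_of(disk_mask(50), scale=0.1))
        assert t["SA"] == pytest.approx(np.pi * 5.0**2, rel=0.02)
        assert t["SRO"] == pytest.approx(1.0, rel=0.03)
        assert t["SSO"] == pytest.approx(1.0, rel=0.01)
        assert t["SAA"] == 0.0

    def test_rectangle_roundness(self):
        t = basic_traits(pair_of(rect_mask(200, 40)))
        expected = 4 * np.pi * 200 * 40 / (2 * (200 + 40)) ** 2
        assert t["SRO"] == pytest.approx(expected, rel=0.03)
        assert t["SA"] == pytest.approx(200 * 40 * 0.01, rel=1e-9)
        assert t["SL"] == pytest.approx(20.0, rel=0.02)

    def test_awn_area_is_exact_pixel_count(self):
        body = rect_mask(150, 40)  # mask canvas is 210 x 100 px
        awns = np.zeros_like(body)
        awns[:10, :] = True  # exactly 10 x 100 = 1000 awn pixels
        t = basic_traits(pair_of(body, awns, scale=0.1))
        assert t["SAA"] == pytest.approx(10.0, abs=1e-12)

    def test_empty_awn_mask_is_zero_not_error(self):
        t = basic_traits(pair_of(rect_mask()))
        assert t["SAA"] == 0.0

    def test_empty_body_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pair_of(np.zeros((50, 50), bool))

    def test_mismatched_mask_shapes_rejected(self):
        with pytest.raises(ValueError, match="identical dimensions"):
            SpikeMaskPair(
                body=np.ones((10, 10), bool),
                awns=np.zeros((10, 11), bool),
                scale=0.1,
                spike_id="s",
                projection=1,
            )

    def test_solidity_bounded_and_high_for_convex(self):
        for body in (disk_mask(), rect_mask(), rhombus_mask()):
            t = basic_traits(pair_of(body))
            assert 0 < t["SSO"] <= 1.0


class TestInvariances:
    def test_translation_invariance_bit_identical(self):
        body = rect_mask(150, 40, pad=60)
        awns = np.zeros_like(body)
        awns[10:20, 60:80] = True
        base = basic_traits(pair_of(body, awns))
        for dy, dx in ((13, -7), (-20, 11)):
            shifted = basic_traits(pair_of(np.roll(body, (dy, dx), (0, 1)), np.roll(awns, (dy, dx), (0, 1))))
            assert shifted == base

    def test_scale_covariance_exact(self):
        body = rhombus_mask()
        t1 = basic_traits(pair_of(body, scale=0.1))
        t2 = basic_traits(pair_of(body, scale=0.2))
        q1 = fit_quadrilateral_model(pair_of(body, scale=0.1))
        q2 = fit_quadrilateral_model(pair_of(body, scale=0.2))
        for key in ("SL", "SP"):
            assert t2[key] == pytest.approx(2 * t1[key], rel=1e-12)
        for key in ("SA", "SAA"):
            assert t2[key] == pytest.approx(4 * t1[key], rel=1e-12) or t1[key] == 0
        assert t2["SRO"] == pytest.approx(t1["SRO"], rel=1e-12)
        assert t2["SSO"] == pytest.approx(t1["SSO"], rel=1e-12)
        assert q2.q_L == pytest.approx(2 * q1.q_L, rel=1e-12)
        assert q2.q_ym == pytest.approx(2 * q1.q_ym, rel=1e-12)
        assert q2.q_S == pytest.approx(4 * q1.q_S, rel=1e-12)


class TestQuadrilateralModel:
    def test_exact_for_rhombus(self):
        q = fit_quadrilateral_model(pair_of(rhombus_mask(300, 80), scale=0.1))
        assert q.q_L == pytest.approx(30.0, rel=0.03)
        assert q.q_ym == pytest.approx(4.0, rel=0.03)
        assert q.q_S == pytest.approx(120.0, rel=0.03)

    def test_rotation_invariance(self):
        body = rhombus_mask(300, 80, pad=120)
        rotated = rotate(body.astype(float), 30, reshape=True, order=1) >= 0.5
        q0 = fit_quadrilateral_model(pair_of(body))
        q30 = fit_quadrilateral_model(pair_of(rotated))
        assert q30.q_L == pytest.approx(q0.q_L, rel=0.03)
        assert q30.q_ym == pytest.approx(q0.q_ym, rel=0.03)
        assert q30.q_S == pytest.approx(q0.q_S, rel=0.03)

    def test_non_elongated_blob_rejected(self):
        with pytest.raises(ValueError, match="elongated"):
            fit_quadrilateral_model(pair_of(disk_mask(50)))

    def test_renderer_axis_recovered(self):
        spec = SyntheticSpikeSpec(body_major_mm=30.0, body_minor_mm=8.0, awn_count=0, seed=4)
        pair, truth = render_spike(spec)
        q = fit_quadrilateral_model(pair)
        assert q.q_L == pytest.approx(truth["body_major_mm"], rel=0.03)


class TestTraitTable:
    def _pairs(self, n_spikes=2):
        pairs = []
        for i in range(n_spikes):
            for proj in (1, 2, 3, 4):
                spec = SyntheticSpikeSpec(awn_count=6, seed=i * 10 + proj)
                pair, _ = render_spike(spec, spike_id=f"spike_{i}", projection=proj)
                pairs.append(pair)
        return pairs

    def test_two_spikes_four_projections(self):
        table = build_trait_table(self._pairs(2))
        assert len(table) == 8
        assert list(table.columns) == ["SL", "SP", "SA", "SAA", "SRO", "SSO", "q_L", "q_ym", "q_S"]
        assert table.attrs["failures"] == []

    def test_empty_input(self):
        table = build_trait_table([])
        assert len(table) == 0

    def test_corrupt_mask_recorded_without_aborting(self, caplog):
        pairs = self._pairs(2)
        pairs[3] = pair_of(disk_mask(30), spike_id="blob", projection=1)  # not elongated
        table = build_trait_table(pairs)
        assert len(table) == 7
        assert len(table.attrs["failures"]) == 1
        assert table.attrs["failures"][0][0] == "blob"

    def test_duplicate_key_raises(self):
        pairs = self._pairs(1)
        with pytest.raises(ValueError, match="duplicate"):
            build_trait_table(pairs + pairs[:1])


class TestMaskIO:
    def test_png_roundtrip(self, tmp_path):
        spec = SyntheticSpikeSpec(awn_count=10, seed=2)
        pair, _ = render_spike(spec, spike_id="io_spike", projection=3)
        write_mask_pair(pair, tmp_path)
        (loaded,) = list(read_mask_pairs(tmp_path, scale=spec.scale))
        assert loaded.spike_id == "io_spike"
        assert loaded.projection == 3
        assert np.array_equal(loaded.body, pair.body)
        assert np.array_equal(loaded.awns, pair.awns)

    def test_missing_awn_mask_raises(self, tmp_path):
        spec = SyntheticSpikeSpec(seed=2)
        pair, _ = render_spike(spec, spike_id="x", projection=1)
        body_path, awn_path = write_mask_pair(pair, tmp_path)
        awn_path.unlink()
        with pytest.raises(FileNotFoundError, match="awn"):
            list(read_mask_pairs(tmp_path, scale=0.1))
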