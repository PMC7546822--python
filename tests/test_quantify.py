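"""Quantification model: segmentation, M0b calibration, CBF formula."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoperf import (
    QuantParams,
    compute_cbf,
    compute_m0b,
    delta_m_from_cbf,
    segment_tissues,
)
from neoperf.quantify import TISSUE_CODES, TissueSegmentation


def scalar_cbf(dm, m0b, p: QuantParams) -> float:
    """Straight-line scalar evaluation of the kinetic model (oracle)."""
    return (
        6000.0 * p.lambda_blood * dm * math.exp(p.ti_ms / p.t1b_ms)
        / (2.0 * p.alpha * p.ti1_ms * m0b)
    )


def scalar_m0b(r, m0, t2, p: QuantParams) -> float:
    return r * m0 * math.exp(p.te_ms / t2 - p.te_ms / p.t2b_ms)


class TestSegmentTissues:
    def _seg(self, intensities, mask=None, params=None):
        t2 = np.asarray(intensities, dtype=float).reshape(-1, 1, 1)
        mask = np.ones_like(t2, bool) if mask is None else mask
        return segment_tissues(t2, mask, params)

    def test_canonical_class_assignment(self):
        # enough CSF voxels that the 99th-percentile robust max is the CSF level
        values = [1.0] * 5 + [0.8, 0.5]
        seg = self._seg(values)
        flat = seg.class_volume.ravel()
        assert all(c == TISSUE_CODES["CSF"] for c in flat[:5])
        assert flat[5] == TISSUE_CODES["WM"]
        assert flat[6] == TISSUE_CODES["GM"]

    def test_wm_lower_bound_closed(self):
        seg = self._seg([1.0] * 5 + [0.75])
        assert seg.class_volume.ravel()[5] == TISSUE_CODES["WM"]

    def test_empty_mask_rejected(self):
        t2 = np.ones((3, 3, 3))
        with pytest.raises(ValueError, match="empty"):
            segment_tissues(t2, np.zeros((3, 3, 3), bool))

    def test_constant_t2_warns_single_class(self):
        t2 = np.full((3, 3, 3), 5.0)
        with pytest.warns(RuntimeWarning, match="constant"):
            seg = segment_tissues(t2, np.ones((3, 3, 3), bool))
        assert len(np.unique(seg.class_volume)) == 1

    def test_background_outside_mask(self):
        t2 = np.ones((2, 2, 2))
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        seg = segment_tissues(t2, mask)
        assert (seg.class_volume == 0).sum() == 7


class TestComputeM0b:
    def _uniform_seg(self, shape, tissue):
        classes = np.full(shape, TISSUE_CODES[tissue], dtype=np.int8)
        return TissueSegmentation(classes)

    def test_csf_hand_calculation(self):
        # 0.87 * 1000 * exp(14/250 - 14/191), frozen from a scalar evaluation
        m0 = np.full((2, 2, 2), 1000.0)
        result = compute_m0b(m0, self._uniform_seg((2, 2, 2), "CSF"))
        assert result.per_tissue["CSF"] == pytest.approx(855.07978667, rel=1e-9)

    def test_te_zero_reduces_to_ratio(self):
        params = QuantParams(te_ms=0.0)
        m0 = np.full((2, 2, 2), 500.0)
        result = compute_m0b(m0, self._uniform_seg((2, 2, 2), "WM"), params)
        assert result.per_tissue["WM"] == pytest.approx(1.19 * 500.0)

    def test_unit_ratio_matched_t2_is_identity(self):
        params = QuantParams(
            ratios={"CSF": 1.0, "WM": 1.0, "GM": 1.0},
            t2_tissue_ms={"CSF": 191.0, "WM": 191.0, "GM": 191.0},
        )
        m0 = np.full((2, 2, 2), 321.0)
        result = compute_m0b(m0, self._uniform_seg((2, 2, 2), "GM"), params)
        assert result.per_tissue["GM"] == pytest.approx(321.0)

    def test_empty_class_falls_back_to_brain_mean(self):
        classes = np.full((2, 2, 2), TISSUE_CODES["GM"], dtype=np.int8)
        m0 = np.full((2, 2, 2), 100.0)
        with pytest.warns(RuntimeWarning, match="CSF"):
            result = compute_m0b(m0, TissueSegmentation(classes))
        assert result.m0_means["CSF"] == pytest.approx(100.0)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_oracle_equivalence_random_inputs(self, rng):
        params = QuantParams()
        for tissue in ("CSF", "WM", "GM"):
            for _ in range(50):
                m0_val = rng.uniform(100, 2000)
                m0 = np.full((2, 2, 2), m0_val)
                got = compute_m0b(m0, self._uniform_seg((2, 2, 2), tissue), params)
                want = scalar_m0b(
                    params.ratios[tissue], m0_val, params.t2_tissue_ms[tissue], params
                )
                assert abs(got.per_tissue[tissue] - want) <= 1e-10 * abs(want)


class TestComputeCBF:
    def test_zero_dm_gives_zero(self):
        dm = np.zeros((3, 3, 3))
        m0b = np.full((3, 3, 3), 500.0)
        cbf = compute_cbf(dm, m0b)
        np.testing.assert_allclose(cbf.volume, 0.0)

    def test_hand_calculation(self):
        # dM=1, M0b=200 with defaults: 6600*exp(1800/1825)/274400
        dm = np.ones((1, 1, 1))
        m0b = np.full((1, 1, 1), 200.0)
        cbf = compute_cbf(dm, m0b)
        assert cbf.volume[0, 0, 0] == pytest.approx(0.0644918850, rel=1e-8)

    def test_linear_in_dm(self, rng):
        dm = rng.normal(size=(4, 4, 3))
        m0b = np.full((4, 4, 3), 800.0)
        one = compute_cbf(dm, m0b).volume
        two = compute_cbf(2 * dm, m0b).volume
        np.testing.assert_allclose(two, 2 * one)

    def test_monotone_in_ti(self):
        dm = np.ones((2, 2, 2))
        m0b = np.full((2, 2, 2), 500.0)
        low = compute_cbf(dm, m0b, QuantParams(ti_ms=1500.0)).volume
        high = compute_cbf(dm, m0b, QuantParams(ti_ms=2000.0)).volume
        assert np.all(high > low)

    def test_near_zero_m0b_marked_undefined(self):
        dm = np.ones((2, 2, 2))
        m0b = np.full((2, 2, 2), 500.0)
        m0b[0, 0, 0] = 1e-12
        cbf = compute_cbf(dm, m0b, mask=np.ones((2, 2, 2), bool))
        assert np.isnan(cbf.volume[0, 0, 0])
        assert cbf.n_undefined == 1

    def test_inverse_round_trip(self, rng):
        params = QuantParams()
        cbf_true = rng.uniform(1, 60, size=(4, 4, 3))
        m0b = rng.uniform(400, 1200, size=(4, 4, 3))
        dm = delta_m_from_cbf(cbf_true, m0b, params)
        got = compute_cbf(dm, m0b, params).volume
        np.testing.assert_allclose(got, cbf_true, rtol=1e-12)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 100.0))
    def test_scale_equivariance(self, scale):
        """Scaling dM and the M0 image together leaves CBF unchanged."""
        rng = np.random.default_rng(0)
        dm = rng.uniform(0.5, 2.0, size=(3, 3, 2))
        m0 = rng.uniform(500, 1500, size=(3, 3, 2))
        classes = np.full((3, 3, 2), TISSUE_CODES["GM"], dtype=np.int8)
        seg = TissueSegmentation(classes)
        base = compute_cbf(dm, compute_m0b(m0, seg)).volume
        scaled = compute_cbf(scale * dm, compute_m0b(scale * m0, seg)).volume
        np.testing.assert_allclose(scaled, base, rtol=1e-10)


class TestQuantParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"alpha": 1.5},
            {"t1b_ms": -1.0},
            {"csf_threshold": 0.7, "wm_threshold": 0.75},
            {"t2_tissue_ms": {"CSF": 250.0, "WM": 222.0}},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            QuantParams(**kwargs)
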