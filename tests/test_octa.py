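"""Speckle-variance OCT-A, depth-gated density, reductions, paired test."""

import numpy as np
import pytest
from scipy import stats

from putkit.octa import (
    InputError,
    OctaImage,
    OctScanSeries,
    paired_compare,
    percent_reduction,
    speckle_variance,
    vessel_density,
)
from putkit.pa_source import ParameterError
from putkit.synthetic_data import OctGenConfig, gen_oct_series


def _series(volumes, **kw):
    return OctScanSeries(volumes=np.asarray(volumes, dtype=float), **kw)


class TestSpeckleVariance:
    def test_identical_repeats_give_zero(self):
        v = np.tile(np.random.default_rng(0).random((4, 1, 16, 8)), (1, 3, 1, 1))
        octa = speckle_variance(_series(v))
        assert np.max(octa.variance) < 1e-24  # zero up to float rounding

    def test_hand_computed_population_variance(self):
        """Repeats {1, 3, 5} at a pixel → population variance 8/3."""
        v = np.zeros((1, 3, 2, 2))
        v[0, :, 0, 0] = [1.0, 3.0, 5.0]
        octa = speckle_variance(_series(v))
        assert octa.variance[0, 0, 0] == pytest.approx(8.0 / 3.0)

    def test_invariant_to_common_offset(self):
        rng = np.random.default_rng(1)
        v = rng.random((2, 3, 8, 8))
        shifted = v + 17.5  # same offset applied to every repeat
        assert np.allclose(
            speckle_variance(_series(v)).variance,
            speckle_variance(_series(shifted)).variance,
        )

    def test_flow_pixels_dominate_static(self):
        """Decorrelated vessel pixels carry ≥5× the OCT-A value of tissue."""
        untreated, _, truth = gen_oct_series(OctGenConfig(seed=4))
        var = speckle_variance(untreated).variance
        vessel = truth["vessel_mask"]
        assert var[vessel].mean() >= 5.0 * var[~vessel].mean()

    def test_single_repeat_rejected(self):
        with pytest.raises(InputError):
            _series(np.zeros((2, 1, 4, 4)))


class TestVesselDensity:
    def _octa(self, variance):
        return OctaImage(variance=variance, axial_pitch_um=3.0, n_repeats=3)

    def test_zero_octa_gives_zero_density(self):
        assert vessel_density(self._octa(np.zeros((4, 128, 8)))) == 0.0

    def test_linear_in_signal(self):
        rng = np.random.default_rng(2)
        v = rng.random((4, 128, 8))
        d1 = vessel_density(self._octa(v))
        d2 = vessel_density(self._octa(2.0 * v))
        assert d2 == pytest.approx(2.0 * d1)

    def test_invariant_to_lateral_permutation(self):
        rng = np.random.default_rng(3)
        v = rng.random((4, 128, 16))
        perm = v[:, :, rng.permutation(16)]
        assert vessel_density(self._octa(perm)) == pytest.approx(
            vessel_density(self._octa(v))
        )

    def test_monotone_in_vessel_fraction(self):
        """Generator sweep: density grows with programmed areal fraction."""
        densities = [
            vessel_density(
                speckle_variance(gen_oct_series(OctGenConfig(vessel_fraction=f, seed=6))[0])
            )
            for f in (0.05, 0.10, 0.20)
        ]
        assert densities[0] < densities[1] < densities[2]

    def test_bad_gate_rejected(self):
        with pytest.raises(ParameterError):
            vessel_density(self._octa(np.ones((2, 128, 4))), (500.0, 600.0))
        with pytest.raises(ParameterError):
            vessel_density(self._octa(np.ones((2, 128, 4))), (300.0, 150.0))


class TestPercentReduction:
    def test_trivial_cases(self):
        assert percent_reduction(5.0, 5.0) == 0.0
        assert percent_reduction(0.0, 5.0) == 100.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ParameterError):
            percent_reduction(1.0, 0.0)


class TestPairedCompare:
    def test_identical_groups(self):
        res = paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_zero_variance_differences_reported_degenerate(self):
        res = paired_compare([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert res.degenerate
        assert np.isnan(res.t_statistic)

    def test_three_pair_textbook_example(self):
        """d = {1, 2, 2}: t = d̄/(s_d/√3) = 5.0; cross-checked against scipy."""
        a, b = [1.0, 2.0, 3.0], [0.0, 0.0, 1.0]
        res = paired_compare(a, b)
        assert res.t_statistic == pytest.approx(5.0, rel=1e-9)
        ref = stats.ttest_rel(a, b)
        assert res.t_statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_too_small_sample_rejected(self):
        with pytest.raises(InputError):
            paired_compare([1.0], [2.0])


def test_end_to_end_reduction_recovery_single_pair():
    """A programmed 45.2 % density reduction is recovered by the pipeline."""
    untreated, treated, truth = gen_oct_series(
        OctGenConfig(seed=0, treated_fraction_retained=0.548)
    )
    est = percent_reduction(
        vessel_density(speckle_variance(treated)),
        vessel_density(speckle_variance(untreated)),
    )
    assert est == pytest.approx(truth["programmed_reduction_pct"], abs=3.0)
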