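"""Active cavitation detection: baseline statistics, 3σ rule, CP counting."""

import dataclasses

import numpy as np
import pytest

from putkit.cavitation_detect import (
    BaselineModel,
    FrameStack,
    InputError,
    auto_tube_mask,
    cavitation_probability,
    cp_map,
    detect_frame,
    fit_baseline,
    flagged_frames,
)
from putkit.pa_source import ParameterError
from putkit.synthetic_data import BmodeGenConfig, gen_bmode_stack


def _stack(frames, **kw):
    return FrameStack(frames=np.asarray(frames, dtype=float), **kw)


class TestFitBaseline:
    def test_constant_stack_has_zero_sd(self):
        baseline = fit_baseline(_stack(np.full((10, 8, 8), 7.0)))
        assert np.all(baseline.sd == 0.0)
        assert np.all(baseline.mean == 7.0)

    def test_gaussian_moments_recovered(self):
        """µ=50, σ=5 over 200 frames: recovered within 3 standard errors."""
        rng = np.random.default_rng(42)
        n, mu, sd = 200, 50.0, 5.0
        baseline = fit_baseline(_stack(rng.normal(mu, sd, size=(n, 32, 32))))
        se_mean = sd / np.sqrt(n)
        se_sd = sd / np.sqrt(2 * n)
        frac_mean = np.mean(np.abs(baseline.mean - mu) <= 3 * se_mean)
        frac_sd = np.mean(np.abs(baseline.sd - sd) <= 3 * se_sd)
        assert frac_mean > 0.985 and frac_sd > 0.985
        assert baseline.mean.mean() == pytest.approx(mu, abs=3 * se_mean / 32)
        assert baseline.sd.mean() == pytest.approx(sd, rel=0.02)

    def test_single_frame_rejected(self):
        with pytest.raises(InputError):
            fit_baseline(_stack(np.zeros((1, 8, 8))))

    def test_global_baseline_switch(self):
        rng = np.random.default_rng(0)
        baseline = fit_baseline(_stack(rng.normal(50, 5, (50, 16, 16))), global_baseline=True)
        assert np.unique(baseline.mean).size == 1
        assert np.unique(baseline.sd).size == 1


class TestDetectFrame:
    mean = np.full((8, 8), 10.0)
    sd = np.ones((8, 8))

    def _baseline(self, mask=None):
        mask = np.zeros((8, 8), bool) if mask is None else mask
        return BaselineModel(mean=self.mean, sd=self.sd, mask=mask, k=3.0)

    def test_baseline_level_frame_not_flagged(self):
        out = detect_frame(self.mean.copy(), self._baseline())
        assert not out["flagged"] and out["n_suprathreshold_pixels"] == 0

    def test_single_suprathreshold_pixel_flagged(self):
        frame = self.mean.copy()
        frame[3, 4] = 10.0 + 3.5  # 3.5 σ above baseline
        out = detect_frame(frame, self._baseline())
        assert out["flagged"] and out["n_suprathreshold_pixels"] == 1

    def test_masked_pixel_ignored(self):
        mask = np.zeros((8, 8), bool)
        mask[3, 4] = True
        frame = self.mean.copy()
        frame[3, 4] = 100.0
        assert not detect_frame(frame, self._baseline(mask))["flagged"]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            detect_frame(np.zeros((4, 4)), self._baseline())


class TestCavitationProbability:
    def test_exact_counting(self):
        """30 of 100 frames carry an injected bright event → CP = 0.30."""
        frames = np.full((100, 16, 16), 10.0)
        frames[:30, 8, 8] = 100.0
        baseline = BaselineModel(
            mean=np.full((16, 16), 10.0), sd=np.ones((16, 16)), mask=np.zeros((16, 16), bool)
        )
        assert cavitation_probability(_stack(frames), baseline) == 0.30

    def test_invariant_under_frame_permutation(self):
        cfg = BmodeGenConfig(p_event=0.4, seed=7)
        stack, _ = gen_bmode_stack(cfg)
        base, _ = gen_bmode_stack(dataclasses.replace(cfg, p_event=0.0, seed=8, pattern_seed=7))
        baseline = fit_baseline(base, auto_mask=True)
        cp = cavitation_probability(stack, baseline)
        rng = np.random.default_rng(0)
        shuffled = _stack(stack.frames[rng.permutation(stack.n_frames)])
        assert cavitation_probability(shuffled, baseline) == cp

    def test_raising_k_never_increases_cp(self):
        cfg = BmodeGenConfig(p_event=0.5, event_contrast_sd=3.5, seed=11)
        stack, _ = gen_bmode_stack(cfg)
        base, _ = gen_bmode_stack(dataclasses.replace(cfg, p_event=0.0, seed=12, pattern_seed=11))
        cps = [
            cavitation_probability(stack, fit_baseline(base, k=k, auto_mask=True))
            for k in (1.0, 2.0, 3.0, 5.0)
        ]
        assert all(a >= b for a, b in zip(cps, cps[1:]))

    def test_frame_level_sensitivity_and_specificity(self):
        """≥0.95 sensitivity/specificity at the default 6σ event contrast."""
        tp = fp = fn = tn = 0
        for seed in range(10):
            cfg = BmodeGenConfig(p_event=0.5, seed=seed, pattern_seed=99)
            stack, truth = gen_bmode_stack(cfg)
            base, _ = gen_bmode_stack(
                dataclasses.replace(cfg, p_event=0.0, seed=1000 + seed)
            )
            baseline = fit_baseline(base, auto_mask=True)
            flags = np.zeros(stack.n_frames, bool)
            flags[flagged_frames(stack, baseline)] = True
            ev = truth["event_frames"]
            tp += int((flags & ev).sum())
            fn += int((~flags & ev).sum())
            fp += int((flags & ~ev).sum())
            tn += int((~flags & ~ev).sum())
        assert tp / (tp + fn) >= 0.95
        assert tn / (tn + fp) >= 0.95


class TestCpMap:
    def _series(self):
        stacks = []
        cfg0 = BmodeGenConfig(p_event=0.0, seed=100, pattern_seed=5)
        base, _ = gen_bmode_stack(cfg0)
        base = dataclasses.replace(base, pressure_MPa=0.8, fluence_mJ_cm2=0.0, role="baseline")
        stacks.append(base)
        for i, (p_ev, fluence) in enumerate([(0.0, 50.0), (0.5, 100.0), (1.0, 200.0)]):
            s, _ = gen_bmode_stack(
                BmodeGenConfig(p_event=p_ev, seed=200 + i, pattern_seed=5)
            )
            stacks.append(
                dataclasses.replace(s, pressure_MPa=0.8, fluence_mJ_cm2=fluence, role="test")
            )
        return stacks

    def test_cells_equal_per_stack_cp(self):
        stacks = self._series()
        baseline = fit_baseline(stacks[0], auto_mask=True)
        table = cp_map(stacks, baseline).table
        for _, row in table.iterrows():
            stack = next(s for s in stacks if s.fluence_mJ_cm2 == row.fluence_mJcm2 and s.role == "test")
            assert row.cp == cavitation_probability(stack, baseline)

    def test_no_events_gives_zero_cp(self):
        stacks = self._series()
        table = cp_map(stacks).table  # baselines fitted from baseline-role stacks
        assert table.loc[table.fluence_mJcm2 == 50.0, "cp"].iloc[0] == 0.0

    def test_missing_baseline_is_configuration_error(self):
        stacks = [s for s in self._series() if s.role != "baseline"]
        with pytest.raises(ParameterError):
            cp_map(stacks, None)


def test_auto_mask_covers_tube_walls():
    stack, truth = gen_bmode_stack(BmodeGenConfig(p_event=0.0, seed=3))
    mask = auto_tube_mask(stack)
    assert mask[truth["wall_mask"]].mean() > 0.99  # walls masked
    assert mask.mean() < 0.25  # but not the whole frame
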