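"""Contracts of the four augmentation operators and the x9 expansion."""

import numpy as np
import pytest

from gaitrank.augment import (
    SCENARIO_C_COMBOS,
    AugmentationSpec,
    expand_scenario_c,
    jitter,
    mixup,
    time_shift,
    window_crop,
)
from gaitrank.grf import VERTICAL_CHANNELS, pad_to_uniform, stance_intervals

from .conftest import make_cycle

OPERATORS = {
    "jitter": jitter,
    "time_shift": time_shift,
    "window_crop": window_crop,
}


def test_spec_validation():
    with pytest.raises(ValueError):
        AugmentationSpec(a_vertical=0.02)  # must be half of a_other
    with pytest.raises(ValueError):
        AugmentationSpec(max_crop_frac=0.05)
    with pytest.raises(ValueError):
        AugmentationSpec(gamma_low=0.95, gamma_high=0.85)


@pytest.mark.parametrize("name", list(OPERATORS))
def test_operator_preserves_shape_and_metadata(name, simple_cycle):
    out = OPERATORS[name](simple_cycle, seed=3)
    assert out.signal.shape == simple_cycle.signal.shape
    assert out.subject_id == simple_cycle.subject_id
    assert out.condition == simple_cycle.condition


@pytest.mark.parametrize("name", list(OPERATORS))
def test_operator_deterministic_given_seed(name, simple_cycle):
    a = OPERATORS[name](simple_cycle, seed=11)
    b = OPERATORS[name](simple_cycle, seed=11)
    assert np.array_equal(a.signal, b.signal)


@pytest.mark.parametrize("name", ["jitter", "window_crop"])
def test_operator_touches_stance_only(name, simple_cycle):
    """Samples outside the detected stance window stay bit-identical, so a
    zero swing phase stays exactly zero."""
    out = OPERATORS[name](simple_cycle, seed=5)
    left, right = stance_intervals(simple_cycle)
    assert np.array_equal(out.signal[0:3, : left.start], simple_cycle.signal[0:3, : left.start])
    assert np.array_equal(out.signal[0:3, left.end :], simple_cycle.signal[0:3, left.end :])
    assert np.array_equal(out.signal[3:6, : right.start], simple_cycle.signal[3:6, : right.start])
    assert np.array_equal(out.signal[3:6, right.end :], simple_cycle.signal[3:6, right.end :])
    # and a genuinely silent swing remains exactly zero
    assert np.all(out.signal[:, :30] == 0.0)
    assert np.all(out.signal[:, 700:] == 0.0)


# ------------------------------------------------------------------
# jitter
# ------------------------------------------------------------------

def test_jitter_zero_channel_unchanged(simple_cycle):
    sig = simple_cycle.signal.copy()
    sig[2] = 0.0  # silence L_ML entirely
    cyc = simple_cycle.copy_with(sig)
    out = jitter(cyc, seed=1)
    assert np.all(out.signal[2] == 0.0)


def test_jitter_rms_ratio_contract(simple_cycle):
    """Perturbation RMS / signal RMS stays within a +/- 25% per channel over
    100 seeds (unit-RMS normalisation of the filtered noise)."""
    left, right = stance_intervals(simple_cycle)
    spans = {0: left, 1: left, 2: left, 3: right, 4: right, 5: right}
    ratios = {ch: [] for ch in range(6)}
    for seed in range(100):
        out = jitter(simple_cycle, seed=seed)
        for ch, si in spans.items():
            x = simple_cycle.signal[ch, si.start : si.end]
            d = out.signal[ch, si.start : si.end] - x
            ratios[ch].append(np.sqrt(np.mean(d**2)) / np.sqrt(np.mean(x**2)))
    for ch, vals in ratios.items():
        a = 0.01 if ch in VERTICAL_CHANNELS else 0.02
        assert np.all((np.array(vals) > 0.75 * a) & (np.array(vals) < 1.25 * a))


def test_jitter_keeps_vertical_nonnegative(simple_cycle):
    for seed in range(20):
        out = jitter(simple_cycle, seed=seed)
        assert np.all(out.signal[1] >= 0.0)
        assert np.all(out.signal[4] >= 0.0)


# ------------------------------------------------------------------
# time shift
# ------------------------------------------------------------------

class _FixedShift:
    """Stub generator that returns scripted leg shifts."""

    def __init__(self, shifts):
        self.shifts = list(shifts)

    def integers(self, lo, hi):
        return self.shifts.pop(0)


def test_time_shift_zero_is_identity(simple_cycle):
    out = time_shift(simple_cycle, seed=_FixedShift([0, 0]))
    assert np.array_equal(out.signal, simple_cycle.signal)


def test_time_shift_moves_one_leg_only(simple_cycle):
    out = time_shift(simple_cycle, seed=_FixedShift([3, 0]))
    n = simple_cycle.n_samples
    assert np.array_equal(out.signal[1, 3:], simple_cycle.signal[1, : n - 3])
    assert np.all(out.signal[0:3, :3] == 0.0)
    assert np.array_equal(out.signal[3:6], simple_cycle.signal[3:6])


def test_time_shift_range_and_units():
    """The +/-15 sample range at 960 Hz spans +/-15.625 ms."""
    spec = AugmentationSpec()
    assert spec.max_shift_samples / 960.0 == pytest.approx(0.015625)
    cyc = make_cycle()
    for seed in range(30):
        out = time_shift(cyc, seed=seed)
        # the leg moved as a unit: some shift k with |k| <= 15 must explain
        # the vertical channel exactly
        found = False
        n = cyc.n_samples
        for k in range(-15, 16):
            ref = np.zeros(n)
            if k > 0:
                ref[k:] = cyc.signal[1, : n - k]
            elif k < 0:
                ref[:k] = cyc.signal[1, -k:]
            else:
                ref = cyc.signal[1]
            if np.array_equal(out.signal[1], ref):
                found = True
                break
        assert found


def test_time_shift_rejects_too_short_cycle():
    tiny = make_cycle(n=20, stance=(2, 18))
    with pytest.raises(ValueError):
        time_shift(tiny, seed=0)


# ------------------------------------------------------------------
# window crop
# ------------------------------------------------------------------

def test_window_crop_right_leg_untouched(simple_cycle):
    out = window_crop(simple_cycle, seed=4)
    assert np.array_equal(out.signal[3:6], simple_cycle.signal[3:6])
    assert out.n_samples == simple_cycle.n_samples


def test_window_crop_peak_preserved(simple_cycle):
    """Linear resampling after a <=3% crop moves the peak by <2%."""
    peak = simple_cycle.signal[1].max()
    for seed in range(100):
        out = window_crop(simple_cycle, seed=seed)
        assert abs(out.signal[1].max() - peak) <= 0.02 * peak


def test_window_crop_stance_too_short():
    tiny = make_cycle(n=100, stance=(10, 40))  # 30-sample stance, 3% < 1
    with pytest.raises(ValueError):
        window_crop(tiny, seed=0)


# ------------------------------------------------------------------
# mixup
# ------------------------------------------------------------------

def test_mixup_identical_inputs_fixed_point(simple_cycle):
    out = mixup(simple_cycle, simple_cycle, seed=8)
    assert np.allclose(out.signal, simple_cycle.signal)


def test_mixup_convex_combination_elementwise():
    c1 = make_cycle(seed=0)
    c2 = make_cycle(seed=3, trial=1)

    class _FixedGamma:
        def uniform(self, lo, hi):
            return 0.9

    out = mixup(c1, c2, seed=_FixedGamma())
    assert np.allclose(out.signal, 0.9 * c1.signal + 0.1 * c2.signal)
    lo = np.minimum(c1.signal, c2.signal)
    hi = np.maximum(c1.signal, c2.signal)
    assert np.all(out.signal >= lo - 1e-12) and np.all(out.signal <= hi + 1e-12)


def test_mixup_rejects_cross_class_and_length_mismatch(simple_cycle):
    other = make_cycle(subject="S2")
    with pytest.raises(ValueError):
        mixup(simple_cycle, other, seed=0)
    longer = make_cycle(n=900)
    with pytest.raises(ValueError):
        mixup(simple_cycle, longer, seed=0)


# ------------------------------------------------------------------
# scenario-C expansion
# ------------------------------------------------------------------

def _training_set(n_subjects=2, n_trials=3):
    cycles = [
        make_cycle(subject=f"S{s}", trial=t, seed=10 * s + t)
        for s in range(n_subjects)
        for t in range(n_trials)
    ]
    return pad_to_uniform(cycles)


def test_expansion_is_nine_fold():
    ds = _training_set()
    out = expand_scenario_c(ds, seed=1)
    assert len(out) == 9 * len(ds)
    assert len(SCENARIO_C_COMBOS) == 8


def test_expansion_single_cycle():
    ds = _training_set(n_subjects=1, n_trials=1)
    with pytest.warns(UserWarning, match="single cycle"):
        out = expand_scenario_c(ds, seed=1)
    assert len(out) == 9


def test_expansion_keeps_originals_and_labels():
    ds = _training_set()
    out = expand_scenario_c(ds, seed=2)
    for orig, copy in zip(ds.cycles, out.cycles[: len(ds)]):
        assert np.array_equal(orig.signal, copy.signal)
    # augmentation never changes the identity label
    per_subject = {}
    for c in out.cycles:
        per_subject[c.subject_id] = per_subject.get(c.subject_id, 0) + 1
    assert all(v == 9 * 3 for v in per_subject.values())


def test_expansion_deterministic():
    ds = _training_set()
    a = expand_scenario_c(ds, seed=5)
    b = expand_scenario_c(ds, seed=5)
    for x, y in zip(a.cycles, b.cycles):
        assert np.array_equal(x.signal, y.signal)
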