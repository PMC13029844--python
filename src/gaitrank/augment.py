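"""Time-series augmentation operators for GRF gait cycles.

Four operators expand a training set while leaving identity labels intact:

* **jitter** — band-limited noise injection.  White noise is low-pass
  filtered (4th-order Butterworth, 30 Hz cutoff), rescaled to unit RMS over
  the stance window, and added as ``x'[n] = x[n] + a * RMS(x) * s[n]`` with
  ``a = 0.01`` on the vertical channels and ``0.02`` on the others.  Only
  stance samples are perturbed; the swing phase stays exactly zero.
* **time_shift** — each leg's three channels move together by an integer
  shift drawn uniformly from ±15 samples (±15.625 ms at 960 Hz),
  independently per leg, with zero fill at the vacated edge.
* **window_crop** — up to 3% of the left-leg stance window is removed (the
  cut split randomly between the two stance ends) and the shortened segment
  is linearly resampled back to the original stance length.  The right leg
  is untouched.
* **mixup** — a convex combination ``gamma*x1 + (1-gamma)*x2`` of two cycles
  of the *same* subject, gamma ~ U(0.85, 0.95), so the result stays strongly
  dominated by one gait instance.

The noise scale factor is applied to the stance-window RMS of each channel
(not the zero-padded full vector), and the filtered noise is renormalised to
unit RMS so the Butterworth gain does not silently change the perturbation
magnitude — both choices keep the effective perturbation at ``a`` relative
RMS per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .grf import (
    DEFAULT_STANCE_THRESHOLD_N,
    GaitDataset,
    GRFCycle,
    LEFT_CHANNELS,
    RIGHT_CHANNELS,
    VERTICAL_CHANNELS,
    detect_stance,
)

__all__ = [
    "AugmentationSpec",
    "SCENARIO_C_COMBOS",
    "jitter",
    "time_shift",
    "window_crop",
    "mixup",
    "apply_recipe",
    "expand_scenario_c",
]


@dataclass(frozen=True)
class AugmentationSpec:
    """Operator parameters.  Defaults are the study values; the vertical
    noise factor must stay at half the factor of the other components."""

    a_vertical: float = 0.01
    a_other: float = 0.02
    noise_cutoff_hz: float = 30.0
    filter_order: int = 4
    max_shift_samples: int = 15
    max_crop_frac: float = 0.03
    gamma_low: float = 0.85
    gamma_high: float = 0.95
    stance_threshold_n: float = DEFAULT_STANCE_THRESHOLD_N

    def __post_init__(self) -> None:
        if abs(self.a_vertical - self.a_other / 2.0) > 1e-12:
            raise ValueError("vertical noise factor must be half of a_other")
        if not 0.0 < self.max_crop_frac <= 0.03:
            raise ValueError("max_crop_frac must lie in (0, 0.03]")
        if not 0.0 <= self.gamma_low < self.gamma_high <= 1.0:
            raise ValueError("need 0 <= gamma_low < gamma_high <= 1")
        if self.max_shift_samples < 0:
            raise ValueError("max_shift_samples must be non-negative")


DEFAULT_SPEC = AugmentationSpec()

_LEG_CHANNELS = (LEFT_CHANNELS, RIGHT_CHANNELS)


def _as_rng(seed):
    """Accept a seed, a Generator, or any generator-like object (tests may
    inject stubs with scripted draws)."""
    if seed is None or isinstance(
        seed, (int, np.integer, np.random.SeedSequence, list, tuple)
    ):
        return np.random.default_rng(seed)
    return seed


def jitter(
    cycle: GRFCycle, spec: AugmentationSpec = DEFAULT_SPEC, seed=None
) -> GRFCycle:
    """Add band-limited noise to the stance samples of every channel."""
    rng = _as_rng(seed)
    sos = sps.butter(
        spec.filter_order,
        spec.noise_cutoff_hz,
        btype="low",
        fs=cycle.sample_rate,
        output="sos",
    )
    out = cycle.signal.copy()
    for leg, channels in enumerate(_LEG_CHANNELS):
        stance = detect_stance(
            cycle.signal[VERTICAL_CHANNELS[leg]], spec.stance_threshold_n
        )
        sl = slice(stance.start, stance.end)
        for ch in channels:
            x = cycle.signal[ch, sl]
            rms = float(np.sqrt(np.mean(x**2)))
            noise = sps.sosfilt(sos, rng.standard_normal(x.size))
            noise_rms = float(np.sqrt(np.mean(noise**2)))
            if rms == 0.0 or noise_rms == 0.0:
                continue  # an all-zero channel is returned unchanged
            a = spec.a_vertical if ch in VERTICAL_CHANNELS else spec.a_other
            out[ch, sl] = x + a * rms * (noise / noise_rms)
        # a force plate cannot pull the foot down: clip the rare noise
        # excursions below zero at the stance edges of the vertical channel
        np.clip(out[VERTICAL_CHANNELS[leg]], 0.0, None, out=out[VERTICAL_CHANNELS[leg]])
    return cycle.copy_with(out)


def time_shift(
    cycle: GRFCycle, spec: AugmentationSpec = DEFAULT_SPEC, seed=None
) -> GRFCycle:
    """Shift each leg along the time axis by an independent integer offset."""
    rng = _as_rng(seed)
    n = cycle.n_samples
    if n < 2 * spec.max_shift_samples:
        raise ValueError("cycle too short for the configured shift range")
    out = np.zeros_like(cycle.signal)
    for channels in _LEG_CHANNELS:
        k = int(rng.integers(-spec.max_shift_samples, spec.max_shift_samples + 1))
        idx = list(channels)
        if k > 0:
            out[idx, k:] = cycle.signal[idx, : n - k]
        elif k < 0:
            out[idx, :k] = cycle.signal[idx, -k:]
        else:
            out[idx] = cycle.signal[idx]
    return cycle.copy_with(out)


def window_crop(
    cycle: GRFCycle, spec: AugmentationSpec = DEFAULT_SPEC, seed=None
) -> GRFCycle:
    """Crop and linearly resample the left-leg stance window.

    Removes 1..floor(max_crop_frac * stance_length) samples, split randomly
    between the stance start and end, then stretches the remainder back so
    cycle length and stance placement are preserved.
    """
    rng = _as_rng(seed)
    stance = detect_stance(cycle.signal[VERTICAL_CHANNELS[0]], spec.stance_threshold_n)
    n_st = stance.length
    max_crop = int(np.floor(spec.max_crop_frac * n_st))
    if max_crop < 1:
        raise ValueError(
            f"left stance of {n_st} samples too short to crop at "
            f"{spec.max_crop_frac:.0%}"
        )
    c = int(rng.integers(1, max_crop + 1))
    front = int(rng.integers(0, c + 1))
    back = c - front
    out = cycle.signal.copy()
    src = slice(stance.start + front, stance.end - back)
    old_grid = np.linspace(0.0, 1.0, n_st - c)
    new_grid = np.linspace(0.0, 1.0, n_st)
    for ch in LEFT_CHANNELS:
        out[ch, stance.start : stance.end] = np.interp(
            new_grid, old_grid, cycle.signal[ch, src]
        )
    return cycle.copy_with(out)


def mixup(
    c1: GRFCycle,
    c2: GRFCycle,
    spec: AugmentationSpec = DEFAULT_SPEC,
    seed=None,
) -> GRFCycle:
    """Convex combination of two same-subject cycles (metadata from ``c1``)."""
    rng = _as_rng(seed)
    if c1.subject_id != c2.subject_id:
        raise ValueError(
            f"mixup requires same-class cycles, got {c1.subject_id!r} "
            f"and {c2.subject_id!r}"
        )
    if c1.n_samples != c2.n_samples:
        raise ValueError("mixup requires equal-length cycles")
    gamma = float(rng.uniform(spec.gamma_low, spec.gamma_high))
    return c1.copy_with(gamma * c1.signal + (1.0 - gamma) * c2.signal)


#: the eight training-set expansion recipes: each original cycle yields one
#: variant per combination, applied left to right.
SCENARIO_C_COMBOS: tuple[tuple[str, ...], ...] = (
    ("jitter",),
    ("time_shift",),
    ("window_crop",),
    ("jitter", "time_shift"),
    ("jitter", "window_crop"),
    ("time_shift", "window_crop"),
    ("jitter", "mixup"),
    ("jitter", "time_shift", "window_crop"),
)

_OPERATORS = {"jitter": jitter, "time_shift": time_shift, "window_crop": window_crop}


def apply_recipe(
    cycle: GRFCycle,
    recipe: tuple[str, ...],
    spec: AugmentationSpec,
    rng: np.random.Generator,
    partner: GRFCycle | None = None,
) -> GRFCycle:
    """Apply a named operator combination in order; ``partner`` feeds mixup."""
    out = cycle
    for name in recipe:
        if name == "mixup":
            if partner is None:
                raise ValueError("mixup requires a partner cycle")
            out = mixup(out, partner, spec, rng)
        else:
            out = _OPERATORS[name](out, spec, rng)
    return out


def expand_scenario_c(
    train: GaitDataset, seed: int = 0, spec: AugmentationSpec = DEFAULT_SPEC
) -> GaitDataset:
    """Nine-fold training-set expansion: originals plus the eight variants.

    Mixup partners are drawn from the same subject's other training cycles
    in the same condition; a subject with a single cycle falls back to the
    cycle itself (with a warning), which degenerates to the identity.
    Augmented copies receive trial ids ``1000 * combo + original`` so keys
    stay unique; labels are never changed.
    """
    if len(train) == 0:
        raise ValueError("cannot expand an empty training set")
    by_group: dict[tuple[str, str], list[int]] = {}
    for i, c in enumerate(train.cycles):
        by_group.setdefault((c.subject_id, c.condition), []).append(i)

    out = list(train.cycles)
    for i, cyc in enumerate(train.cycles):
        for j, combo in enumerate(SCENARIO_C_COMBOS):
            rng = np.random.default_rng(np.random.SeedSequence((seed, i, j)))
            partner = None
            if "mixup" in combo:
                pool = [k for k in by_group[(cyc.subject_id, cyc.condition)] if k != i]
                if pool:
                    partner = train.cycles[int(rng.choice(pool))]
                else:
                    warnings.warn(
                        f"subject {cyc.subject_id!r} has a single cycle; "
                        "mixup falls back to the cycle itself",
                        stacklevel=2,
                    )
                    partner = cyc
            aug = apply_recipe(cyc, combo, spec, rng, partner)
            aug.trial_id = 1000 * (j + 1) + cyc.trial_id
            out.append(aug)
    return GaitDataset(
        cycles=out, subjects=dict(train.subjects), sample_rate=train.sample_rate
    )
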