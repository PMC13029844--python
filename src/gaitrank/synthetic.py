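"""Synthetic gait-population generator.

Emulates the statistical structure of a force-plate identification study:
a cohort of subjects whose body masses follow N(74.33, 16.63^2) kg, each
walking 14-20 trials per condition either unloaded or carrying a 4.6 kg
briefcase in one self-chosen hand.  Every subject owns a private waveform
template — vertical-force peak amplitudes and timings, braking/propulsion
lobes, medial-lateral wobble — drawn once at "enrolment", so identity
information lives in the template while trial-to-trial noise provides
realistic within-subject variability.

Waveform model (per limb, on a normalised stance axis tau in [0, 1]):

* vertical  F_V  = BW_eff * [A1 g(tau; t1) + A2 g(tau; t2) + M g(tau; 0.5)],
  Gaussian bumps giving the canonical M-shape: two peaks (A1, A2 ~ 1.05-1.25
  body weights at t1 ~ 0.25, t2 ~ 0.75 of stance) and a mid-stance valley
  whose depth (0.70-0.85 BW) fixes the small corrective amplitude M;
* anterior-posterior  F_AP = BW_eff * [-B g(tau; tb) + P g(tau; tp)] —
  a braking lobe followed by a propulsion lobe (0.15-0.25 BW each);
* medial-lateral  F_ML = BW_eff * small multi-bump profile (0.03-0.10 BW).

All three are tapered smoothly to zero at the stance edges.  Carrying a
briefcase adds its mass to the effective weight, inflates the carrying-side
vertical amplitudes more than the contralateral side, amplifies the
carrying-side ML component and slightly lengthens stance — the directions
reported for asymmetric load carriage in the gait literature.

The recording layout mirrors a two-plate walkway: the left stance starts the
cycle, the right stance begins near the cycle midpoint, and the cycle length
is set so that the total vertical impulse matches effective weight x
duration (a walker must, on average, support their own weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .grf import GaitDataset, GRFCycle, Subject, pad_to_uniform

__all__ = [
    "GRAVITY",
    "LimbTemplate",
    "SubjectProfile",
    "GeneratorConfig",
    "sample_population",
    "generate_cycle",
    "build_study",
]

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class LimbTemplate:
    """Subject- and limb-specific waveform parameters (amplitudes in units
    of effective body weight, timings as fractions of stance)."""

    a1: float          # first vertical peak, 1.05-1.25 BW
    a2: float          # second vertical peak, 1.05-1.25 BW
    valley: float      # mid-stance vertical force, 0.70-0.85 BW
    t1: float          # first peak timing, 0.22-0.28 of stance
    t2: float          # second peak timing, 0.72-0.78 of stance
    peak_width: float  # Gaussian width of the vertical peaks
    ap_brake: float    # braking amplitude, 0.15-0.25 BW
    ap_prop: float     # propulsion amplitude, 0.15-0.25 BW
    ap_tb: float       # braking lobe centre
    ap_tp: float       # propulsion lobe centre
    ml_amp: float      # medial-lateral amplitude, 0.03-0.10 BW
    ml_centres: tuple[float, ...]
    ml_gains: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.t1 < self.t2:
            raise ValueError("first vertical peak must precede the second")


@dataclass(frozen=True)
class SubjectProfile:
    """Generative identity of one subject."""

    subject_id: str
    body_mass_kg: float
    height_cm: float
    carrying_hand: str
    stance_duration_s: float
    right_stance_offset_frac: float
    left: LimbTemplate
    right: LimbTemplate

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ValueError("body mass must be positive")
        if self.carrying_hand not in ("left", "right"):
            raise ValueError("carrying hand must be 'left' or 'right'")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs. Defaults reproduce the emulated cohort: 215
    subjects, masses N(74.33, 16.63^2) kg truncated to [45, 130], heights
    N(174.41, 9.49^2) cm, 14-20 trials per condition, 4.6 kg briefcase.

    The load coefficients encode the asymmetry direction: the carrying-side
    limb inflates its vertical amplitudes by ``delta_carry`` (default 6%),
    the contralateral limb by ``delta_contra`` (2%), the carrying-side ML
    component is multiplied by ``ml_load_gain`` and stance lengthens by
    ``load_stance_inflation``.  The magnitudes are configurable model
    choices; only their ordering (carry > contralateral >= 0) is asserted.
    """

    n_subjects: int = 215
    trials_min: int = 14
    trials_max: int = 20
    sample_rate: float = 960.0
    briefcase_mass_kg: float = 4.6
    mass_mean_kg: float = 74.33
    mass_sd_kg: float = 16.63
    mass_bounds_kg: tuple[float, float] = (45.0, 130.0)
    height_mean_cm: float = 174.41
    height_sd_cm: float = 9.49
    delta_carry: float = 0.06
    delta_contra: float = 0.02
    ml_load_gain: float = 1.3
    load_stance_inflation: float = 0.03
    amp_noise_sd: float = 0.02          # multiplicative, per amplitude
    timing_noise_frac: float = 0.01     # of stance, per peak timing
    stance_noise_sd_s: float = 0.03     # additive, seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not self.trials_min <= self.trials_max:
            raise ValueError("trials_min must not exceed trials_max")
        if min(self.amp_noise_sd, self.timing_noise_frac, self.stance_noise_sd_s) < 0:
            raise ValueError("noise scales must be non-negative")
        if not self.delta_carry >= self.delta_contra >= 0:
            raise ValueError("require delta_carry >= delta_contra >= 0")

    def noiseless(self) -> "GeneratorConfig":
        """Copy with all intra-subject noise switched off."""
        return replace(
            self, amp_noise_sd=0.0, timing_noise_frac=0.0, stance_noise_sd_s=0.0
        )


# ------------------------------------------------------------------
# population sampling
# ------------------------------------------------------------------

def _sample_limb(rng: np.random.Generator) -> LimbTemplate:
    n_ml = int(rng.integers(2, 4))
    centres = np.sort(rng.uniform(0.15, 0.85, size=n_ml))
    gains = rng.uniform(0.4, 1.0, size=n_ml) * rng.choice([-1.0, 1.0], size=n_ml)
    gains[-1] = abs(gains[-1])  # dominant lateral push near toe-off
    return LimbTemplate(
        a1=float(rng.uniform(1.05, 1.25)),
        a2=float(rng.uniform(1.05, 1.25)),
        valley=float(rng.uniform(0.70, 0.85)),
        t1=float(rng.uniform(0.22, 0.28)),
        t2=float(rng.uniform(0.72, 0.78)),
        peak_width=float(rng.uniform(0.155, 0.175)),
        ap_brake=float(rng.uniform(0.15, 0.25)),
        ap_prop=float(rng.uniform(0.15, 0.25)),
        ap_tb=float(rng.uniform(0.17, 0.23)),
        ap_tp=float(rng.uniform(0.77, 0.83)),
        ml_amp=float(rng.uniform(0.03, 0.10)),
        ml_centres=tuple(float(c) for c in centres),
        ml_gains=tuple(float(g) for g in gains),
    )


def sample_population(config: GeneratorConfig) -> list[SubjectProfile]:
    """Draw the cohort: one :class:`SubjectProfile` per subject.

    Masses come from the truncated normal fitted to the emulated cohort;
    every template parameter is drawn once per subject (and per limb, so
    subjects possess a natural left/right asymmetry).  Deterministic for a
    fixed ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    lo, hi = config.mass_bounds_kg
    a = (lo - config.mass_mean_kg) / config.mass_sd_kg
    b = (hi - config.mass_mean_kg) / config.mass_sd_kg
    masses = stats.truncnorm.rvs(
        a, b,
        loc=config.mass_mean_kg,
        scale=config.mass_sd_kg,
        size=config.n_subjects,
        random_state=rng,
    )
    width = max(3, len(str(config.n_subjects)))
    profiles = []
    for i in range(config.n_subjects):
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:0{width}d}",
                body_mass_kg=float(masses[i]),
                height_cm=float(rng.normal(config.height_mean_cm, config.height_sd_cm)),
                carrying_hand="left" if rng.random() < 0.5 else "right",
                stance_duration_s=float(rng.uniform(0.60, 0.75)),
                right_stance_offset_frac=float(rng.normal(0.5, 0.01)),
                left=_sample_limb(rng),
                right=_sample_limb(rng),
            )
        )
    return profiles


# ------------------------------------------------------------------
# waveform synthesis
# ------------------------------------------------------------------

def _gauss(tau: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((tau - centre) / width) ** 2)


def _edge_taper(tau: np.ndarray, ramp: float = 0.08) -> np.ndarray:
    """Smoothstep ramp from 0 at each stance edge over ``ramp`` of stance."""
    u = np.clip(tau / ramp, 0.0, 1.0)
    v = np.clip((1.0 - tau) / ramp, 0.0, 1.0)
    s = lambda x: x * x * (3.0 - 2.0 * x)  # noqa: E731
    return s(u) * s(v)


def _jittered(value: float, rng: np.random.Generator, sd: float) -> float:
    return value * (1.0 + rng.normal(0.0, sd)) if sd > 0 else value


def _limb_stance(
    tmpl: LimbTemplate,
    n: int,
    bw_eff: float,
    ml_gain: float,
    rng: np.random.Generator,
    cfg: GeneratorConfig,
) -> np.ndarray:
    """Three stance-phase channels (AP, V, ML) of one limb, length ``n``."""
    tau = np.linspace(0.0, 1.0, n)
    a_sd, t_sd = cfg.amp_noise_sd, cfg.timing_noise_frac
    a1 = _jittered(tmpl.a1, rng, a_sd)
    a2 = _jittered(tmpl.a2, rng, a_sd)
    valley = _jittered(tmpl.valley, rng, a_sd)
    t1 = tmpl.t1 + (rng.normal(0.0, t_sd) if t_sd > 0 else 0.0)
    t2 = tmpl.t2 + (rng.normal(0.0, t_sd) if t_sd > 0 else 0.0)
    w = tmpl.peak_width
    # mid-stance correction so that F_V(0.5) equals the valley target
    mid = valley - a1 * _gauss(np.array([0.5]), t1, w)[0] - a2 * _gauss(
        np.array([0.5]), t2, w
    )[0]
    fv = a1 * _gauss(tau, t1, w) + a2 * _gauss(tau, t2, w) + mid * _gauss(tau, 0.5, 0.12)
    fv = np.clip(fv, 0.0, None)

    brake = _jittered(tmpl.ap_brake, rng, a_sd)
    prop = _jittered(tmpl.ap_prop, rng, a_sd)
    fap = -brake * _gauss(tau, tmpl.ap_tb, 0.10) + prop * _gauss(tau, tmpl.ap_tp, 0.10)

    ml_amp = _jittered(tmpl.ml_amp, rng, a_sd) * ml_gain
    fml = np.zeros(n)
    for c, g in zip(tmpl.ml_centres, tmpl.ml_gains):
        fml += g * _gauss(tau, c, 0.16)
    peak = np.max(np.abs(fml))
    if peak > 0:
        fml *= ml_amp / peak

    taper = _edge_taper(tau)
    return np.vstack([fap * taper, fv * taper, fml * taper]) * bw_eff


def generate_cycle(
    profile: SubjectProfile,
    condition: str,
    trial_seed,
    config: GeneratorConfig | None = None,
) -> GRFCycle:
    """Synthesise one six-channel gait cycle for a subject and condition.

    ``trial_seed`` may be an int or a :class:`numpy.random.SeedSequence`;
    the cycle is fully determined by (profile, condition, trial_seed, config).
    """
    cfg = config or GeneratorConfig()
    if condition not in ("unloaded", "loaded_left", "loaded_right"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(trial_seed)
    fs = cfg.sample_rate

    loaded = condition != "unloaded"
    load_side = condition.removeprefix("loaded_") if loaded else None
    mass_eff = profile.body_mass_kg + (cfg.briefcase_mass_kg if loaded else 0.0)
    weight_eff = mass_eff * GRAVITY

    stance_s = profile.stance_duration_s * (
        1.0 + (cfg.load_stance_inflation if loaded else 0.0)
    )

    sides = {}
    for side, tmpl in (("left", profile.left), ("right", profile.right)):
        if loaded:
            delta = cfg.delta_carry if side == load_side else cfg.delta_contra
            ml_gain = cfg.ml_load_gain if side == load_side else 1.0
        else:
            delta, ml_gain = 0.0, 1.0
        dur = stance_s + (
            rng.normal(0.0, cfg.stance_noise_sd_s) if cfg.stance_noise_sd_s > 0 else 0.0
        )
        n = max(int(round(dur * fs)), 16)
        sides[side] = _limb_stance(tmpl, n, weight_eff * (1.0 + delta), ml_gain, rng, cfg)

    n_left = sides["left"].shape[1]
    n_right = sides["right"].shape[1]

    # Cycle length from the impulse balance: the summed vertical impulse of
    # both stances should equal effective weight x cycle duration, i.e. the
    # walker supports their own (loaded) weight on average over the cycle.
    imp_samples = (np.sum(sides["left"][1]) + np.sum(sides["right"][1])) / weight_eff
    length = max(int(round(imp_samples)), n_left + 2, n_right + 2)
    # Right stance starts near the cycle midpoint but must fit inside the
    # impulse-determined length; clipping it earlier simply lengthens the
    # double-support overlap, which is how walkers with a lower mean stance
    # force do keep supporting their weight on average.
    offset = int(round(profile.right_stance_offset_frac * length))
    offset = int(np.clip(offset, 1, length - n_right))

    signal = np.zeros((6, length))
    signal[0:3, :n_left] = sides["left"]
    signal[3:6, offset : offset + n_right] = sides["right"]

    return GRFCycle(
        subject_id=profile.subject_id,
        condition=condition,
        trial_id=-1,
        signal=signal,
        body_mass_kg=profile.body_mass_kg,
        sample_rate=fs,
    )


# ------------------------------------------------------------------
# study assembly
# ------------------------------------------------------------------

def _trial_seed(master: int, subject_index: int, condition: str, trial: int):
    """Stated counter scheme: per-cycle seeds derive from the master seed so
    any single cycle is regenerable without rebuilding the study."""
    cond_code = ("unloaded", "loaded_left", "loaded_right").index(condition)
    return np.random.SeedSequence((master, subject_index, cond_code, trial))


def build_study(
    config: GeneratorConfig | None = None,
    profiles: list[SubjectProfile] | None = None,
) -> tuple[GaitDataset, GaitDataset]:
    """Generate the full two-condition study.

    Returns ``(unloaded, loaded)`` datasets padded to one shared unified
    length, with a roster recording ground-truth masses and carrying hands.
    Each subject contributes a per-condition trial count drawn uniformly
    from [trials_min, trials_max]; the loaded condition uses the subject's
    fixed carrying hand.
    """
    cfg = config or GeneratorConfig()
    if profiles is None:
        profiles = sample_population(cfg)
    count_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))

    roster = {
        p.subject_id: Subject(
            subject_id=p.subject_id,
            body_mass_kg=p.body_mass_kg,
            height_cm=p.height_cm,
            carrying_hand=p.carrying_hand,
        )
        for p in profiles
    }

    unloaded_cycles: list[GRFCycle] = []
    loaded_cycles: list[GRFCycle] = []
    for si, p in enumerate(profiles):
        loaded_cond = f"loaded_{p.carrying_hand}"
        for cond, sink in (("unloaded", unloaded_cycles), (loaded_cond, loaded_cycles)):
            n_trials = int(count_rng.integers(cfg.trials_min, cfg.trials_max + 1))
            for t in range(n_trials):
                cyc = generate_cycle(p, cond, _trial_seed(cfg.seed, si, cond, t), cfg)
                cyc.trial_id = t
                sink.append(cyc)

    n_max = max(c.n_samples for c in unloaded_cycles + loaded_cycles)
    unloaded = pad_to_uniform(unloaded_cycles, subjects=roster, target_length=n_max)
    loaded = pad_to_uniform(loaded_cycles, subjects=dict(roster), target_length=n_max)
    return unloaded, loaded
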