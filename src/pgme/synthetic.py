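"""Seeded generator of trunk-acceleration-like walking epochs and matched
faller / non-faller cohorts.

An epoch is built from (i) stride-time jitter: step intervals
T_i = (1/step_freq) * (1 + eps_i) with eps_i ~ N(0, stride_cv^2); (ii) a
Fourier-series gait waveform per axis, phase-locked to the stride (two
steps), so left/right asymmetry and a dominant step-frequency component
arise naturally; (iii) a damped-oscillation impact transient at every
cycle start mimicking heel strike; and (iv) additive Gaussian noise whose
SD is modulated across five step-phase bins.  The "faller" effect
multiplies the noise SD in one phase bin (default 60%, factor 0.5), i.e.
phase-localized *reduced* irregularity, the direction reported for
single-time fallers.

Cohorts are matched pairs: one faller and one non-faller share a
demographic draw; per-subject random effects perturb gait parameters so
between-subject variance exceeds within-subject variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .signal_prep import AccelEpoch, StepCycleSet

__all__ = ["GaitSimParams", "simulate_epoch", "simulate_cohort"]


def _default_harmonics() -> dict:
    # amplitudes (m/s^2) of the first 6 harmonics of the stride frequency;
    # AP/V dominated by the even (step-frequency) harmonics, ML by the odd
    return {
        "AP": (0.06, 0.50, 0.06, 0.16, 0.03, 0.05),
        "ML": (0.40, 0.08, 0.12, 0.04, 0.02, 0.01),
        "V": (0.05, 0.65, 0.08, 0.20, 0.04, 0.06),
    }


def _default_phase_profile() -> np.ndarray:
    return np.ones(5)


@dataclass
class GaitSimParams:
    """Generative parameters for one subject's walking epochs.

    ``phase_noise_profile`` holds a multiplicative noise-SD factor for the
    five step-phase bins [0,20)%, [20,40)%, ...; ``effect_delta`` scales
    the bin containing ``effect_phase`` (applied for "faller" subjects).
    """

    step_freq: float = 2.0        # Hz
    stride_cv: float = 0.03       # fractional stride-time jitter
    harmonics: dict = field(default_factory=_default_harmonics)
    impact_freq: float = 12.0     # Hz, heel-strike burst
    impact_amp: float = 1.0       # m/s^2, on V (AP gets half)
    impact_decay: float = 0.05    # s, exponential decay constant
    noise_sigma: float = 0.15     # m/s^2 baseline per axis
    phase_noise_profile: np.ndarray = field(default_factory=_default_phase_profile)
    effect_phase: int = 60        # % of step cycle
    effect_delta: float = 1.0     # 1.0 = no effect
    fs: float = 100.0
    duration: float = 30.0        # s
    seed: int = 0

    def __post_init__(self):
        self.phase_noise_profile = np.asarray(self.phase_noise_profile, float)
        if self.effect_delta <= 0:
            raise ConfigurationError("effect_delta must be positive")
        if self.stride_cv < 0:
            raise ConfigurationError("stride_cv must be non-negative")
        if any(a < 0 for ax in self.harmonics.values() for a in ax):
            raise ConfigurationError("harmonic amplitudes must be non-negative")
        if int(round(self.fs * self.duration)) < 2:
            raise ConfigurationError("inconsistent fs/duration")


# fixed per-axis harmonic phase offsets (radians), frozen for
# reproducibility; the even (step-rate) V harmonics sit at 3*pi/2 so the
# integrated vertical velocity has its minima at the cycle starts, making
# the generator's true boundaries the oracle for cycle detection
_3PI2 = 4.71238898038469
_PHASE_OFFSETS = {
    "AP": (0.3, 0.0, 1.1, 0.7, 2.0, 1.4),
    "ML": (0.0, 0.9, 0.4, 1.8, 0.2, 2.4),
    "V": (1.2, _3PI2, 0.8, _3PI2, 1.6, _3PI2),
}


def simulate_epoch(params: GaitSimParams, rng: np.random.Generator | None = None):
    """Generate one epoch; returns (AccelEpoch, true boundary samples).

    The true step-cycle boundaries (sample indices of cycle starts) are
    returned so downstream detectors can be tested against ground truth.
    """
    rng = rng or np.random.default_rng(params.seed)
    n = int(round(params.fs * params.duration))
    t = np.arange(n) / params.fs

    # stride-jittered step boundaries covering the epoch
    mean_T = 1.0 / params.step_freq
    n_cycles = int(np.ceil(params.duration / mean_T)) + 4
    eps = rng.normal(0.0, params.stride_cv, size=n_cycles)
    T = mean_T * np.clip(1.0 + eps, 0.2, 3.0)
    starts = np.concatenate([[0.0], np.cumsum(T)])

    # continuous step phase phi(t) in [0, 1), piecewise linear per cycle
    cycle_of_t = np.searchsorted(starts, t, side="right") - 1
    phi = (t - starts[cycle_of_t]) / T[np.minimum(cycle_of_t, len(T) - 1)]
    phi = np.clip(phi, 0.0, 1.0 - 1e-12)
    # stride phase: two consecutive step cycles form one stride
    stride_phi = (cycle_of_t % 2 + phi) / 2.0

    # phase-binned noise SD, with the faller effect applied to one bin
    profile = params.phase_noise_profile.copy()
    bin_idx = min(int(params.effect_phase // 20), 4)
    profile[bin_idx] *= params.effect_delta
    sigma_t = params.noise_sigma * profile[
        np.minimum((phi * 5).astype(int), 4)
    ]

    samples = np.empty((3, n))
    for c, ax in enumerate(("AP", "ML", "V")):
        amps = params.harmonics[ax]
        offs = _PHASE_OFFSETS[ax]
        wave = np.zeros(n)
        for h, (a, ph) in enumerate(zip(amps, offs), start=1):
            wave += a * np.cos(2 * np.pi * h * stride_phi + ph)
        samples[c] = wave

    # heel-strike impact transient at each cycle start (V and AP)
    imp_scale = {"AP": 0.5, "ML": 0.15, "V": 1.0}
    for t0 in starts:
        if t0 >= params.duration:
            break
        i0 = int(np.ceil(t0 * params.fs))
        if i0 >= n:
            continue
        span = min(n - i0, int(6 * params.impact_decay * params.fs) + 1)
        tt = t[i0:i0 + span] - t0
        burst = (params.impact_amp * np.exp(-tt / params.impact_decay)
                 * np.sin(2 * np.pi * params.impact_freq * tt))
        for c, ax in enumerate(("AP", "ML", "V")):
            samples[c, i0:i0 + span] += imp_scale[ax] * burst

    samples += sigma_t * rng.standard_normal((3, n))

    boundaries = np.array(
        [int(round(s * params.fs)) for s in starts if s * params.fs < n],
        dtype=int,
    )
    epoch = AccelEpoch(samples=samples, fs=params.fs, source_id="synthetic")
    return epoch, boundaries


def true_cycles(boundaries: np.ndarray, fs: float) -> StepCycleSet:
    """Wrap ground-truth boundaries from the simulator as a StepCycleSet."""
    return StepCycleSet(boundaries=boundaries, fs=fs)


def _subject_params(base: GaitSimParams, rng: np.random.Generator,
                    is_faller: bool, effect_delta: float) -> GaitSimParams:
    """Per-subject random effects on the generative parameters."""
    step = base.step_freq * (1.0 + rng.normal(0.0, 0.04))
    noise = base.noise_sigma * float(np.exp(rng.normal(0.0, 0.15)))
    harmonics = {
        ax: tuple(a * float(np.exp(rng.normal(0.0, 0.10))) for a in amps)
        for ax, amps in base.harmonics.items()
    }
    return replace(
        base,
        step_freq=float(np.clip(step, 1.2, 3.0)),
        noise_sigma=noise,
        harmonics=harmonics,
        effect_delta=effect_delta if is_faller else 1.0,
    )


def simulate_cohort(
    n_pairs: int,
    base_params: GaitSimParams | None = None,
    epochs_per_subject: int = 10,
    effect_delta: float = 0.5,
    effect_phase: int = 60,
    seed: int = 0,
):
    """Matched faller / non-faller cohort of synthetic walking recordings.

    Returns
    -------
    recordings : dict subject_id -> list of (AccelEpoch, true boundaries)
    cohort : DataFrame with subject_id, label (1 = faller), pair_id and
        synthetic demographics (age, sex, height, weight, fall_history);
        matched pairs share a demographic draw.
    """
    base = base_params or GaitSimParams()
    base = replace(base, effect_phase=effect_phase)
    root = np.random.SeedSequence(seed)
    recordings: dict[str, list] = {}
    rows = []
    for pair, pair_ss in enumerate(root.spawn(n_pairs)):
        demo_rng = np.random.default_rng(pair_ss.spawn(1)[0])
        demo = {
            "age": float(np.round(demo_rng.normal(76.0, 6.7), 1)),
            "sex": int(demo_rng.integers(0, 2)),
            "height": float(np.round(demo_rng.normal(171.0, 8.5), 1)),
            "weight": float(np.round(demo_rng.normal(74.0, 12.0), 1)),
        }
        for label in (1, 0):
            sid = f"P{pair:03d}_{'F' if label else 'N'}"
            subj_ss = pair_ss.spawn(1)[0]
            subj_rng = np.random.default_rng(subj_ss)
            params = _subject_params(base, subj_rng, bool(label), effect_delta)
            epochs = []
            for _ in range(epochs_per_subject):
                ep_rng = np.random.default_rng(subj_ss.spawn(1)[0])
                epoch, bounds = simulate_epoch(params, rng=ep_rng)
                epoch.source_id = sid
                epochs.append((epoch, bounds))
            recordings[sid] = epochs
            rows.append({
                "subject_id": sid, "label": label, "pair_id": pair,
                "fall_history": int(subj_rng.random() <
                                    (0.45 if label else 0.34)),
                **demo,
            })
    cohort = pd.DataFrame(rows)
    return recordings, cohort
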