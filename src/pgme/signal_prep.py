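"""Raw tri-axial acceleration -> screened 30-s walking epochs, velocities,
step cycles and step-phase windows.

The analysis unit is a 30-s epoch of lower-back acceleration in the
anterioposterior (AP), mediolateral (ML) and vertical (V) directions.
Epochs are screened for walking with a spectral/impact-peak proxy, velocity
is estimated by integration plus MEMD detrending, step cycles are the
intervals between consecutive vertical-velocity minima, and phase windows
pool the samples lying within 10% of the step time after 0, 20, 40, 60 and
80% of each cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks, periodogram

from . import memd as memd_mod
from .exceptions import ConfigurationError, DataError, DegenerateInputError

__all__ = [
    "AXES",
    "AccelEpoch",
    "VelocityEpoch",
    "StepCycleSet",
    "PhaseWindowSet",
    "ScreenConfig",
    "segment_epochs",
    "screen_walking",
    "estimate_velocity",
    "detect_step_cycles",
    "phase_windows",
    "load_recording",
]

AXES = ("AP", "ML", "V")
EPOCH_SECONDS = 30.0
PHASES = (0, 20, 40, 60, 80)


@dataclass
class AccelEpoch:
    """One fixed-length, three-channel acceleration window.

    ``samples`` is a (3, N) array in AP/ML/V order with N = round(30 * fs)
    unless ``duration_s`` was overridden at segmentation time.
    """

    samples: np.ndarray
    fs: float
    axes: tuple[str, ...] = AXES
    source_id: str = ""
    start_index: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 3:
            raise DataError("AccelEpoch requires a (3, N) sample matrix")
        if len(self.axes) != 3 or len(set(self.axes)) != 3:
            raise ConfigurationError("exactly three uniquely labeled axes required")
        if not np.all(np.isfinite(self.samples)):
            bad = np.where(~np.all(np.isfinite(self.samples), axis=0))[0]
            raise DataError(
                f"non-finite samples in range [{bad.min()}, {bad.max()}]"
            )
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def axis(self, name: str) -> np.ndarray:
        return self.samples[self.axes.index(name)]


@dataclass
class VelocityEpoch:
    """Integrated, MEMD-detrended 3D velocity for one epoch."""

    samples: np.ndarray
    fs: float
    axes: tuple[str, ...] = AXES
    detrend_report: dict = field(default_factory=dict)

    def axis(self, name: str) -> np.ndarray:
        return self.samples[self.axes.index(name)]


@dataclass
class StepCycleSet:
    """Step-cycle boundaries (vertical-velocity extrema) for one epoch.

    ``boundaries`` are strictly increasing sample indices; cycle i spans
    boundaries[i]..boundaries[i+1] and is valid when its duration lies in
    [0.3 s, 1.0 s].
    """

    boundaries: np.ndarray
    fs: float
    valid: np.ndarray = None

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if np.any(np.diff(self.boundaries) <= 0):
            raise DataError("cycle boundaries must be strictly increasing")
        if self.valid is None:
            dur_s = self.durations / self.fs
            self.valid = (dur_s >= 0.3) & (dur_s <= 1.0)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def durations(self) -> np.ndarray:
        """Per-cycle length in samples."""
        return np.diff(self.boundaries)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class PhaseWindowSet:
    """Pooled sample indices for each step-cycle phase of one epoch."""

    phase_labels: tuple[int, ...]
    index_sets: dict[int, np.ndarray]


@dataclass
class ScreenConfig:
    """Programmatic stand-in for visual walking-epoch inclusion checks.

    An epoch passes when, on at least ``min_pass_frac`` of sliding
    subwindows, (a) the dominant spectral peak of V or AP lies in the
    locomotion band with sufficient prominence and (b) the impact-peak
    count matches the step count implied by the dominant frequency.
    """

    band: tuple[float, float] = (1.2, 3.5)
    peak_prominence_ratio: float = 3.0   # peak power / median band power
    impact_tolerance: float = 0.30
    window_s: float = 3.0
    step_s: float = 1.0
    min_pass_frac: float = 0.80
    enabled: bool = True


# ---------------------------------------------------------------------------
# segmentation and screening
# ---------------------------------------------------------------------------

def load_recording(path, axes=AXES) -> tuple[np.ndarray, float]:
    """Read a delimited text recording with columns time, AP, ML, V.

    Returns the (3, N) sample matrix and the sampling rate inferred from
    the time column.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in ("time", *axes) if c not in df.columns]
    if missing:
        raise ConfigurationError(f"recording {path} lacks columns {missing}")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise DataError(f"recording {path} too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    return df.loc[:, list(axes)].to_numpy(dtype=float).T, fs


def segment_epochs(
    bout: np.ndarray,
    fs: float,
    source_id: str = "",
    duration_s: float = EPOCH_SECONDS,
) -> list[AccelEpoch]:
    """Cut a (3, N) walking bout into consecutive non-overlapping epochs.

    The trailing remainder shorter than ``duration_s`` is discarded; bouts
    shorter than one epoch yield an empty list.
    """
    bout = np.asarray(bout, dtype=float)
    if bout.ndim != 2 or bout.shape[0] != 3:
        raise ConfigurationError(
            "bout must be (3, N) with channels mapped to AP/ML/V"
        )
    if fs <= 0:
        raise ConfigurationError("sampling rate must be positive")
    if not np.all(np.isfinite(bout)):
        bad = np.where(~np.all(np.isfinite(bout), axis=0))[0]
        raise DataError(f"non-finite samples in range [{bad.min()}, {bad.max()}]")
    n_epoch = int(round(duration_s * fs))
    n = bout.shape[1]
    epochs = []
    for start in range(0, n - n_epoch + 1, n_epoch):
        epochs.append(
            AccelEpoch(
                samples=bout[:, start:start + n_epoch].copy(),
                fs=fs,
                source_id=source_id,
                start_index=start,
            )
        )
    return epochs


def _subwindow_checks(seg: np.ndarray, fs: float, cfg: ScreenConfig):
    """Run the two walking criteria on one subwindow of V and AP signals."""
    best = None
    for x in seg:  # V first, then AP; either may carry the gait rhythm
        x = x - x.mean()
        f, p = periodogram(x, fs=fs)
        band = (f >= cfg.band[0]) & (f <= cfg.band[1])
        if not band.any() or p[band].max() <= 0:
            continue
        i_peak = np.argmax(np.where(band, p, 0.0))
        f_dom = f[i_peak]
        med = np.median(p[(f > 0.3) & (f < 10.0)]) if (p > 0).any() else 0.0
        prominent = med > 0 and p[i_peak] / med >= cfg.peak_prominence_ratio
        if not prominent:
            continue
        # criterion (b): impact peaks at roughly one per step
        expected = f_dom * len(x) / fs
        pk, _ = find_peaks(x, height=1.0 * x.std(), distance=max(1, int(0.3 * fs)))
        count_ok = abs(len(pk) - expected) <= cfg.impact_tolerance * expected
        cand = {"dominant_freq": float(f_dom), "peak_ok": True,
                "impact_count": len(pk), "expected_count": float(expected),
                "count_ok": bool(count_ok)}
        if count_ok:
            return cand
        best = cand
    return best or {"dominant_freq": None, "peak_ok": False,
                    "impact_count": 0, "expected_count": 0.0, "count_ok": False}


def screen_walking(epoch: AccelEpoch, cfg: ScreenConfig | None = None):
    """Decide whether an epoch looks like steady walking.

    Slides 3-s subwindows across the epoch; each must show a prominent
    locomotion-band spectral peak in V or AP and an impact-peak count
    consistent with the dominant frequency.  The epoch is accepted when at
    least 80% of subwindows pass both checks.

    Returns (accepted, report) — never raises on signal content.
    """
    cfg = cfg or ScreenConfig()
    if not cfg.enabled:
        return True, {"enabled": False}
    n_win = int(cfg.window_s * epoch.fs)
    step = max(1, int(cfg.step_s * epoch.fs))
    v, ap = epoch.axis("V"), epoch.axis("AP")
    if np.ptp(v) == 0 and np.ptp(ap) == 0:
        return False, {"pass_frac": 0.0, "windows": [],
                       "reason": "no spectral peaks (constant signal)"}
    results = []
    for start in range(0, epoch.n_samples - n_win + 1, step):
        seg = np.stack([v[start:start + n_win], ap[start:start + n_win]])
        if np.ptp(seg) == 0:
            results.append({"peak_ok": False, "count_ok": False})
            continue
        results.append(_subwindow_checks(seg, epoch.fs, cfg))
    if not results:
        return False, {"pass_frac": 0.0, "windows": [], "reason": "epoch too short"}
    passed = [r["peak_ok"] and r["count_ok"] for r in results]
    frac = float(np.mean(passed))
    accepted = frac >= cfg.min_pass_frac
    report = {"pass_frac": frac, "windows": results,
              "reason": None if accepted else "walking criteria unmet"}
    return accepted, report


# ---------------------------------------------------------------------------
# velocity, step cycles, phase windows
# ---------------------------------------------------------------------------

def estimate_velocity(
    epoch: AccelEpoch,
    cutoff_hz: float = 0.5,
    n_dirs: int = memd_mod.N_DIRS,
) -> VelocityEpoch:
    """Numerically integrate the acceleration and remove slow drift.

    Per channel: the epoch mean is subtracted, the signal integrated by the
    cumulative trapezoid rule, and the resulting 3-channel velocity is
    MEMD-detrended — the residual and every IMF with zero-crossing
    frequency below ``cutoff_hz`` are removed — so intra-step variation is
    preserved while integration drift and inter-stride trends vanish.
    """
    acc = epoch.samples - epoch.samples.mean(axis=1, keepdims=True)
    vel = cumulative_trapezoid(acc, dx=1.0 / epoch.fs, axis=1, initial=0.0)
    detrended, report = memd_mod.detrend_memd(
        vel.T, fs=epoch.fs, cutoff_hz=cutoff_hz, n_dirs=n_dirs
    )
    detrended = detrended - detrended.mean(axis=0)  # zero-mean invariant
    return VelocityEpoch(
        samples=detrended.T, fs=epoch.fs, axes=epoch.axes,
        detrend_report=report,
    )


def detect_step_cycles(
    vel: VelocityEpoch,
    min_separation_s: float = 0.3,
    prominence_sd: float = 0.1,
    extremum: str = "minima",
) -> StepCycleSet:
    """Step-cycle boundaries from the vertical velocity.

    Boundaries are the local minima (default) of the vertical velocity with
    a minimum separation of 0.3 s and prominence of at least 0.1 SD;
    ``extremum='maxima'`` flips the convention.  Cycles whose duration
    falls outside [0.3 s, 1.0 s] are marked invalid.
    """
    v = vel.axis("V")
    sd = v.std()
    if sd == 0:
        raise DegenerateInputError("no gait cycles: constant vertical velocity")
    sig = -v if extremum == "minima" else v
    peaks, _ = find_peaks(
        sig,
        distance=max(1, int(round(min_separation_s * vel.fs))),
        prominence=prominence_sd * sd,
    )
    if len(peaks) < 2:
        raise DegenerateInputError("no gait cycles: fewer than 2 extrema found")
    return StepCycleSet(boundaries=peaks, fs=vel.fs)


def phase_windows(
    cycles: StepCycleSet,
    phases=PHASES,
    width: float = 0.10,
    n_samples: int | None = None,
) -> PhaseWindowSet:
    """Pool sample indices of each step-cycle phase across valid cycles.

    For a valid cycle starting at s with duration T and phase p%, the
    window is [s + round(p*T/100), s + round(p*T/100) + floor(width*T)),
    at least one sample wide.  ``n_samples`` clips windows to the epoch.
    """
    if width <= 0:
        raise ConfigurationError("phase window width must be positive")
    if any(p < 0 or p >= 100 for p in phases):
        raise ConfigurationError("phases must lie in [0, 100)")
    if cycles.n_valid < 1:
        raise DataError("phase windows require at least one valid cycle")
    pooled: dict[int, list] = {int(p): [] for p in phases}
    starts = cycles.boundaries[:-1]
    durations = cycles.durations
    for s, T, ok in zip(starts, durations, cycles.valid):
        if not ok:
            continue
        w = max(1, int(np.floor(width * T)))
        for p in phases:
            w0 = int(s + round(p * T / 100.0))
            idx = np.arange(w0, w0 + w)
            if n_samples is not None:
                idx = idx[idx < n_samples]
            pooled[int(p)].append(idx)
    index_sets = {
        p: (np.concatenate(v) if v else np.empty(0, dtype=int))
        for p, v in pooled.items()
    }
    return PhaseWindowSet(phase_labels=tuple(int(p) for p in phases),
                          index_sets=index_sets)
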