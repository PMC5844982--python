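"""Conventional trunk-acceleration gait features.

The battery mirrors the standard accelerometry literature: acceleration
SD, stride regularity from the unbiased autocorrelation, harmonic ratio,
index of harmonicity, Welch-spectrum descriptors (dominant frequency,
amplitude, width, slope, range), low-frequency percentage, and largest
Lyapunov exponents by the Rosenstein and Wolf algorithms (raw and per
stride).  Features needing a body model (walking speed, step length) are
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch
from scipy.spatial.distance import cdist

from .embedding import AMICurve, _mi_nats, select_lag
from .exceptions import DataError
from .signal_prep import AccelEpoch, StepCycleSet

__all__ = [
    "SpectralConfig",
    "basic_stats",
    "stride_regularity",
    "harmonic_ratio",
    "index_of_harmonicity",
    "spectral_features",
    "low_freq_percentage",
    "lyapunov_rosenstein",
    "lyapunov_wolf",
    "compute_features",
    "subject_features",
]

_DIRS = ("AP", "ML", "V")


@dataclass
class SpectralConfig:
    """Conventions for the spectral feature battery (all configurable;
    the cited methods literature, not a single source, fixes them)."""

    welch_segment_s: float = 5.0
    welch_overlap: float = 0.5
    dominant_band: tuple[float, float] = (0.5, 3.0)
    slope_band: tuple[float, float] = (0.5, 10.0)
    power_band: tuple[float, float] = (0.0, 10.0)
    lfp_cutoff: float = 0.7
    range_central: float = 0.98
    n_harmonics_hr: int = 20
    n_harmonics_ih: int = 6


def _magnitude(epoch: AccelEpoch) -> np.ndarray:
    return np.linalg.norm(epoch.samples, axis=0)


def basic_stats(epoch: AccelEpoch) -> dict:
    """Per-axis acceleration SD plus the SD of the vector-magnitude signal."""
    out = {f"acc_sd_{ax}": float(epoch.axis(ax).std()) for ax in _DIRS}
    out["acc_sd_mag"] = float(_magnitude(epoch).std())
    return out


def _unbiased_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelation coefficient with unbiased (1/(N-lag)) normalization."""
    x = x - x.mean()
    n = len(x)
    denom = np.sum(x * x) / n
    if denom == 0:
        return np.zeros(max_lag + 1)
    out = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        out[lag] = np.sum(x[: n - lag] * x[lag:]) / (n - lag) / denom
    return out


def stride_regularity(
    epoch: AccelEpoch, cycles: StepCycleSet, min_cycles: int = 10
) -> dict:
    """Stride regularity (autocorrelation at the stride lag) per direction,
    plus stride-time and stride-frequency statistics.

    One stride is two step cycles, so the stride lag is twice the mean
    valid cycle duration; regularity is the unbiased autocorrelation
    coefficient at that lag (peak within +-10% searched for robustness).
    """
    if cycles.n_valid < min_cycles:
        raise DataError(
            f"stride regularity needs >= {min_cycles} valid cycles"
        )
    durs = cycles.durations[cycles.valid]
    stride_lag = int(round(2.0 * durs.mean()))
    window = max(1, int(round(0.1 * stride_lag)))
    out = {}
    sigs = {ax: epoch.axis(ax) for ax in _DIRS}
    sigs["mag"] = _magnitude(epoch)
    for name, x in sigs.items():
        ac = _unbiased_autocorr(x, stride_lag + window)
        lo = max(1, stride_lag - window)
        out[f"stride_regularity_{name}"] = float(ac[lo:stride_lag + window + 1].max())
    # stride times from alternate cycle boundaries
    b = cycles.boundaries
    stride_samples = b[2::2] - b[:-2:2]
    stride_t = stride_samples / cycles.fs
    stride_t = stride_t[(stride_t >= 0.6) & (stride_t <= 2.0)]
    if len(stride_t) < 2:
        stride_t = 2.0 * durs / cycles.fs
    out["stride_time"] = float(stride_t.mean())
    out["stride_time_variability"] = float(stride_t.std(ddof=1))
    freqs = 1.0 / stride_t
    out["stride_frequency"] = float(freqs.mean())
    out["stride_frequency_variability"] = float(freqs.std(ddof=1))
    return out


def _harmonic_amplitudes(x: np.ndarray, fs: float, f0: float, n_harm: int):
    """Finite-series Fourier amplitude at each harmonic of f0."""
    t = np.arange(len(x)) / fs
    x = x - x.mean()
    amps = np.empty(n_harm)
    for h in range(1, n_harm + 1):
        c = np.sum(x * np.exp(-2j * np.pi * h * f0 * t))
        amps[h - 1] = 2.0 * np.abs(c) / len(x)
    return amps


def harmonic_ratio(epoch: AccelEpoch, stride_freq: float,
                   cfg: SpectralConfig | None = None) -> dict:
    """Harmonic ratio per direction from the first 20 stride harmonics.

    AP and V are step-periodic, so their ratio is even over odd harmonic
    amplitude sums; ML alternates left/right and uses odd over even.
    """
    cfg = cfg or SpectralConfig()
    out = {}
    for ax in _DIRS:
        amps = _harmonic_amplitudes(
            epoch.axis(ax), epoch.fs, stride_freq, cfg.n_harmonics_hr
        )
        even = amps[1::2].sum()
        odd = amps[0::2].sum()
        if ax == "ML":
            ratio = odd / even if even > 0 else np.inf
        else:
            ratio = even / odd if odd > 0 else np.inf
        out[f"harmonic_ratio_{ax}"] = float(ratio)
    return out


def index_of_harmonicity(epoch: AccelEpoch, stride_freq: float,
                         cfg: SpectralConfig | None = None) -> dict:
    """Power at the fundamental over the cumulative power of the
    fundamental plus the first 5 higher harmonics (in [0, 1]).

    The movement fundamental is the step frequency for AP/V and the stride
    frequency for ML.
    """
    cfg = cfg or SpectralConfig()
    out = {}
    for ax in _DIRS:
        f0 = stride_freq if ax == "ML" else 2.0 * stride_freq
        amps = _harmonic_amplitudes(
            epoch.axis(ax), epoch.fs, f0, cfg.n_harmonics_ih
        )
        power = amps ** 2
        total = power.sum()
        out[f"index_harmonicity_{ax}"] = (
            float(power[0] / total) if total > 0 else 0.0
        )
    return out


def _welch(x: np.ndarray, fs: float, cfg: SpectralConfig):
    nper = int(cfg.welch_segment_s * fs)
    nper = min(nper, len(x))
    return welch(x - x.mean(), fs=fs, nperseg=nper,
                 noverlap=int(cfg.welch_overlap * nper))


def spectral_features(epoch: AccelEpoch,
                      cfg: SpectralConfig | None = None) -> dict:
    """Welch-spectrum descriptors per direction.

    Dominant frequency and normalized amplitude of the 0.5-3 Hz peak, full
    width at half the peak, log-log spectral slope over 0.5-10 Hz, and the
    band holding the central 98% of 0-10 Hz power.
    """
    cfg = cfg or SpectralConfig()
    out = {}
    for ax in _DIRS:
        f, p = _welch(epoch.axis(ax), epoch.fs, cfg)
        lo, hi = cfg.dominant_band
        band = (f >= lo) & (f <= hi)
        pb, pf = cfg.power_band
        power_band = (f >= pb) & (f <= pf)
        total = np.trapezoid(p[power_band], f[power_band])
        if not band.any() or p[band].max() == 0 or total == 0:
            for k in ("dominant_freq", "spectral_amplitude", "spectral_width",
                      "spectral_slope", "spectral_range"):
                out[f"{k}_{ax}"] = np.nan
            continue
        i_peak = int(np.argmax(np.where(band, p, 0.0)))
        f_dom, p_dom = f[i_peak], p[i_peak]
        out[f"dominant_freq_{ax}"] = float(f_dom)
        df = f[1] - f[0]
        out[f"spectral_amplitude_{ax}"] = float(p_dom * df / total)
        # full width at half maximum around the dominant peak
        half = p_dom / 2.0
        i_l = i_peak
        while i_l > 0 and p[i_l] > half:
            i_l -= 1
        i_r = i_peak
        while i_r < len(p) - 1 and p[i_r] > half:
            i_r += 1
        out[f"spectral_width_{ax}"] = float(f[i_r] - f[i_l])
        sl_band = (f >= cfg.slope_band[0]) & (f <= cfg.slope_band[1]) & (p > 0)
        slope = np.polyfit(np.log(f[sl_band]), np.log(p[sl_band]), 1)[0]
        out[f"spectral_slope_{ax}"] = float(slope)
        # central-98% power band
        cum = np.cumsum(p[power_band])
        cum = cum / cum[-1]
        tail = (1.0 - cfg.range_central) / 2.0
        fb = f[power_band]
        f_lo = fb[np.searchsorted(cum, tail)]
        f_hi = fb[min(np.searchsorted(cum, 1.0 - tail), len(fb) - 1)]
        out[f"spectral_range_{ax}"] = float(f_hi - f_lo)
    return out


def low_freq_percentage(epoch: AccelEpoch,
                        cfg: SpectralConfig | None = None) -> dict:
    """Percentage of 0-10 Hz spectral power below 0.7 Hz, per direction
    and for the vector magnitude."""
    cfg = cfg or SpectralConfig()
    out = {}
    sigs = {ax: epoch.axis(ax) for ax in _DIRS}
    sigs["mag"] = _magnitude(epoch)
    for name, x in sigs.items():
        f, p = _welch(x, epoch.fs, cfg)
        band = (f > 0) & (f <= cfg.power_band[1])
        total = np.trapezoid(p[band], f[band])
        low = band & (f < cfg.lfp_cutoff)
        val = 100.0 * np.trapezoid(p[low], f[low]) / total if total > 0 else np.nan
        out[f"low_freq_pct_{name}"] = float(val)
    return out


# ---------------------------------------------------------------------------
# Lyapunov exponents
# ---------------------------------------------------------------------------

def _delay_embed_1d(x: np.ndarray, lag: int, dim: int) -> np.ndarray:
    rows = len(x) - (dim - 1) * lag
    if rows < 2:
        raise DataError("series too short for the requested embedding")
    return np.stack([x[i * lag: i * lag + rows] for i in range(dim)], axis=1)


def _series_lag(x: np.ndarray, fs: float, max_lag_s: float = 1.0) -> int:
    """Embedding lag of a scalar series from its AMI flattening point."""
    max_lag = min(int(max_lag_s * fs), (len(x) - 2) // 2)
    ami = np.array([
        _mi_nats(x[: len(x) - tau], x[tau:], 32) for tau in range(max_lag + 1)
    ])
    return select_lag(AMICurve(lags=np.arange(max_lag + 1), ami=ami))


def lyapunov_rosenstein(
    x: np.ndarray,
    fs: float,
    lag: int | None = None,
    dim: int = 5,
    theiler_s: float = 0.5,
    fit_range_s: tuple[float, float] = (0.0, 0.25),
    horizon_s: float | None = None,
    min_sep_factor: float = 1e-8,
) -> float:
    """Largest Lyapunov exponent (1/s) by the mean log nearest-neighbor
    divergence method.

    Each embedded point is paired with its nearest neighbor outside a
    temporal exclusion window; the slope of the averaged log-divergence
    curve over ``fit_range_s`` (default the early linear region, about
    half a stride for gait data) is the exponent.  Neighbors closer than
    ``min_sep_factor`` times the attractor extent are excluded — exact
    recurrences of a periodic orbit otherwise make the divergence curve
    track floating-point noise instead of dynamics.
    """
    x = np.asarray(x, dtype=float)
    lag = lag or _series_lag(x, fs)
    E = _delay_embed_1d(x, lag, dim)
    n = len(E)
    theiler = max(1, int(theiler_s * fs))
    horizon = int((horizon_s or (fit_range_s[1] * 2 + 1.0 / fs)) * fs)
    horizon = max(horizon, int(fit_range_s[1] * fs) + 1)
    usable = n - horizon
    if usable < theiler + 2:
        raise DataError("insufficient neighbors for Rosenstein estimate")
    D = cdist(E[:usable], E[:usable])
    ii = np.arange(usable)
    D[np.abs(ii[:, None] - ii[None, :]) <= theiler] = np.inf
    ext = float(np.linalg.norm(E.max(axis=0) - E.min(axis=0)))
    D[D < min_sep_factor * ext] = np.inf
    nn = np.argmin(D, axis=1)
    ks = np.arange(horizon + 1)
    logs = np.full((usable, len(ks)), np.nan)
    for i in range(usable):
        j = nn[i]
        if not np.isfinite(D[i, j]):
            continue
        d = np.linalg.norm(E[i:i + horizon + 1] - E[j:j + horizon + 1], axis=1)
        good = d > 0
        logs[i, good] = np.log(d[good])
    with np.errstate(all="ignore"):
        curve = np.nanmean(logs, axis=0)
    t = ks / fs
    fit = (t >= fit_range_s[0]) & (t <= fit_range_s[1]) & np.isfinite(curve)
    if fit.sum() < 2:
        raise DataError("divergence curve too short to fit")
    return float(np.polyfit(t[fit], curve[fit], 1)[0])


def lyapunov_wolf(
    x: np.ndarray,
    fs: float,
    lag: int | None = None,
    dim: int = 5,
    evolve_s: float = 0.1,
    theiler_s: float = 0.5,
    min_sep_factor: float = 1e-3,
    max_sep_factor: float = 0.1,
) -> float:
    """Largest Lyapunov exponent (1/s) by trajectory following with
    replacement (Wolf's algorithm).

    A fiducial trajectory is followed; the separation from a nearby
    trajectory is evolved for ``evolve_s`` seconds, its log growth is
    accumulated, and the comparison point is replaced by the nearest point
    within the admissible separation band.
    """
    x = np.asarray(x, dtype=float)
    lag = lag or _series_lag(x, fs)
    E = _delay_embed_1d(x, lag, dim)
    n = len(E)
    m = max(1, int(evolve_s * fs))
    theiler = max(1, int(theiler_s * fs))
    ext = float(np.linalg.norm(E.max(axis=0) - E.min(axis=0)))
    d_min, d_max = min_sep_factor * ext, max_sep_factor * ext

    def find_neighbor(i):
        d = np.linalg.norm(E - E[i], axis=1)
        d[np.abs(np.arange(n) - i) <= theiler] = np.inf
        d[np.arange(n) >= n - m] = np.inf
        d[(d <= d_min) | (d > d_max)] = np.inf
        j = int(np.argmin(d))
        return (j, d[j]) if np.isfinite(d[j]) else (None, None)

    total_log, total_t = 0.0, 0.0
    i = 0
    j, L = find_neighbor(i)
    while i + m < n:
        if j is None:
            i += m
            if i + m >= n:
                break
            j, L = find_neighbor(i)
            continue
        L1 = float(np.linalg.norm(E[i + m] - E[j + m]))
        if L1 > 0 and L > 0:
            total_log += np.log(L1 / L)
            total_t += m / fs
        i += m
        if i + m >= n:
            break
        # replacement: nearest admissible point to the evolved fiducial
        j, L = find_neighbor(i)
    if total_t == 0:
        raise DataError("insufficient neighbors for Wolf estimate")
    return float(total_log / total_t)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def compute_features(
    epoch: AccelEpoch,
    cycles: StepCycleSet,
    cfg: SpectralConfig | None = None,
    include_lyapunov: bool = True,
) -> dict:
    """Full conventional-feature vector for one epoch.

    Lyapunov exponents (Rosenstein and Wolf, raw and per stride, per
    direction and vector magnitude) dominate the runtime and can be
    switched off for quick passes.
    """
    cfg = cfg or SpectralConfig()
    out = basic_stats(epoch)
    reg = stride_regularity(epoch, cycles)
    out.update(reg)
    stride_freq = reg["stride_frequency"]
    out.update(harmonic_ratio(epoch, stride_freq, cfg))
    out.update(index_of_harmonicity(epoch, stride_freq, cfg))
    out.update(spectral_features(epoch, cfg))
    out.update(low_freq_percentage(epoch, cfg))
    if include_lyapunov:
        stride_t = reg["stride_time"]
        sigs = {ax: epoch.axis(ax) for ax in _DIRS}
        sigs["mag"] = _magnitude(epoch)
        for name, x in sigs.items():
            try:
                lam_r = lyapunov_rosenstein(
                    x, epoch.fs, theiler_s=stride_t,
                    fit_range_s=(0.0, 0.5 * stride_t),
                )
            except DataError:
                lam_r = np.nan
            try:
                lam_w = lyapunov_wolf(x, epoch.fs, theiler_s=stride_t)
            except DataError:
                lam_w = np.nan
            out[f"lyap_rosenstein_{name}"] = lam_r
            out[f"lyap_wolf_{name}"] = lam_w
            out[f"lyap_rosenstein_stride_{name}"] = lam_r * stride_t
            out[f"lyap_wolf_stride_{name}"] = lam_w * stride_t
    return out


def subject_features(feature_dicts: list[dict]) -> dict:
    """Median across an individual's epoch feature vectors (ignoring NaN),
    mirroring the subject-level PGME aggregation."""
    if not feature_dicts:
        raise DataError("no epoch feature vectors supplied")
    keys = feature_dicts[0].keys()
    with np.errstate(all="ignore"):
        return {
            k: float(np.nanmedian([d[k] for d in feature_dicts])) for k in keys
        }
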