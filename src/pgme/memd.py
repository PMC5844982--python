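"""Multivariate empirical mode decomposition (MEMD) and coarse-graining.

A d-channel signal is decomposed into intrinsic mode functions (IMFs) by
iterative sifting: the signal is projected onto a set of low-discrepancy
direction vectors on the unit (d-1)-sphere, extrema of each projection
define multichannel cubic-spline envelopes, and the mean envelope over all
directions is subtracted until the candidate is an IMF.  IMFs come out
ordered from high to low frequency; the leftover slow trend is the
residual.

Coarse-grained versions of the dynamics at scale k are the partial sums
of IMFs from k upwards plus the residual: scale 1 returns the original
signal, larger scales progressively low-pass filtered versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks
from scipy.stats import norm as _norm

from .exceptions import DataError, DegenerateInputError

__all__ = [
    "IMFDecomposition",
    "CoarseGrained",
    "memd",
    "coarse_grain",
    "detrend_memd",
    "zero_crossing_freq",
]

#: default number of projection directions
N_DIRS = 64
#: hard cap on sifting iterations per IMF
MAX_SIFT = 15
#: mean-envelope / candidate norm ratio below which a sift pass counts as
#: converged; two consecutive converged passes stop the sift
STOP_RATIO = 0.075


@dataclass
class IMFDecomposition:
    """Ordered high-to-low-frequency IMFs plus residual for one signal.

    ``imfs[k]`` and ``residual`` are (N, d) arrays; their sum reproduces
    the input to floating-point accuracy (telescoping construction).
    """

    imfs: list[np.ndarray]
    residual: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass
class CoarseGrained:
    """Low-pass version of the dynamics at one temporal scale."""

    series: np.ndarray | None
    scale: int
    missing: bool = False


# ---------------------------------------------------------------------------
# direction set
# ---------------------------------------------------------------------------

def _radical_inverse(base: int, n: int) -> np.ndarray:
    """Van der Corput radical-inverse sequence for indices 1..n."""
    idx = np.arange(1, n + 1)
    out = np.zeros(n)
    f = 1.0 / base
    work = idx.copy()
    while work.max() > 0:
        out += f * (work % base)
        work //= base
        f /= base
    return out


_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37)


def hammersley_directions(n_dirs: int, d: int) -> np.ndarray:
    """Deterministic low-discrepancy direction vectors on the unit
    (d-1)-sphere.

    A Hammersley point set in the unit hypercube is pushed through the
    inverse Gaussian CDF coordinate-wise and normalized; uniform quasi-random
    points on the sphere result because the multivariate normal is
    rotationally symmetric.
    """
    pts = np.empty((n_dirs, d))
    pts[:, 0] = (np.arange(n_dirs) + 0.5) / n_dirs
    for j in range(1, d):
        pts[:, j] = _radical_inverse(_PRIMES[(j - 1) % len(_PRIMES)], n_dirs)
    pts = np.clip(pts, 1e-12, 1 - 1e-12)
    z = _norm.ppf(pts)
    return z / np.linalg.norm(z, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# sifting
# ---------------------------------------------------------------------------

def _mirror_knots(idx: np.ndarray, values: np.ndarray, n: int):
    """Extend extrema knots by reflecting up to 2 extrema across each
    signal end, so envelope splines do not swing wildly at the borders."""
    left_t, left_v = [], []
    for j in range(min(3, len(idx))):
        t = -int(idx[j])
        if t < idx[0]:
            left_t.append(t)
            left_v.append(values[j])
        if len(left_t) == 2:
            break
    right_t, right_v = [], []
    for j in range(1, min(4, len(idx) + 1)):
        t = 2 * (n - 1) - int(idx[-j])
        if t > idx[-1]:
            right_t.append(t)
            right_v.append(values[-j])
        if len(right_t) == 2:
            break
    ts = list(sorted(left_t)) + list(idx) + list(right_t)
    vs = [left_v[i] for i in np.argsort(left_t)] + list(values) + right_v
    return np.asarray(ts, dtype=float), np.asarray(vs)


def _envelope(signal: np.ndarray, extrema: np.ndarray) -> np.ndarray | None:
    """Natural cubic-spline envelope through the multichannel signal at the
    given extrema sample indices (mirror-extended)."""
    if len(extrema) < 2:
        return None
    n = signal.shape[0]
    ts, vs = _mirror_knots(extrema, signal[extrema], n)
    cs = CubicSpline(ts, vs, bc_type="natural", axis=0)
    return cs(np.arange(n))


@njit(cache=True)
def _local_maxima_nb(p):
    """Strict local maxima; plateaus collapse to their midpoint."""
    n = p.shape[0]
    out = np.empty(n, np.int64)
    m = 0
    i = 1
    while i < n - 1:
        if p[i - 1] < p[i]:
            j = i
            while j < n - 1 and p[j + 1] == p[j]:
                j += 1
            if j < n - 1 and p[j + 1] < p[j]:
                out[m] = (i + j) // 2
                m += 1
                i = j + 1
                continue
            i = j + 1
        else:
            i += 1
    return out[:m]


@njit(cache=True)
def _natural_spline_eval(ts, vs, n):
    """Natural cubic spline through (ts, vs[:, c]) per channel, evaluated
    at the integer grid 0..n-1 (ts must bracket that range)."""
    m = ts.shape[0]
    d = vs.shape[1]
    out = np.empty((n, d))
    if m == 2:
        for k in range(n):
            w = (k - ts[0]) / (ts[1] - ts[0])
            for c in range(d):
                out[k, c] = vs[0, c] + w * (vs[1, c] - vs[0, c])
        return out
    h = ts[1:] - ts[:-1]
    M = np.zeros((m, d))
    nint = m - 2
    b = np.empty(nint)
    cdiag = np.empty(nint)
    rhs = np.empty((nint, d))
    for i in range(nint):
        b[i] = 2.0 * (h[i] + h[i + 1])
        cdiag[i] = h[i + 1]
        for c in range(d):
            rhs[i, c] = 6.0 * ((vs[i + 2, c] - vs[i + 1, c]) / h[i + 1]
                               - (vs[i + 1, c] - vs[i, c]) / h[i])
    for i in range(1, nint):           # Thomas forward sweep
        w = h[i] / b[i - 1]
        b[i] -= w * cdiag[i - 1]
        for c in range(d):
            rhs[i, c] -= w * rhs[i - 1, c]
    for c in range(d):                 # back substitution (natural ends = 0)
        M[nint, c] = rhs[nint - 1, c] / b[nint - 1]
    for i in range(nint - 2, -1, -1):
        for c in range(d):
            M[i + 1, c] = (rhs[i, c] - cdiag[i] * M[i + 2, c]) / b[i]
    s = 0
    for k in range(n):
        x = float(k)
        while s < m - 2 and x > ts[s + 1]:
            s += 1
        hh = ts[s + 1] - ts[s]
        A = (ts[s + 1] - x) / hh
        B = (x - ts[s]) / hh
        f = hh * hh / 6.0
        for c in range(d):
            out[k, c] = (A * vs[s, c] + B * vs[s + 1, c]
                         + ((A ** 3 - A) * M[s, c]
                            + (B ** 3 - B) * M[s + 1, c]) * f)
    return out


@njit(cache=True)
def _env_one_nb(sig, idx, n):
    """Mirror-extend extrema by 2 on each side and spline the envelope."""
    m = idx.shape[0]
    left_t = np.empty(2)
    left_i = np.empty(2, np.int64)
    nl = 0
    for j in range(min(3, m)):
        t = -float(idx[j])
        if t < idx[0]:
            left_t[nl] = t
            left_i[nl] = idx[j]
            nl += 1
            if nl == 2:
                break
    right_t = np.empty(2)
    right_i = np.empty(2, np.int64)
    nr = 0
    for j in range(1, min(3, m) + 1):
        t = 2.0 * (n - 1) - idx[m - j]
        if t > idx[m - 1]:
            right_t[nr] = t
            right_i[nr] = idx[m - j]
            nr += 1
            if nr == 2:
                break
    mt = nl + m + nr
    ts = np.empty(mt)
    vs = np.empty((mt, sig.shape[1]))
    for j in range(nl):                 # left ts were collected decreasing
        ts[nl - 1 - j] = left_t[j]
        vs[nl - 1 - j] = sig[left_i[j]]
    for j in range(m):
        ts[nl + j] = idx[j]
        vs[nl + j] = sig[idx[j]]
    for j in range(nr):
        ts[nl + m + j] = right_t[j]
        vs[nl + m + j] = sig[right_i[j]]
    return _natural_spline_eval(ts, vs, n)


@njit(cache=True)
def _mean_envelope_nb(h, dirs_t):
    """Direction-averaged (max+min)/2 envelope; numba hot path.

    Returns (envelope, directions used, max extrema count over directions).
    """
    n, d = h.shape
    n_dirs = dirs_t.shape[1]
    proj = np.dot(h, dirs_t)
    acc = np.zeros((n, d))
    used = 0
    max_extrema = 0
    for i in range(n_dirs):
        p = np.ascontiguousarray(proj[:, i])
        pk_max = _local_maxima_nb(p)
        pk_min = _local_maxima_nb(-p)
        tot = pk_max.shape[0] + pk_min.shape[0]
        if tot > max_extrema:
            max_extrema = tot
        if pk_max.shape[0] < 2 or pk_min.shape[0] < 2:
            continue
        acc += 0.5 * (_env_one_nb(h, pk_max, n) + _env_one_nb(h, pk_min, n))
        used += 1
    return acc, used, max_extrema


@njit(cache=True)
def _max_proj_extrema_nb(h, dirs_t, stop_at=3):
    """Largest extrema count over projections, with early exit."""
    proj = np.dot(h, dirs_t)
    best = 0
    for i in range(dirs_t.shape[1]):
        p = np.ascontiguousarray(proj[:, i])
        tot = _local_maxima_nb(p).shape[0] + _local_maxima_nb(-p).shape[0]
        if tot > best:
            best = tot
        if best >= stop_at:
            return best
    return best


def _mean_envelope(h: np.ndarray, dirs: np.ndarray):
    """Average of (max+min)/2 envelopes over all projection directions.

    Returns (mean_envelope | None, max extrema count over directions).
    """
    acc, used, max_extrema = _mean_envelope_nb(
        np.ascontiguousarray(h), np.ascontiguousarray(dirs.T)
    )
    if used == 0:
        return None, max_extrema
    return acc / used, max_extrema


def _mean_envelope_ref(h: np.ndarray, dirs: np.ndarray):
    """scipy-based reference for the numba envelope kernel (tests only)."""
    proj = h @ dirs.T
    acc = np.zeros_like(h)
    used = 0
    max_extrema = 0
    for i in range(dirs.shape[0]):
        p = proj[:, i]
        pk_max, _ = find_peaks(p)
        pk_min, _ = find_peaks(-p)
        max_extrema = max(max_extrema, len(pk_max) + len(pk_min))
        env_max = _envelope(h, pk_max)
        env_min = _envelope(h, pk_min)
        if env_max is None or env_min is None:
            continue
        acc += 0.5 * (env_max + env_min)
        used += 1
    if used == 0:
        return None, max_extrema
    return acc / used, max_extrema


def _count_channel_extrema(x: np.ndarray) -> int:
    """Extrema count of a single channel (interior sign changes of slope)."""
    d = np.diff(x)
    s = np.sign(d)
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1])) if len(s) > 1 else 0


def memd(
    signal: np.ndarray,
    n_dirs: int = N_DIRS,
    max_sift: int = MAX_SIFT,
    stop_ratio: float = STOP_RATIO,
    max_imfs: int | None = None,
) -> IMFDecomposition:
    """Decompose an (N, d) multichannel signal into IMFs plus residual.

    Parameters
    ----------
    signal : (N, d) array, d >= 2.
    n_dirs : number of low-discrepancy projection directions on the sphere.
    max_sift : hard cap on sifting iterations per IMF.
    stop_ratio : mean-envelope/candidate norm ratio; a sift pass below this
        on two consecutive passes ends the sift.
    max_imfs : stop after this many IMFs, lumping the rest into the
        residual (exact telescoping is preserved); ``meta['truncated']``
        records whether the remainder still looked oscillatory.

    Notes
    -----
    Sifting per IMF: project onto every direction, build multichannel
    cubic-spline envelopes through the signal at projected extrema (mirror
    boundary extension of 2 extrema), subtract the direction-averaged mean
    envelope, repeat.  Extraction ends when every projection of the
    remainder has fewer than 3 extrema.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise DataError("memd expects an (N, d) array with d >= 2 channels")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite values in memd input")
    for c in range(x.shape[1]):
        if _count_channel_extrema(x[:, c]) < 4:
            raise DegenerateInputError(
                f"channel {c} has fewer than 4 extrema; too featureless for MEMD"
            )

    dirs = hammersley_directions(n_dirs, x.shape[1])
    remainder = x.copy()
    imfs: list[np.ndarray] = []
    sift_counts: list[int] = []
    truncated = False

    while True:
        if max_imfs is not None and len(imfs) >= max_imfs:
            # remainder still oscillatory -> truncation, not exhaustion
            truncated = _max_proj_extrema_nb(
                np.ascontiguousarray(remainder), np.ascontiguousarray(dirs.T)
            ) >= 3
            break
        h = remainder.copy()
        prev_ok = False
        extracted = False
        n_sift = 0
        for _ in range(max_sift):
            m, n_ext = _mean_envelope(h, dirs)
            if m is None or n_ext < 3:
                break
            h = h - m
            n_sift += 1
            extracted = True
            ratio = np.linalg.norm(m) / max(np.linalg.norm(h) , 1e-300)
            ok = ratio < stop_ratio
            if ok and prev_ok:
                break
            prev_ok = ok
        if not extracted:
            break
        imfs.append(h)
        sift_counts.append(n_sift)
        remainder = remainder - h
        # residual test: fewer than 3 extrema in every projection
        if _max_proj_extrema_nb(
            np.ascontiguousarray(remainder), np.ascontiguousarray(dirs.T)
        ) < 3:
            break

    return IMFDecomposition(
        imfs=imfs,
        residual=remainder,
        meta={
            "n_dirs": n_dirs,
            "max_sift": max_sift,
            "stop_ratio": stop_ratio,
            "sift_counts": sift_counts,
            "truncated": truncated,
        },
    )


def coarse_grain(dec: IMFDecomposition, k: int) -> CoarseGrained:
    """Sum of IMFs k..M plus residual; scale 1 returns the original signal.

    If the decomposition holds fewer than k IMFs the scale is flagged
    missing rather than filled with zeros.  A truncated decomposition
    (``max_imfs`` reached with an oscillatory remainder) still yields every
    scale up to ``max_imfs`` exactly, by telescoping.
    """
    if k < 1:
        raise ValueError("scale k must be >= 1")
    truncated = dec.meta.get("truncated", False)
    # with truncation the residual itself is the k = n_imfs + 1 coarse level
    available = k <= dec.n_imfs or (truncated and k == dec.n_imfs + 1)
    if not available:
        return CoarseGrained(series=None, scale=k, missing=True)
    out = dec.residual.copy()
    for imf in dec.imfs[k - 1:]:
        out += imf
    return CoarseGrained(series=out, scale=k, missing=False)


def zero_crossing_freq(x: np.ndarray, fs: float) -> float:
    """Mean zero-crossing frequency (Hz) of an (N,) or (N, d) signal.

    Each pair of zero crossings corresponds to one oscillation period, so
    the rate is crossings / (2 * duration); channel values are averaged.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    n = x.shape[0]
    dur = n / fs
    freqs = []
    for c in range(x.shape[1]):
        s = np.sign(x[:, c])
        s = s[s != 0]
        crossings = int(np.sum(s[1:] != s[:-1])) if len(s) > 1 else 0
        freqs.append(crossings / (2.0 * dur))
    return float(np.mean(freqs))


def detrend_memd(
    signal: np.ndarray,
    fs: float,
    cutoff_hz: float = 0.5,
    n_dirs: int = N_DIRS,
    **memd_kwargs,
):
    """Remove the residual and every IMF slower than ``cutoff_hz``.

    Preserves intra-step oscillations (stride ~1 Hz, step ~2 Hz at normal
    walking) while removing integration drift and slow nonlinear trends.

    Returns
    -------
    detrended : (N, d) array
    report : dict with ``removed_imfs`` (indices, 0-based), ``imf_freqs``
        (Hz per IMF) and ``n_imfs``.
    """
    dec = memd(signal, n_dirs=n_dirs, **memd_kwargs)
    freqs = [zero_crossing_freq(imf, fs) for imf in dec.imfs]
    removed = [i for i, f in enumerate(freqs) if f < cutoff_hz]
    out = np.zeros_like(dec.residual)
    for i, imf in enumerate(dec.imfs):
        if i not in removed:
            out += imf
    report = {"removed_imfs": removed, "imf_freqs": freqs, "n_imfs": dec.n_imfs}
    return out, report
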