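"""Delay embedding of the tri-axial trunk dynamics.

The gait dynamics are reconstructed as two nested state spaces built from
the AP/ML/V channels: a 6-dimensional space stacking the three axes at
lags 0 and l, and a 9-dimensional space adding lag 2l.  The lag l is
chosen per epoch from the average mutual information (AMI) function of the
acceleration — the first lag at which the AMI decrease flattens below a
threshold (0.01 nats/sample by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, DegenerateInputError

__all__ = [
    "AMICurve",
    "EmbeddedPair",
    "average_mutual_information",
    "select_lag",
    "embed",
]


@dataclass
class AMICurve:
    """Average mutual information vs lag, axis-averaged, in nats."""

    lags: np.ndarray
    ami: np.ndarray
    per_axis: np.ndarray | None = None  # (3, n_lags) before averaging


@dataclass
class EmbeddedPair:
    """6-dim (X) and 9-dim (Y) delay embeddings sharing a row range.

    Row j of X holds the three axes at samples j and j+l; row j of Y adds
    sample j+2l.  Both are truncated to the common range j = 0..N-2l-1 so
    every Y row has an X counterpart (needed for the nested match counts of
    the entropy estimator).
    """

    X: np.ndarray
    Y: np.ndarray
    lag: int
    row_index: np.ndarray

    def __post_init__(self):
        if self.X.shape != (self.Y.shape[0], 6) or self.Y.shape[1] != 9:
            raise DataError("embedding shapes must be (T, 6) and (T, 9)")


def _mi_nats(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Mutual information of two series from an equal-width joint histogram."""
    h, _, _ = np.histogram2d(x, y, bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def average_mutual_information(
    channels: np.ndarray,
    max_lag: int = 100,
    bins: int = 32,
) -> AMICurve:
    """AMI curve of a (3, N) signal, averaged over the three axes.

    For each axis, MI between x(t) and x(t+tau) is estimated from a joint
    equal-width histogram with ``bins`` bins per margin (nats); the three
    curves are then averaged so a single common lag serves the
    multichannel embedding.  tau = 0 returns the binned marginal entropy,
    the maximum of each axis-wise curve.
    """
    x = np.asarray(channels, dtype=float)
    if hasattr(channels, "samples"):  # AccelEpoch passthrough
        x = np.asarray(channels.samples, dtype=float)
    if x.ndim != 2 or x.shape[0] != 3:
        raise DataError("expected a (3, N) channel matrix")
    n = x.shape[1]
    if n <= 2 * max_lag:
        raise DataError(f"need N > 2*max_lag (= {2 * max_lag}), got N = {n}")
    for c in range(3):
        if np.ptp(x[c]) == 0:
            raise DegenerateInputError(
                f"constant channel {c}: mutual information undefined"
            )
    lags = np.arange(max_lag + 1)
    curves = np.empty((3, len(lags)))
    for c in range(3):
        for tau in lags:
            a = x[c, : n - tau]
            b = x[c, tau:]
            curves[c, tau] = _mi_nats(a, b, bins)
    return AMICurve(lags=lags, ami=curves.mean(axis=0), per_axis=curves)


def select_lag(curve: AMICurve, threshold: float = 0.01) -> int:
    """Smallest lag at which the AMI decrease flattens below ``threshold``
    nats/sample; falls back to the first local minimum (then the global
    minimum) if no lag qualifies.  Always >= 1.
    """
    ami = np.asarray(curve.ami, dtype=float)
    if len(ami) < 2:
        raise DataError("AMI curve needs at least 2 lags")
    dec = ami[:-1] - ami[1:]  # decrease at tau = 1..max_lag
    hits = np.where(dec < threshold)[0]
    if len(hits) > 0:
        return int(hits[0] + 1)
    interior = np.where((ami[1:-1] < ami[:-2]) & (ami[1:-1] <= ami[2:]))[0]
    if len(interior) > 0:
        return int(interior[0] + 1)
    return max(1, int(np.argmin(ami)))


def embed(channels: np.ndarray, lag: int) -> EmbeddedPair:
    """Build the nested 6- and 9-dimensional delay embeddings.

    Row j (j = 0..N-2l-1) of Y is
    (AP_j, ML_j, V_j, AP_{j+l}, ML_{j+l}, V_{j+l}, AP_{j+2l}, ML_{j+2l},
    V_{j+2l}); X is its first six coordinates.
    """
    x = np.asarray(channels, dtype=float)
    if hasattr(channels, "samples"):
        x = np.asarray(channels.samples, dtype=float)
    if x.ndim != 2 or x.shape[0] != 3:
        raise DataError("expected a (3, N) channel matrix")
    if lag < 1:
        raise DataError("lag must be >= 1")
    n = x.shape[1]
    t = n - 2 * lag
    if t < 1:
        raise DataError(f"epoch too short for lag {lag}: N = {n} <= 2*lag")
    blocks = [x[:, 0:t], x[:, lag:lag + t], x[:, 2 * lag:2 * lag + t]]
    Y = np.concatenate([b.T for b in blocks], axis=1)
    return EmbeddedPair(X=Y[:, :6].copy(), Y=Y, lag=int(lag),
                        row_index=np.arange(t))
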