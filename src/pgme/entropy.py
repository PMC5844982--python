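"""Phase-dependent generalized multiscale entropy (PGME).

The generalized sample entropy qSaEn of a signal is
``log_q(n_x) - log_q(n_y)``, where n_x and n_y are the normalized counts
of point pairs closer than a tolerance r in the 6- and 9-dimensional
reconstructed state spaces, and log_q is the Tsallis q-logarithm
``(n^(1-q) - 1) / (1 - q)`` (natural log in the q -> 1 limit, where qSaEn
reduces to the conventional sample entropy).  q < 1 reweights the count
ratio so regular and irregular regimes are penalized differently, which
exposes phase-dependent irregularity changes invisible to ordinary sample
entropy.

PGME evaluates qSaEn on the coarse-grained (MEMD partial-sum) versions of
the embedded dynamics, restricted to step-phase windows, over a grid of
scales k, step phases and q orders — one 6 x 5 x 21 tensor per epoch, and
the element-wise median across an individual's epochs at subject level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import memd as memd_mod
from .embedding import average_mutual_information, embed, select_lag
from .exceptions import DataError
from .signal_prep import AccelEpoch, StepCycleSet, phase_windows

__all__ = [
    "EntropyConfig",
    "MatchCounts",
    "PGMETensor",
    "qlog",
    "count_matches",
    "qsaen",
    "pgme_epoch",
    "pgme_subject",
]


def _default_q_grid() -> np.ndarray:
    return np.linspace(-1.0, 1.0, 21)


@dataclass
class EntropyConfig:
    """Parameters of the PGME estimator.

    r_factor multiplies the mean of the per-axis SDs of the raw epoch to
    give the match tolerance r (held fixed across scales, phases and q).
    The q grid spans [-1, 1] in steps of 0.1; the Theiler window excludes
    temporally adjacent pairs from the counts (0 = off).
    """

    r_factor: float = 0.3
    q_grid: np.ndarray = field(default_factory=_default_q_grid)
    scales: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    phases: tuple[int, ...] = (0, 20, 40, 60, 80)
    theiler: int = 0
    phase_width: float = 0.10
    min_valid_cycles: int = 10
    #: "within": both template and candidate rows inside the phase window;
    #: "anywhere": templates in the window, candidates anywhere
    match_mode: str = "within"
    # embedding / MEMD knobs carried along for pipeline convenience
    ami_max_lag: int = 100
    ami_bins: int = 32
    lag_threshold: float = 0.01
    n_dirs: int = memd_mod.N_DIRS

    def __post_init__(self):
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")


@dataclass
class MatchCounts:
    """Normalized pair-match probabilities in the two state spaces.

    The max-norm and the nested column structure (X = first six Y
    coordinates over a shared row range) guarantee 0 <= n_y <= n_x <= 1.
    A count with n_y = 0 is undefined and propagates as missing.
    """

    n_x: float
    n_y: float
    pairs_evaluated: int

    @property
    def defined(self) -> bool:
        return self.n_y > 0


def qlog(n, q) -> np.ndarray | float:
    """Tsallis q-order logarithm (n^(1-q) - 1)/(1-q); ln(n) at q = 1.

    Broadcasts over arrays of n and/or q; raises on non-positive n.
    """
    n_arr = np.asarray(n, dtype=float)
    q_arr = np.asarray(q, dtype=float)
    if np.any(n_arr <= 0):
        raise ValueError("q-logarithm requires positive argument")
    n_b, q_b = np.broadcast_arrays(n_arr, q_arr)
    out = np.empty(n_b.shape)
    lim = np.abs(q_b - 1.0) < 1e-9
    out[lim] = np.log(n_b[lim])
    nl = ~lim
    out[nl] = (n_b[nl] ** (1.0 - q_b[nl]) - 1.0) / (1.0 - q_b[nl])
    if out.ndim == 0:
        return float(out)
    return out


def count_matches(
    X: np.ndarray,
    Y: np.ndarray,
    index_set: np.ndarray,
    r: float,
    theiler: int = 0,
    match_mode: str = "within",
) -> MatchCounts:
    """Fraction of admissible point pairs with max-norm distance <= r, in
    the 6-dim (n_x) and 9-dim (n_y) spaces, over an identical denominator.

    Pairs (i, j) are rows of the embeddings indexed by ``index_set``
    (sample indices), with i != j and |i - j| > theiler.  With
    ``match_mode='anywhere'`` templates come from the window but
    candidates from the whole row range.
    """
    idx = np.asarray(index_set, dtype=int)
    if r <= 0:
        raise ValueError("match radius r must be positive")
    if len(idx) < 2:
        raise DataError("fewer than 2 points in index set")
    if match_mode == "within":
        rows_i = rows_j = idx
        dx = squareform(pdist(X[idx], metric="chebyshev"))
        dy = squareform(pdist(Y[idx], metric="chebyshev"))
        sep = np.abs(idx[:, None] - idx[None, :])
        admissible = sep > theiler  # also kills the diagonal (i == j)
    elif match_mode == "anywhere":
        from scipy.spatial.distance import cdist

        rows_i, rows_j = idx, np.arange(X.shape[0])
        dx = cdist(X[rows_i], X, metric="chebyshev")
        dy = cdist(Y[rows_i], Y, metric="chebyshev")
        sep = np.abs(rows_i[:, None] - rows_j[None, :])
        admissible = sep > theiler
    else:
        raise ValueError(f"unknown match_mode {match_mode!r}")
    denom = int(admissible.sum())
    if denom == 0:
        raise DataError("no admissible pairs (Theiler window too wide)")
    n_x = float(np.sum((dx <= r) & admissible)) / denom
    n_y = float(np.sum((dy <= r) & admissible)) / denom
    return MatchCounts(n_x=n_x, n_y=n_y, pairs_evaluated=denom)


def qsaen(counts: MatchCounts, q) -> np.ndarray | float:
    """Generalized sample entropy log_q(n_x) - log_q(n_y).

    At q = 1 this is ln(n_x / n_y), the conventional sample entropy.
    Returns NaN where the counts are undefined (n_y = 0).
    """
    if not counts.defined:
        q_arr = np.asarray(q, dtype=float)
        return np.nan if q_arr.ndim == 0 else np.full(q_arr.shape, np.nan)
    return qlog(counts.n_x, q) - qlog(counts.n_y, q)


@dataclass
class PGMETensor:
    """qSaEn values on the (scale, phase, q) grid; NaN marks missing cells."""

    values: np.ndarray
    scales: tuple[int, ...]
    phases: tuple[int, ...]
    q_grid: np.ndarray
    level: str = "epoch"  # or "subject"
    meta: dict = field(default_factory=dict)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def cell(self, scale: int, phase: int, q: float) -> float:
        k = self.scales.index(scale)
        p = self.phases.index(phase)
        iq = int(np.argmin(np.abs(self.q_grid - q)))
        return float(self.values[k, p, iq])

    def to_long_dataframe(self, subject: str = "") -> pd.DataFrame:
        rows = []
        for a, k in enumerate(self.scales):
            for b, p in enumerate(self.phases):
                for c, q in enumerate(self.q_grid):
                    v = self.values[a, b, c]
                    rows.append((subject, k, p, q, v, not np.isfinite(v)))
        return pd.DataFrame(
            rows, columns=["subject", "scale", "phase", "q", "value", "missing"]
        )


def pgme_epoch(
    epoch: AccelEpoch,
    cycles: StepCycleSet,
    cfg: EntropyConfig | None = None,
) -> PGMETensor:
    """PGME tensor of one accepted walking epoch.

    Pipeline: embedding lag l from the AMI of the raw acceleration; 9-dim
    delay embedding Y; MEMD of Y; per scale k the coarse-grained dynamics
    (partial IMF sum) give the 9-dim space and its first six columns the
    6-dim space; the tolerance r = r_factor * mean(SD_AP, SD_ML, SD_V) of
    the raw epoch; per phase window, matches are counted once and the
    whole q grid is evaluated from the shared counts (counts do not depend
    on q).  Cells at scales beyond the IMF count, or with undefined
    counts, are NaN.
    """
    cfg = cfg or EntropyConfig()
    if cycles.n_valid < cfg.min_valid_cycles:
        raise DataError(
            f"epoch has {cycles.n_valid} valid cycles; "
            f"need >= {cfg.min_valid_cycles}"
        )
    curve = average_mutual_information(
        epoch.samples, max_lag=cfg.ami_max_lag, bins=cfg.ami_bins
    )
    lag = select_lag(curve, threshold=cfg.lag_threshold)
    pair = embed(epoch.samples, lag)
    max_scale = max(cfg.scales)
    dec = memd_mod.memd(pair.Y, n_dirs=cfg.n_dirs, max_imfs=max_scale - 1)
    r = cfg.r_factor * float(np.mean(epoch.samples.std(axis=1)))
    windows = phase_windows(
        cycles, phases=cfg.phases, width=cfg.phase_width,
        n_samples=epoch.n_samples,
    )
    t_rows = pair.Y.shape[0]
    nq = len(cfg.q_grid)
    values = np.full((len(cfg.scales), len(cfg.phases), nq), np.nan)
    for a, k in enumerate(cfg.scales):
        cg = memd_mod.coarse_grain(dec, k)
        if cg.missing:
            continue
        Yk = cg.series
        Xk = Yk[:, :6]
        for b, p in enumerate(cfg.phases):
            idx = windows.index_sets[int(p)]
            idx = idx[idx < t_rows]
            if len(idx) < 2:
                continue
            try:
                counts = count_matches(
                    Xk, Yk, idx, r, theiler=cfg.theiler,
                    match_mode=cfg.match_mode,
                )
            except DataError:
                continue
            values[a, b, :] = qsaen(counts, cfg.q_grid)
    return PGMETensor(
        values=values, scales=tuple(cfg.scales), phases=tuple(cfg.phases),
        q_grid=cfg.q_grid, level="epoch",
        meta={"lag": lag, "r": r, "n_imfs": dec.n_imfs},
    )


def pgme_subject(tensors: list[PGMETensor]) -> PGMETensor:
    """Element-wise median over an individual's epoch tensors.

    Missing cells are ignored; a cell stays missing when more than half of
    the epochs miss it.
    """
    if not tensors:
        raise DataError("pgme_subject requires at least one epoch tensor")
    first = tensors[0]
    stack = np.stack([t.values for t in tensors])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(stack, axis=0)
    frac_missing = np.mean(~np.isfinite(stack), axis=0)
    med[frac_missing > 0.5] = np.nan
    return PGMETensor(
        values=med, scales=first.scales, phases=first.phases,
        q_grid=first.q_grid, level="subject",
        meta={"n_epochs": len(tensors)},
    )
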