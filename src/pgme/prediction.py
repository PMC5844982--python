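"""PLS-based fall-prediction and group-contrast pipeline.

Subjects are matched faller / non-faller pairs.  Features (PGME cells,
conventional gait features, demographics) are Z-scored on training data
only, projected onto latent variables by NIPALS partial least squares, and
classified by linear discriminant analysis on the scores.  Feature
importance is ranked by target-projection (TP) loadings; backward feature
elimination drops, at each round, the feature whose removal minimizes the
internal cross-validation error.  Models are compared across 500 (or
fewer) stratified pair-preserving holdouts with percentile-bootstrap
confidence intervals, and by the small-sample Akaike criterion (AICc) with
relative likelihoods.  Faller vs non-faller PGME contrasts use Wilcoxon
rank-sum tests per (scale, phase, q) cell with Benjamini-Hochberg FDR
control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .entropy import PGMETensor
from .exceptions import ConfigurationError, DataError

__all__ = [
    "CohortTable",
    "PLSModel",
    "PerformanceReport",
    "make_holdouts",
    "nipals_pls",
    "fit_plsda",
    "predict_plsda",
    "tp_loadings",
    "backward_select",
    "confusion_rates",
    "evaluate_holdouts",
    "bootstrap_ci",
    "aicc",
    "aicc_compare",
    "group_compare",
]


@dataclass
class CohortTable:
    """Subject-by-feature matrix with faller labels and matched-pair ids."""

    features: pd.DataFrame            # index: subject_id
    labels: pd.Series                 # 1 = faller
    pair_id: pd.Series

    def __post_init__(self):
        counts = pd.crosstab(self.pair_id, self.labels)
        if not ((counts == 1).all().all() and set(counts.columns) == {0, 1}):
            raise DataError(
                "each pair_id must group exactly one faller and one non-faller"
            )


@dataclass
class PLSModel:
    """Fitted NIPALS PLS latent structure with an LDA discriminant."""

    weights: np.ndarray               # (p, A)
    loadings: np.ndarray              # (p, A)
    y_loadings: np.ndarray            # (A,)
    scores: np.ndarray                # (n, A) training scores
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray                  # regression vector in (scaled) x space
    n_components: int
    feature_names: list[str]
    scale_mean: np.ndarray | None = None   # Z-scoring statistics (train only)
    scale_sd: np.ndarray | None = None
    lda: LinearDiscriminantAnalysis | None = None
    X_centered: np.ndarray | None = None   # kept for TP-loadings
    selected_features: list[str] | None = None

    @property
    def rotations(self) -> np.ndarray:
        """Projection matrix R with scores = X_centered @ R."""
        return self.weights @ np.linalg.inv(self.loadings.T @ self.weights)


@dataclass
class PerformanceReport:
    """Holdout-level classification rates with bootstrap CIs."""

    per_rep: pd.DataFrame
    summary: dict = field(default_factory=dict)
    aicc: float | None = None
    n_components: int | None = None


# ---------------------------------------------------------------------------
# holdout generation
# ---------------------------------------------------------------------------

def make_holdouts(
    pair_id: pd.Series,
    n_reps: int = 500,
    train_frac: float = 0.8,
    seed: int = 0,
):
    """Stratified pair-preserving train/test splits.

    Matched pairs move together, so every train and test set holds fallers
    and non-fallers in equal proportion by construction.  Returns a list
    of (train_subjects, test_subjects) index arrays, reproducible under
    ``seed``.
    """
    if not 0 < train_frac < 1:
        raise ConfigurationError("train_frac must be in (0, 1)")
    pairs = pair_id.unique()
    n_train = int(round(train_frac * len(pairs)))
    if n_train < 1 or n_train >= len(pairs):
        raise DataError("cohort too small for the requested split")
    rng = np.random.default_rng(seed)
    splits = []
    subjects = pair_id.index.to_numpy()
    for _ in range(n_reps):
        perm = rng.permutation(pairs)
        train_pairs = set(perm[:n_train])
        mask = pair_id.isin(train_pairs).to_numpy()
        splits.append((subjects[mask], subjects[~mask]))
    return splits


# ---------------------------------------------------------------------------
# NIPALS PLS + LDA
# ---------------------------------------------------------------------------

def _zscore_fit(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    return mu, sd


def nipals_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    tol: float = 1e-10,
    max_iter: int = 500,
    feature_names: list[str] | None = None,
) -> PLSModel:
    """PLS1 by the non-linear iterative partial least squares algorithm.

    Per component: weight w <- X'u / |X'u| (u is the current response
    residual), score t = Xw, x-loading p = X't/t't, y-loading
    q = y't/t't; X and y are then deflated.  With a univariate response
    the weight update converges in one pass, but the update loop still
    iterates to the stated tolerance for fidelity with the general
    algorithm.  Scores come out mutually orthogonal.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    sd = X.std(axis=0)
    if np.any(sd == 0):
        names = feature_names or [f"f{i}" for i in range(p)]
        dead = [names[i] for i in np.where(sd == 0)[0]]
        raise DataError(f"zero-variance feature(s): {dead}")
    n_components = int(min(n_components, p, n - 1))
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        u = yc
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xc.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                break
            w_new = w_new / norm
            t = Xc @ w_new
            qa = float(yc @ t / (t @ t))
            u_new = yc  # univariate response: u is y itself
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        t = Xc @ w
        tt = float(t @ t)
        if tt == 0:
            n_components = a
            W, P, T, q = W[:, :a], P[:, :a], T[:, :a], q[:a]
            break
        pvec = Xc.T @ t / tt
        qa = float(yc @ t / tt)
        Xc = Xc - np.outer(t, pvec)
        yc = yc - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
    if n_components == 0:
        raise DataError("no PLS component could be extracted")
    R = W @ np.linalg.inv(P.T @ W)
    coef = R @ q
    return PLSModel(
        weights=W, loadings=P, y_loadings=q, scores=T,
        x_mean=x_mean, y_mean=y_mean, coef=coef,
        n_components=n_components,
        feature_names=feature_names or [f"f{i}" for i in range(p)],
        X_centered=X - x_mean,
    )


def _lda_on_scores(T: np.ndarray, y: np.ndarray) -> LinearDiscriminantAnalysis:
    lda = LinearDiscriminantAnalysis()
    lda.fit(T, y.astype(int))
    return lda


def _cv_error_se(X, y, n_components, cv, seed):
    """Internal K-fold CV misclassification of PLS scores + LDA.

    Returns (error, standard error of the fold-level error rates)."""
    n = len(y)
    cv = min(cv, n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, cv)
    wrong = 0
    fold_rates = []
    for f in folds:
        mask = np.ones(n, dtype=bool)
        mask[f] = False
        if len(np.unique(y[mask])) < 2:
            wrong += len(f)
            fold_rates.append(1.0)
            continue
        mu, sd = _zscore_fit(X[mask])
        sd = np.where(sd == 0, 1.0, sd)
        try:
            m = nipals_pls((X[mask] - mu) / sd, y[mask], n_components)
        except DataError:
            wrong += len(f)
            fold_rates.append(1.0)
            continue
        lda = _lda_on_scores(m.scores, y[mask])
        Xt = (X[f] - mu) / sd - m.x_mean
        pred = lda.predict(Xt @ m.rotations)
        wrong += int(np.sum(pred != y[f]))
        fold_rates.append(np.mean(pred != y[f]))
    se = float(np.std(fold_rates, ddof=1) / np.sqrt(len(fold_rates))) \
        if len(fold_rates) > 1 else 0.0
    return wrong / n, se


def _cv_error(X, y, n_components, cv, seed) -> float:
    return _cv_error_se(X, y, n_components, cv, seed)[0]


def fit_plsda(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    max_components: int = 10,
    cv: int = 10,
    seed: int = 0,
    n_components: int | None = None,
) -> PLSModel:
    """Z-score, fit NIPALS PLS, and train an LDA on the latent scores.

    The number of latent vectors (up to ``max_components``) is chosen by
    internal K-fold cross-validation with the one-standard-error rule —
    the smallest count whose error is within one SE of the minimum — so
    noise components do not inflate the model; classification uses the
    LDA posterior at threshold 0.5.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    mu, sd = _zscore_fit(Xa)
    if np.any(sd == 0):
        nm = names or [f"f{i}" for i in range(Xa.shape[1])]
        raise DataError(
            f"zero-variance feature(s): {[nm[i] for i in np.where(sd == 0)[0]]}"
        )
    Xz = (Xa - mu) / sd
    cap = int(min(max_components, Xa.shape[1], len(y) - 2))
    if n_components is None:
        errs = [_cv_error_se(Xa, y, c, cv, seed) for c in range(1, cap + 1)]
        e_best, se_best = min(errs)
        n_components = 1 + next(
            i for i, (e, _) in enumerate(errs) if e <= e_best + se_best
        )
    model = nipals_pls(Xz, y.astype(float), n_components, feature_names=names)
    model.scale_mean, model.scale_sd = mu, sd
    model.lda = _lda_on_scores(model.scores, y)
    return model


def predict_plsda(model: PLSModel, X: np.ndarray | pd.DataFrame):
    """Posterior faller probability and 0.5-threshold class for new data."""
    Xa = np.asarray(X, dtype=float)
    Xz = (Xa - model.scale_mean) / model.scale_sd
    T = (Xz - model.x_mean) @ model.rotations
    proba = model.lda.predict_proba(T)[:, 1]
    return proba, (proba >= 0.5).astype(int)


def tp_loadings(model: PLSModel) -> pd.DataFrame:
    """Target-projection feature ranking.

    The PLS regression vector defines the single response-predictive
    direction; projecting the training data onto it gives the target
    score, and the feature loadings on that score — |X' t_tp / t_tp't_tp|
    — rank features by their influence on the prediction.  Ties break by
    feature name for determinism.
    """
    b = model.coef
    nb = np.linalg.norm(b)
    if nb == 0:
        raise DataError("null regression vector; nothing to project")
    t_tp = model.X_centered @ (b / nb)
    p_tp = model.X_centered.T @ t_tp / float(t_tp @ t_tp)
    df = pd.DataFrame({
        "feature": model.feature_names,
        "tp_loading": np.abs(p_tp),
    })
    df = df.sort_values(
        ["tp_loading", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def backward_select(
    X: pd.DataFrame,
    y: np.ndarray,
    max_components: int = 10,
    cv: int = 10,
    seed: int = 0,
):
    """Backward feature elimination on the training partition.

    Round by round, the error (1 - accuracy, internal K-fold CV) of the
    model without each remaining feature is computed and the feature whose
    removal minimizes the error is dropped, until one feature remains.
    The subset with the global minimum error over the trace is returned.

    Returns (selected feature list, trace DataFrame of (n_features,
    removed, error)).
    """
    if X.shape[1] < 1:
        raise DataError("backward selection needs at least one feature")
    y = np.asarray(y).astype(int)
    remaining = list(X.columns)
    trace = []
    base_err = _cv_error(
        X[remaining].to_numpy(float), y,
        min(max_components, len(remaining)), cv, seed,
    )
    trace.append({"n_features": len(remaining), "removed": None,
                  "error": base_err, "subset": tuple(remaining)})
    best_subset, best_err = tuple(remaining), base_err
    rng = np.random.default_rng(seed)
    while len(remaining) > 1:
        errs = []
        round_seed = int(rng.integers(0, 2**31 - 1))
        # one fold assignment per round so candidate errors are paired
        for feat in remaining:
            cand = [f for f in remaining if f != feat]
            e = _cv_error(
                X[cand].to_numpy(float), y,
                min(max_components, len(cand)), cv, round_seed,
            )
            errs.append((e, feat))
        e_min, drop = min(errs)
        remaining = [f for f in remaining if f != drop]
        trace.append({"n_features": len(remaining), "removed": drop,
                      "error": e_min, "subset": tuple(remaining)})
        if e_min < best_err:
            best_err, best_subset = e_min, tuple(remaining)
    return list(best_subset), pd.DataFrame(trace)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def confusion_rates(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Accuracy, sensitivity, specificity, PPV and NPV from labels."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    def _safe(a, b):
        return a / b if b > 0 else np.nan
    return {
        "accuracy": _safe(tp + tn, tp + tn + fp + fn),
        "sensitivity": _safe(tp, tp + fn),
        "specificity": _safe(tn, tn + fp),
        "ppv": _safe(tp, tp + fp),
        "npv": _safe(tn, tn + fn),
    }


def bootstrap_ci(values, n_boot: int = 1000, alpha: float = 0.05,
                 seed: int = 0):
    """Percentile bootstrap CI of the mean of repetition-level values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    rng = np.random.default_rng(seed)
    means = rng.choice(v, size=(n_boot, len(v)), replace=True).mean(axis=1)
    return float(np.quantile(means, alpha / 2)), float(np.quantile(means, 1 - alpha / 2))


def evaluate_holdouts(
    features: pd.DataFrame,
    labels: pd.Series,
    splits,
    max_components: int = 10,
    cv: int = 10,
    seed: int = 0,
    n_boot: int = 1000,
) -> PerformanceReport:
    """Fit and score a PLS-DA model on every holdout split.

    Z-scoring and component selection happen inside each training
    partition only.  The report carries per-repetition rates, their means
    with 95% percentile-bootstrap CIs, the pooled held-out binomial
    log-likelihood, and the AICc of the modal model size.
    """
    rows = []
    loglik = 0.0
    n_obs = 0
    comps = []
    rng = np.random.default_rng(seed)
    for train_ids, test_ids in splits:
        rep_seed = int(rng.integers(0, 2**31 - 1))
        model = fit_plsda(
            features.loc[train_ids], labels.loc[train_ids].to_numpy(),
            max_components=max_components, cv=cv, seed=rep_seed,
        )
        proba, pred = predict_plsda(model, features.loc[test_ids])
        y_test = labels.loc[test_ids].to_numpy()
        rows.append(confusion_rates(y_test, pred))
        p = np.clip(proba, 1e-12, 1 - 1e-12)
        loglik += float(np.sum(y_test * np.log(p) + (1 - y_test) * np.log(1 - p)))
        n_obs += len(y_test)
        comps.append(model.n_components)
    per_rep = pd.DataFrame(rows)
    k = int(np.median(comps)) + 1  # latent vectors + intercept
    summary = {}
    for col in per_rep.columns:
        lo, hi = bootstrap_ci(per_rep[col], n_boot=n_boot, seed=seed)
        summary[col] = {"mean": float(np.nanmean(per_rep[col])),
                        "ci_low": lo, "ci_high": hi}
    report = PerformanceReport(per_rep=per_rep, summary=summary,
                               n_components=k - 1)
    report.aicc = aicc(loglik, k, n_obs)
    return report


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion
    -2 logL + 2k + 2k(k+1)/(n-k-1); undefined (raises) when n <= k + 1."""
    if n <= k + 1:
        raise DataError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_compare(models: dict) -> pd.DataFrame:
    """Pairwise AICc comparison across named models.

    ``models`` maps name -> AICc value (or PerformanceReport).  Relative
    likelihood of model i vs the best is exp((AICc_min - AICc_i)/2);
    RL < 0.05 marks a significantly worse model.
    """
    vals = {
        name: (m.aicc if isinstance(m, PerformanceReport) else float(m))
        for name, m in models.items()
    }
    best = min(vals.values())
    rows = []
    for name, v in vals.items():
        delta = v - best
        rows.append({
            "model": name, "aicc": v, "delta_aicc": delta,
            "rel_likelihood": float(np.exp(-delta / 2.0)),
            "significantly_worse": bool(np.exp(-delta / 2.0) < 0.05),
        })
    return pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)


# ---------------------------------------------------------------------------
# group contrasts
# ---------------------------------------------------------------------------

def group_compare(
    tensors_fallers: list[PGMETensor],
    tensors_nonfallers: list[PGMETensor],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cell Wilcoxon rank-sum contrast of subject-level PGME tensors
    with Benjamini-Hochberg FDR control across all tested cells.

    Cells missing in any direction-relevant way (fewer than 2 finite
    values per group) are skipped and excluded from the correction count.
    """
    if not tensors_fallers or not tensors_nonfallers:
        raise DataError("both groups need at least one tensor")
    ref = tensors_fallers[0]
    A = np.stack([t.values for t in tensors_fallers])
    B = np.stack([t.values for t in tensors_nonfallers])
    rows = []
    for i, k in enumerate(ref.scales):
        for j, p in enumerate(ref.phases):
            for m, q in enumerate(ref.q_grid):
                a = A[:, i, j, m]
                b = B[:, i, j, m]
                a, b = a[np.isfinite(a)], b[np.isfinite(b)]
                if len(a) < 2 or len(b) < 2:
                    continue
                stat = stats.mannwhitneyu(a, b, alternative="two-sided")
                rows.append({
                    "scale": k, "phase": p, "q": float(q),
                    "median_diff": float(np.median(a) - np.median(b)),
                    "p_value": float(stat.pvalue),
                })
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(p_adjusted=[], significant=[])
    rej, p_adj, _, _ = multipletests(df["p_value"], alpha=alpha,
                                     method="fdr_bh")
    df["p_adjusted"] = p_adj
    df["significant"] = rej
    return df
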