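"""Inferential layer: MANOVA (Wilks' lambda), ANOVA ranking, Friedman, SHAP.

manova_wilks tests whether a grouping variable simultaneously explains
variance across all signature channels, via Lambda = det(W)/det(W+B) and
Rao's F approximation (exact for <=2 groups or <=2 variables); a
label-permutation p-value is available for small or non-normal samples.
anova_feature_ranking orders individual channels by one-way F — used as a
ranking, not as model inference, and therefore reported without
multiple-testing correction.  friedman_rank_stability checks whether
per-fold feature-importance rankings are consistent across CV folds.
shap_linear gives the closed-form Shapley attributions of a linear
decision function, phi_j(x) = w_j (x_j - mu_j), which are exact for
linear models with an independence-style background.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    notes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise StatsError(f"p-value out of range: {self.p_value}")


def _as_matrix(data, labels) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise StatsError("data must be a samples x channels matrix")
    y = np.asarray(labels)
    if len(y) != X.shape[0]:
        raise StatsError("labels length must match number of samples")
    if np.isnan(X).any():
        raise StatsError("missing values are not supported")
    return X, y


def _scatter(X: np.ndarray, y: np.ndarray):
    """Within- and between-group scatter matrices."""
    groups = np.unique(y)
    grand = X.mean(axis=0)
    p = X.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in groups:
        Xg = X[y == g]
        mg = Xg.mean(axis=0)
        d = Xg - mg
        W += d.T @ d
        dm = (mg - grand)[:, None]
        B += len(Xg) * (dm @ dm.T)
    return W, B, len(groups)


def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    W, B, _ = _scatter(X, y)
    T = W + B
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_t <= 0 or sign_w <= 0:
        raise StatsError(
            "singular scatter matrix; use permutation mode or regularize"
        )
    return float(np.exp(logdet_w - logdet_t))


def manova_wilks(
    data,
    labels,
    n_permutations: int = 0,
    rng: np.random.Generator | int | None = None,
) -> TestResult:
    """One-way MANOVA via Wilks' Lambda with Rao's F approximation.

    ``n_permutations > 0`` additionally reports a label-shuffle p-value
    (proportion of permuted Lambdas <= observed, with the +1 correction)
    in ``notes['p_permutation']``.
    """
    X, y = _as_matrix(data, labels)
    n, p = X.shape
    groups, counts = np.unique(y, return_counts=True)
    g = len(groups)
    if g < 2:
        raise StatsError("MANOVA requires >= 2 groups")
    if (counts < 2).any():
        raise StatsError("every group needs >= 2 samples")
    if n <= p + g:
        raise StatsError(f"need n > channels + groups ({p + g}), got {n}")
    lam = _wilks_lambda(X, y)

    q = g - 1  # hypothesis df
    ve = n - g  # error df
    denom = p * p + q * q - 5
    t = np.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    w = ve + q - (p + q + 1) / 2
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2
    lam_t = lam ** (1 / t)
    f_stat = (1 - lam_t) / lam_t * df2 / df1
    p_value = float(sps.f.sf(f_stat, df1, df2))
    notes = {"F": float(f_stat), "groups": g, "n": n}
    if n_permutations:
        rng = np.random.default_rng(rng)
        hits = 0
        y_perm = y.copy()
        for _ in range(n_permutations):
            rng.shuffle(y_perm)
            if _wilks_lambda(X, y_perm) <= lam:
                hits += 1
        notes["p_permutation"] = (hits + 1) / (n_permutations + 1)
        notes["n_permutations"] = n_permutations
    return TestResult("wilks_lambda", lam, (df1, float(df2)), p_value, notes)


def anova_feature_ranking(data, labels, channels: list[str] | None = None) -> pd.DataFrame:
    """One-way ANOVA F per channel, ranked by F descending.

    Output is explicitly a *ranking* of channel separability, not model
    inference: no multiple-testing correction is applied (recorded in the
    ``use`` column).
    """
    X, y = _as_matrix(data, labels)
    groups = np.unique(y)
    if len(groups) < 2:
        raise StatsError("ANOVA ranking requires >= 2 groups")
    channels = channels or [f"ch{i}" for i in range(X.shape[1])]
    if len(channels) != X.shape[1]:
        raise StatsError("channel names must match matrix columns")
    rows = []
    for j, ch in enumerate(channels):
        samples = [X[y == g, j] for g in groups]
        f, p = sps.f_oneway(*samples)
        rows.append({"channel": ch, "F": float(f), "p_value": float(p)})
    df = pd.DataFrame(rows).sort_values("F", ascending=False, kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    df["use"] = "ranking, not inference (no multiplicity correction)"
    return df.reset_index(drop=True)


def _midranks(row: np.ndarray) -> np.ndarray:
    return sps.rankdata(row, method="average")


def friedman_rank_stability(values) -> TestResult:
    """Friedman chi-square over a folds x features value matrix.

    Values are midranked within each fold; ties use the standard tie
    correction.  A fully tied matrix (all folds constant) yields
    chi2 = 0, p = 1.  Supports k >= 2 features (chi2 with k-1 df).
    """
    M = np.asarray(values, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise StatsError("need a folds x features matrix, both dims >= 2")
    n, k = M.shape
    ranks = np.vstack([_midranks(row) for row in M])
    col_sums = ranks.sum(axis=0)
    chi2 = (12.0 / (n * k * (k + 1))) * float(
        ((col_sums - n * (k + 1) / 2.0) ** 2).sum()
    )
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in M:
        _, t = np.unique(row, return_counts=True)
        tie_sum += float((t**3 - t).sum())
    correction = 1.0 - tie_sum / (n * k * (k * k - 1))
    if correction <= 0:
        return TestResult("friedman_chi2", 0.0, (float(k - 1),), 1.0,
                          {"note": "all folds fully tied"})
    chi2 /= correction
    p = float(sps.chi2.sf(chi2, k - 1))
    return TestResult("friedman_chi2", float(chi2), (float(k - 1),), p,
                      {"n_folds": n, "n_features": k})


def shap_linear(
    weights,
    background_mean,
    samples,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form Shapley attributions for f(x) = w.x + b.

    Returns ``(phi, importance)``: phi is an n x d attribution matrix with
    phi_j(x) = w_j (x_j - mu_j) (the intercept cancels), and importance is
    mean |phi_j| over samples normalized to sum to 1 across features.
    """
    w = np.asarray(weights, dtype=float).ravel()
    mu = np.asarray(background_mean, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if w.shape[0] != mu.shape[0] or X.shape[1] != w.shape[0]:
        raise StatsError("weights, background mean and samples must align")
    phi = (X - mu) * w
    mean_abs = np.abs(phi).mean(axis=0)
    total = mean_abs.sum()
    importance = mean_abs / total if total > 0 else np.full_like(mean_abs, 1.0 / len(w))
    return phi, importance
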