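"""Statistical chain: scaling, resampling, balancing, CV, correlation,
stepwise regression.

Feature matrices are min-max scaled to [0, 1].  Class imbalance in the
dominant-emotion labels is corrected with SMOTE: each minority class is
oversampled to the majority count with synthetic points interpolated
between real minority samples and their k nearest same-class
neighbors.  Train/test splits preserve class proportions (stratified
K-fold, K = 3 by default).  Association between synchrony features and
emotion probabilities is measured with Pearson correlation (two-sided
p from the t transform), and a forward stepwise OLS selects synchrony
predictors of an emotion channel by adjusted R² with a p-to-enter
guard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.interpolate import CubicSpline
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "minmax_normalize",
    "minmax_inverse",
    "spline_resample",
    "smote_oversample",
    "FoldAssignment",
    "stratified_kfold",
    "pearson_matrix",
    "RegressionReport",
    "stepwise_forward",
]


def _as_frame(X) -> pd.DataFrame:
    return X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))


def minmax_normalize(X) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rescale each feature linearly onto [0, 1].

    Returns the scaled matrix and a per-feature (min, max) bounds frame
    for the inverse transform.  Constant features cannot be rescaled and
    raise, naming the offending columns.
    """
    Xf = _as_frame(X)
    mins = Xf.min(axis=0)
    maxs = Xf.max(axis=0)
    constant = list(Xf.columns[(maxs - mins) == 0])
    if constant:
        raise ValueError(f"constant feature(s) cannot be min-max scaled: {constant}")
    scaled = (Xf - mins) / (maxs - mins)
    bounds = pd.DataFrame({"min": mins, "max": maxs})
    return scaled, bounds


def minmax_inverse(scaled, bounds: pd.DataFrame) -> pd.DataFrame:
    Xf = _as_frame(scaled)
    return Xf * (bounds["max"] - bounds["min"]) + bounds["min"]


def spline_resample(t: Sequence[float], values, grid: Sequence[float]) -> np.ndarray:
    """Cubic-spline interpolation of a timestamped series onto a grid.

    Fits one C² cubic spline per feature (not-a-knot end conditions, so
    data sampled from a single cubic is reproduced exactly) and
    evaluates it on ``grid``.  Requires at least 4 support points;
    requests outside the support range raise rather than extrapolate.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if t.size < 4:
        raise ValueError("spline resampling needs at least 4 support points")
    if grid.min() < t.min() or grid.max() > t.max():
        raise ValueError("grid extends outside the support range (no extrapolation)")
    spline = CubicSpline(t, v, axis=0)
    return spline(grid)


def smote_oversample(
    X, y, k: int = 5, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """SMOTE: oversample every minority class to the majority count.

    Each synthetic sample lies on the segment between a randomly chosen
    minority sample a and one of its k nearest same-class neighbors b:
    x = a + lam * (b - a), lam ~ U(0, 1).  k is capped at class size − 1.
    Original rows are preserved verbatim at the head of the output.
    Deterministic under ``seed``.
    """
    Xf = _as_frame(X).reset_index(drop=True)
    ys = pd.Series(np.asarray(y), name="label").reset_index(drop=True)
    if len(Xf) != len(ys):
        raise ValueError("X and y length mismatch")
    counts = ys.value_counts()
    singletons = list(counts[counts < 2].index)
    if singletons:
        raise ValueError(
            f"class(es) with a single sample cannot be SMOTE-oversampled: {singletons}"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    majority = counts.max()
    rng = np.random.default_rng(seed)
    new_X: list[np.ndarray] = []
    new_y: list[object] = []
    for label in counts.index:
        n_needed = int(majority - counts[label])
        if n_needed == 0:
            continue
        members = Xf[ys == label].to_numpy(dtype=float)
        k_eff = min(k, len(members) - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(members)
        _, idx = nn.kneighbors(members)  # column 0 is the point itself
        for _ in range(n_needed):
            a_i = int(rng.integers(len(members)))
            b_i = int(idx[a_i, 1 + rng.integers(k_eff)])
            lam = rng.random()
            new_X.append(members[a_i] + lam * (members[b_i] - members[a_i]))
            new_y.append(label)
    if not new_X:
        return Xf.copy(), ys.copy()
    X_out = pd.concat(
        [Xf, pd.DataFrame(new_X, columns=Xf.columns)], ignore_index=True
    )
    y_out = pd.concat([ys, pd.Series(new_y, name="label")], ignore_index=True)
    return X_out, y_out


@dataclass
class FoldAssignment:
    """Stratified fold indices: per-fold class proportions stay within
    one sample of the global proportions."""

    K: int
    fold: np.ndarray
    seed: int

    def split(self, fold_index: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_rows, test_rows) for one fold."""
        test = np.flatnonzero(self.fold == fold_index)
        train = np.flatnonzero(self.fold != fold_index)
        return train, test


def stratified_kfold(y, K: int = 3, seed: int = 0) -> FoldAssignment:
    """Stratified K-fold assignment (shuffled, seed-deterministic)."""
    ys = np.asarray(y)
    counts = pd.Series(ys).value_counts()
    small = list(counts[counts < K].index)
    if small:
        raise ValueError(f"class(es) smaller than K={K}: {small}")
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    fold = np.empty(len(ys), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(ys), 1)), ys)):
        fold[test_idx] = f
    return FoldAssignment(K, fold, seed)


def pearson_matrix(
    X: pd.DataFrame, Y: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p for every (X column, Y column) pair.

    Rows are pairwise-complete: each pair uses every row where both
    columns are observed.  Pairs with fewer than 3 complete rows or a
    constant column are undefined and flagged as NaN (with a warning)
    rather than propagated silently.  Returns (r, p, n) frames indexed
    by X columns with Y columns as columns.
    """
    X = _as_frame(X)
    Y = _as_frame(Y)
    r = pd.DataFrame(index=X.columns, columns=Y.columns, dtype=float)
    p = pd.DataFrame(index=X.columns, columns=Y.columns, dtype=float)
    n = pd.DataFrame(index=X.columns, columns=Y.columns, dtype=int)
    for xc in X.columns:
        for yc in Y.columns:
            mask = X[xc].notna() & Y[yc].notna()
            xs = X.loc[mask, xc].to_numpy(dtype=float)
            ys = Y.loc[mask, yc].to_numpy(dtype=float)
            n.loc[xc, yc] = len(xs)
            if len(xs) < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
                warnings.warn(
                    f"correlation undefined for ({xc}, {yc})", stacklevel=2
                )
                r.loc[xc, yc] = np.nan
                p.loc[xc, yc] = np.nan
                continue
            res = sps.pearsonr(xs, ys)
            r.loc[xc, yc] = res.statistic
            p.loc[xc, yc] = res.pvalue
    return r, p, n


@dataclass
class RegressionReport:
    """Forward-selection OLS result in standard report layout.

    ``table`` rows are the intercept followed by the predictors in
    selection order, with columns B (unstandardized coefficient),
    SE, beta (standardized), t and sig (two-sided p).  ``path`` records
    the adjusted R² after each accepted step.
    """

    selected: list[str]
    table: pd.DataFrame
    adj_r2: float
    path: list[tuple[str, float]] = field(default_factory=list)


def _fit_ols(X: pd.DataFrame, y: np.ndarray, cols: list[str]):
    design = sm.add_constant(X[cols], has_constant="add")
    return sm.OLS(y, design).fit()


def stepwise_forward(
    X: pd.DataFrame,
    y,
    p_enter: float = 0.05,
    min_adj_r2_gain: float = 1e-4,
) -> RegressionReport:
    """Forward stepwise OLS selection by adjusted R².

    At each step the candidate giving the largest adjusted R² is
    admitted provided it is significant and the adjusted-R² gain is at
    least ``min_adj_r2_gain``; selection stops otherwise.  Because the
    entrant is the best of all remaining candidates, its partial-F
    p-value is Bonferroni-corrected by the number of candidates
    examined at that step before comparing against ``p_enter`` — this
    keeps the probability of admitting any predictor into an all-noise
    model at roughly ``p_enter`` regardless of the candidate count.
    The final refit reports B, SE, standardized beta (B · sd(x)/sd(y)),
    t and two-sided p per predictor.
    """
    X = _as_frame(X)
    yv = np.asarray(y, dtype=float)
    if len(X) != len(yv):
        raise ValueError("X and y length mismatch")
    selected: list[str] = []
    path: list[tuple[str, float]] = []
    current_adj = -np.inf
    remaining = list(X.columns)
    while remaining:
        best = None
        n_examined = 0
        for cand in remaining:
            cols = selected + [cand]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = _fit_ols(X, yv, cols)
                except np.linalg.LinAlgError:
                    continue
            if np.linalg.matrix_rank(X[cols].to_numpy()) < len(cols):
                warnings.warn(f"skipping collinear candidate {cand!r}",
                              stacklevel=2)
                continue
            n_examined += 1
            if best is None or fit.rsquared_adj > best[1]:
                best = (cand, fit.rsquared_adj, fit)
        if best is None:
            break
        cand, adj, fit = best
        p_cand = min(1.0, float(fit.pvalues[cand]) * n_examined)
        baseline = current_adj if selected else 0.0
        if not np.isnan(p_cand) and p_cand < p_enter and adj - baseline >= min_adj_r2_gain:
            selected.append(cand)
            remaining.remove(cand)
            current_adj = adj
            path.append((cand, adj))
        else:
            break

    if not selected:
        table = pd.DataFrame(
            [{"B": float(np.mean(yv)), "SE": float(np.std(yv, ddof=1) / max(np.sqrt(len(yv)), 1)),
              "beta": np.nan, "t": np.nan, "sig": np.nan}],
            index=["(Constant)"],
        )
        return RegressionReport([], table, 0.0, [])

    fit = _fit_ols(X, yv, selected)
    sd_y = np.std(yv, ddof=1)
    rows = []
    index = []
    for name in ["const"] + selected:
        B = float(fit.params[name])
        SE = float(fit.bse[name])
        if name == "const":
            beta = np.nan
            index.append("(Constant)")
        else:
            beta = B * np.std(X[name].to_numpy(), ddof=1) / sd_y if sd_y > 0 else np.nan
            index.append(name)
        t = B / SE if SE > 0 else np.inf * np.sign(B)
        rows.append({"B": B, "SE": SE, "beta": beta,
                     "t": t, "sig": float(fit.pvalues[name])})
    table = pd.DataFrame(rows, index=index)
    return RegressionReport(selected, table, float(fit.rsquared_adj), path)
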