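"""Internal/external validation statistics and applicability domain.

Implements the full battery of regression diagnostics conventional in
QSAR work: training-fit statistics (R2, adjusted R2, RMSE, MAE, Lin's
concordance correlation, residual standard error s, Fisher F),
leave-one-out and leave-many-out cross-validation (Q2_LOO, Q2_LMO),
Y-scrambling (chance-correlation baseline), the external predictivity
family Q2_F1/F2/F3 + R2_ex + CCC_ex, and the Williams-plot
applicability domain (leverage vs standardized residual, warning
leverage h* = 3(p+1)/n).

Conventions: RMSE uses denominator n while the residual standard error
s uses n - p - 1, so the two are reported separately; CCC uses
population (1/n) moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    LinearModel,
    ModelError,
    fit_mlr,
    hat_diagonal,
    loo_predictions,
    q2_loo,
)

__all__ = [
    "ValidationReport",
    "DomainDiagnostics",
    "YScrambleResult",
    "ccc",
    "fit_statistics",
    "crossval_statistics",
    "external_statistics",
    "q2_lmo",
    "y_scramble",
    "williams",
    "validate_model",
]


def ccc(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    my, mp = y.mean(), yhat.mean()
    vy = np.mean((y - my) ** 2)
    vp = np.mean((yhat - mp) ** 2)
    cov = np.mean((y - my) * (yhat - mp))
    denom = vy + vp + (my - mp) ** 2
    if denom == 0.0:
        return 1.0
    return float(2.0 * cov / denom)


@dataclass
class ValidationReport:
    """All fit, cross-validation, scrambling and external statistics."""

    # training fit
    r2_tr: Optional[float] = None
    r2_adj: Optional[float] = None
    rmse_tr: Optional[float] = None
    mae_tr: Optional[float] = None
    ccc_tr: Optional[float] = None
    s: Optional[float] = None
    F: Optional[float] = None
    # leave-one-out
    q2_loo: Optional[float] = None
    rmse_cv: Optional[float] = None
    mae_cv: Optional[float] = None
    ccc_cv: Optional[float] = None
    # leave-many-out / scrambling
    q2_lmo: Optional[float] = None
    r2_yscr: Optional[float] = None
    q2_yscr: Optional[float] = None
    # external
    r2_ex: Optional[float] = None
    q2_f1: Optional[float] = None
    q2_f2: Optional[float] = None
    q2_f3: Optional[float] = None
    ccc_ex: Optional[float] = None
    rmse_ex: Optional[float] = None
    mae_ex: Optional[float] = None
    # sizes
    n_training: Optional[int] = None
    n_external: Optional[int] = None
    p: Optional[int] = None

    def as_dict(self) -> dict:
        return asdict(self)

    def update(self, other: "ValidationReport") -> "ValidationReport":
        for key, value in other.as_dict().items():
            if value is not None:
                setattr(self, key, value)
        return self


def fit_statistics(
    model: LinearModel, X: pd.DataFrame | np.ndarray, y: Sequence[float]
) -> ValidationReport:
    """Training-set goodness-of-fit statistics for a fitted model."""
    y = np.asarray(y, dtype=float)
    yhat = model.predict(X)
    n, p = len(y), model.p
    if n <= p + 1:
        raise ModelError(f"need n > p + 1 (n={n}, p={p})")
    residuals = y - yhat
    rss = float(residuals @ residuals)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss
    return ValidationReport(
        r2_tr=r2,
        r2_adj=1.0 - (1.0 - r2) * (n - 1) / (n - p - 1),
        rmse_tr=float(np.sqrt(rss / n)),
        mae_tr=float(np.mean(np.abs(residuals))),
        ccc_tr=ccc(y, yhat),
        s=float(np.sqrt(rss / (n - p - 1))),
        F=(r2 / p) / ((1.0 - r2) / (n - p - 1)) if r2 < 1.0 else float("inf"),
        n_training=n,
        p=p,
    )


def crossval_statistics(
    X: pd.DataFrame | np.ndarray, y: Sequence[float]
) -> ValidationReport:
    """Leave-one-out statistics (Q2_LOO, RMSE_cv, MAE_cv, CCC_cv).

    CCC_cv concords the observed activities with the LOO predictions.
    """
    y = np.asarray(y, dtype=float)
    pred = loo_predictions(X, y)
    press = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return ValidationReport(
        q2_loo=1.0 - press / tss,
        rmse_cv=float(np.sqrt(press / len(y))),
        mae_cv=float(np.mean(np.abs(y - pred))),
        ccc_cv=ccc(y, pred),
    )


def external_statistics(
    model: LinearModel,
    X_ext: pd.DataFrame | np.ndarray,
    y_ext: Sequence[float],
    y_train: Sequence[float],
) -> ValidationReport:
    """External predictivity: R2_ex, Q2_F1/F2/F3, CCC_ex, RMSE/MAE_ex.

    Q2_F1 references the training mean, Q2_F2 the external mean, and
    Q2_F3 compares per-point external residual variance with per-point
    training variance; hence Q2_F1 >= Q2_F2 always.
    """
    y_ext = np.asarray(y_ext, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if len(y_ext) == 0:
        raise ModelError("empty external set")
    yhat = model.predict(X_ext)
    press = float(np.sum((y_ext - yhat) ** 2))
    ss_train_mean = float(np.sum((y_ext - y_train.mean()) ** 2))
    ss_ext_mean = float(np.sum((y_ext - y_ext.mean()) ** 2))
    tr_var = float(np.sum((y_train - y_train.mean()) ** 2)) / len(y_train)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(y_ext, yhat)[0, 1] if len(y_ext) > 1 else np.nan
    return ValidationReport(
        r2_ex=float(r**2) if np.isfinite(r) else None,
        q2_f1=1.0 - press / ss_train_mean if ss_train_mean > 0 else None,
        q2_f2=1.0 - press / ss_ext_mean if ss_ext_mean > 0 else None,
        q2_f3=1.0 - (press / len(y_ext)) / tr_var if tr_var > 0 else None,
        ccc_ex=ccc(y_ext, yhat),
        rmse_ex=float(np.sqrt(press / len(y_ext))),
        mae_ex=float(np.mean(np.abs(y_ext - yhat))),
        n_external=len(y_ext),
    )


def q2_lmo(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    leave_fraction: float = 0.3,
    iterations: int = 1000,
    seed: int = 0,
) -> float:
    """Leave-many-out cross-validated determination coefficient.

    Each iteration leaves out ``round(leave_fraction * n)`` molecules,
    refits on the retained set and accumulates the left-out squared
    prediction errors (PRESS) and squared deviations from the
    retained-set mean (TSS); the score is ``1 - sum PRESS / sum TSS``
    pooled over all iterations.  Pooling (rather than averaging
    per-iteration ratios) makes the statistic converge to Q2_LOO as
    the left-out fraction shrinks to a single molecule.  Seeded and
    reproducible.
    """
    if not 0.0 < leave_fraction <= 0.5:
        raise ModelError(f"leave_fraction must be in (0, 0.5], got {leave_fraction}")
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = Xdf.shape[1]
    n_out = max(1, int(round(leave_fraction * n)))
    if n - n_out < p + 2:
        raise ModelError(
            f"retained subset ({n - n_out}) smaller than p + 2 ({p + 2})"
        )
    rng = np.random.default_rng(seed)
    press_total = tss_total = 0.0
    n_ok = 0
    for _ in range(iterations):
        out = rng.choice(n, size=n_out, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[out] = False
        try:
            model = fit_mlr(Xdf.iloc[mask], y[mask])
        except ModelError:
            continue  # subsample degenerate (e.g. constant column)
        pred = model.predict(Xdf.iloc[~mask])
        press_total += float(np.sum((y[~mask] - pred) ** 2))
        tss_total += float(np.sum((y[~mask] - y[mask].mean()) ** 2))
        n_ok += 1
    if n_ok == 0 or tss_total == 0.0:
        raise ModelError("every leave-many-out refit was degenerate")
    return 1.0 - press_total / tss_total


@dataclass
class YScrambleResult:
    r2_mean: float
    q2_mean: float
    r2_values: np.ndarray
    q2_values: np.ndarray


def y_scramble(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    iterations: int = 300,
    seed: int = 0,
) -> YScrambleResult:
    """Chance-correlation baseline: refit after permuting the activities.

    Returns the mean scrambled R2 and Q2_LOO plus the per-iteration
    values (for the scrambling scatter plot).  A sound model shows
    near-zero scrambled means, far below its real R2.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    r2s = np.empty(iterations)
    q2s = np.empty(iterations)
    tss = float(np.sum((y - y.mean()) ** 2))
    for it in range(iterations):
        perm = rng.permutation(len(y))
        y_perm = y[perm]
        model = fit_mlr(Xdf, y_perm)
        resid = y_perm - model.predict(Xdf)
        r2s[it] = 1.0 - float(resid @ resid) / tss
        try:
            q2s[it] = q2_loo(Xdf, y_perm)
        except ModelError:
            q2s[it] = np.nan
    return YScrambleResult(
        r2_mean=float(np.mean(r2s)),
        q2_mean=float(np.nanmean(q2s)),
        r2_values=r2s,
        q2_values=q2s,
    )


@dataclass
class DomainDiagnostics:
    """Williams-plot quantities: leverage and standardized residuals."""

    ids: list[str]
    leverages: np.ndarray
    std_residuals: np.ndarray
    h_star: float
    inside_domain: np.ndarray  # bool per molecule
    outlier_ids: list[str]  # |std residual| > 3
    is_training: np.ndarray  # bool per molecule

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "leverage": self.leverages,
                "std_residual": self.std_residuals,
                "inside_domain": self.inside_domain,
                "training": self.is_training,
            },
            index=self.ids,
        )


def williams(
    model: LinearModel,
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    X_other: Optional[pd.DataFrame] = None,
    y_other: Optional[Sequence[float]] = None,
    residual_sd: Optional[float] = None,
) -> DomainDiagnostics:
    """Applicability-domain diagnostics for training (and external) sets.

    Leverage ``h_i = x_i^T (X^T X)^{-1} x_i`` with the intercept column;
    warning leverage ``h* = 3(p+1)/n_training``.  Standardized residuals
    divide by ``residual_sd`` (default: the training residual standard
    error s).  A molecule is inside the domain iff ``h_i <= h*`` and
    ``|standardized residual| <= 3``.
    """
    cols = model.descriptor_names
    Xt = X_train[cols].to_numpy(dtype=float) if isinstance(X_train, pd.DataFrame) \
        else np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    n, p = Xt.shape
    design = np.column_stack([np.ones(n), Xt])
    xtx = design.T @ design
    if np.linalg.matrix_rank(xtx) < p + 1:
        raise ModelError("singular X'X; cannot compute leverages")
    xtx_inv = np.linalg.inv(xtx)

    def leverage(block: np.ndarray) -> np.ndarray:
        d = np.column_stack([np.ones(len(block)), block])
        return np.einsum("ij,jk,ik->i", d, xtx_inv, d)

    resid_train = y_train - model.predict(Xt)
    if residual_sd is None:
        residual_sd = float(np.sqrt(resid_train @ resid_train / (n - p - 1)))
    ids = list(X_train.index) if isinstance(X_train, pd.DataFrame) else [
        str(i) for i in range(n)
    ]
    h = leverage(Xt)
    std_resid = resid_train / residual_sd
    is_training = np.ones(n, dtype=bool)
    if X_other is not None:
        Xo = X_other[cols].to_numpy(dtype=float) if isinstance(X_other, pd.DataFrame) \
            else np.asarray(X_other, dtype=float)
        y_other = np.asarray(y_other, dtype=float)
        ids += list(X_other.index) if isinstance(X_other, pd.DataFrame) else [
            f"ext{i}" for i in range(len(Xo))
        ]
        h = np.concatenate([h, leverage(Xo)])
        std_resid = np.concatenate(
            [std_resid, (y_other - model.predict(Xo)) / residual_sd]
        )
        is_training = np.concatenate([is_training, np.zeros(len(Xo), dtype=bool)])
    h_star = 3.0 * (p + 1) / n
    inside = (h <= h_star) & (np.abs(std_resid) <= 3.0)
    outliers = [ids[i] for i in np.nonzero(np.abs(std_resid) > 3.0)[0]]
    return DomainDiagnostics(
        ids=ids,
        leverages=h,
        std_residuals=std_resid,
        h_star=h_star,
        inside_domain=inside,
        outlier_ids=outliers,
        is_training=is_training,
    )


def validate_model(
    model: LinearModel,
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    X_ext: Optional[pd.DataFrame] = None,
    y_ext: Optional[Sequence[float]] = None,
    lmo_fraction: float = 0.3,
    lmo_iterations: int = 1000,
    scramble_iterations: int = 300,
    seed: int = 0,
) -> ValidationReport:
    """Assemble the full validation report for a fitted model."""
    cols = model.descriptor_names
    Xt = X_train[cols]
    report = fit_statistics(model, Xt, y_train)
    report.update(crossval_statistics(Xt, y_train))
    report.q2_lmo = q2_lmo(Xt, y_train, lmo_fraction, lmo_iterations, seed=seed)
    scramble = y_scramble(Xt, y_train, scramble_iterations, seed=seed + 1)
    report.r2_yscr = scramble.r2_mean
    report.q2_yscr = scramble.q2_mean
    if X_ext is not None and len(X_ext) > 0:
        report.update(external_statistics(model, X_ext[cols], y_ext, y_train))
    return report
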