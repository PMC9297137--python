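"""Covariate-adjusted linear-regression screen.

Each tract-level Twitter-derived feature y is regressed, one model per
feature, on the food-desert indicator plus the 12 SES covariates:

    y = b0 + b_FD * FD + b_1 * SES_1 + ... + b_12 * SES_12 + error

The quantity of interest is b_FD, its standard error, the two-sided t-test
p-value (df = n - 14) and the model R^2.  Features with p < alpha form the
"significant set" consumed by classification model 5.  No multiple-testing
correction is applied; the report carries raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import SES_FEATURES, TRACT_FEATURES


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    beta_fd: float
    se: float
    p_value: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class ScreenResult:
    results: tuple[AssociationResult, ...]
    alpha: float

    @property
    def significant(self) -> tuple[str, ...]:
        return tuple(r.feature for r in self.results if r.p_value < self.alpha)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature": r.feature,
                    "beta": r.beta_fd,
                    "p_value": r.p_value,
                    "se": r.se,
                    "r_squared": r.r_squared,
                    "n": r.n,
                }
                for r in self.results
            ],
            columns=["feature", "beta", "p_value", "se", "r_squared", "n"],
        )


def fit_adjusted_model(
    y: np.ndarray,
    fd: np.ndarray,
    controls: np.ndarray,
    feature: str = "y",
) -> AssociationResult:
    """Fit the adjusted OLS model and report the food-desert coefficient.

    Rows with any missing value are dropped listwise.  The fit uses a QR
    decomposition of the design [1, FD, controls]; standard errors come
    from the unscaled covariance (X'X)^-1 times the residual variance.

    Degenerate conventions: an all-constant y returns beta_fd = 0,
    r_squared = 0, p_value = 1.  A rank-deficient design raises, naming
    the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    fd = np.asarray(fd, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if controls.ndim == 1:
        controls = controls[:, None]
    if not (len(y) == len(fd) == len(controls)):
        raise ValueError("y, fd and controls must have equal length")
    keep = ~(np.isnan(y) | np.isnan(fd) | np.isnan(controls).any(axis=1))
    y, fd, controls = y[keep], fd[keep], controls[keep]
    n = len(y)
    p = controls.shape[1] + 2
    if n < 20:
        raise ValueError(f"need >= 20 complete rows for feature {feature!r}, got {n}")
    if np.ptp(y) == 0.0:
        return AssociationResult(feature, 0.0, float("nan"), 1.0, 0.0, n)

    X = np.column_stack([np.ones(n), fd, controls])
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    if (diag < tol).any():
        names = ["intercept", "food_desert"] + [
            f"control_{i}" for i in range(controls.shape[1])
        ]
        bad = [names[i] for i in np.flatnonzero(diag < tol)]
        raise np.linalg.LinAlgError(
            f"rank-deficient design for feature {feature!r}; collinear columns: {bad}"
        )
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    df_resid = n - p
    sigma2 = float(resid @ resid) / df_resid
    Rinv = np.linalg.inv(R)
    cov = (Rinv @ Rinv.T) * sigma2
    se = float(np.sqrt(cov[1, 1]))
    beta_fd = float(beta[1])
    tstat = beta_fd / se
    p_value = float(2.0 * stats.t.sf(abs(tstat), df_resid))
    tss = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - float(resid @ resid) / tss
    return AssociationResult(feature, beta_fd, se, p_value, r_squared, n)


def run_association_screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    features: Sequence[str] = TRACT_FEATURES,
) -> ScreenResult:
    """Run the per-feature adjusted screen over the analysis table.

    Returns one result per feature, in reporting order, plus the
    significant set (raw p < alpha).
    """
    missing = [c for c in (*features, "is_food_desert", *SES_FEATURES) if c not in table]
    if missing:
        raise ValueError(f"analysis table is missing columns: {missing}")
    fd = table["is_food_desert"].astype(float).to_numpy()
    controls = table[list(SES_FEATURES)].astype(float).to_numpy()
    results = [
        fit_adjusted_model(table[f].to_numpy(dtype=float), fd, controls, feature=f)
        for f in features
    ]
    return ScreenResult(results=tuple(results), alpha=alpha)


def export_screen_report(screen: ScreenResult, path: str | Path) -> None:
    """Write the screen results as a CSV (feature, beta, p_value, se, r_squared)."""
    screen.to_frame().to_csv(path, index=False)
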