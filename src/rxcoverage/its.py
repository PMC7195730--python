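"""Segmented-regression interrupted time series for quarterly rates.

The model for a rate series :math:`y_t` (percent) with intervention at
quarter index :math:`t_0` is

.. math::

    y_t = \\beta_0 + \\beta_1 t + \\beta_2 \\, \\mathbf{1}\\{t \\ge t_0\\}
          + \\beta_3 (t - t_0) \\, \\mathbf{1}\\{t \\ge t_0\\} + \\epsilon_t

so :math:`\\beta_0` is the baseline level, :math:`\\beta_1` the
pre-intervention slope, :math:`\\beta_2` the level change at the
intervention onset and :math:`\\beta_3` the slope change (post-slope minus
pre-slope).  The intervention quarter itself belongs to the post segment:
the level-change indicator is already 1 at :math:`t = t_0` while the
slope-change term is still 0 there.  The model is fitted without a roll-in
gap.

Estimation is ordinary least squares (optionally denominator-weighted);
standard errors are iid by default, with Newey-West (HAC, lag 1) available
as the usual ITS robustness option.  Missing quarters are dropped, never
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson

PARAM_NAMES = ("baseline_level", "pre_slope", "level_change", "slope_change")


@dataclass(frozen=True)
class ITSFit:
    """Four segmented-regression parameters with SEs and p-values."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    se: np.ndarray  # length 4
    p_values: np.ndarray  # length 4
    conf_low: np.ndarray  # 95% CI bounds, length 4
    conf_high: np.ndarray
    t0: int
    n_pre: int
    n_post: int
    durbin_watson: float
    rss: float

    @property
    def params(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])

    def to_frame(self, drug_class: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": drug_class,
                "parameter": PARAM_NAMES,
                "estimate": self.params,
                "se": self.se,
                "p_value": self.p_values,
                "ci95_low": self.conf_low,
                "ci95_high": self.conf_high,
            }
        )


def _extract_points(points) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """(t, rate, n) arrays from a DataFrame or an iterable of tuples."""
    if isinstance(points, pd.DataFrame):
        t = points["t"].to_numpy(dtype=float)
        rate_col = "rate_percent" if "rate_percent" in points.columns else "rate"
        y = points[rate_col].to_numpy(dtype=float)
        n = points["n"].to_numpy(dtype=float) if "n" in points.columns else None
    else:
        rows = [tuple(p) for p in points]
        t = np.array([r[0] for r in rows], dtype=float)
        y = np.array([r[1] for r in rows], dtype=float)
        n = (
            np.array([r[2] for r in rows], dtype=float)
            if rows and len(rows[0]) > 2
            else None
        )
    return t, y, n


def build_design(points, t0: int) -> np.ndarray:
    """Design matrix [1, t, post, (t - t0) * post] with post = 1{t >= t0}."""
    t, _, _ = _extract_points(points)
    if not (t.min() < t0 <= t.max()):
        raise ValueError(
            f"intervention index t0={t0} must lie strictly inside the observed "
            f"range [{t.min():.0f}, {t.max():.0f}]"
        )
    post = (t >= t0).astype(float)
    return np.column_stack([np.ones_like(t), t, post, (t - t0) * post])


def fit_segmented(
    points,
    t0: int,
    error_model: str = "iid",
    weighted: bool = False,
) -> ITSFit:
    """Fit the four-parameter segmented regression.

    Parameters
    ----------
    points : DataFrame with columns ``t`` and ``rate_percent`` (or ``rate``),
        optionally ``n``; or an iterable of ``(t, rate[, n])`` tuples.
        Rows with missing rates are dropped (complete-case).
    t0 : 0-based index of the first post-intervention quarter; must lie
        strictly inside the observed range.
    error_model : "iid" (OLS standard errors) or "newey-west" (HAC lag 1).
    weighted : weight each quarter by its denominator ``n``.
    """
    t, y, n = _extract_points(points)
    keep = ~np.isnan(y)
    t, y = t[keep], y[keep]
    if n is not None:
        n = n[keep]
    n_pre = int((t < t0).sum())
    n_post = int((t >= t0).sum())
    if n_pre < 3 or n_post < 3:
        raise ValueError(
            f"need at least 3 points per segment, got {n_pre} pre and {n_post} post"
        )
    X = build_design(list(zip(t, y)), t0)
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design (degenerate segment)")
    if weighted:
        if n is None:
            raise ValueError("weighted fit requires denominators n")
        model = sm.WLS(y, X, weights=n)
    else:
        model = sm.OLS(y, X)
    if error_model == "newey-west":
        res = model.fit(cov_type="HAC", cov_kwds={"maxlags": 1})
    elif error_model == "iid":
        res = model.fit()
    else:
        raise ValueError(f"unknown error_model {error_model!r}")
    ci = res.conf_int(alpha=0.05)
    return ITSFit(
        beta0=res.params[0],
        beta1=res.params[1],
        beta2=res.params[2],
        beta3=res.params[3],
        se=np.asarray(res.bse),
        p_values=np.asarray(res.pvalues),
        conf_low=np.asarray(ci)[:, 0],
        conf_high=np.asarray(ci)[:, 1],
        t0=int(t0),
        n_pre=n_pre,
        n_post=n_post,
        durbin_watson=float(durbin_watson(res.resid)),
        rss=float(np.sum(res.resid**2)),
    )


def predict(fit: ITSFit, t) -> np.ndarray | float:
    """Fitted rate at quarter index t (all four terms)."""
    t_arr = np.asarray(t, dtype=float)
    post = (t_arr >= fit.t0).astype(float)
    out = (
        fit.beta0
        + fit.beta1 * t_arr
        + post * (fit.beta2 + fit.beta3 * (t_arr - fit.t0))
    )
    return out if out.ndim else float(out)


def counterfactual(fit: ITSFit, t) -> np.ndarray | float:
    """Pre-trend extrapolation (baseline level and pre-slope only)."""
    t_arr = np.asarray(t, dtype=float)
    out = fit.beta0 + fit.beta1 * t_arr
    return out if out.ndim else float(out)
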