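"""Spearman correlation of marker abundances against clinical indicators.

Rank correlations are computed pairwise-complete: each OTU x indicator cell
uses only the samples where both values are observed, and records how many
that was. Cells with fewer than three complete pairs are flagged
not-computable (rho and p are NaN) rather than raising. P-values use the
t approximation on midranks, switching to exact permutation enumeration for
very small samples (n <= 9).

An optional partial mode residualises both variables on a stated covariate
set (regression on ranks) before correlating, for when confounders should be
held fixed.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["spearman", "spearman_matrix"]


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Midrank Spearman rho (Pearson correlation of the rank vectors)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def _exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p: enumerate all orderings of y's ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    sx = np.sqrt((rx_c**2).sum())
    n = len(y)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        ryp = ry[list(perm)]
        ry_c = ryp - ryp.mean()
        sy = np.sqrt((ry_c**2).sum())
        if sx == 0 or sy == 0:
            rho = np.nan
        else:
            rho = (rx_c * ry_c).sum() / (sx * sy)
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float, int]:
    """Pairwise-complete Spearman correlation.

    Returns ``(rho, p, n_used)``. NaNs in either input drop the pair; fewer
    than 3 complete pairs gives ``(nan, nan, n_used)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    rho = _spearman_rho(x, y)
    if np.isnan(rho):
        return np.nan, np.nan, n
    if n <= exact_max_n:
        p = _exact_p(x, y, rho)
    else:
        # t approximation with n-2 df on the midrank rho
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, float(min(p, 1.0)), n


def _residual_ranks(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of the rank-transformed values on rank-transformed covariates."""
    ry = stats.rankdata(values)
    rc = np.column_stack([stats.rankdata(c) for c in covariates.T])
    design = np.column_stack([np.ones(len(ry)), rc])
    beta, *_ = np.linalg.lstsq(design, ry, rcond=None)
    return ry - design @ beta


def spearman_matrix(
    abund: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Correlate every abundance column against every clinical indicator.

    Returns a long-format frame (otu, indicator, rho, p, n_used). When
    ``covariates`` names clinical columns, a partial Spearman is computed by
    correlating the rank-regression residuals of both variables on those
    covariates (samples missing any covariate are dropped for that cell).
    """
    shared = [s for s in abund.index if s in clinical.index]
    if not shared:
        raise ValueError("no shared samples between abundance and clinical tables")
    a = abund.loc[shared]
    c = clinical.loc[shared]
    indicators = [col for col in c.columns if covariates is None or col not in covariates]
    rows = []
    for otu in a.columns:
        x_full = a[otu].to_numpy(dtype=float)
        for ind in indicators:
            y_full = c[ind].to_numpy(dtype=float)
            if covariates:
                cov = c[covariates].to_numpy(dtype=float)
                ok = ~(np.isnan(x_full) | np.isnan(y_full) | np.isnan(cov).any(axis=1))
                n = int(ok.sum())
                if n < 3 + len(covariates):
                    rows.append({"otu": otu, "indicator": ind,
                                 "rho": np.nan, "p": np.nan, "n_used": n})
                    continue
                xr = _residual_ranks(x_full[ok], cov[ok])
                yr = _residual_ranks(y_full[ok], cov[ok])
                rho, p, _ = spearman(xr, yr)
                rows.append({"otu": otu, "indicator": ind,
                             "rho": rho, "p": p, "n_used": n})
            else:
                rho, p, n = spearman(x_full, y_full)
                rows.append({"otu": otu, "indicator": ind,
                             "rho": rho, "p": p, "n_used": n})
    return pd.DataFrame(rows)
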