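"""Thin wrappers around statsmodels logistic fits.

Every model in the pipeline is a plain logistic regression; what differs
is the design matrix.  Fits that do not converge or show perfect
separation are *flagged*, never silently dropped: downstream tables carry
the flag and set the p-value to missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

try:  # statsmodels moved/renamed this across versions
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    class PerfectSeparationError(Exception):
        pass

#: |beta| beyond which a binary-outcome fit is treated as separated
_SEPARATION_BETA = 15.0


@dataclass
class LogitFit:
    params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    separation: bool

    @property
    def ok(self) -> bool:
        return self.converged and not self.separation

    def wald(self, idx: int = 1) -> tuple[float, float, float, float, float]:
        """(beta, se, z, two-sided p, OR) for coefficient ``idx``."""
        from scipy import stats

        beta = float(self.params[idx])
        se = float(self.bse[idx])
        if not self.ok or not np.isfinite(se) or se == 0:
            return beta, se, np.nan, np.nan, float(np.exp(beta))
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
        return beta, se, z, p, float(np.exp(beta))


def fit_logit(y: np.ndarray, X: np.ndarray) -> LogitFit:
    """Fit P(y=1) = expit(X beta); X must already contain the intercept."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        k = X.shape[1]
        return LogitFit(np.full(k, np.nan), np.full(k, np.nan), np.nan, False, True)
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    converged = bool(res.mle_retvals.get("converged", True))
    separation = bool(
        np.any(np.abs(params) > _SEPARATION_BETA) or not np.all(np.isfinite(bse))
    )
    return LogitFit(params, bse, float(res.llf), converged, separation)


def covariate_design(
    cov: pd.DataFrame,
    columns: tuple[str, ...] = ("age", "sex", "smoke", "population"),
    include_traits: bool = False,
) -> np.ndarray:
    """Covariate block (no intercept) from the covariate table.

    ``population`` is dummy-coded with the largest group as reference, so
    the block has one column fewer than there are populations.  Trait
    columns (q1..q3) are appended when requested and present.
    """
    blocks = []
    for col in columns:
        if col == "population":
            pop = cov["population"].astype(str)
            ref = pop.value_counts().idxmax()
            levels = [g for g in sorted(pop.unique()) if g != ref]
            for g in levels:
                blocks.append((pop == g).to_numpy(dtype=float))
        else:
            blocks.append(cov[col].to_numpy(dtype=float))
    if include_traits:
        for q in ("q1", "q2", "q3"):
            if q in cov.columns and cov[q].notna().all():
                blocks.append(cov[q].to_numpy(dtype=float))
    if not blocks:
        return np.empty((len(cov), 0))
    return np.column_stack(blocks)


def add_intercept(*blocks: np.ndarray) -> np.ndarray:
    """Stack column blocks after a leading column of ones."""
    n = len(blocks[0])
    cols = [np.ones(n)]
    for b in blocks:
        b = np.asarray(b, dtype=float)
        cols.append(b.reshape(n, -1))
    return np.column_stack(cols)
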