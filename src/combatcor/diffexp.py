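"""Differential-expression engines.

Four per-gene testing routes are implemented around a single group contrast:

* naive t-test / OLS on X1 only (``ols_de`` with ``include_batch=False``) —
  applied to raw data this is the unadjusted two-sample t-test; applied to
  batch-corrected data it is the naive two-step analysis that ignores the
  induced sample correlation;
* one-step OLS on [X1, X2] (``include_batch=True``);
* GLS on adjusted data whitened by the Cholesky factor of the repaired
  correlation matrix (``gls_de``);
* the full pipeline ``combatcor_pipeline``: location/scale correction, then
  the induced-correlation model, then GLS with residual degrees of freedom
  n - rank([X1, X2]) — the batch parameters were spent in step one even
  though only X1 appears in the second-stage model.

All engines report two-sided t-tests on the first group coefficient plus
Benjamini-Hochberg q-values; genes with zero residual variance are flagged
and given p = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from statsmodels.stats.multitest import multipletests

from .correction import ExpressionMatrix, combat_adjust, combat_fit
from .correlation import CorrelationModel, build_correlation_model, default_zeta
from .design import GroupBatchDesign

__all__ = ["DEResult", "ols_de", "gls_de", "combatcor_pipeline", "bh_adjust", "run_method"]


@dataclass
class DEResult:
    """Per-gene group-effect tests for one method on one dataset."""

    gene_ids: list
    estimate: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: int
    p: np.ndarray
    q: np.ndarray
    method: str
    zero_variance: np.ndarray  # boolean flag per gene

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "estimate": self.estimate,
                "se": self.se,
                "t": self.t,
                "df": self.df,
                "p": self.p,
                "q": self.q,
                "method": self.method,
            }
        )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _t_tests(Y: np.ndarray, X: np.ndarray, coef_idx: int, df: int, method: str, gene_ids) -> DEResult:
    """Vectorized per-gene OLS t-test on one coefficient of X."""
    if df <= 0:
        raise ValueError(f"nonpositive residual degrees of freedom ({df})")
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = Y @ (XtX_inv @ X.T).T          # (G, p)
    resid = Y - coef @ X.T
    rss = (resid**2).sum(axis=1)
    sigma2 = rss / df
    var_c = XtX_inv[coef_idx, coef_idx]
    se = np.sqrt(sigma2 * var_c)
    est = coef[:, coef_idx]
    zero = se <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} genes have zero residual variance; p set to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, est / np.where(zero, 1.0, se))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[zero] = 1.0
    q = bh_adjust(p)
    return DEResult(
        gene_ids=list(gene_ids),
        estimate=est,
        se=se,
        t=t,
        df=int(df),
        p=p,
        q=q,
        method=method,
        zero_variance=zero,
    )


def ols_de(
    Y: ExpressionMatrix,
    d: GroupBatchDesign,
    include_batch: bool = False,
    df_resid: int | None = None,
    method: str | None = None,
) -> DEResult:
    """Per-gene OLS t-tests on the group coefficient.

    ``include_batch=True`` is the one-step analysis (batch indicators enter
    the model).  ``df_resid`` overrides the residual degrees of freedom, for
    two-step analyses where batch parameters were estimated upstream.
    """
    if Y.n_samples != d.n:
        raise ValueError("expression/design sample count mismatch")
    X = np.hstack([d.X1, d.X2]) if include_batch else d.X1
    df = d.n - X.shape[1] if df_resid is None else int(df_resid)
    tag = method or ("one_step" if include_batch else "ols")
    return _t_tests(Y.values, X, coef_idx=1, df=df, method=tag, gene_ids=Y.gene_ids)


def gls_de(
    Y_adj: ExpressionMatrix,
    d: GroupBatchDesign,
    cm: CorrelationModel,
    df: int,
    method: str = "gls",
) -> DEResult:
    """GLS t-tests: whiten X1 and each adjusted gene by the inverse Cholesky
    factor of the repaired correlation matrix, then run OLS with the supplied
    residual degrees of freedom."""
    if Y_adj.n_samples != d.n:
        raise ValueError("expression/design sample count mismatch")
    if cm.M_tilde.shape[0] != d.n:
        raise ValueError(
            f"correlation model is {cm.M_tilde.shape[0]}x{cm.M_tilde.shape[0]} "
            f"but the design has {d.n} samples"
        )
    L = cm.whitener
    Xw = solve_triangular(L, d.X1, lower=True)
    Yw = solve_triangular(L, Y_adj.values.T, lower=True).T
    return _t_tests(Yw, Xw, coef_idx=1, df=df, method=method, gene_ids=Y_adj.gene_ids)


def combatcor_pipeline(
    Y: ExpressionMatrix,
    d: GroupBatchDesign,
    zeta: float | None = None,
    mean_only: bool = False,
    eb: bool = True,
) -> DEResult:
    """Three-step correlation-aware pipeline on batch-affected data.

    1. location/scale correction (fit + adjust);
    2. induced-correlation model for the design, repaired with ``zeta``
       (default: midpoint of the recommended range for n);
    3. GLS differential expression with df = n - rank([X1, X2]).
    """
    if d.n_batches < 2:
        raise ValueError("design has a single batch; nothing to correct")
    if zeta is None:
        zeta = default_zeta(d.n)
    fit = combat_fit(Y, d, mean_only=mean_only, eb=eb)
    Y_adj = combat_adjust(fit, Y)
    cm = build_correlation_model(d, zeta)
    df = d.n - d.full_rank
    return gls_de(Y_adj, d, cm, df=df, method=f"combatcor(zeta={zeta:g})")


#: method tags accepted by run_method / the simulation replicate driver
METHOD_TAGS = ("ttest_raw", "benchmark", "one_step", "combat_naive", "combatcor")


def run_method(
    tag: str,
    Y: ExpressionMatrix,
    d: GroupBatchDesign,
    Y_bench: ExpressionMatrix | None = None,
    zeta: float | None = None,
) -> DEResult:
    """Dispatch one differential-expression method by tag.

    ``benchmark`` requires the matched batch-free matrix ``Y_bench``;
    ``combat_naive`` is the location/scale correction followed by naive OLS
    on X1 only (correlation ignored), the analysis whose miscalibration the
    pipeline exists to fix.
    """
    if tag == "ttest_raw":
        return ols_de(Y, d, include_batch=False, method="ttest_raw")
    if tag == "benchmark":
        if Y_bench is None:
            raise ValueError("benchmark method needs the batch-free matrix")
        return ols_de(Y_bench, d, include_batch=False, method="benchmark")
    if tag == "one_step":
        return ols_de(Y, d, include_batch=True, method="one_step")
    if tag == "combat_naive":
        fit = combat_fit(Y, d)
        Y_adj = combat_adjust(fit, Y)
        return ols_de(Y_adj, d, include_batch=False, method="combat_naive")
    if tag == "combatcor":
        return combatcor_pipeline(Y, d, zeta=zeta)
    raise ValueError(f"unknown method tag {tag!r}; expected one of {METHOD_TAGS}")
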