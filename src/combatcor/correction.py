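"""Batch-effect removal: regression (mean-only) and location/scale adjustment.

Two correctors are provided for log-scale expression matrices:

* :func:`meanonly_adjust` — per gene, fit OLS on the joint group-batch design
  and subtract the estimated batch terms, protecting the group structure.
* :func:`combat_fit` / :func:`combat_adjust` — the empirical-Bayes
  location/scale model: per-gene, per-batch shifts ``gamma`` and scale
  factors ``delta`` are estimated on standardized data and shrunk toward
  batch-level priors (normal for gamma, inverse-gamma for delta^2) whose
  hyperparameters are set by method of moments, with the parametric
  fixed-point solve for the posterior estimates.

Both operate on the model

    Y_ijg = alpha_g + X1 beta_g + gamma_ig + delta_ig * eps_ijg

where i indexes batches, j samples within a batch and g genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import GroupBatchDesign

__all__ = [
    "ExpressionMatrix",
    "BatchCorrectionFit",
    "meanonly_adjust",
    "combat_fit",
    "combat_adjust",
    "combat_residual_variance",
]

EB_CONV_TOL = 1e-4
EB_MAX_ITER = 500


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values."""

    values: np.ndarray
    gene_ids: list
    sample_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes x samples array")
        G, n = self.values.shape
        if len(self.gene_ids) != G:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {G} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(values, list(self.gene_ids), list(self.sample_ids))


def _check_alignment(Y: ExpressionMatrix, d: GroupBatchDesign) -> None:
    if Y.n_samples != d.n:
        raise ValueError(f"expression has {Y.n_samples} samples but design has {d.n}")
    if list(Y.sample_ids) != list(d.sample_ids):
        bad = [a for a, b in zip(Y.sample_ids, d.sample_ids) if a != b]
        raise ValueError(f"sample order mismatch between expression and design: {bad[:10]}")


def meanonly_adjust(Y: ExpressionMatrix, d: GroupBatchDesign) -> ExpressionMatrix:
    """Remove OLS-estimated batch shifts, leaving the group structure intact.

    Per gene, fit ``Y_g ~ [X1, X2]`` and subtract the estimated per-batch
    shifts, re-anchored at the batch-size-weighted grand mean so that the
    overall expression level of each gene is preserved (the anchoring is a
    per-gene constant and does not affect group-effect estimates).  This
    makes the output identical to the location/scale corrector run with
    ``mean_only=True, eb=False``.
    """
    _check_alignment(Y, d)
    if d.X2.shape[1] == 0:
        raise ValueError("design has a single batch; nothing to adjust")
    onehot = d.batch_onehot
    X = np.hstack([onehot, d.X1[:, 1:]])  # same span as [X1, X2]
    coef = np.linalg.lstsq(X, Y.values.T, rcond=None)[0]
    batch_loc = coef[: d.n_batches, :].T           # (G, B)
    shift = batch_loc - (batch_loc @ (d.batch_sizes / d.n))[:, None]
    return Y.copy_with(Y.values - shift @ onehot.T)


@dataclass
class BatchCorrectionFit:
    """Fitted location/scale batch model for one expression matrix + design.

    ``gamma_star`` and ``delta2_star`` are on the standardized (Z) scale;
    multiply gamma_star by ``sqrt(sigma2)`` to express shifts in log-expression
    units.  With ``eb=False`` they equal the per-batch method-of-moments
    estimates ``gamma_hat`` / ``delta2_hat`` exactly.
    """

    design: GroupBatchDesign
    gene_ids: list
    sample_ids: list
    alpha: np.ndarray            # (G,) background expression
    beta_group: np.ndarray       # (G, p1-1) protected group effects
    sigma2: np.ndarray           # (G,) pooled residual variance (divisor n)
    gamma_hat: np.ndarray        # (G, B) per-batch means of Z
    delta2_hat: np.ndarray       # (G, B) per-batch variances of Z
    gamma_star: np.ndarray       # (G, B) EB-shrunk location effects
    delta2_star: np.ndarray      # (G, B) EB-shrunk squared scale effects
    gamma_bar: np.ndarray        # (B,) prior means for gamma
    tau2_bar: np.ndarray         # (B,) prior variances for gamma
    lambda_bar: np.ndarray       # (B,) inverse-gamma shape for delta^2
    theta_bar: np.ndarray        # (B,) inverse-gamma scale for delta^2
    mean_only: bool
    eb: bool
    parametric: bool
    n_iter: np.ndarray           # (B,) fixed-point iterations used per batch

    def stand_mean(self) -> np.ndarray:
        """Batch-free mean surface alpha_g + X1 beta_g, shape (G, n)."""
        Xg = self.design.X1[:, 1:]
        return self.alpha[:, None] + self.beta_group @ Xg.T


def _mom_inverse_gamma(d2: np.ndarray) -> tuple[float, float]:
    """Method-of-moments (shape, scale) of an inverse-gamma from draws ``d2``."""
    m = d2.mean()
    s2 = d2.var(ddof=1) if d2.size > 1 else 0.0
    if not s2 > 0:  # degenerate spread: hyperparameters are undefined
        return float("nan"), float("nan")
    shape = (2 * s2 + m**2) / s2
    scale = (m * s2 + m**3) / s2
    return float(shape), float(scale)


def _eb_fixed_point(Z_i, g_hat, d2_hat, g_bar, t2, a, b, conv=EB_CONV_TOL, max_iter=EB_MAX_ITER):
    """Parametric EB posterior estimates for one batch, vectorized over genes.

    Iterates the coupled posterior-mean updates for the location effect and
    the posterior expectation of the squared scale effect until the largest
    relative change falls below ``conv``.
    """
    n_i = Z_i.shape[1]
    g_old = g_hat.copy()
    d_old = d2_hat.copy()
    it = 0
    while it < max_iter:
        g_new = (t2 * n_i * g_hat + d_old * g_bar) / (t2 * n_i + d_old)
        sum2 = ((Z_i - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n_i / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        it += 1
        if change < conv:
            break
    return g_old, d_old, it


def combat_fit(
    Y: ExpressionMatrix,
    d: GroupBatchDesign,
    parametric: bool = True,
    mean_only: bool = False,
    eb: bool = True,
) -> BatchCorrectionFit:
    """Fit the location/scale batch model on standardized expression.

    Standardization uses the full [group, batch] OLS fit: the batch-free mean
    surface is ``alpha_g + X1 beta_g`` with ``alpha_g`` the batch-size-weighted
    grand mean of the batch locations (or the reference batch's location when
    the design carries a reference batch), and ``sigma2_g`` the residual mean
    square with divisor n.  Per-batch location/scale estimates on the Z scale
    are then shrunk by parametric empirical Bayes unless ``eb=False``.
    """
    _check_alignment(Y, d)
    B = d.n_batches
    if B < 2:
        raise ValueError("ComBat needs at least 2 batches")
    sizes = d.batch_sizes
    if not mean_only and sizes.min() < 2:
        lone = [lev for lev, s in zip(d.batch_levels, sizes) if s < 2]
        raise ValueError(
            f"batches {lone} have a single sample; scale effects are not estimable "
            "— rerun with mean_only=True"
        )
    if not parametric:
        raise NotImplementedError("only the parametric EB variant is implemented")

    onehot = d.batch_onehot  # (n, B)
    Xg = d.X1[:, 1:]
    X = np.hstack([onehot, Xg])  # full-rank iff [X1, X2] is
    coef = np.linalg.lstsq(X, Y.values.T, rcond=None)[0]  # (B + p1-1, G)
    batch_loc = coef[:B, :].T            # (G, B) per-batch locations
    beta_group = coef[B:, :].T           # (G, p1-1)

    w = sizes / d.n
    if d.reference_batch is not None:
        ref = d.batch_levels.index(d.reference_batch)
        alpha = batch_loc[:, ref].copy()
    else:
        ref = None
        alpha = batch_loc @ w

    fitted = (X @ coef).T
    resid = Y.values - fitted
    if ref is None:
        sigma2 = (resid**2).mean(axis=1)
    else:
        in_ref = onehot[:, ref].astype(bool)
        sigma2 = (resid[:, in_ref] ** 2).mean(axis=1)

    sd = np.sqrt(np.where(sigma2 > 0, sigma2, 1.0))
    stand_mean = alpha[:, None] + beta_group @ Xg.T
    Z = (Y.values - stand_mean) / sd[:, None]

    gamma_hat = (Z @ onehot) / sizes  # (G, B)
    if mean_only:
        delta2_hat = np.ones_like(gamma_hat)
    else:
        centered = Z - gamma_hat @ onehot.T
        delta2_hat = (centered**2) @ onehot / np.maximum(sizes - 1, 1)

    gamma_bar = gamma_hat.mean(axis=0)
    tau2_bar = gamma_hat.var(axis=0, ddof=1)
    lambda_bar = np.empty(B)
    theta_bar = np.empty(B)
    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    n_iter = np.zeros(B, dtype=int)

    for i in range(B):
        if mean_only:
            lambda_bar[i] = np.nan
            theta_bar[i] = np.nan
        else:
            lambda_bar[i], theta_bar[i] = _mom_inverse_gamma(delta2_hat[:, i])
        if not eb:
            continue
        if mean_only:
            # posterior mean with unit scale and a single effective observation
            t2 = tau2_bar[i]
            gamma_star[:, i] = (t2 * gamma_hat[:, i] + gamma_bar[i]) / (t2 + 1.0)
            delta2_star[:, i] = 1.0
        else:
            idx = d.batch_indices(d.batch_levels[i])
            g, d2, it = _eb_fixed_point(
                Z[:, idx],
                gamma_hat[:, i],
                delta2_hat[:, i],
                gamma_bar[i],
                tau2_bar[i],
                lambda_bar[i],
                theta_bar[i],
            )
            gamma_star[:, i] = g
            delta2_star[:, i] = d2
            n_iter[i] = it

    if ref is not None:
        # the reference batch itself is left untouched by the adjustment
        gamma_star[:, ref] = 0.0
        delta2_star[:, ref] = 1.0

    return BatchCorrectionFit(
        design=d,
        gene_ids=list(Y.gene_ids),
        sample_ids=list(Y.sample_ids),
        alpha=alpha,
        beta_group=beta_group,
        sigma2=sigma2,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau2_bar=tau2_bar,
        lambda_bar=lambda_bar,
        theta_bar=theta_bar,
        mean_only=mean_only,
        eb=eb,
        parametric=parametric,
        n_iter=n_iter,
    )


def combat_adjust(fit: BatchCorrectionFit, Y: ExpressionMatrix) -> ExpressionMatrix:
    """Apply a fitted location/scale correction to an expression matrix.

    Returns ``sigma_g * (Z - gamma*_i) / delta*_i + alpha_g + X1 beta_g`` per
    sample of batch i; with a reference batch, samples of that batch are
    returned unchanged.
    """
    if list(Y.gene_ids) != list(fit.gene_ids) or list(Y.sample_ids) != list(fit.sample_ids):
        raise ValueError("expression matrix does not match the fitted genes/samples")
    d = fit.design
    onehot = d.batch_onehot
    sd = np.sqrt(np.where(fit.sigma2 > 0, fit.sigma2, 1.0))
    stand_mean = fit.stand_mean()
    Z = (Y.values - stand_mean) / sd[:, None]
    shift = fit.gamma_star @ onehot.T          # (G, n)
    # floor guards constant genes (delta2 = 0/0); their Z is 0 anyway
    scale = np.sqrt(np.maximum(fit.delta2_star, 1e-12)) @ onehot.T
    adjusted = (Z - shift) / scale * sd[:, None] + stand_mean
    if d.reference_batch is not None:
        ref = d.batch_levels.index(d.reference_batch)
        in_ref = onehot[:, ref].astype(bool)
        adjusted[:, in_ref] = Y.values[:, in_ref]
    return Y.copy_with(adjusted)


def combat_residual_variance(fit: BatchCorrectionFit, d: GroupBatchDesign | None = None) -> np.ndarray:
    """Batch-size-weighted residual variance sum_i (n_i/n) delta*_ig^2 sigma_g^2.

    This is the residual variance implied by the fitted scale effects: it is
    inflated when most delta exceed 1 (diminished significance downstream) and
    deflated when most fall below 1 (exaggerated significance).
    """
    d = d if d is not None else fit.design
    w = d.batch_sizes / d.n
    return (fit.delta2_star @ w) * fit.sigma2
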