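"""Group-batch design matrices and balance diagnostics.

A differential-expression study processed in batches is described by two
design matrices: ``X1`` holds an intercept plus reference-coded indicators of
the biological groups, and ``X2`` holds reference-coded indicators of the
batches.  Whether the groups are distributed proportionally across batches
("balance") determines how batch adjustment interacts with downstream
inference, so the balance of a design is a first-class diagnostic here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupBatchDesign",
    "BalanceReport",
    "ConfoundedDesignError",
    "build_design",
    "balance_report",
]

#: tolerance on |S12| entries below which a design is declared balanced;
#: balance is a combinatorial property, so this only absorbs float round-off
BALANCE_TOL = 1e-10


class ConfoundedDesignError(ValueError):
    """Raised when group and batch indicators are collinear (rank-deficient)."""


@dataclass(frozen=True)
class GroupBatchDesign:
    """Sample-to-(group, batch) assignment and the derived design matrices.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, in column order of the expression matrix.
    group, batch : numpy arrays of labels
        Per-sample biological group and batch labels.
    group_levels, batch_levels : lists
        Ordered category levels; the first level of each is the reference
        (dropped) level in the coding.
    X1 : (n, p1) array
        Intercept column of ones followed by drop-first group indicators.
    X2 : (n, B-1) array
        Drop-first batch indicators (empty when B == 1).
    """

    sample_ids: list
    group: np.ndarray
    batch: np.ndarray
    group_levels: list
    batch_levels: list
    X1: np.ndarray
    X2: np.ndarray
    reference_batch: object = None
    batch_onehot: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.X1.shape[0]

    @property
    def p1(self) -> int:
        return self.X1.shape[1]

    @property
    def n_batches(self) -> int:
        return len(self.batch_levels)

    @property
    def batch_sizes(self) -> np.ndarray:
        """Number of samples per batch, in ``batch_levels`` order."""
        return self.batch_onehot.sum(axis=0).astype(int)

    @property
    def full_rank(self) -> int:
        """rank([X1, X2]) = p1 + (B - 1) for a non-confounded design."""
        return self.p1 + self.X2.shape[1]

    def batch_indices(self, level) -> np.ndarray:
        return np.flatnonzero(self.batch == level)


@dataclass(frozen=True)
class BalanceReport:
    """Covariance between group and batch codings, and the balance verdict.

    ``S12`` is the sample covariance matrix between the non-intercept columns
    of X1 and the columns of X2; ``S22`` is the sample covariance of X2.  A
    design is balanced when every group is split across batches in the same
    proportions, which is equivalent to S12 = 0.
    """

    S12: np.ndarray
    S22: np.ndarray
    is_balanced: bool
    max_abs_S12: float


def _dummies(labels: np.ndarray, levels: list) -> np.ndarray:
    """Drop-first indicator columns for ``labels`` over ordered ``levels``."""
    cols = [(labels == lev).astype(float) for lev in levels[1:]]
    if not cols:
        return np.empty((labels.shape[0], 0))
    return np.column_stack(cols)


def _collinear_columns(X1: np.ndarray, X2: np.ndarray, batch_levels: list) -> list:
    """Names of X2 columns lying (numerically) in the span of X1 and the
    preceding X2 columns — used only to make confounding errors actionable."""
    bad = []
    basis = X1
    for j in range(X2.shape[1]):
        col = X2[:, j]
        resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(col)):
            bad.append(f"batch[{batch_levels[j + 1]}]")
        else:
            basis = np.column_stack([basis, col])
    return bad


def build_design(groups, batches, sample_ids=None, reference_batch=None) -> GroupBatchDesign:
    """Build a validated :class:`GroupBatchDesign` from per-sample labels.

    Parameters
    ----------
    groups, batches : sequences of labels, equal length (>= 2 samples)
    sample_ids : optional sequence of unique sample names
    reference_batch : optional batch level
        If given, this batch becomes the reference (dropped) level of X2 and
        downstream correction anchors to it.

    Raises
    ------
    ConfoundedDesignError
        If [X1, X2] is rank deficient; the message names the collinear
        batch columns.
    ValueError
        On length mismatches, empty levels, or duplicate sample ids.
    """
    group = np.asarray(list(groups), dtype=object)
    batch = np.asarray(list(batches), dtype=object)
    if group.shape[0] != batch.shape[0]:
        raise ValueError(
            f"groups ({group.shape[0]}) and batches ({batch.shape[0]}) differ in length"
        )
    n = group.shape[0]
    if n < 2:
        raise ValueError("a design needs at least 2 samples")
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    else:
        sample_ids = [str(s) for s in sample_ids]
        if len(sample_ids) != n:
            raise ValueError("sample_ids length does not match labels")
        if len(set(sample_ids)) != n:
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")

    group_levels = list(pd.unique(group))
    batch_levels = list(pd.unique(batch))
    if reference_batch is not None:
        if reference_batch not in batch_levels:
            raise ValueError(
                f"reference batch {reference_batch!r} not among batch levels {batch_levels}"
            )
        batch_levels.remove(reference_batch)
        batch_levels.insert(0, reference_batch)

    # every level is non-empty by construction (levels come from the data)
    X1 = np.column_stack([np.ones(n), _dummies(group, group_levels)])
    X2 = _dummies(batch, batch_levels)
    onehot = np.column_stack([(batch == lev).astype(float) for lev in batch_levels])

    X = np.hstack([X1, X2])
    expected = X1.shape[1] + X2.shape[1]
    if np.linalg.matrix_rank(X) < expected:
        bad = _collinear_columns(X1, X2, batch_levels)
        raise ConfoundedDesignError(
            "group and batch designs are confounded: "
            f"columns {bad or ['<within X1>']} are collinear with the rest of [X1, X2]"
        )

    return GroupBatchDesign(
        sample_ids=sample_ids,
        group=group,
        batch=batch,
        group_levels=group_levels,
        batch_levels=batch_levels,
        X1=X1,
        X2=X2,
        reference_batch=reference_batch,
        batch_onehot=onehot,
    )


def balance_report(d: GroupBatchDesign) -> BalanceReport:
    """Quantify group-batch balance via the covariance S12 between codings.

    With a single batch, S12 is empty and the design is balanced by
    convention.  For B >= 2 the design is balanced iff max|S12| <= tol, which
    holds exactly when every group is split proportionally across batches.
    """
    G = d.X1[:, 1:]
    if d.X2.shape[1] == 0:
        return BalanceReport(
            S12=np.empty((G.shape[1], 0)),
            S22=np.empty((0, 0)),
            is_balanced=True,
            max_abs_S12=0.0,
        )
    Gc = G - G.mean(axis=0)
    Bc = d.X2 - d.X2.mean(axis=0)
    denom = d.n - 1
    S12 = Gc.T @ Bc / denom
    S22 = Bc.T @ Bc / denom
    max_abs = float(np.abs(S12).max()) if S12.size else 0.0
    return BalanceReport(S12=S12, S22=S22, is_balanced=max_abs <= BALANCE_TOL, max_abs_S12=max_abs)
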