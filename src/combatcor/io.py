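"""Reading and writing the package's tabular interchange formats.

Expression matrices travel as TSV/CSV with a ``gene_id`` first column and
one column per sample; phenotype tables carry ``sample``, ``group`` and
``batch`` columns whose sample order must match the expression columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .correction import ExpressionMatrix
from .design import GroupBatchDesign, build_design

__all__ = ["read_expression", "write_expression", "read_phenotype", "write_de_results"]


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return ExpressionMatrix(values, df["gene_id"].astype(str).tolist(), list(df.columns[1:]))


def write_expression(Y: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(Y.values, columns=Y.sample_ids)
    df.insert(0, "gene_id", Y.gene_ids)
    # repr-precision floats so a round trip preserves values exactly
    df.to_csv(path, sep=_sep(path), index=False, float_format="%.17g")


def read_phenotype(path, expression: ExpressionMatrix | None = None,
                   reference_batch=None) -> GroupBatchDesign:
    """Load a sample/group/batch table and build the validated design.

    If ``expression`` is given, the phenotype rows must cover exactly its
    samples in the same order; mismatches are hard errors naming the ids.
    """
    df = pd.read_csv(path, sep=_sep(path))
    required = {"sample", "group", "batch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    samples = df["sample"].astype(str).tolist()
    if expression is not None:
        exp_samples = list(expression.sample_ids)
        if samples != exp_samples:
            missing_ids = sorted(set(exp_samples) - set(samples))
            extra_ids = sorted(set(samples) - set(exp_samples))
            detail = []
            if missing_ids:
                detail.append(f"missing from phenotype: {missing_ids}")
            if extra_ids:
                detail.append(f"not in expression: {extra_ids}")
            if not detail:
                detail.append("same samples but different order")
            raise ValueError(f"{path}: sample mismatch with expression ({'; '.join(detail)})")
    return build_design(df["group"].tolist(), df["batch"].tolist(),
                        sample_ids=samples, reference_batch=reference_batch)


def write_de_results(res, path) -> None:
    res.to_frame().to_csv(path, sep=_sep(path), index=False)
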