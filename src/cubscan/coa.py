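"""Correspondence analysis of the sequences x codons RSCU table.

Implemented from first principles as the SVD of the chi-square standardized
residual matrix: with P the table over its grand total, row masses r and
column masses c, decompose S = Dr^{-1/2} (P - r c^T) Dc^{-1/2}.  Principal
coordinates are the mass-rescaled singular vectors times singular values;
per-axis inertia fractions are squared singular values over total inertia,
and total inertia equals the table's chi-square statistic divided by its
grand total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_SV_TOL = 1e-10


@dataclass(frozen=True)
class CoaResult:
    row_coords: pd.DataFrame      # sequences x d, columns f1..fd
    col_coords: pd.DataFrame      # codons x d
    singular_values: np.ndarray   # non-increasing, > tolerance
    inertias: np.ndarray          # per-axis fractions of total inertia
    total_inertia: float
    row_masses: pd.Series
    col_masses: pd.Series


def correspondence_analysis(matrix: pd.DataFrame, n_axes: int = 2) -> CoaResult:
    """Run CA on a non-negative table (rows: sequences, columns: codons).

    All-zero columns are dropped with a warning (zero-mass points have no
    chi-square geometry); all-zero rows are an error.  A rank-zero table
    (all row profiles identical) yields a zero-inertia result with empty
    axes.  ``n_axes`` caps the number of reported coordinate axes; the full
    singular value spectrum is always retained.
    """
    X = matrix.astype(float)
    if (X.values < 0).any():
        raise ValueError("CA requires a non-negative table")
    zero_cols = X.columns[(X.sum(axis=0) == 0)]
    if len(zero_cols):
        warnings.warn(f"dropping {len(zero_cols)} all-zero column(s) before CA",
                      stacklevel=2)
        X = X.drop(columns=zero_cols)
    if (X.sum(axis=1) == 0).any():
        bad = X.index[X.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero row(s) in CA input: {bad}")
    if X.shape[0] < 2:
        raise ValueError("CA needs at least 2 rows")

    grand = float(X.values.sum())
    P = X.values / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > max(_SV_TOL, sv[0] * _SV_TOL if sv.size else 0.0)
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep, :]

    total_inertia = float(np.sum(sv ** 2))
    inertias = (sv ** 2) / total_inertia if total_inertia > 0 else np.zeros(0)

    d = min(n_axes, sv.size)
    axes = [f"f{i + 1}" for i in range(d)]
    row_pc = (U[:, :d] * sv[:d]) / np.sqrt(r)[:, None]
    col_pc = (Vt[:d, :].T * sv[:d]) / np.sqrt(c)[:, None]
    return CoaResult(
        row_coords=pd.DataFrame(row_pc, index=X.index, columns=axes),
        col_coords=pd.DataFrame(col_pc, index=X.columns, columns=axes),
        singular_values=sv,
        inertias=inertias,
        total_inertia=total_inertia,
        row_masses=pd.Series(r, index=X.index),
        col_masses=pd.Series(c, index=X.columns),
    )


def project_groups(result: CoaResult, groups: pd.Series) -> pd.DataFrame:
    """Mass-weighted centroid of each group's rows on the reported axes."""
    groups = groups.reindex(result.row_coords.index)
    if groups.isna().any():
        missing = result.row_coords.index[groups.isna()].tolist()
        raise KeyError(f"rows without group label: {missing}")
    out = {}
    for g in sorted(groups.unique()):
        mask = (groups == g).values
        w = result.row_masses.values[mask]
        coords = result.row_coords.values[mask]
        out[g] = (coords * w[:, None]).sum(axis=0) / w.sum()
    return pd.DataFrame.from_dict(out, orient="index",
                                  columns=result.row_coords.columns)
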