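"""Missingness filtering, TAMPOR ratio normalization, and sample-level QC.

TAMPOR (median polish of ratios) harmonizes log2 abundances across TMT
batches or acquisition centers: values are first expressed as log2 ratios
against a per-batch denominator — the pooled reference (GIS) channels in
``gis_denominator`` mode, or all samples of the batch in
``all_sample_denominator`` mode — and then alternately centered by
per-protein and per-sample medians until both residual medians vanish.
The global per-protein median abundance is added back at the end so the
output stays on the log2-abundance scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import nanmedian_rows
from .exceptions import ConfigurationError, EmptyResultError

GIS_DENOMINATOR = "gis_denominator"  # TMT-like default
ALL_SAMPLE_DENOMINATOR = "all_sample_denominator"  # DIA-like default


@dataclass(frozen=True)
class PreprocessParams:
    max_missing_frac: float = 0.5
    tampor_mode: str = GIS_DENOMINATOR
    tol: float = 1e-4
    max_iter: int = 250
    outlier_z: float = -3.0

    def __post_init__(self):
        if not 0 < self.max_missing_frac <= 1:
            raise ValueError("max_missing_frac must be in (0, 1]")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


@dataclass(frozen=True)
class TamporReport:
    iterations: int
    max_abs_row_median: float
    max_abs_col_median: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "max_abs_row_median": self.max_abs_row_median,
            "max_abs_col_median": self.max_abs_col_median,
            "converged": self.converged,
        }


def _subject_columns(matrix: pd.DataFrame, traits: pd.DataFrame | None) -> list[str]:
    if traits is None or "is_reference" not in traits.columns:
        return list(matrix.columns)
    refs = set(traits.loc[traits["is_reference"], "sample_id"])
    return [c for c in matrix.columns if c not in refs]


def filter_by_missingness(
    matrix: pd.DataFrame,
    params: PreprocessParams = PreprocessParams(),
    traits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Drop proteins missing in ``max_missing_frac`` or more of the subject
    samples (reference channels are excluded from the denominator)."""
    if matrix.empty:
        raise EmptyResultError("empty abundance matrix")
    subj = _subject_columns(matrix, traits)
    frac = matrix[subj].isna().mean(axis=1)
    keep = frac < params.max_missing_frac
    if not keep.any():
        raise EmptyResultError(
            f"all {len(matrix)} proteins exceed the {params.max_missing_frac:.0%} missingness cap"
        )
    return matrix.loc[keep]


def tampor_normalize(
    matrix: pd.DataFrame,
    traits: pd.DataFrame,
    params: PreprocessParams = PreprocessParams(),
) -> tuple[pd.DataFrame, TamporReport]:
    """Median polish of log2 ratios across batches/centers.

    Samples are blocked by their batch label; cohorts without batches
    (label-free multicenter acquisition) form a single cohort-wide block,
    since diagnosis groups are typically confounded with center and a
    per-center denominator would remove disease signal by construction.
    ``gis_denominator`` mode requires at least one reference channel per
    batch; reference channels are consumed as denominators and dropped from
    the output.
    """
    tr = traits.set_index("sample_id").reindex(matrix.columns)
    if "batch" in tr.columns and tr["batch"].notna().any():
        block = tr["batch"]
        if block.isna().any():
            missing = list(block.index[block.isna()])[:5]
            raise ConfigurationError(f"samples without batch assignment: {missing}")
    else:
        block = pd.Series("all", index=tr.index)

    is_ref = tr.get("is_reference", pd.Series(False, index=tr.index)).fillna(False)
    log_ratio = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    for b, cols in matrix.columns.to_series().groupby(block.to_numpy()):
        cols = list(cols)
        if params.tampor_mode == GIS_DENOMINATOR:
            denom_cols = [c for c in cols if is_ref[c]]
            if not denom_cols:
                raise ConfigurationError(f"batch {b!r} has no reference (GIS) channel")
        else:
            denom_cols = cols
        denom = nanmedian_rows(matrix[denom_cols].to_numpy())
        log_ratio[cols] = matrix[cols].to_numpy() - denom[:, None]

    subj_cols = [c for c in matrix.columns if not is_ref[c]]
    resid = log_ratio[subj_cols].to_numpy()

    it, row_med_max, col_med_max = 0, np.inf, np.inf
    for it in range(1, params.max_iter + 1):
        row_med = nanmedian_rows(resid)
        row_med = np.where(np.isfinite(row_med), row_med, 0.0)
        resid = resid - row_med[:, None]
        col_med = nanmedian_rows(resid.T)
        col_med = np.where(np.isfinite(col_med), col_med, 0.0)
        resid = resid - col_med[None, :]
        row_med_max = float(np.max(np.abs(row_med), initial=0.0))
        col_med_max = float(np.max(np.abs(col_med), initial=0.0))
        if row_med_max <= params.tol and col_med_max <= params.tol:
            break

    # residual medians after the last polish pass
    final_row = np.nanmax(np.abs(np.nan_to_num(nanmedian_rows(resid))))
    final_col = np.nanmax(np.abs(np.nan_to_num(nanmedian_rows(resid.T))))
    converged = bool(final_row <= params.tol and final_col <= params.tol)

    # back to log2-abundance scale: add the global per-protein median
    center = nanmedian_rows(matrix[subj_cols].to_numpy())
    out = pd.DataFrame(
        resid + np.where(np.isfinite(center), center, 0.0)[:, None],
        index=matrix.index, columns=subj_cols,
    )
    report = TamporReport(
        iterations=it,
        max_abs_row_median=float(final_row),
        max_abs_col_median=float(final_col),
        converged=converged,
    )
    return out, report


def mds_qc(matrix: pd.DataFrame, traits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on Euclidean distances.

    Missing values are median-imputed per protein for the distance
    computation only.  Returns sample coordinates with batch/center labels.
    """
    if matrix.shape[1] < 3:
        raise ValueError("MDS needs at least 3 samples")
    X = matrix.to_numpy(dtype=float)
    med = nanmedian_rows(X)
    med = np.where(np.isfinite(med), med, 0.0)
    idx = np.where(np.isnan(X))
    X[idx] = med[idx[0]]

    sq = np.sum(X**2, axis=0)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (X.T @ X)
    np.clip(D2, 0.0, None, out=D2)
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, v = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1][:2]
    coords = v[:, order] * np.sqrt(np.clip(w[order], 0.0, None))

    out = pd.DataFrame(coords, index=matrix.columns, columns=["MDS1", "MDS2"])
    out.index.name = "sample_id"
    if traits is not None:
        tr = traits.set_index("sample_id").reindex(out.index)
        for col in ("batch", "center", "group"):
            if col in tr.columns:
                out[col] = tr[col]
    return out.reset_index()


def detect_outliers(
    matrix: pd.DataFrame, params: PreprocessParams = PreprocessParams()
) -> list[str]:
    """Flag samples whose total connectivity (sum of correlations with all
    other samples) is more than ``|outlier_z|`` SD below the cohort mean."""
    if matrix.shape[1] < 4:
        raise ValueError("outlier screen needs at least 4 samples")
    if not np.isfinite(params.outlier_z):
        return []
    X = matrix.to_numpy(dtype=float)
    med = nanmedian_rows(X)
    med = np.where(np.isfinite(med), med, 0.0)
    idx = np.where(np.isnan(X))
    X = X.copy()
    X[idx] = med[idx[0]]
    C = np.corrcoef(X.T)
    connectivity = C.sum(axis=1) - 1.0
    sd = connectivity.std(ddof=1)
    if sd == 0:
        return []
    z = (connectivity - connectivity.mean()) / sd
    return [s for s, zi in zip(matrix.columns, z) if zi < params.outlier_z]
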