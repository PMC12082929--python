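"""Per-protein removal of nuisance covariate variation by bootstrap OLS.

For every protein, abundance is regressed on the protected terms (diagnosis
group, never subtracted) plus the nuisance terms (age, sex, batch/center)
over case-resampled complete-case datasets.  The bootstrap mean of each
nuisance coefficient is subtracted from the observed values; protected
variation and missingness are left untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from ._util import child_rng

DEFAULT_NUISANCE = ["age", "sex", "batch"]


@dataclass(frozen=True)
class AdjustParams:
    nuisance: list[str] = field(default_factory=lambda: list(DEFAULT_NUISANCE))
    protected: list[str] = field(default_factory=lambda: ["group"])
    n_boot: int = 200
    min_complete: int = 10  # proteins with fewer complete cases pass through
    seed: int = 0

    def __post_init__(self):
        if set(self.nuisance) & set(self.protected):
            raise ValueError("nuisance and protected terms must be disjoint")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


def _covariate_ok(traits: pd.DataFrame, columns: list[str]) -> pd.Series:
    """Samples with every used covariate present (non-null, non-empty)."""
    ok = pd.Series(True, index=traits.index)
    for col in columns:
        if col not in traits.columns:
            raise KeyError(f"covariate {col!r} not in traits")
        s = traits[col]
        if pd.api.types.is_numeric_dtype(s):
            ok &= s.notna()
        else:
            ok &= s.notna() & (s.astype(str) != "")
    return ok


def _encode(traits: pd.DataFrame, columns: list[str], valid: pd.Series,
            reference_group: str = "control") -> pd.DataFrame:
    """Indicator/centered-numeric encoding; levels and centering are taken
    from the valid samples only (others are excluded from every fit)."""
    parts = []
    for col in columns:
        s = traits[col]
        if col == "age" or pd.api.types.is_numeric_dtype(s):
            x = s.astype(float)
            x = (x - x[valid].mean()).fillna(0.0)
            parts.append(x.rename(col))
        else:
            levels = sorted(s[valid].astype(str).unique())
            if col == "group" and reference_group in levels:
                levels.remove(reference_group)
                levels = [reference_group] + levels
            for lv in levels[1:]:  # first level is the reference
                parts.append((s.astype(str) == lv).astype(float).rename(f"{col}[{lv}]"))
    if not parts:
        return pd.DataFrame(index=traits.index)
    return pd.concat(parts, axis=1)


def bootstrap_regress(
    matrix: pd.DataFrame,
    traits: pd.DataFrame,
    params: AdjustParams = AdjustParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (adjusted matrix, coefficient table).

    The coefficient table has one row per (protein, term) with the bootstrap
    mean estimate, bootstrap SE, and the complete-case count; proteins with
    fewer than ``min_complete`` complete cases are passed through unadjusted
    and flagged with term ``"<skipped>"``.
    """
    tr = traits.set_index("sample_id").reindex(matrix.columns)
    if tr.isna().all(axis=1).any():
        missing = list(tr.index[tr.isna().all(axis=1)])[:5]
        raise KeyError(f"samples without trait rows: {missing}")

    nuis_cols = [c for c in params.nuisance if c in tr.columns and tr[c].notna().any()]
    # samples lacking a covariate (e.g. reference channels without age) are
    # excluded from every fit and pass through unadjusted
    valid = _covariate_ok(tr, params.protected + nuis_cols)
    if not valid.any():
        raise ValueError("no samples with complete covariates")
    for col in list(nuis_cols):
        if tr.loc[valid, col].nunique(dropna=True) <= 1:
            warnings.warn(f"nuisance term {col!r} is constant; dropped", stacklevel=2)
            nuis_cols.remove(col)
    prot = _encode(tr, params.protected, valid)
    nuis = _encode(tr, nuis_cols, valid)
    # drop terms constant within the valid samples (e.g. a single batch)
    for frame, kind in ((nuis, "nuisance"), (prot, "protected")):
        for col in list(frame.columns):
            if frame.loc[valid, col].std(ddof=0) == 0:
                warnings.warn(f"{kind} term {col!r} is constant; dropped", stacklevel=2)
                frame.drop(columns=col, inplace=True)
    design = pd.concat([prot, nuis], axis=1)
    X_full = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    terms = ["(intercept)"] + list(design.columns)
    nuis_idx = np.array([terms.index(c) for c in nuis.columns], dtype=int)
    cov_ok = valid.to_numpy()

    if np.linalg.matrix_rank(X_full[cov_ok]) < X_full.shape[1]:
        _, r, piv = linalg.qr(X_full[cov_ok], mode="economic", pivoting=True)
        bad = [terms[piv[i]] for i in range(X_full.shape[1])
               if abs(r[i, i]) < 1e-10 * abs(r[0, 0])]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {bad}")

    rng = child_rng(params.seed, "bootstrap_regress")
    Y = matrix.to_numpy(dtype=float)
    adjusted = Y.copy()
    n_prot, n_samp = Y.shape
    B, p = params.n_boot, X_full.shape[1]
    records = []

    for i in range(n_prot):
        y = Y[i]
        obs = np.isfinite(y) & cov_ok
        n_c = int(obs.sum())
        pid = matrix.index[i]
        if n_c < params.min_complete:
            records.append((pid, "<skipped>", np.nan, np.nan, n_c))
            continue
        X = X_full[obs]
        yo = y[obs]
        # case resampling as multinomial weights; weighted normal equations
        W = rng.multinomial(n_c, np.full(n_c, 1.0 / n_c), size=B).astype(float)
        P = (X[:, :, None] * X[:, None, :]).reshape(n_c, p * p)
        G = (W @ P).reshape(B, p, p)
        c = (W * yo[None, :]) @ X
        try:
            betas = np.linalg.solve(G, c[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            betas = np.stack([np.linalg.pinv(G[b]) @ c[b] for b in range(B)])
        mean_b = betas.mean(axis=0)
        se_b = betas.std(axis=0, ddof=1) if B > 1 else np.zeros(p)
        if nuis_idx.size:
            adjusted[i, obs] = yo - X[:, nuis_idx] @ mean_b[nuis_idx]
        for j, t in enumerate(terms):
            records.append((pid, t, mean_b[j], se_b[j], n_c))

    coef = pd.DataFrame(
        records, columns=["protein", "term", "estimate", "bootstrap_se", "n_complete"]
    )
    out = pd.DataFrame(adjusted, index=matrix.index, columns=matrix.columns)
    return out, coef
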