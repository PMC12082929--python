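"""Cross-cohort module preservation and synthetic eigenproteins.

Preservation of reference-cohort modules in a test cohort is quantified by
permutation Z statistics: for each module, density (mean within-module
signed adjacency in the test cohort) and connectivity preservation
(correlation of intramodular connectivity and of correlation-matrix
entries between cohorts) are compared against random same-size protein
sets.  ``Z_summary = (Z_density + Z_connectivity) / 2``; values above 10
indicate strong preservation (upper-tail normal p below 1e-23), values
above 2 moderate preservation (p below 0.05).

Synthetic eigenproteins project reference modules into the test cohort
using only each module's top hubs (by reference kME), so a module's
abundance can be scored in a cohort that did not build the network.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import child_rng, zscore_rows
from .bicor import bicor_matrix
from .network import EigenproteinSet, ModulePartition, NetworkParams, signed_adjacency


@dataclass(frozen=True)
class PreservationParams:
    n_perm: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_perm < 50:
            raise ValueError("n_perm must be >= 50 for reported Z scores")


@dataclass(frozen=True)
class SyntheticMEParams:
    hub_fraction: float = 0.20
    min_hubs: int = 4

    def __post_init__(self):
        if not 0 < self.hub_fraction <= 1:
            raise ValueError("hub_fraction must be in (0, 1]")
        if self.min_hubs < 2:
            raise ValueError("min_hubs must be >= 2")


def z_to_p(z: float) -> float:
    """Upper-tail standard normal probability for a preservation Z score."""
    return float(stats.norm.sf(z))


def _set_stats(idx: np.ndarray, cor_ref: np.ndarray, cor_test: np.ndarray,
               adj_test: np.ndarray, adj_ref: np.ndarray) -> tuple[float, float, float]:
    m = idx.size
    sub_t = adj_test[np.ix_(idx, idx)]
    density = (sub_t.sum() - m) / (m * (m - 1))
    k_ref = adj_ref[np.ix_(idx, idx)].sum(axis=1) - 1.0
    k_test = sub_t.sum(axis=1) - 1.0
    cor_kim = _pearson(k_ref, k_test)
    iu = np.triu_indices(m, k=1)
    cor_cor = _pearson(cor_ref[np.ix_(idx, idx)][iu], cor_test[np.ix_(idx, idx)][iu])
    return density, cor_kim, cor_cor


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def module_preservation(
    ref_matrix: pd.DataFrame,
    test_matrix: pd.DataFrame,
    partition: ModulePartition,
    params: PreservationParams = PreservationParams(),
    network_params: NetworkParams = NetworkParams(),
) -> pd.DataFrame:
    """Permutation Z_summary of each reference module in the test cohort.

    Modules with fewer than 5 proteins present in the test cohort are
    reported with missing statistics; modules where less than half the
    members are present are flagged ``low_overlap``.
    """
    shared = ref_matrix.index.intersection(test_matrix.index)
    cor_ref = bicor_matrix(ref_matrix.loc[shared].to_numpy(dtype=float),
                           network_params.max_p_outliers)
    cor_test = bicor_matrix(test_matrix.loc[shared].to_numpy(dtype=float),
                            network_params.max_p_outliers)
    adj_ref = signed_adjacency(cor_ref, network_params)
    adj_test = signed_adjacency(cor_test, network_params)
    pos = {p: i for i, p in enumerate(shared)}
    rng = child_rng(params.seed, "module_preservation")
    n_shared = len(shared)

    rows = []
    for m in partition.modules:
        members = partition.members(m)
        present = [p for p in members if p in pos]
        size = len(present)
        low_overlap = size < 0.5 * len(members)
        if size < 5:
            rows.append({"module": m, "size": size, "low_overlap": low_overlap,
                         "Z_density": np.nan, "Z_connectivity": np.nan,
                         "Z_summary": np.nan})
            continue
        idx = np.array(sorted(pos[p] for p in present))
        obs = _set_stats(idx, cor_ref, cor_test, adj_test, adj_ref)
        null = np.empty((params.n_perm, 3))
        for b in range(params.n_perm):
            ridx = np.sort(rng.choice(n_shared, size=size, replace=False))
            null[b] = _set_stats(ridx, cor_ref, cor_test, adj_test, adj_ref)
        mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
        sd[sd == 0] = np.nan
        z = (np.array(obs) - mu) / sd
        z_density = float(z[0])
        z_connectivity = float(np.median(z[1:3]))
        rows.append({
            "module": m, "size": size, "low_overlap": low_overlap,
            "Z_density": z_density, "Z_connectivity": z_connectivity,
            "Z_summary": (z_density + z_connectivity) / 2.0,
        })
    out = pd.DataFrame(rows)
    ranks = out[["Z_density", "Z_connectivity"]].rank(ascending=False)
    out["median_rank"] = ranks.median(axis=1)
    return out


def synthetic_eigenproteins(
    ref_kme: pd.DataFrame,
    partition: ModulePartition,
    test_matrix: pd.DataFrame,
    params: SyntheticMEParams = SyntheticMEParams(),
) -> tuple[EigenproteinSet, pd.DataFrame]:
    """Module eigenproteins in a test cohort from top reference hubs.

    Per module: rank members by reference kME, take the top
    ``hub_fraction`` (at least ``min_hubs`` found in the test cohort,
    extending down the ranking as needed); the synthetic eigenprotein is
    the first principal component of the standardized hub rows in the test
    matrix, sign-aligned to a positive mean hub correlation.  Returns the
    eigenprotein set and a per-module hub report.
    """
    eig, ve, report = {}, {}, []
    for m in partition.modules:
        members = [p for p in partition.members(m) if p in ref_kme.index]
        if not members or m not in ref_kme.columns:
            warnings.warn(f"module {m} absent from reference kME; skipped", stacklevel=2)
            continue
        ranked = ref_kme.loc[members, m].sort_values(ascending=False).index
        n_top = math.ceil(params.hub_fraction * len(members))
        hubs = [p for p in ranked[:n_top] if p in test_matrix.index]
        j = n_top
        while len(hubs) < params.min_hubs and j < len(ranked):
            if ranked[j] in test_matrix.index:
                hubs.append(ranked[j])
            j += 1
        if len(hubs) < params.min_hubs:
            warnings.warn(f"module {m}: fewer than {params.min_hubs} hubs found "
                          "in the test cohort; skipped", stacklevel=2)
            continue
        X = zscore_rows(test_matrix.loc[hubs].to_numpy(dtype=float))
        if not np.any(X):
            warnings.warn(f"module {m}: hub profiles degenerate (constant) in the "
                          "test cohort; skipped", stacklevel=2)
            continue
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        v = vt[0]
        sd = v.std(ddof=1)
        v = (v - v.mean()) / (sd if sd > 0 else 1.0)
        member_cor = (X @ v) / ((X.shape[1] - 1) * np.maximum(X.std(axis=1, ddof=1), 1e-12))
        if member_cor.mean() < 0:
            v = -v
        eig[m] = v
        ve[m] = float(s[0] ** 2 / np.sum(s**2))
        report.append({"module": m, "n_members": len(members), "n_hubs": len(hubs),
                       "hubs": ";".join(hubs)})
    if not eig:
        return (
            EigenproteinSet(eigenproteins=pd.DataFrame(columns=test_matrix.columns),
                            var_explained=pd.Series(dtype=float)),
            pd.DataFrame(report),
        )
    E = pd.DataFrame(eig, index=test_matrix.columns).T
    return EigenproteinSet(eigenproteins=E, var_explained=pd.Series(ve)), pd.DataFrame(report)
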