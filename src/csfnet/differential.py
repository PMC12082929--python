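"""Differential protein abundance: one-way ANOVA with BH correction,
DAP-set comparisons, cross-platform effect-size concordance, and peptide
coordinate mapping for mutation-level analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bicor import bicor, bicor_p
from .exceptions import InsufficientOverlapError

DAP_COLUMNS = ["log2_diff", "F", "p", "q", "direction", "n_A", "n_B"]


@dataclass
class DAPTable:
    """Per-protein differential abundance for one two-group comparison.

    ``log2_diff`` is mean(group B) − mean(group A); ``direction`` flags
    up/down at raw p < alpha (ns otherwise, untested when a group has fewer
    than 2 observed values).
    """

    comparison: tuple[str, str]
    table: pd.DataFrame  # indexed by protein, DAP_COLUMNS
    alpha: float = 0.05

    @property
    def name(self) -> str:
        return f"{self.comparison[1]}_vs_{self.comparison[0]}"

    def significant(self) -> pd.Index:
        p = self.table["p"]
        return self.table.index[(p < self.alpha) & p.notna()]

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "comparison", self.name)
        out.index.name = "protein"
        return out


def oneway_anova(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Vectorized equal-variance one-way ANOVA per protein across all group
    levels of ``groups`` (sample -> label).  Missing values are ignored;
    rows where any group has < 2 observed values are left untested (NaN).
    """
    levels = [g for g in pd.unique(groups.dropna())]
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    cols = groups.index.intersection(matrix.columns)
    sub = matrix[cols]
    g = groups.reindex(cols)

    counts, means, sqs = [], [], []
    for lv in levels:
        block = sub.loc[:, (g == lv).to_numpy()].to_numpy(dtype=float)
        finite = np.isfinite(block)
        n = finite.sum(axis=1).astype(float)
        s = np.nansum(np.where(finite, block, 0.0), axis=1)
        ss = np.nansum(np.where(finite, block**2, 0.0), axis=1)
        counts.append(n)
        with np.errstate(invalid="ignore", divide="ignore"):
            means.append(np.where(n > 0, s / n, np.nan))
        sqs.append(ss)
    counts = np.stack(counts)
    means = np.stack(means)
    sqs = np.stack(sqs)

    testable = (counts >= 2).all(axis=0)
    N = counts.sum(axis=0)
    grand = np.nansum(counts * np.nan_to_num(means), axis=0) / np.where(N > 0, N, np.nan)
    ssb = np.nansum(counts * (means - grand) ** 2, axis=0)
    ssw = np.nansum(sqs - counts * np.nan_to_num(means) ** 2, axis=0)
    dfb = len(levels) - 1
    dfw = N - len(levels)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = np.full(len(sub), np.nan)
    ok = testable & (dfw > 0) & np.isfinite(F)
    p[ok] = stats.f.sf(F[ok], dfb, dfw[ok])
    # zero within-group variance with a between-group difference: p -> 0
    degen = testable & (dfw > 0) & ~np.isfinite(F) & (ssb > 0) & (ssw <= 0)
    p[degen] = 0.0
    F = np.where(ok | degen, F, np.nan)
    p = np.where(testable, p, np.nan)

    out = pd.DataFrame({"F": F, "p": p, "N": N}, index=sub.index)
    for lv, n, m in zip(levels, counts, means):
        out[f"n_{lv}"] = n.astype(int)
        out[f"mean_{lv}"] = m
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg q-values; NaNs (untested) propagate as NaN."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def anova_bh(
    matrix: pd.DataFrame,
    groups: pd.Series,
    comparisons: list[tuple[str, str]],
    alpha: float = 0.05,
) -> list[DAPTable]:
    """One DAPTable per (groupA, groupB) comparison; F/p from the two groups'
    observed values only, BH applied across all tested proteins within the
    comparison."""
    known = set(groups.dropna().unique())
    tables = []
    for a, b in comparisons:
        for lab in (a, b):
            if lab not in known:
                raise KeyError(f"unknown group label {lab!r}")
        mask = groups.isin([a, b])
        res = oneway_anova(matrix, groups[mask])
        log2_diff = res[f"mean_{b}"] - res[f"mean_{a}"]
        q = bh_adjust(res["p"].to_numpy())
        direction = np.where(
            res["p"].isna(), "untested",
            np.where(
                (res["p"] < alpha) & (log2_diff > 0), "up",
                np.where((res["p"] < alpha) & (log2_diff < 0), "down", "ns"),
            ),
        )
        table = pd.DataFrame(
            {
                "log2_diff": log2_diff,
                "F": res["F"],
                "p": res["p"],
                "q": q,
                "direction": direction,
                "n_A": res[f"n_{a}"],
                "n_B": res[f"n_{b}"],
            },
            index=res.index,
        )
        tables.append(DAPTable(comparison=(a, b), table=table, alpha=alpha))
    return tables


def compare_dap_sets(tables: list[DAPTable]) -> tuple[pd.DataFrame, pd.Series]:
    """Cross-tabulate DAP membership across comparisons.

    Returns the per-protein boolean membership matrix and the count of
    proteins in every intersection cell (patterns keyed like "10" for
    significant-in-first-only).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 DAP tables")
    proteins = tables[0].table.index
    for t in tables[1:]:
        proteins = proteins.union(t.table.index)
    names, seen = [], {}
    for t in tables:  # disambiguate repeated comparison names
        k = seen.get(t.name, 0) + 1
        seen[t.name] = k
        names.append(t.name if k == 1 else f"{t.name}#{k}")
    membership = pd.DataFrame(
        dict(zip(names, (proteins.isin(t.significant()) for t in tables))),
        index=proteins,
    )
    patterns = membership.apply(lambda r: "".join("1" if v else "0" for v in r), axis=1)
    counts = patterns.value_counts().sort_index()
    counts.name = "n_proteins"
    return membership, counts


@dataclass(frozen=True)
class ConcordanceResult:
    bicor_r: float
    p: float
    quadrant_counts: dict[str, int]
    n_shared: int


def effectsize_concordance(
    table_a: DAPTable, table_b: DAPTable, alpha: float = 0.05
) -> ConcordanceResult:
    """Biweight midcorrelation of log2 effect sizes over proteins significant
    (raw p < alpha) in both comparisons, with quadrant (sign-agreement)
    counts."""
    shared = table_a.table.index.intersection(table_b.table.index)
    pa = table_a.table.loc[shared, "p"]
    pb = table_b.table.loc[shared, "p"]
    sig = shared[(pa < alpha) & (pb < alpha) & pa.notna() & pb.notna()]
    if len(sig) < 5:
        raise InsufficientOverlapError(
            f"only {len(sig)} proteins significant in both comparisons (need >= 5)"
        )
    da = table_a.table.loc[sig, "log2_diff"].to_numpy()
    db = table_b.table.loc[sig, "log2_diff"].to_numpy()
    r = bicor(da, db)
    quadrants = {
        "both_up": int(np.sum((da > 0) & (db > 0))),
        "both_down": int(np.sum((da < 0) & (db < 0))),
        "a_up_b_down": int(np.sum((da > 0) & (db <= 0))),
        "a_down_b_up": int(np.sum((da <= 0) & (db > 0))),
    }
    return ConcordanceResult(
        bicor_r=float(r), p=bicor_p(r, len(sig)), quadrant_counts=quadrants,
        n_shared=int(len(sig)),
    )


_ALPHA = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


def map_peptides_to_sequence(peptides: list[str], canonical_seq: str) -> pd.DataFrame:
    """Map peptides onto a canonical protein sequence as 1-based inclusive
    (start, end) coordinates; all exact-substring occurrences are reported,
    unmatched peptides are flagged unmapped."""
    seq = canonical_seq.upper()
    if not set(seq) <= _ALPHA:
        raise ValueError("sequence must be an uppercase amino-acid string")
    rows = []
    for pep in peptides:
        if not pep:
            raise ValueError("empty peptide")
        pep = pep.upper()
        if not set(pep) <= _ALPHA:
            raise ValueError("peptides must be uppercase amino-acid strings")
        start = seq.find(pep)
        found = False
        while start != -1:
            rows.append({"peptide": pep, "start": start + 1, "end": start + len(pep),
                         "mapped": True})
            found = True
            start = seq.find(pep, start + 1)
        if not found:
            rows.append({"peptide": pep, "start": pd.NA, "end": pd.NA, "mapped": False})
    return pd.DataFrame(rows, columns=["peptide", "start", "end", "mapped"])
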