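"""Module-trait association: eigenprotein-disease bicor (per disease group
vs controls), eigenprotein ANOVA across all groups, and DAP-over-module
overlay statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bicor import bicor, bicor_p
from .differential import DAPTable, bh_adjust, oneway_anova
from .network import UNASSIGNED, EigenproteinSet, ModulePartition

STAR_THRESHOLDS = [(0.001, "***"), (0.01, "**"), (0.05, "*")]


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for thr, mark in STAR_THRESHOLDS:
        if p < thr:
            return mark
    return ""


def module_trait_bicor(
    eigenproteins: EigenproteinSet,
    traits: pd.DataFrame,
    disease_groups: list[str] | None = None,
    control_group: str = "control",
) -> pd.DataFrame:
    """Eigenprotein vs binary disease trait, one disease group at a time.

    For each disease group the samples are subset to that group plus
    controls (disease = 1, control = 0); the association is the bicor of
    the eigenprotein with the binary trait and its Student-t p-value.
    Subsets with fewer than 5 samples are reported untestable (NaN).
    """
    tr = traits.loc[~traits.get("is_reference", False).astype(bool)]
    tr = tr.set_index("sample_id")
    if disease_groups is None:
        disease_groups = [g for g in tr["group"].unique() if g != control_group]
    E = eigenproteins.eigenproteins
    rows = []
    for grp in disease_groups:
        sel = tr.index[(tr["group"] == grp) | (tr["group"] == control_group)]
        sel = sel.intersection(E.columns)
        y = (tr.loc[sel, "group"] == grp).astype(float).to_numpy()
        n = len(sel)
        for m in E.index:
            if n < 5:
                r, p = np.nan, np.nan
            else:
                r = bicor(E.loc[m, sel].to_numpy(), y)
                p = bicor_p(r, n)
            rows.append({"module": m, "trait": grp, "bicor_r": r, "p": p,
                         "n_used": n, "stars": _stars(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def eigenprotein_anova(
    eigenproteins: EigenproteinSet, traits: pd.DataFrame
) -> pd.DataFrame:
    """One-way ANOVA of each module eigenprotein across all diagnosis
    groups, BH-corrected across modules."""
    tr = traits.loc[~traits.get("is_reference", False).astype(bool)]
    groups = tr.set_index("sample_id")["group"]
    E = eigenproteins.eigenproteins
    common = E.columns.intersection(groups.index)
    res = oneway_anova(E[common], groups.loc[common])
    out = pd.DataFrame({"F": res["F"], "p": res["p"]}, index=E.index)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out.index.name = "module"
    return out


def dap_module_overlay(dap: DAPTable, partition: ModulePartition) -> pd.DataFrame:
    """Per module: fraction of members that are DAPs in the comparison, and
    the mean log2 difference of those DAPs.  Unassigned proteins are
    reported as their own category."""
    sig = set(dap.significant())
    rows = []
    categories = partition.modules + [UNASSIGNED]
    for m in categories:
        if m == UNASSIGNED:
            members = partition.labels.index[partition.labels == UNASSIGNED]
        else:
            members = partition.members(m)
        hit = [p for p in members if p in sig]
        frac = len(hit) / len(members) if len(members) else np.nan
        mean_diff = (
            float(dap.table.loc[hit, "log2_diff"].mean()) if hit else np.nan
        )
        rows.append({
            "module": m, "comparison": dap.name, "n_members": len(members),
            "n_da": len(hit), "frac_da": frac, "mean_log2_diff": mean_diff,
        })
    return pd.DataFrame(rows)
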