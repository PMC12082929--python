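"""Gene-set and cell-type enrichment of network modules by one-tailed
Fisher's exact test.

The background is the set of detected network proteins (gene symbols taken
from the "UniProtAC|GeneSymbol" ids), not the genome: CSF detectability is
itself a strong filter, and enrichment is asked within the measured
proteome."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io import gene_symbol
from .network import ModulePartition


@dataclass
class GeneSetCollection:
    sets: dict[str, tuple[str, list[str]]]  # name -> (description, members)
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def parse_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file: one set per line — name, description, members."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc = fields[0], fields[1]
            members = []
            seen = set()
            for g in fields[2:]:
                g = g.strip().upper()
                if g and g not in seen:
                    seen.add(g)
                    members.append(g)
            if not members:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = (desc, members)
    if not sets:
        warnings.warn(f"empty GMT file: {path}", stacklevel=2)
    return GeneSetCollection(sets=sets, source=str(path))


def fisher_enrichment(
    partition: ModulePartition,
    collection: GeneSetCollection,
    background: list[str] | None = None,
    min_set: int = 5,
    max_set: int = 1000,
) -> pd.DataFrame:
    """Upper-tail (enrichment-only) hypergeometric p per (module, set).

    Sets are intersected with the background and skipped outside
    [min_set, max_set]; BH is applied across all (module, set) pairs of the
    collection.  Odds ratio is ad/bc with a 0.5 continuity correction when
    any cell is zero.
    """
    if background is None:
        background = [
            gene_symbol(p) for p in partition.labels.index if gene_symbol(p)
        ]
    bg = set(g.upper() for g in background)
    if not bg:
        raise ValueError("empty background")
    N = len(bg)

    module_genes = {}
    for m in partition.modules:
        module_genes[m] = {
            gene_symbol(p) for p in partition.members(m) if gene_symbol(p)
        } & bg

    rows = []
    for name, (_, members) in collection.sets.items():
        genes = set(members) & bg
        if not min_set <= len(genes) <= max_set:
            continue
        K = len(genes)
        for m, mod in module_genes.items():
            n_mod = len(mod)
            a = len(mod & genes)
            b = n_mod - a
            c = K - a
            d = N - n_mod - c
            # upper tail: P(X >= a) for X ~ Hypergeom(N, K, n_mod)
            p = float(stats.hypergeom.sf(a - 1, N, K, n_mod))
            if min(a, b, c, d) == 0:
                orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            else:
                orr = (a * d) / (b * c)
            rows.append({
                "module": m, "set": name, "overlap": a, "module_size": n_mod,
                "set_size": K, "background_size": N, "odds_ratio": orr, "p": p,
            })
    out = pd.DataFrame(
        rows, columns=["module", "set", "overlap", "module_size", "set_size",
                       "background_size", "odds_ratio", "p"],
    )
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = np.nan
    return out


def celltype_enrichment(
    partition: ModulePartition, markers: pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """Fisher enrichment against cell-type marker lists (two-column table:
    gene, cell_type)."""
    sets = {
        ct: (f"{ct} markers", sorted(set(sub["gene"].str.upper())))
        for ct, sub in markers.groupby("cell_type")
    }
    return fisher_enrichment(partition, GeneSetCollection(sets=sets), **kwargs)
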