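"""Readers and writers for the pipeline's tabular interchange formats.

All tables are plain text: abundance matrices as TSV with a leading
``ProteinID`` column (rows = "UniProtAC|GeneSymbol", columns = samples,
log2 scale, empty cells = missing), sample traits as CSV, gene sets as
standard GMT, cell-type markers as two-column TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

TRAIT_COLUMNS = [
    "sample_id",
    "group",
    "symptomatic",
    "age",
    "sex",
    "batch",
    "center",
    "platform",
    "is_reference",
]


def write_abundance(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "ProteinID"
    out.to_csv(path, sep="\t", float_format="%.6g", na_rep="")


def read_abundance(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="ProteinID")
    return df.astype(float)


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index=False)


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "is_reference" in df.columns:
        df["is_reference"] = df["is_reference"].astype(bool)
    if "symptomatic" in df.columns:
        df["symptomatic"] = df["symptomatic"].astype(bool)
    return df


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    """Write gene sets as GMT lines: name, description, then members."""
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_markers(markers: pd.DataFrame, path: str | Path) -> None:
    """Two-column marker table (gene, cell_type)."""
    markers.to_csv(path, sep="\t", index=False)


def read_markers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = ["gene", "cell_type"]
    df["gene"] = df["gene"].str.upper()
    return df


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default, sort_keys=True)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def gene_symbol(protein_id: str) -> str | None:
    """Extract the gene symbol from a "UniProtAC|GeneSymbol" identifier."""
    if "|" not in protein_id:
        return None
    sym = protein_id.split("|", 1)[1].strip().upper()
    return sym or None
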