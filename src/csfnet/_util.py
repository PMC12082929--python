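"""Shared helpers: deterministic seed derivation and small numeric utilities."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master: int, name: str) -> int:
    """Derive a stable child seed from a master seed and an operation name.

    Every stochastic stage draws its own generator from (master, op-name) so
    stages are reproducible independently of execution order.
    """
    digest = hashlib.blake2b(f"{int(master)}:{name}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def child_rng(master: int, name: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, name))


def nanmedian_rows(x: np.ndarray) -> np.ndarray:
    """Row medians ignoring NaN; rows that are all-NaN give NaN without warning."""
    out = np.full(x.shape[0], np.nan)
    mask = ~np.all(np.isnan(x), axis=1)
    if mask.any():
        out[mask] = np.nanmedian(x[mask], axis=1)
    return out


def zscore_rows(x: np.ndarray, impute_median: bool = True) -> np.ndarray:
    """Z-score each row over its observed entries; optionally median-impute NaN.

    Rows with zero variance are centered only (returned as zeros).
    """
    x = np.asarray(x, dtype=float).copy()
    mean = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, ddof=1, keepdims=True)
    sd[~np.isfinite(sd) | (sd == 0)] = 1.0
    z = (x - mean) / sd
    if impute_median:
        med = np.nanmedian(z, axis=1)
        med[~np.isfinite(med)] = 0.0
        idx = np.where(np.isnan(z))
        z[idx] = med[idx[0]]
    return z
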