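"""Directional gene-set enrichment with the Stouffer method.

Per-gene two-sided p values from the differential-expression stage are
converted to signed z scores (sign taken from the fold change) and
combined per gene set as ``Z = sum(z_i) / sqrt(n)``; set-level p values
are two-sided normal tails, adjusted across sets with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .types import InputError

__all__ = ["gene_level_z", "stouffer_set_test"]

log = logging.getLogger(__name__)

# smallest p admitted before the normal quantile saturates
_P_FLOOR = float(np.finfo(float).tiny)


def gene_level_z(de: pd.DataFrame) -> pd.Series:
    """Signed per-gene z score, ``z = sign(log2fc) * Phi^-1(1 - p/2)``.

    Genes with missing log2fc or p (untested in the DE stage) are
    skipped with a log entry.  p = 0 is clipped to the smallest positive
    float so the quantile stays finite.
    """
    usable = de["log2fc"].notna() & de["p"].notna()
    n_skipped = int((~usable).sum())
    if n_skipped:
        log.info("gene_level_z: skipping %d genes without DE statistics", n_skipped)
    sub = de.loc[usable]
    p = np.clip(sub["p"].to_numpy(dtype=float), _P_FLOOR, 1.0)
    z = np.sign(sub["log2fc"].to_numpy(dtype=float)) * stats.norm.isf(p / 2.0)
    return pd.Series(z, index=sub.index, name="z")


def stouffer_set_test(
    z: pd.Series,
    sets: dict[str, list[str]],
    min_size: int = 3,
) -> pd.DataFrame:
    """Stouffer combination of gene z scores within each set.

    Each set is intersected with the tested gene universe (the index of
    ``z``); sets smaller than ``min_size`` after intersection are
    dropped.  Returns one row per tested set with columns
    ``n_genes_tested, stouffer_z, p, padj, direction``, BH-adjusted
    across the tested sets.
    """
    if not sets:
        raise InputError("empty gene-set collection")
    universe = set(z.index)
    rows = []
    for name in sorted(sets):
        members = sorted(set(sets[name]) & universe)
        n = len(members)
        if n < min_size:
            continue
        zsum = float(z.loc[members].sum())
        stouffer = zsum / np.sqrt(n)
        p = 2.0 * stats.norm.sf(abs(stouffer))
        rows.append(
            {
                "set_name": name,
                "n_genes_tested": n,
                "stouffer_z": stouffer,
                "p": p,
                "direction": "up" if stouffer > 0 else "down",
            }
        )
    out = pd.DataFrame(rows).set_index("set_name") if rows else pd.DataFrame(
        columns=["n_genes_tested", "stouffer_z", "p", "padj", "direction"]
    )
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
        out = out[["n_genes_tested", "stouffer_z", "p", "padj", "direction"]]
    return out
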