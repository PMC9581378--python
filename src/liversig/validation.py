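"""Re-testing candidate genes in independent cohorts.

Candidates from the discovery cohort are re-tested in each validation
dataset with the same NB-Wald machinery and reference-group convention;
multiplicity is controlled within the candidate set per dataset
(confirmation, not discovery).  Cross-dataset robustness is summarized
as direction concordance: the fraction of datasets in which the sign of
the fold change agrees with discovery, among datasets where the gene is
present.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diffexpr
from .types import CountMatrix, InputError

__all__ = ["revalidate", "concordance"]


def revalidate(
    candidates: pd.DataFrame,
    dataset: CountMatrix,
    contrast: str,
    reference: str = "NAS0-1",
) -> pd.DataFrame:
    """Wald-test the candidate genes in one validation dataset.

    Size factors and dispersions come from the full dataset; the BH
    family is the candidate set only.  Candidates missing from the
    dataset's gene universe are flagged ``present = False`` and carry no
    statistics.

    Returns one row per candidate gene with columns
    ``present, log2fc, se, wald_stat, p, padj``.
    """
    if len(candidates) == 0:
        raise InputError("candidate table is empty")
    wanted = list(candidates.index)
    present = [g for g in wanted if g in dataset.gene_ids]
    if not present:
        raise InputError(
            f"no candidate gene present in dataset; missing: {wanted}"
        )
    factors = diffexpr.size_factors(dataset)
    dispersions = diffexpr.estimate_dispersion(dataset, factors)
    full = diffexpr.wald_test(dataset, factors, dispersions, contrast, reference)
    out = pd.DataFrame(
        index=pd.Index(wanted, name="gene_id"),
        columns=["present", "log2fc", "se", "wald_stat", "p", "padj"],
    )
    out["present"] = [g in dataset.gene_ids for g in wanted]
    sub = full.loc[present, ["log2fc", "se", "wald_stat", "p"]]
    out.loc[present, ["log2fc", "se", "wald_stat", "p"]] = sub
    tested = out.index[out["present"] & out["p"].notna()]
    if len(tested):
        out.loc[tested, "padj"] = diffexpr.bh_adjust(
            out.loc[tested, "p"].to_numpy(dtype=float)
        )
    for col in ("log2fc", "se", "wald_stat", "p", "padj"):
        out[col] = out[col].astype(float)
    out.attrs["contrast"] = contrast
    out.attrs["reference"] = reference
    return out


def concordance(
    reports: dict[str, pd.DataFrame],
    discovery: pd.DataFrame,
) -> pd.Series:
    """Per-gene direction concordance across validation datasets.

    For each discovery candidate, the fraction of datasets in which
    ``sign(log2fc)`` matches the discovery sign, computed over datasets
    where the gene is present; genes present nowhere get NaN.  A report
    may hold several rows per gene (one per contrast); a dataset counts
    as concordant only when every tested contrast matches.  Invariant to
    the ordering of datasets.
    """
    if not reports:
        raise InputError("at least one validation report is required")
    out = {}
    for g in discovery.index:
        disc_sign = np.sign(discovery.loc[g, "log2fc"])
        agree = 0
        n_present = 0
        for rep in reports.values():
            if g not in rep.index:
                continue
            rows = rep.loc[[g]]
            lfc = rows.loc[rows["present"].astype(bool), "log2fc"].dropna()
            if len(lfc):
                n_present += 1
                agree += int((np.sign(lfc.to_numpy()) == disc_sign).all())
        out[g] = agree / n_present if n_present else np.nan
    return pd.Series(out, name="direction_concordance")
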