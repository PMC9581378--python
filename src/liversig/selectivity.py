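"""Liver-selectivity scoring and secretome filtering of DEG candidates.

A gene is a promising circulating-biomarker candidate when (1) it is
differentially expressed across disease severity, (2) its expression is
liver-selective across a tissue atlas, and (3) its product is plausibly
secreted into blood.  Selectivity is scored by the coefficient of
variation (CV) of the gene's TPM vector across all tissues combined with
its absolute liver expression: a gene expressed in few tissues has a
high CV, and a liver-selective gene additionally has high liver TPM
(towards the top-right corner of the CV-vs-liver-TPM plane).  Secretion
evidence is the disjunction of three membership lists (hepatocyte
secretome, blood proteome detection, sequence-based prediction).  A
non-secreted but liver-selective enzyme can still be carried as an
*indirect* candidate when its catalytic product is measurable in plasma
(e.g. a methionine adenosyltransferase read out via circulating
S-adenosylmethionine).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .types import InputError, TissueAtlas

__all__ = [
    "tissue_cv",
    "classify_selective",
    "secretion_flags",
    "select_candidates",
    "secreted_deg_count",
    "plot_selectivity",
]

log = logging.getLogger(__name__)

EVIDENCE_SOURCES = ("hepatocyte_secretome", "blood_proteome", "predicted_secreted")


def tissue_cv(atlas: TissueAtlas) -> pd.DataFrame:
    """Per-gene selectivity scores from a tissue atlas.

    CV = sample standard deviation / mean of the gene's TPM vector across
    all tissues (liver included, ddof=1).  Genes with zero mean TPM have
    an undefined CV and are excluded with a log entry.

    Returns a DataFrame with columns ``liver_tpm, cv, liver_is_max``.
    """
    if atlas.n_tissues < 3:
        raise InputError(
            f"atlas has {atlas.n_tissues} tissues; CV needs at least 3"
        )
    tpm = atlas.tpm.to_numpy(dtype=float)
    mean = tpm.mean(axis=1)
    sd = tpm.std(axis=1, ddof=1)
    nonzero = mean > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        log.info("tissue_cv: excluding %d genes with zero mean TPM", n_dropped)
    liver = atlas.tpm[atlas.liver].to_numpy(dtype=float)
    row_max = tpm.max(axis=1)
    out = pd.DataFrame(
        {
            "liver_tpm": liver[nonzero],
            "cv": sd[nonzero] / mean[nonzero],
            "liver_is_max": liver[nonzero] >= row_max[nonzero] * (1 - 1e-12),
        },
        index=atlas.gene_ids[nonzero],
    )
    return out


def classify_selective(
    scores: pd.DataFrame,
    liver_tpm_floor: float = 10.0,
    cv_quantile: float = 0.90,
) -> pd.DataFrame:
    """Flag liver-selective genes and rank all scored genes.

    selective  <=>  liver_tpm >= floor  AND  cv >= empirical
    ``cv_quantile`` across all scored genes  AND  cv > 0  AND  liver is
    the maximal tissue (a constant-expression gene is never selective,
    even when the empirical quantile degenerates to zero).  Ranks (1 =
    most selective) order by descending CV with liver TPM as tie-break,
    then gene id.
    """
    if len(scores) == 0:
        raise InputError("no scored genes to classify")
    if not 0 < cv_quantile < 1:
        raise InputError("cv_quantile must lie in (0, 1)")
    cv_cut = float(np.quantile(scores["cv"].to_numpy(), cv_quantile))
    out = scores.copy()
    out["selective"] = (
        (out["liver_tpm"] >= liver_tpm_floor)
        & (out["cv"] >= cv_cut)
        & (out["cv"] > 0)
        & out["liver_is_max"]
    )
    order = out.sort_values(
        ["cv", "liver_tpm"], ascending=[False, False], kind="mergesort"
    ).index
    rank = pd.Series(np.arange(1, len(order) + 1), index=order)
    out["selectivity_rank"] = rank.reindex(out.index)
    out.attrs["cv_cut"] = cv_cut
    return out


def _read_symbols(symbols, source: str) -> set[str]:
    up = [str(s).upper() for s in symbols]
    if len(up) != len(set(up)):
        warnings.warn(
            f"duplicate symbols in {source} list; deduplicating", stacklevel=3
        )
    return set(up)


def secretion_flags(
    genes,
    list_hepatocyte,
    list_blood,
    list_predicted,
) -> pd.DataFrame:
    """Per-gene secretion-evidence flags from the three membership lists.

    Matching is case-insensitive exact symbol match.  ``secreted`` is the
    OR of the three flags.
    """
    hep = _read_symbols(list_hepatocyte, "hepatocyte secretome")
    blood = _read_symbols(list_blood, "blood proteome")
    pred = _read_symbols(list_predicted, "predicted secreted")
    genes = list(genes)
    up = [str(g).upper() for g in genes]
    out = pd.DataFrame(
        {
            "hepatocyte_secretome": [g in hep for g in up],
            "blood_proteome": [g in blood for g in up],
            "predicted_secreted": [g in pred for g in up],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    out["secreted"] = out.any(axis=1)
    return out


def select_candidates(
    deg_set: set[str],
    de: pd.DataFrame,
    scores: pd.DataFrame,
    evidence: pd.DataFrame,
    indirect_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble the candidate biomarker table.

    candidates = DEGs  ∩  liver-selective  ∩  (secreted  ∪  indirect),
    where *indirect* genes (keys of ``indirect_map``) are carried despite
    lacking secretion evidence because a named metabolite serves as the
    circulating readout.

    The composite rank averages three per-candidate ranks — padj
    ascending, \\|log2fc\\| descending, CV descending — and resolves ties
    lexicographically by gene id.  Returns an empty table when no DEG
    survives; that is a legitimate outcome, not an error.
    """
    indirect_map = dict(indirect_map or {})
    columns = [
        "log2fc",
        "padj",
        "cv",
        "liver_tpm",
        *EVIDENCE_SOURCES,
        "secreted",
        "marker_mode",
        "metabolite_name",
        "composite_rank",
    ]
    selective = set(scores.index[scores["selective"]])
    secreted = set(evidence.index[evidence["secreted"]])
    kept = sorted(
        (deg_set & selective & (secreted | set(indirect_map)))
    )
    if not kept:
        return pd.DataFrame(columns=columns, index=pd.Index([], name="gene_id"))
    rows = []
    for g in kept:
        is_secreted = g in secreted
        ev = evidence.loc[g] if g in evidence.index else None
        rows.append(
            {
                "gene_id": g,
                "log2fc": float(de.loc[g, "log2fc"]),
                "padj": float(de.loc[g, "padj"]),
                "cv": float(scores.loc[g, "cv"]),
                "liver_tpm": float(scores.loc[g, "liver_tpm"]),
                **{
                    src: bool(ev[src]) if ev is not None else False
                    for src in EVIDENCE_SOURCES
                },
                "secreted": is_secreted,
                "marker_mode": "direct" if is_secreted else "indirect_metabolite",
                "metabolite_name": indirect_map.get(g, "") if not is_secreted else "",
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    r_padj = out["padj"].rank(method="average", ascending=True)
    r_lfc = out["log2fc"].abs().rank(method="average", ascending=False)
    r_cv = out["cv"].rank(method="average", ascending=False)
    mean_rank = (r_padj + r_lfc + r_cv) / 3.0
    order = sorted(out.index, key=lambda g: (mean_rank[g], g))
    out["composite_rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=order
    ).reindex(out.index)
    return out.sort_values("composite_rank")[columns]


def secreted_deg_count(deg_set: set[str], evidence: pd.DataFrame) -> int:
    """Number of DEGs whose product carries any secretion evidence."""
    secreted = set(evidence.index[evidence["secreted"]])
    return len(deg_set & secreted)


def plot_selectivity(
    scores: pd.DataFrame,
    deg_set: set[str],
    candidates: pd.DataFrame,
    path,
) -> None:
    """CV-versus-liver-TPM scatter with DEGs and candidates highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    x = np.log10(scores["liver_tpm"] + 1.0)
    ax.scatter(x, scores["cv"], s=6, c="0.8", label="all genes")
    degs = scores.index.intersection(sorted(deg_set))
    ax.scatter(
        np.log10(scores.loc[degs, "liver_tpm"] + 1.0),
        scores.loc[degs, "cv"],
        s=12,
        c="tab:green",
        label="DEGs",
    )
    cand = scores.index.intersection(candidates.index)
    ax.scatter(
        np.log10(scores.loc[cand, "liver_tpm"] + 1.0),
        scores.loc[cand, "cv"],
        s=40,
        facecolors="none",
        edgecolors="tab:red",
        label="candidates",
    )
    ax.set_xlabel("log10(liver TPM + 1)")
    ax.set_ylabel("CV across tissues")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
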