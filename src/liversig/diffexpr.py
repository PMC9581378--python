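"""Negative-binomial differential expression between histology groups.

The model: counts for gene *g* in sample *j* are negative binomial with
mean ``mu_gj = q_g(group_j) * s_j`` and variance ``mu + alpha_g * mu**2``,
where ``s_j`` is a per-sample size factor (median-of-ratios) and
``alpha_g`` a per-gene overdispersion.  The group-level abundance ``q`` is
fitted by maximum likelihood per group, the log2 fold change between a
contrast group and the reference is tested with a Wald statistic whose
standard error comes from the observed Fisher information, and p values
are adjusted with the Benjamini-Hochberg step-up.

Deliberate simplifications relative to full empirical-Bayes NB pipelines
(no dispersion shrinkage toward a mean-trend, no outlier refitting, no
independent filtering) are documented in the methods note; calibration is
verified by simulation instead of by replicating any particular tool.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import CountMatrix, InputError

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "wald_test",
    "bh_adjust",
    "deg_sets",
    "pca_top_variable",
    "DISPERSION_FLOOR",
]

DISPERSION_FLOOR = 1e-8

RESULT_COLUMNS = ["base_mean", "log2fc", "se", "wald_stat", "p", "padj"]


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with a nonzero count in every sample; for
    each sample the factor is the median across reference genes of the
    ratio count / geometric-mean-count.
    """
    counts = cm.counts.to_numpy(dtype=float)
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise InputError(
            "no gene has nonzero counts in every sample; cannot form the "
            "median-of-ratios reference set"
        )
    logc = np.log(counts[ref])
    log_geo_mean = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_geo_mean, axis=0))
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


def estimate_dispersion(
    cm: CountMatrix, factors: pd.Series, floor: float = DISPERSION_FLOOR
) -> pd.Series:
    """Method-of-moments NB dispersion per gene, pooled within groups.

    On size-factor-normalized counts, each group contributes the moment
    estimate ``(s2 - m) / m**2`` (variance = mu + alpha mu**2 solved for
    alpha); group estimates are pooled with weights ``n_g - 1`` and the
    result clipped at ``floor``.  Genes with all-zero counts get NaN and
    are excluded downstream.
    """
    norm = cm.counts.to_numpy(dtype=float) / factors.reindex(cm.sample_ids).to_numpy()
    n_genes = norm.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    for group in cm.groups():
        cols = [cm.sample_ids.get_loc(s) for s in cm.samples_in(group)]
        if len(cols) < 2:
            raise InputError(f"group {group!r} has fewer than 2 samples")
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m**2
        ok = m > 0
        w = len(cols) - 1
        num[ok] += w * a[ok]
        den[ok] += w
    with np.errstate(invalid="ignore"):
        alpha = num / den
    alpha = np.where(den > 0, np.maximum(alpha, floor), np.nan)
    return pd.Series(alpha, index=cm.gene_ids, name="dispersion")


def _fit_group(k: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 60):
    """MLE of the group abundance q for NB(mean = q*s_j, disp = alpha).

    Solves the score equation sum_j (k_j - q s_j) / (1 + alpha q s_j) = 0
    by Newton iteration on log q, vectorized over genes.  Groups with all
    zero counts sit at the boundary; q is clamped at half a normalized
    count so the log fold change stays finite.

    Returns (q, fisher_info) arrays of shape (n_genes,).
    """
    k = np.asarray(k, dtype=float)
    s = np.asarray(s, dtype=float)
    total_s = s.sum()
    q_floor = 0.5 / total_s
    q = np.maximum(k.sum(axis=1) / total_s, q_floor)
    b = np.log(q)
    for _ in range(n_iter):
        q = np.exp(b)
        mu = q[:, None] * s[None, :]
        denom = 1.0 + alpha[:, None] * mu
        g = ((k - mu) / denom).sum(axis=1)
        # d/dq of the score, times q (chain rule for log-scale Newton)
        dg_dq = -(s[None, :] * (1.0 + alpha[:, None] * k) / denom**2).sum(axis=1)
        step = g / (dg_dq * q)
        step = np.clip(step, -4.0, 4.0)
        b = b - step
        if np.max(np.abs(g)) < 1e-10:
            break
    q = np.maximum(np.exp(b), q_floor)
    mu = q[:, None] * s[None, :]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return q, info


def wald_test(
    cm: CountMatrix,
    factors: pd.Series,
    dispersions: pd.Series,
    contrast: str,
    reference: str = "NAS0-1",
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``contrast`` versus ``reference``.

    Returns a DataFrame over the full gene universe with columns
    ``base_mean, log2fc, se, wald_stat, p, padj``; genes with zero counts
    in both contrast groups (or undefined dispersion) carry NaN
    statistics and do not enter the BH family.
    """
    for label in (contrast, reference):
        samples = cm.samples_in(label)
        if not samples:
            raise InputError(f"contrast group {label!r} absent from sample sheet")
        if len(samples) < 2:
            raise InputError(f"contrast group {label!r} has fewer than 2 samples")

    s_all = factors.reindex(cm.sample_ids).to_numpy(dtype=float)
    counts = cm.counts.to_numpy(dtype=float)
    base_mean = (counts / s_all).mean(axis=1)

    idx_c = [cm.sample_ids.get_loc(x) for x in cm.samples_in(contrast)]
    idx_r = [cm.sample_ids.get_loc(x) for x in cm.samples_in(reference)]
    k_c, s_c = counts[:, idx_c], s_all[idx_c]
    k_r, s_r = counts[:, idx_r], s_all[idx_r]

    alpha = dispersions.reindex(cm.gene_ids).to_numpy(dtype=float)
    tested = ~np.isnan(alpha) & ((k_c.sum(axis=1) + k_r.sum(axis=1)) > 0)

    out = pd.DataFrame(
        np.nan, index=cm.gene_ids, columns=RESULT_COLUMNS, dtype=float
    )
    out["base_mean"] = base_mean
    if tested.any():
        a = alpha[tested]
        q_c, info_c = _fit_group(k_c[tested], s_c, a)
        q_r, info_r = _fit_group(k_r[tested], s_r, a)
        ln2 = np.log(2.0)
        log2fc = (np.log(q_c) - np.log(q_r)) / ln2
        se = np.sqrt(1.0 / info_c + 1.0 / info_r) / ln2
        wald = log2fc / se
        p = 2.0 * stats.norm.sf(np.abs(wald))
        out.loc[tested, "log2fc"] = log2fc
        out.loc[tested, "se"] = se
        out.loc[tested, "wald_stat"] = wald
        out.loc[tested, "p"] = p
        out.loc[tested, "padj"] = bh_adjust(p)
    out.attrs["contrast"] = contrast
    out.attrs["reference"] = reference
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values.

    ``padj_(i) = min_{j >= i} m * p_(j) / j``, clipped at 1, returned in
    the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InputError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def deg_sets(
    results: dict[str, pd.DataFrame], alpha: float = 0.05
) -> tuple[dict[str, set[str]], dict[tuple[str, ...], int]]:
    """DEG sets per contrast plus Venn-style intersection counts.

    All result tables must share the same gene universe (full index,
    untested genes NaN).  Returns ``({label: set_of_genes}, {label tuple:
    intersection count})`` with every pairwise and, for three contrasts,
    the triple intersection.
    """
    labels = list(results)
    if not labels:
        raise InputError("no DE results supplied")
    universe = results[labels[0]].index
    for lab in labels[1:]:
        if not results[lab].index.equals(universe):
            raise InputError(f"result table {lab!r} has a different gene universe")
    sets = {
        lab: set(df.index[df["padj"] < alpha]) for lab, df in results.items()
    }
    overlaps: dict[tuple[str, ...], int] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            overlaps[(a, b)] = len(sets[a] & sets[b])
    if len(labels) >= 3:
        from itertools import combinations

        for combo in combinations(labels, 3):
            inter = set.intersection(*(sets[c] for c in combo))
            overlaps[combo] = len(inter)
    return sets, overlaps


def pca_top_variable(
    cm: CountMatrix,
    n_top: int = 500,
    factors: pd.Series | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA on the most variable genes.

    Counts are normalized, transformed with log2(x + 1), the ``n_top``
    genes with highest variance retained, and the centered sample x gene
    matrix decomposed by SVD.  Component signs follow the convention that
    the largest-magnitude gene loading on each component is positive.

    Returns (coordinates DataFrame indexed by sample, variance-explained
    fractions).
    """
    if cm.counts.shape[1] < 2:
        raise InputError("PCA requires at least 2 samples")
    if n_top > cm.counts.shape[0]:
        raise InputError(
            f"n_top={n_top} exceeds the {cm.counts.shape[0]} available genes"
        )
    if factors is None:
        factors = size_factors(cm)
    norm = cm.counts.to_numpy(dtype=float) / factors.reindex(cm.sample_ids).to_numpy()
    logx = np.log2(norm + 1.0)
    gene_var = logx.var(axis=1, ddof=1)
    top = np.argsort(gene_var, kind="mergesort")[::-1][:n_top]
    x = logx[top].T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    coords = u * sv
    n_comp = coords.shape[1]
    var_explained = sv**2 / (sv**2).sum() if sv.size else np.array([])
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return pd.DataFrame(coords, index=cm.sample_ids, columns=cols), var_explained
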