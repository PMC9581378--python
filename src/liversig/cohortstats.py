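"""Clinical cohort layer: histology classifiers and nonparametric tests.

Histology grading follows the CRN/Kleiner conventions: the NAFLD
activity score (NAS) is the unweighted sum of steatosis (0-3), lobular
inflammation (0-3) and hepatocellular ballooning (0-2); fibrosis stages
F1a/F1b/F1c collapse to F1; the histological NASH rule requires all
three NAS components to be present.  Group comparisons use the
Kruskal-Wallis test with midranks and tie correction, Dunn's post hoc z
against the reference group, and Spearman correlation; summaries report
median with interquartile range per group as clinical tables do.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .types import InputError

__all__ = [
    "collapse_fibrosis",
    "nas_group",
    "nash_classify",
    "eligibility",
    "body_composition",
    "kruskal_wallis",
    "dunn_posthoc",
    "spearman",
    "summarize_cohort",
    "filter_count",
]

_FIBROSIS_LABELS = {"0", "1a", "1b", "1c", "1", "2", "3", "4"}

NAS_GROUPS = {"NAS0-1": (0, 1), "NAS2-3": (2, 3), "NAS4-6": (4, 6)}


def collapse_fibrosis(stage_label) -> int:
    """Collapse fibrosis sub-stages: 1a/1b/1c -> 1, others unchanged."""
    label = str(stage_label).strip().lower().lstrip("f")
    if label not in _FIBROSIS_LABELS:
        raise InputError(f"unknown fibrosis stage label {stage_label!r}")
    return 1 if label in {"1a", "1b", "1c"} else int(label)


def nas_group(nas_total: int) -> str:
    """Map a NAS total to its severity group label.

    0-1 no/mild, 2-3 moderate, 4-6 more advanced.  Totals of 7-8, while
    arithmetically possible, fall outside the defined grouping and raise.
    """
    if not 0 <= nas_total <= 8:
        raise InputError(f"NAS total {nas_total} outside 0-8")
    for label, (lo, hi) in NAS_GROUPS.items():
        if lo <= nas_total <= hi:
            return label
    raise InputError(
        f"NAS total {nas_total} is outside the defined groups (0-1, 2-3, 4-6)"
    )


def nash_classify(steatosis: int, inflammation: int, ballooning: int) -> bool:
    """Histological NASH rule: steatosis, ballooning and inflammation all present."""
    if not (0 <= steatosis <= 3 and 0 <= inflammation <= 3 and 0 <= ballooning <= 2):
        raise InputError(
            f"sub-scores out of range: steatosis={steatosis}, "
            f"inflammation={inflammation}, ballooning={ballooning}"
        )
    return steatosis >= 1 and ballooning >= 1 and inflammation >= 1


def eligibility(fib4=None, nfs=None, te_kpa=None) -> bool:
    """Screening rule for likely NASH with fibrosis.

    True iff FIB-4 >= 1.30, NAFLD fibrosis score >= -1.455, or transient
    elastography >= 7.0 kPa (inclusive thresholds; scores are inputs,
    their internal formulas are not computed here).
    """
    values = [fib4, nfs, te_kpa]
    if all(v is None or (isinstance(v, float) and np.isnan(v)) for v in values):
        raise InputError("eligibility requires at least one screening score")

    def ok(v):
        return v is not None and not (isinstance(v, float) and np.isnan(v))

    return (
        (ok(fib4) and fib4 >= 1.30)
        or (ok(nfs) and nfs >= -1.455)
        or (ok(te_kpa) and te_kpa >= 7.0)
    )


def body_composition(weight_kg: float, fat_kg: float, bone_kg: float):
    """Derived DXA covariates: lean mass and fat percent.

    lean = weight - fat - bone;  fat% = 100 * fat / weight.
    """
    if weight_kg <= 0:
        raise InputError("weight must be positive")
    if fat_kg < 0 or bone_kg < 0:
        raise InputError("fat and bone mass must be non-negative")
    if fat_kg + bone_kg > weight_kg:
        raise InputError(
            f"fat ({fat_kg}) + bone ({bone_kg}) exceeds total weight ({weight_kg})"
        )
    lean = weight_kg - fat_kg - bone_kg
    fat_pct = 100.0 * fat_kg / weight_kg
    return lean, fat_pct


def _ranks_and_tie_term(pooled: np.ndarray):
    ranks = stats.rankdata(pooled)  # midranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    return ranks, tie_sum


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square(k-1).

    ``groups`` is a list of 1-D numeric arrays, one per group.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InputError("Kruskal-Wallis requires at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise InputError("empty group in Kruskal-Wallis input")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise InputError("all values identical; tie correction degenerate")
    n = len(pooled)
    ranks, tie_sum = _ranks_and_tie_term(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - tie_sum / (n**3 - n)
    h /= correction
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def dunn_posthoc(
    groups: dict[str, np.ndarray], reference_label: str
) -> pd.DataFrame:
    """Dunn's post hoc z tests of each group against the reference.

    z_i = (Rbar_i - Rbar_ref) / sqrt(V * (1/n_i + 1/n_ref)) with the
    tie-corrected variance V = (N(N+1)/12) - tie_sum/(12(N-1)).  Two-sided
    normal p values are BH-adjusted across the reference comparisons only
    (the study design compares every group to the no/mild group, not all
    pairs).
    """
    if reference_label not in groups:
        raise InputError(f"reference group {reference_label!r} absent")
    labels = list(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks, tie_sum = _ranks_and_tie_term(pooled)
    mean_rank: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for lab, arr in zip(labels, arrays):
        mean_rank[lab] = float(ranks[start : start + len(arr)].mean())
        sizes[lab] = len(arr)
        start += len(arr)
    variance = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    rows = []
    for lab in labels:
        if lab == reference_label:
            continue
        se = np.sqrt(variance * (1.0 / sizes[lab] + 1.0 / sizes[reference_label]))
        z = (mean_rank[lab] - mean_rank[reference_label]) / se
        rows.append(
            {
                "comparison": f"{lab} vs {reference_label}",
                "z": z,
                "p": 2.0 * stats.norm.sf(abs(z)),
            }
        )
    out = pd.DataFrame(rows).set_index("comparison")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    rho is the Pearson correlation of the midranks; p comes from the t
    approximation with n-2 degrees of freedom, or from full permutation
    enumeration when ``exact=True`` (only sensible for n <= 9).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InputError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise InputError("Spearman correlation requires n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise InputError("constant input vector; rank correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 9:
            raise InputError("exact permutation p only supported for n <= 9")
        from itertools import permutations

        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        obs = abs(rho)
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = float((rx_c[list(perm)] * ry_c).sum()) / denom
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


_GRADE_VARIABLES = {
    "steatosis": range(0, 4),
    "lobular_inflammation": range(0, 4),
    "ballooning": range(0, 3),
    "nas_total": range(0, 9),
    "fibrosis_stage": range(0, 5),
}


def summarize_cohort(
    sheet: pd.DataFrame,
    group_col: str = "nas_group",
    continuous: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical-table summaries of a cohort sheet.

    Returns ``(summary, frequencies)``:

    * ``summary`` — one row per continuous variable with per-group
      ``median (Q1;Q3)`` (linear-interpolation quantiles) and the
      Kruskal-Wallis p value;
    * ``frequencies`` — long-format counts per grade per group for the
      histology variables present (plus a NASH yes/no row), the layout
      used by histology frequency tables.
    """
    if group_col not in sheet.columns:
        raise InputError(f"group column {group_col!r} absent from sheet")
    group_labels = [g for g in sheet[group_col].unique()]
    group_labels.sort(key=lambda g: str(g))
    if continuous is None:
        skip = set(_GRADE_VARIABLES) | {group_col, "participant_id", "nash"}
        continuous = [
            c
            for c in sheet.columns
            if c not in skip and pd.api.types.is_numeric_dtype(sheet[c])
        ]
    rows = []
    for var in continuous:
        if sheet[var].isna().all():
            warnings.warn(f"variable {var!r} all missing; skipped", stacklevel=2)
            continue
        row: dict[str, object] = {"variable": var}
        arrays = []
        for g in group_labels:
            vals = sheet.loc[sheet[group_col] == g, var].dropna().to_numpy(float)
            if len(vals):
                q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
                row[g] = f"{med:.3g} ({q1:.3g};{q3:.3g})"
                arrays.append(vals)
            else:
                row[g] = ""
        try:
            _, p = kruskal_wallis(arrays)
            row["kw_p"] = p
        except InputError:
            row["kw_p"] = np.nan
        rows.append(row)
    summary = pd.DataFrame(rows)

    freq_rows = []
    for var, grades in _GRADE_VARIABLES.items():
        if var not in sheet.columns:
            continue
        for grade in grades:
            entry = {"variable": var, "grade": str(grade)}
            for g in group_labels:
                entry[g] = int(
                    (sheet.loc[sheet[group_col] == g, var] == grade).sum()
                )
            freq_rows.append(entry)
    if "nash" in sheet.columns:
        for label, value in (("no", False), ("yes", True)):
            entry = {"variable": "nash", "grade": label}
            for g in group_labels:
                entry[g] = int(
                    (sheet.loc[sheet[group_col] == g, "nash"] == value).sum()
                )
            freq_rows.append(entry)
    frequencies = pd.DataFrame(freq_rows)
    return summary, frequencies


def _is_frequency_table(df: pd.DataFrame) -> bool:
    return {"variable", "grade"}.issubset(df.columns)


def filter_count(data: pd.DataFrame, predicate, variable: str | None = None) -> int:
    """Count participants satisfying a predicate.

    Two input shapes are accepted:

    * a long-format frequency table (columns ``variable, grade`` plus one
      count column per group): ``variable`` selects the grade rows and
      ``predicate(grade)`` decides which grades count; the group counts of
      matching grades are summed;
    * a per-participant cohort sheet: ``predicate(row)`` is evaluated per
      row and True rows are counted.
    """
    if len(data) == 0:
        return 0
    if _is_frequency_table(data):
        if variable is None:
            raise InputError("variable name required for frequency-table input")
        sub = data[data["variable"] == variable]
        if len(sub) == 0:
            raise InputError(f"unknown variable {variable!r} in frequency table")
        count_cols = [c for c in data.columns if c not in ("variable", "grade")]
        mask = [bool(predicate(g)) for g in sub["grade"]]
        return int(sub.loc[mask, count_cols].to_numpy().sum())
    try:
        mask = data.apply(predicate, axis=1)
    except KeyError as exc:
        raise InputError(f"predicate references unknown column: {exc}") from exc
    return int(mask.sum())


def parse_nas_group_label(label: str) -> tuple[int, int]:
    """NAS bounds (lo, hi) from a label like ``'NAS2-3'``."""
    m = re.fullmatch(r"NAS(\d+)-(\d+)", str(label))
    if not m:
        raise InputError(f"cannot parse NAS group label {label!r}")
    lo, hi = int(m.group(1)), int(m.group(2))
    if not 0 <= lo <= hi <= 8:
        raise InputError(f"NAS bounds out of range in label {label!r}")
    return lo, hi


__all__.append("parse_nas_group_label")
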