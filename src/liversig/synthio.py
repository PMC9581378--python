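"""Synthetic study generator with planted ground truth.

Every input the discovery pipeline consumes can be simulated here at
desk scale: a negative-binomial count matrix with group-specific planted
fold changes and per-sample library-size factors, a cross-tissue TPM
atlas with planted liver-selective genes, three secretion-evidence gene
lists, and a clinical cohort sheet (histology sub-scores consistent with
each participant's severity group, continuous covariates with a
requested Spearman correlation structure via a Gaussian copula, and
plasma analytes).  All generators are pure functions of
(configuration, seed), and every planted non-null effect is returned in
an explicit truth table so downstream stages can be tested for exact
recovery.

The default configuration mirrors a small bariatric-surgery NAFLD
cohort: 26 participants in three severity groups (8 / 12 / 6), 2000
genes, a 33-tissue atlas, four planted liver-selective candidate genes
(three with secretion evidence, one enzyme read out via a plasma
metabolite), and a background of non-selective differentially expressed
genes so the filters are non-trivially exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohortstats import nas_group, nash_classify, parse_nas_group_label
from .types import CountMatrix, InputError, TissueAtlas

__all__ = [
    "SimulationConfig",
    "default_config",
    "simulate_counts",
    "simulate_atlas",
    "simulate_secretome_lists",
    "simulate_cohort",
    "simulate_gene_sets",
]

EVIDENCE_SOURCES = ("hepatocyte_secretome", "blood_proteome", "predicted_secreted")

# non-liver tissue names for the atlas, HPA-flavoured; sliced to n_tissues-1
_TISSUES = [
    "adipose", "adrenal_gland", "bone_marrow", "brain", "breast", "colon",
    "duodenum", "endometrium", "esophagus", "fallopian_tube", "gallbladder",
    "heart", "kidney", "lung", "lymph_node", "ovary", "pancreas", "placenta",
    "prostate", "rectum", "salivary_gland", "skeletal_muscle", "skin",
    "small_intestine", "smooth_muscle", "spleen", "stomach", "testis",
    "thyroid", "tonsil", "urinary_bladder", "appendix", "cerebellum",
    "pituitary", "parathyroid", "epididymis", "seminal_vesicle",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    ``planted_deg_lfc`` maps gene id -> {group label: log2 fold change
    versus the reference group}; ``planted_liver_selective`` is the set
    of genes given a liver-dominant atlas profile;
    ``secretome_membership`` maps gene id -> subset of the three
    evidence source names; ``clinical_rank_correlations`` maps covariate
    pairs to target Spearman rho.
    """

    seed: int = 0
    n_genes: int = 2000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"NAS0-1": 8, "NAS2-3": 12, "NAS4-6": 6}
    )
    reference_group: str = "NAS0-1"
    baseline_mean_log_range: tuple[float, float] = (np.log(20.0), np.log(2000.0))
    dispersion: float = 0.05
    size_factor_log_range: tuple[float, float] = (np.log(0.7), np.log(1.4))
    planted_deg_lfc: dict[str, dict[str, float]] = field(default_factory=dict)
    n_tissues: int = 33
    planted_liver_selective: frozenset[str] = frozenset()
    atlas_background_tpm: float = 1.0
    atlas_liver_tpm: float = 500.0
    atlas_noise_sd: float = 0.10
    secretome_membership: dict[str, frozenset[str]] = field(default_factory=dict)
    indirect_markers: dict[str, str] = field(default_factory=dict)
    clinical_rank_correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("bmi", "fat_pct"): 0.80,
            ("age", "plasma_igfbp1"): 0.47,
            ("bmi", "plasma_sam"): 0.51,
        }
    )

    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def validate(self) -> None:
        for group, n in self.group_sizes.items():
            if n < 2:
                raise InputError(
                    f"group {group!r} has size {n}; differential expression "
                    "requires at least 2 replicates per group"
                )
        if self.reference_group not in self.group_sizes:
            raise InputError(
                f"reference group {self.reference_group!r} not among group sizes"
            )
        if np.any(np.asarray(self.dispersion) <= 0):
            raise InputError("dispersion must be strictly positive")
        universe = set(self.gene_ids())
        planted = set(self.planted_deg_lfc) | set(self.planted_liver_selective)
        planted |= set(self.secretome_membership)
        outside = planted - universe
        if outside:
            raise InputError(
                f"planted gene ids outside the simulated universe: "
                f"{sorted(outside)[:5]}"
            )
        for gene, sources in self.secretome_membership.items():
            unknown = set(sources) - set(EVIDENCE_SOURCES)
            if unknown:
                raise InputError(
                    f"unknown evidence sources for {gene}: {sorted(unknown)}"
                )
        for pair, rho in self.clinical_rank_correlations.items():
            if not -1.0 <= rho <= 1.0:
                raise InputError(f"target Spearman rho for {pair} outside [-1, 1]")


def default_config(seed: int = 0) -> SimulationConfig:
    """Default planted scenario.

    Four candidate genes (G0001-G0004) are liver-selective and strongly
    downregulated with severity; G0001-G0003 carry secretion evidence
    spread over the three sources and G0004 is a non-secreted enzyme
    mapped to a plasma metabolite.  Forty additional non-selective DEGs
    and a handful of selective non-DEGs make every filter informative,
    and ~150 background genes receive random secretion evidence.
    """
    cfg = SimulationConfig(seed=seed)
    genes = cfg.gene_ids()
    candidates = ["G0001", "G0002", "G0003", "G0004"]
    lfc: dict[str, dict[str, float]] = {}
    for g in candidates:
        lfc[g] = {"NAS2-3": -1.5, "NAS4-6": -2.0}
    # non-selective DEGs, alternating direction; half only in the
    # advanced group so the Venn structure is non-degenerate
    extra = [f"G{i:04d}" for i in range(100, 140)]
    for j, g in enumerate(extra):
        val = 1.5 if j % 2 == 0 else -1.5
        lfc[g] = (
            {"NAS2-3": val, "NAS4-6": val} if j % 4 < 2 else {"NAS4-6": val}
        )
    selective = frozenset(candidates + [f"G{i:04d}" for i in range(50, 56)])
    membership: dict[str, frozenset[str]] = {
        "G0001": frozenset({"hepatocyte_secretome"}),
        "G0002": frozenset({"blood_proteome"}),
        "G0003": frozenset({"predicted_secreted", "hepatocyte_secretome"}),
    }
    rng = np.random.default_rng(seed + 20_000)
    background = rng.choice(
        [g for g in genes if g not in candidates], size=150, replace=False
    )
    for g in background:
        k = int(rng.integers(1, 4))
        membership[str(g)] = frozenset(
            rng.choice(EVIDENCE_SOURCES, size=k, replace=False).tolist()
        )
    return replace(
        cfg,
        planted_deg_lfc=lfc,
        planted_liver_selective=selective,
        secretome_membership=membership,
        indirect_markers={"G0004": "S-adenosylmethionine"},
    )


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    samples, groups = [], []
    for group, n in config.group_sizes.items():
        for i in range(n):
            samples.append(f"{group}_r{i + 1:02d}")
            groups.append(group)
    return samples, groups


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the count matrix and return it with the planted truth.

    Counts are NB(mean = baseline * 2**lfc(group) * size_factor,
    variance = mu + alpha mu**2); the truth table lists every planted
    non-null (gene, group, log2fc, sign).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    samples, group_of = _sample_ids(config)
    lo, hi = config.baseline_mean_log_range
    baseline = np.exp(rng.uniform(lo, hi, size=config.n_genes))
    s_lo, s_hi = config.size_factor_log_range
    size_factors = np.exp(rng.uniform(s_lo, s_hi, size=len(samples)))

    lfc = np.zeros((config.n_genes, len(samples)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, per_group in config.planted_deg_lfc.items():
        for j, group in enumerate(group_of):
            if group in per_group:
                lfc[gene_pos[g], j] = per_group[group]

    mean = baseline[:, None] * (2.0**lfc) * size_factors[None, :]
    alpha = np.broadcast_to(
        np.asarray(config.dispersion, dtype=float), (config.n_genes,)
    )
    n_param = 1.0 / alpha
    p_param = n_param[:, None] / (n_param[:, None] + mean)
    counts = rng.negative_binomial(n_param[:, None], p_param)

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples),
        pd.Series(group_of, index=samples, name="nas_group"),
    )
    truth_rows = [
        {
            "gene_id": g,
            "group": group,
            "log2fc": v,
            "sign": int(np.sign(v)),
        }
        for g, per_group in sorted(config.planted_deg_lfc.items())
        for group, v in sorted(per_group.items())
    ]
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "group", "log2fc", "sign"])
    return cm, truth


def simulate_atlas(
    config: SimulationConfig,
) -> tuple[TissueAtlas, frozenset[str]]:
    """Simulate the cross-tissue TPM atlas with planted selective genes.

    Planted genes: liver TPM around ``atlas_liver_tpm``, background TPM
    elsewhere, both with multiplicative lognormal noise.  Non-planted
    genes: a gene-specific base TPM shared by all tissues, with the same
    noise, hence a low CV.
    """
    if config.n_tissues < 3:
        raise InputError(
            f"n_tissues={config.n_tissues}; the cross-tissue CV needs >= 3 tissues"
        )
    if config.atlas_liver_tpm <= config.atlas_background_tpm:
        raise InputError("atlas_liver_tpm must exceed atlas_background_tpm")
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    genes = config.gene_ids()
    tissues = ["liver"] + _TISSUES[: config.n_tissues - 1]
    if len(tissues) < config.n_tissues:
        tissues += [f"tissue_{i}" for i in range(len(tissues), config.n_tissues)]

    base = np.exp(rng.uniform(np.log(5.0), np.log(200.0), size=config.n_genes))
    tpm = base[:, None] * np.ones((1, config.n_tissues))
    planted = config.planted_liver_selective
    mask = np.array([g in planted for g in genes])
    tpm[mask, :] = config.atlas_background_tpm
    tpm[mask, 0] = config.atlas_liver_tpm
    if config.atlas_noise_sd > 0:
        noise = np.exp(
            rng.normal(0.0, config.atlas_noise_sd, size=tpm.shape)
        )
        tpm = tpm * noise
    atlas = TissueAtlas(
        pd.DataFrame(tpm, index=pd.Index(genes, name="gene_id"), columns=tissues)
    )
    return atlas, frozenset(planted)


def simulate_secretome_lists(
    config: SimulationConfig,
) -> dict[str, list[str]]:
    """Materialize the three secretion-evidence gene lists.

    The union of the three lists equals the planted secreted truth set
    (genes with any evidence source in ``secretome_membership``).
    """
    config.validate()
    lists: dict[str, list[str]] = {src: [] for src in EVIDENCE_SOURCES}
    for gene in sorted(config.secretome_membership):
        for src in config.secretome_membership[gene]:
            lists[src].append(gene)
    return lists


# ------------------------------------------------------------------ cohort

# marginal quantile functions for the copula-driven covariates
def _marginals():
    from scipy import stats as st

    return {
        "age": lambda u: st.norm.ppf(u, loc=47.0, scale=9.0),
        "bmi": lambda u: st.norm.ppf(u, loc=47.0, scale=5.5),
        "fat_pct": lambda u: st.norm.ppf(u, loc=49.0, scale=4.5),
        "c_peptide": lambda u: st.lognorm.ppf(u, s=0.45, scale=900.0),
        "plasma_lpa": lambda u: st.lognorm.ppf(u, s=0.8, scale=40.0),
        "plasma_igfbp1": lambda u: st.lognorm.ppf(u, s=0.6, scale=20.0),
        "plasma_a2ap": lambda u: st.norm.ppf(u, loc=100.0, scale=12.0),
        "plasma_sam": lambda u: st.lognorm.ppf(u, s=0.4, scale=90.0),
    }


_PLASMA_COLUMNS = ["plasma_lpa", "plasma_igfbp1", "plasma_a2ap", "plasma_sam"]

# fibrosis-stage probabilities per severity group (stages 0..4); stage-1
# draws are emitted as sub-stage labels 1a/1b/1c to exercise collapsing
_FIBROSIS_P = {
    "NAS0-1": [1.00, 0.00, 0.00, 0.00, 0.00],
    "NAS2-3": [0.75, 0.25, 0.00, 0.00, 0.00],
    "NAS4-6": [0.20, 0.35, 0.30, 0.15, 0.00],
}


def _spearman_to_pearson(rho_s: float) -> float:
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _copula_correlation(
    names: list[str], targets: dict[tuple[str, str], float]
) -> np.ndarray:
    """Build the Gaussian-copula correlation matrix, failing loudly on
    the first pair that makes it non-positive-semi-definite."""
    d = len(names)
    pos = {n: i for i, n in enumerate(names)}
    corr = np.eye(d)
    for (a, b), rho_s in targets.items():
        if a not in pos or b not in pos:
            raise InputError(f"unknown covariate in correlation pair ({a}, {b})")
        r = _spearman_to_pearson(rho_s)
        corr[pos[a], pos[b]] = corr[pos[b], pos[a]] = r
        if np.linalg.eigvalsh(corr).min() < -1e-9:
            raise InputError(
                f"correlation targets infeasible: adding pair ({a}, {b}) "
                "makes the copula correlation matrix non-positive-semi-definite"
            )
    return corr


def _valid_subscore_combos(lo: int, hi: int) -> list[tuple[int, int, int]]:
    return [
        (s, i, b)
        for s in range(4)
        for i in range(4)
        for b in range(3)
        if lo <= s + i + b <= hi
    ]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the clinical cohort sheet and the plasma analyte table.

    Histology sub-scores are drawn uniformly from the combinations
    compatible with each participant's severity group (so NAS totals are
    in range by construction); fibrosis stages follow group-specific
    frequencies with sub-stage labels for stage 1; continuous covariates
    are generated through a Gaussian copula hitting the requested
    Spearman correlations, then mapped to clinically plausible marginals.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    marginals = _marginals()
    names = list(marginals)
    corr = _copula_correlation(names, config.clinical_rank_correlations)

    rows = []
    participant = 0
    for group, n in config.group_sizes.items():
        lo, hi = parse_nas_group_label(group)
        combos = _valid_subscore_combos(lo, hi)
        for _ in range(n):
            participant += 1
            s, i, b = combos[rng.integers(len(combos))]
            stage = rng.choice(5, p=_FIBROSIS_P.get(group, [1, 0, 0, 0, 0]))
            if stage == 1:
                raw = rng.choice(["1a", "1b", "1c"])
            else:
                raw = str(stage)
            rows.append(
                {
                    "participant_id": f"P{participant:03d}",
                    "steatosis": s,
                    "lobular_inflammation": i,
                    "ballooning": b,
                    "nas_total": s + i + b,
                    "nas_group": nas_group(s + i + b),
                    "nash": nash_classify(s, i, b),
                    "fibrosis_stage_raw": raw,
                    "fibrosis_stage": 1 if stage == 1 else int(stage),
                }
            )
    sheet = pd.DataFrame(rows)
    n_total = len(sheet)

    # Gaussian copula sample -> uniforms -> marginals (monotone maps
    # preserve the Spearman correlation of the latent normals)
    w, v = np.linalg.eigh(corr)
    l_mat = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n_total, len(names))) @ l_mat.T
    from scipy import stats as st

    u = st.norm.cdf(z)
    cov = {name: marginals[name](u[:, j]) for j, name in enumerate(names)}

    sheet["age"] = np.round(np.clip(cov["age"], 20.0, 75.0), 1)
    height = rng.normal(1.72, 0.08, size=n_total)
    sheet["bmi"] = np.round(np.clip(cov["bmi"], 35.0, 65.0), 1)
    sheet["weight_kg"] = np.round(sheet["bmi"] * height**2, 1)
    sheet["fat_pct"] = np.round(np.clip(cov["fat_pct"], 30.0, 62.0), 1)
    sheet["fat_kg"] = np.round(sheet["fat_pct"] / 100.0 * sheet["weight_kg"], 1)
    sheet["bone_kg"] = np.round(np.clip(rng.normal(3.2, 0.25, n_total), 2.2, 4.2), 2)
    sheet["lean_kg"] = np.round(
        sheet["weight_kg"] - sheet["fat_kg"] - sheet["bone_kg"], 1
    )
    sheet["c_peptide"] = np.round(cov["c_peptide"], 0)
    # liver-stiffness and fibrosis scores shift upward with severity
    te_base = {"NAS0-1": 5.0, "NAS2-3": 8.5, "NAS4-6": 13.0}
    sheet["te_kpa"] = np.round(
        [
            te_base.get(g, 7.0) * float(np.exp(rng.normal(0.0, 0.25)))
            for g in sheet["nas_group"]
        ],
        1,
    )
    sheet["fib4"] = np.round(np.exp(rng.normal(np.log(0.65), 0.4, n_total)), 2)
    sheet["nfs"] = np.round(rng.normal(-1.0, 0.8, n_total), 2)

    plasma = pd.DataFrame({"participant_id": sheet["participant_id"]})
    for col in _PLASMA_COLUMNS:
        vals = np.round(cov[col], 2)
        plasma[col] = vals
        sheet[col] = vals
    return sheet, plasma


def simulate_gene_sets(
    config: SimulationConfig,
    n_random_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 40),
) -> dict[str, list[str]]:
    """Gene-set collection for the enrichment stage.

    Two signal sets collect the planted down- and up-regulated genes;
    the rest are random draws from the universe (null sets).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    genes = config.gene_ids()
    down = sorted(
        g
        for g, per_group in config.planted_deg_lfc.items()
        if all(v < 0 for v in per_group.values())
    )
    up = sorted(
        g
        for g, per_group in config.planted_deg_lfc.items()
        if all(v > 0 for v in per_group.values())
    )
    sets: dict[str, list[str]] = {}
    if down:
        sets["PLANTED_DOWNREGULATED"] = down
    if up:
        sets["PLANTED_UPREGULATED"] = up
    lo, hi = set_size_range
    for i in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"RANDOM_SET_{i + 1:02d}"] = sorted(members.tolist())
    return sets
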