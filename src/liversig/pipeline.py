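"""Orchestrated end-to-end runs: configuration, bundles and discovery.

``write_bundle`` materializes a complete synthetic study (counts, sample
sheet, atlas, secretion lists, gene sets, cohort sheet, plasma table,
truth tables) on disk; ``run_discovery`` executes differential
expression -> enrichment -> selectivity/secretome candidate selection ->
optional validation -> cohort summaries from a :class:`RunConfig`,
writing every output as TSV with a JSON provenance sidecar.  Runs are
deterministic: the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohortstats, diffexpr, enrichment, io, selectivity, synthio, validation
from .types import InputError, PipelineStageError

__all__ = ["RunConfig", "write_bundle", "run_discovery", "combined_de"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and knobs of a discovery run.

    ``validation_datasets`` maps a dataset name to a
    ``(counts_path, samples_path)`` pair.
    """

    out_dir: str
    counts: str
    samples: str
    atlas: str
    list_hepatocyte: str
    list_blood: str
    list_predicted: str
    gmt: str | None = None
    cohort: str | None = None
    indirect_map: str | None = None
    validation_datasets: dict[str, tuple[str, str]] = field(default_factory=dict)
    reference: str = "NAS0-1"
    alpha: float = 0.05
    liver_tpm_floor: float = 10.0
    cv_quantile: float = 0.90
    min_set_size: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InputError(f"alpha={self.alpha} must lie in (0, 1)")
        if not 0 < self.cv_quantile < 1:
            raise InputError("cv_quantile must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise InputError(f"config {path} must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        vd = raw.get("validation_datasets") or {}
        raw["validation_datasets"] = {k: tuple(v) for k, v in vd.items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_bundle(config: synthio.SimulationConfig, out_dir) -> RunConfig:
    """Simulate every pipeline input and write it under ``out_dir``.

    Returns a :class:`RunConfig` pointing at the written files, ready
    for :func:`run_discovery`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm, truth = synthio.simulate_counts(config)
    atlas, selective_truth = synthio.simulate_atlas(config)
    lists = synthio.simulate_secretome_lists(config)
    sheet, plasma = synthio.simulate_cohort(config)
    sets = synthio.simulate_gene_sets(config)

    io.write_counts(cm, out / "counts.tsv", out / "samples.tsv")
    io.write_atlas(atlas, out / "atlas.tsv")
    list_paths = {}
    for src, short in (
        ("hepatocyte_secretome", "hepatocyte"),
        ("blood_proteome", "blood"),
        ("predicted_secreted", "predicted"),
    ):
        p = out / f"secretome_{short}.txt"
        io.write_gene_list(lists[src], p)
        list_paths[short] = str(p)
    io.write_gmt(sets, out / "gene_sets.gmt")
    io.write_sheet(sheet, out / "cohort.tsv")
    io.write_sheet(plasma, out / "plasma.tsv")
    io.write_table(truth, out / "truth_degs.tsv", index=False)
    io.write_gene_list(sorted(selective_truth), out / "truth_selective.txt")
    secreted_truth = sorted(
        g for g, src in config.secretome_membership.items() if src
    )
    io.write_gene_list(secreted_truth, out / "truth_secreted.txt")
    indirect_path = out / "indirect_map.tsv"
    indirect_path.write_text(
        "".join(f"{g}\t{m}\n" for g, m in sorted(config.indirect_markers.items()))
    )
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["planted_deg_lfc"] = {
        g: dict(v) for g, v in config.planted_deg_lfc.items()
    }
    cfg_dict["planted_liver_selective"] = sorted(config.planted_liver_selective)
    cfg_dict["secretome_membership"] = {
        g: sorted(v) for g, v in config.secretome_membership.items()
    }
    cfg_dict["clinical_rank_correlations"] = {
        f"{a}|{b}": rho
        for (a, b), rho in config.clinical_rank_correlations.items()
    }
    io.write_provenance(out / "bundle.provenance.json", config.seed, cfg_dict, "simulate")
    return RunConfig(
        out_dir=str(out / "results"),
        counts=str(out / "counts.tsv"),
        samples=str(out / "samples.tsv"),
        atlas=str(out / "atlas.tsv"),
        list_hepatocyte=list_paths["hepatocyte"],
        list_blood=list_paths["blood"],
        list_predicted=list_paths["predicted"],
        gmt=str(out / "gene_sets.gmt"),
        cohort=str(out / "cohort.tsv"),
        indirect_map=str(indirect_path),
        seed=config.seed,
    )


def combined_de(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-gene best evidence across contrasts.

    For each gene, take the contrast with the smallest adjusted p value
    and report its log2fc/padj; used to rank candidates when several
    contrasts share the reference group.
    """
    labels = list(results)
    first = results[labels[0]]
    best = first.copy()
    for lab in labels[1:]:
        other = results[lab]
        better = other["padj"] < best["padj"].fillna(float("inf"))
        better = better.fillna(False)
        best.loc[better, :] = other.loc[better, :]
    return best


def _stage(name: str, fn, created: list[Path]):
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:  # abort: remove partial outputs
        for p in created:
            p.unlink(missing_ok=True)
        raise PipelineStageError(name, exc) from exc
    log.info("stage %-12s %6.2fs", name, time.perf_counter() - t0)
    return result


def run_discovery(cfg: RunConfig) -> dict:
    """Execute the full discovery pipeline.

    Returns a dict with the in-memory results (DE tables, DEG sets,
    enrichment, scores, candidates, validation, summaries) and the paths
    of every written artifact.  Any stage failure aborts with the stage
    name and removes partial outputs.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    cfg_dict = cfg.to_dict()

    def emit(df: pd.DataFrame, name: str, stage: str, index: bool = True) -> Path:
        p = out / name
        io.write_table(df, p, index=index)
        io.write_provenance(p.with_suffix(p.suffix + ".json"), cfg.seed, cfg_dict, stage)
        created.extend([p, p.with_suffix(p.suffix + ".json")])
        return p

    # ---- inputs -----------------------------------------------------
    def load():
        cm = io.read_counts(cfg.counts, cfg.samples)
        atlas = io.read_atlas(cfg.atlas)
        lists = {
            "hepatocyte": io.read_gene_list(cfg.list_hepatocyte),
            "blood": io.read_gene_list(cfg.list_blood),
            "predicted": io.read_gene_list(cfg.list_predicted),
        }
        gmt = io.read_gmt(cfg.gmt) if cfg.gmt else None
        cohort = io.read_sheet(cfg.cohort) if cfg.cohort else None
        indirect = io.read_indirect_map(cfg.indirect_map) if cfg.indirect_map else {}
        return cm, atlas, lists, gmt, cohort, indirect

    cm, atlas, lists, gmt, cohort, indirect = _stage("read", load, created)

    contrasts = [g for g in cm.groups() if g != cfg.reference]
    if not contrasts:
        raise PipelineStageError(
            "de", InputError("no non-reference group to contrast")
        )

    # ---- differential expression ------------------------------------
    def de_stage():
        factors = diffexpr.size_factors(cm)
        dispersions = diffexpr.estimate_dispersion(cm, factors)
        results = {
            g: diffexpr.wald_test(cm, factors, dispersions, g, cfg.reference)
            for g in contrasts
        }
        for g, df in results.items():
            emit(df, f"de_{g}.tsv", "de")
        coords, var_exp = diffexpr.pca_top_variable(
            cm, n_top=min(500, cm.counts.shape[0]), factors=factors
        )
        emit(coords, "pca_coordinates.tsv", "de")
        return factors, dispersions, results

    factors, dispersions, de_results = _stage("de", de_stage, created)

    def deg_stage():
        sets, overlaps = diffexpr.deg_sets(de_results, alpha=cfg.alpha)
        rows = [
            {"contrast": g, "n_degs": len(s), "genes": ";".join(sorted(s))}
            for g, s in sets.items()
        ]
        rows += [
            {
                "contrast": " & ".join(combo),
                "n_degs": n,
                "genes": "",
            }
            for combo, n in overlaps.items()
        ]
        emit(pd.DataFrame(rows), "deg_sets.tsv", "de", index=False)
        return sets, overlaps

    sets_by_contrast, venn = _stage("deg_sets", deg_stage, created)
    deg_union: set[str] = set().union(*sets_by_contrast.values())

    # ---- enrichment --------------------------------------------------
    enrich_results = {}
    if gmt:
        def enrich_stage():
            for g, df in de_results.items():
                z = enrichment.gene_level_z(df)
                res = enrichment.stouffer_set_test(z, gmt, min_size=cfg.min_set_size)
                enrich_results[g] = res
                emit(res, f"enrichment_{g}.tsv", "enrichment")
        _stage("enrichment", enrich_stage, created)

    # ---- selectivity + secretome ------------------------------------
    def select_stage():
        scores = selectivity.tissue_cv(atlas)
        scores = selectivity.classify_selective(
            scores, cfg.liver_tpm_floor, cfg.cv_quantile
        )
        evidence = selectivity.secretion_flags(
            scores.index, lists["hepatocyte"], lists["blood"], lists["predicted"]
        )
        best_de = combined_de(de_results)
        cands = selectivity.select_candidates(
            deg_union, best_de, scores, evidence, indirect
        )
        n_secreted = selectivity.secreted_deg_count(deg_union, evidence)
        emit(scores, "selectivity_scores.tsv", "select")
        emit(cands, "candidates.tsv", "select")
        try:
            selectivity.plot_selectivity(
                scores, deg_union, cands, out / "selectivity_scatter.png"
            )
        except Exception:  # plotting is best-effort decoration
            log.warning("selectivity scatter could not be rendered")
        return scores, evidence, cands, n_secreted

    scores, evidence, candidates, n_secreted_degs = _stage(
        "select", select_stage, created
    )

    # ---- validation --------------------------------------------------
    val_reports: dict[str, pd.DataFrame] = {}
    concord = None
    if cfg.validation_datasets and len(candidates):
        def val_stage():
            nonlocal concord
            for name, (cpath, spath) in cfg.validation_datasets.items():
                ds = io.read_counts(cpath, spath)
                per_contrast = []
                for g in [x for x in ds.groups() if x != cfg.reference]:
                    rep = validation.revalidate(candidates, ds, g, cfg.reference)
                    rep = rep.assign(dataset=name, contrast=g)
                    per_contrast.append(rep)
                val_reports[name] = pd.concat(per_contrast)
            long = pd.concat(val_reports.values())
            emit(long, "validation.tsv", "validate")
            concord = validation.concordance(val_reports, candidates)
            emit(concord.to_frame(), "concordance.tsv", "validate")
        _stage("validate", val_stage, created)

    # ---- cohort summaries -------------------------------------------
    summaries = None
    if cohort is not None:
        def cohort_stage():
            summary, freq = cohortstats.summarize_cohort(cohort)
            emit(summary, "cohort_summary.tsv", "clinstats", index=False)
            emit(freq, "cohort_frequencies.tsv", "clinstats", index=False)
            return summary, freq
        summaries = _stage("clinstats", cohort_stage, created)

    overview = pd.DataFrame(
        [
            {
                "n_genes": cm.counts.shape[0],
                "n_samples": cm.counts.shape[1],
                **{f"n_degs_{g}": len(s) for g, s in sets_by_contrast.items()},
                "n_degs_union": len(deg_union),
                "n_secreted_degs": n_secreted_degs,
                "n_candidates": len(candidates),
            }
        ]
    )
    emit(overview, "run_overview.tsv", "summary", index=False)

    return {
        "counts": cm,
        "factors": factors,
        "dispersions": dispersions,
        "de": de_results,
        "deg_sets": sets_by_contrast,
        "venn": venn,
        "deg_union": deg_union,
        "enrichment": enrich_results,
        "scores": scores,
        "evidence": evidence,
        "candidates": candidates,
        "n_secreted_degs": n_secreted_degs,
        "validation": val_reports,
        "concordance": concord,
        "summaries": summaries,
        "out_dir": str(out),
    }
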