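"""Readers and writers for the on-disk pipeline formats.

All tabular files are TSV with ``#``-prefixed comment lines and gene ids
in the first column; gene lists are one symbol per line; gene-set
collections use the standard GMT layout (name, description, then
tab-separated members).  Every writer has a matching reader and the pair
round-trips exactly.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import pandas as pd

from .types import CountMatrix, InputError, TissueAtlas

__all__ = [
    "read_counts",
    "read_sheet",
    "read_atlas",
    "read_gene_list",
    "read_gmt",
    "read_indirect_map",
    "write_counts",
    "write_sheet",
    "write_atlas",
    "write_gene_list",
    "write_gmt",
    "write_table",
    "read_table",
    "write_provenance",
    "config_hash",
]


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_counts(counts_path, samples_path, group_col: str = "nas_group") -> CountMatrix:
    """Read a count matrix TSV plus its sample sheet into a CountMatrix.

    The counts file has gene ids in the first column and sample ids as
    header; the sample sheet has sample ids in the first column and a
    ``group_col`` column with the severity label.
    """
    counts = _read_tsv(counts_path, index_col=0)
    sheet = _read_tsv(samples_path, index_col=0)
    if group_col not in sheet.columns:
        raise InputError(
            f"sample sheet {samples_path} lacks group column {group_col!r}"
        )
    return CountMatrix(counts, sheet[group_col])


def read_sheet(path) -> pd.DataFrame:
    """Read a cohort sheet TSV (per-participant rows)."""
    sheet = _read_tsv(path)
    if "participant_id" not in sheet.columns:
        raise InputError(f"cohort sheet {path} lacks a participant_id column")
    return sheet


def read_atlas(path, liver: str = "liver") -> TissueAtlas:
    return TissueAtlas(_read_tsv(path, index_col=0), liver=liver)


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: member list}."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(
                f"{path}:{lineno}: GMT line has {len(fields)} tab fields, needs >= 3"
            )
        name = fields[0]
        if name in sets:
            raise InputError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = [f for f in fields[2:] if f]
    return sets


def read_indirect_map(path) -> dict[str, str]:
    """Two-column TSV: gene id -> circulating metabolite name."""
    df = _read_tsv(path, header=None, names=["gene_id", "metabolite"])
    return dict(zip(df["gene_id"].astype(str), df["metabolite"].astype(str)))


# ------------------------------------------------------------------ writers

def write_counts(cm: CountMatrix, counts_path, samples_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    sheet = pd.DataFrame({"nas_group": cm.sample_group})
    sheet.index.name = "sample_id"
    sheet.to_csv(samples_path, sep="\t")


def write_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def write_atlas(atlas: TissueAtlas, path) -> None:
    atlas.tpm.to_csv(path, sep="\t")


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in sets.items()
    ]
    Path(path).write_text("".join(f"{line}\n" for line in lines))


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return _read_tsv(path, index_col=index_col)


# -------------------------------------------------------------- provenance

def config_hash(config_dict: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, seed: int, config_dict: dict, stage: str) -> None:
    """JSON sidecar recording seed, config hash and stage for an output file."""
    from . import __version__

    sidecar = {
        "seed": seed,
        "config_hash": config_hash(config_dict),
        "stage": stage,
        "package_version": __version__,
    }
    Path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
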