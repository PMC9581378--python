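"""Core data containers shared across the pipeline.

Counts and atlas tables are held as plain pandas objects wrapped in thin
frozen dataclasses that enforce the structural contracts (integer counts,
labelled samples, a single liver column) once, at construction time, so
that downstream numerical code can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["InputError", "PipelineStageError", "CountMatrix", "TissueAtlas"]


class InputError(ValueError):
    """An input object or file violates a structural contract."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample RNA-seq counts with per-sample group labels.

    Parameters
    ----------
    counts
        DataFrame with unique gene ids as index, unique sample ids as
        columns, and non-negative integer entries.
    sample_group
        Series mapping every sample id (column of ``counts``) to its
        histology group label (e.g. ``"NAS0-1"``).
    """

    counts: pd.DataFrame
    sample_group: pd.Series

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene ids: {dups[:5]}")
        if c.columns.has_duplicates:
            raise InputError("duplicate sample ids in count matrix")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                bad = np.argwhere(np.mod(vals, 1) != 0)
                g, s = bad[0]
                raise InputError(
                    f"non-integer count for gene {c.index[g]!r}, sample {c.columns[s]!r}"
                )
            object.__setattr__(self, "counts", c.astype(np.int64))
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)
            g, s = bad[0]
            raise InputError(
                f"negative count for gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        missing = [s for s in c.columns if s not in self.sample_group.index]
        if missing:
            raise InputError(f"samples without a group label: {missing}")
        # keep only labels for present samples, in column order
        object.__setattr__(
            self, "sample_group", self.sample_group.reindex(c.columns)
        )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.sample_group:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_group[s] == group]

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.sample_group)


@dataclass(frozen=True)
class TissueAtlas:
    """Gene x tissue TPM table with a designated liver column.

    The atlas emulates consensus cross-tissue expression (one value per
    gene per tissue, TPM units) and is the substrate for the
    coefficient-of-variation selectivity score.
    """

    tpm: pd.DataFrame
    liver: str = "liver"

    def __post_init__(self):
        t = self.tpm
        if t.index.has_duplicates:
            raise InputError("duplicate gene ids in tissue atlas")
        n_liver = int((t.columns == self.liver).sum())
        if n_liver != 1:
            raise InputError(
                f"atlas must contain exactly one {self.liver!r} column, found {n_liver}"
            )
        if (t.to_numpy() < 0).any():
            raise InputError("negative TPM values in tissue atlas")

    @property
    def gene_ids(self) -> pd.Index:
        return self.tpm.index

    @property
    def tissue_names(self) -> pd.Index:
        return self.tpm.columns

    @property
    def n_tissues(self) -> int:
        return self.tpm.shape[1]
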