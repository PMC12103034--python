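"""Expression dataset container shared by all pipeline stages.

An :class:`ExpressionDataset` carries a genes × samples value matrix, gene
annotations (length, GC fraction, chromosome), sample metadata (family,
affection status, sex, batch) and a processing-stage tag.  Stages are
strictly ordered (``raw`` → ``log2fpkm`` → ``normalized`` →
``residualized``) and every normalization operation asserts and advances
the tag, so a matrix can never silently skip a step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STAGES = ("raw", "log2fpkm", "normalized", "residualized")

STATUS_LEVELS = ("case", "control", "validation")
SEX_LEVELS = ("F", "M", "unknown")


class StageError(ValueError):
    """An operation was applied at the wrong processing stage."""


@dataclass
class ExpressionDataset:
    """Genes × samples expression matrix with annotations and metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene ids), samples in columns (sample ids).
        Non-negative integers at the ``raw`` stage, reals afterwards.
    genes : pandas.DataFrame
        Indexed by gene id with columns ``length_bp`` (> 0), ``gc_frac``
        (in [0, 1]) and ``chrom``.
    samples : pandas.DataFrame
        Indexed by sample id with columns ``family_id``, ``status``
        (case / control / validation), ``sex`` (F / M / unknown) and
        ``batch``.
    stage : str
        One of ``raw``, ``log2fpkm``, ``normalized``, ``residualized``.
    """

    values: pd.DataFrame
    genes: pd.DataFrame
    samples: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not self.values.index.is_unique:
            raise ValueError("gene ids are not unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids are not unique")
        if not self.values.index.equals(self.genes.index):
            raise ValueError("values rows and gene annotations are misaligned")
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("values columns and sample metadata are misaligned")
        for col in ("length_bp", "gc_frac", "chrom"):
            if col not in self.genes.columns:
                raise ValueError(f"gene annotation column {col!r} missing")
        for col in ("family_id", "status", "sex", "batch"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata column {col!r} missing")
        if (self.genes["length_bp"] <= 0).any():
            raise ValueError("gene lengths must be positive")
        gc = self.genes["gc_frac"].to_numpy(float)
        if ((gc < 0) | (gc > 1)).any():
            raise ValueError("gc_frac must lie in [0, 1]")
        bad_status = set(self.samples["status"]) - set(STATUS_LEVELS)
        if bad_status:
            raise ValueError(f"unknown status levels: {sorted(bad_status)}")
        bad_sex = set(self.samples["sex"]) - set(SEX_LEVELS)
        if bad_sex:
            raise ValueError(f"unknown sex levels: {sorted(bad_sex)}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.stage == "raw":
            if (arr < 0).any():
                raise ValueError("raw counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("raw counts must be integers")

    # -- convenience ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"operation requires stage in {allowed}, dataset is at {self.stage!r}"
            )

    def with_values(self, values: pd.DataFrame, stage: str | None = None) -> "ExpressionDataset":
        """Return a copy carrying new values (and optionally a new stage)."""
        return replace(self, values=values, stage=self.stage if stage is None else stage)

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        """Row-subset preserving order of `gene_ids`."""
        return replace(
            self,
            values=self.values.loc[gene_ids],
            genes=self.genes.loc[gene_ids],
        )

    def case_control_mask(self) -> pd.Series:
        """Boolean case indicator over the case/control samples only."""
        st = self.samples["status"]
        return (st[st.isin(["case", "control"])] == "case")
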