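"""Fold-change estimation from case/control expression matrices.

The signature logic downstream is threshold-on-FC only, so this module
deliberately implements the simplest defensible estimator: per-gene
pseudocounted ratio of group means, with optional library-size scaling.
Moderated estimators (dispersion shrinkage etc.) are out of scope; tables
produced by external DE tools can be imported instead via
:func:`import_external_de`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ValidationError
from .signatures import FoldChangeProfile, _normalize_symbol

__all__ = ["ExpressionMatrix", "DEConfig", "compute_fc", "import_external_de"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression values with case/control labels.

    ``values`` is a DataFrame indexed by gene symbol with sample columns;
    ``group_labels`` maps every sample to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    group_labels: Mapping[str, str]

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate gene {dup!r} in expression matrix")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValidationError("expression values must be finite and >= 0")
        labels = {str(s): str(g) for s, g in self.group_labels.items()}
        unknown = set(labels) - set(map(str, df.columns))
        if unknown:
            raise ValidationError(f"design labels for unknown samples: {sorted(unknown)}")
        bad = {g for g in labels.values() if g not in ("case", "control")}
        if bad:
            raise ValidationError(f"group labels must be case/control, got {sorted(bad)}")
        for grp in ("case", "control"):
            if not any(g == grp for g in labels.values()):
                raise ValidationError(f"no samples labelled {grp!r}")
        object.__setattr__(self, "group_labels", labels)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(map(str, self.values.columns))

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_labels.get(s) == group]

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, design_path: str | Path) -> "ExpressionMatrix":
        """Matrix TSV (first column ``gene``) plus two-column design TSV
        (``sample``, ``group``)."""
        df = pd.read_csv(matrix_path, sep="\t", comment="#")
        df.columns = [str(c) for c in df.columns]
        if df.columns[0].lower() != "gene":
            raise FormatError(f"{matrix_path}: first column must be 'gene'")
        df = df.set_index(df.columns[0])
        df.index = [_normalize_symbol(g) for g in df.index]
        design = pd.read_csv(design_path, sep="\t", comment="#")
        design.columns = [str(c).strip().lower() for c in design.columns]
        if not {"sample", "group"} <= set(design.columns):
            raise FormatError(f"{design_path}: expected columns 'sample' and 'group'")
        labels = dict(zip(design["sample"].astype(str), design["group"].astype(str)))
        return cls(df, labels)

    def to_tsv(self, matrix_path: str | Path, design_path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(matrix_path, sep="\t", index=False, float_format="%.6g")
        pd.DataFrame(
            {"sample": list(self.group_labels), "group": list(self.group_labels.values())}
        ).to_csv(design_path, sep="\t", index=False)


@dataclass(frozen=True)
class DEConfig:
    """Fold-change estimator settings.

    ``pseudocount`` stabilises ratios for low/zero-expression genes — with
    tiny control groups a single zero would otherwise produce infinite FC.
    """

    pseudocount: float = 1.0
    mean_type: str = "arithmetic"
    library_size_normalize: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pseudocount) and self.pseudocount > 0):
            raise ValidationError(f"pseudocount must be > 0, got {self.pseudocount!r}")
        if self.mean_type not in ("arithmetic", "geometric"):
            raise ValidationError(
                f"mean_type must be 'arithmetic' or 'geometric', got {self.mean_type!r}"
            )


def compute_fc(matrix: ExpressionMatrix, config: DEConfig = DEConfig()) -> FoldChangeProfile:
    """Per-gene fold change ``(mean_case + eps) / (mean_control + eps)``.

    With ``library_size_normalize`` each sample is first scaled to a fixed
    total of 10^6 (counts per million), making FC invariant to per-sample
    and global sequencing-depth factors.
    """
    df = matrix.values.astype(float)
    case = matrix.group_samples("case")
    control = matrix.group_samples("control")
    if config.library_size_normalize:
        sizes = df.sum(axis=0)
        if (sizes <= 0).any():
            raise ValidationError("library-size normalization needs positive column sums")
        df = df * (1e6 / sizes)
    if config.mean_type == "arithmetic":
        mean_case = df[case].mean(axis=1)
        mean_control = df[control].mean(axis=1)
    else:
        mean_case = pd.Series(stats.gmean(df[case], axis=1), index=df.index)
        mean_control = pd.Series(stats.gmean(df[control], axis=1), index=df.index)
    eps = config.pseudocount
    fc = (mean_case + eps) / (mean_control + eps)
    return FoldChangeProfile("case_vs_control", {g: float(v) for g, v in fc.items()})


def import_external_de(path: str | Path, *, contrast_id: str | None = None) -> FoldChangeProfile:
    """Import an externally computed DE table (e.g. a DESeq2 results export).

    Requires a ``gene`` column plus either ``log2FoldChange`` or ``fc``;
    extra columns (baseMean, pvalue, padj, ...) are ignored.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty DE table: {path}") from None
    cols = {str(c).strip().lower(): c for c in df.columns}
    if "gene" not in cols:
        raise FormatError(f"{path}: missing 'gene' column")
    if "log2foldchange" in cols:
        fc = 2.0 ** pd.to_numeric(df[cols["log2foldchange"]], errors="coerce")
    elif "fc" in cols:
        fc = pd.to_numeric(df[cols["fc"]], errors="coerce")
    else:
        raise FormatError(
            f"{path}: missing fold-change column (expected 'log2FoldChange' or 'fc')"
        )
    if fc.isna().any():
        gene = df.loc[fc.isna(), cols["gene"]].iloc[0]
        raise FormatError(f"{path}: non-numeric fold change for gene {gene!r}")
    return FoldChangeProfile(
        contrast_id or path.stem, dict(zip(df[cols["gene"]].astype(str), fc.astype(float)))
    )
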