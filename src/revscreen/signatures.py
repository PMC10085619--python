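"""Fold-change profiles and threshold-based gene signatures.

A *fold-change profile* maps gene symbols to linear-scale fold changes for
one contrast (disease vs normal, treated vs untreated, or an agent
perturbation).  A *gene signature* is the pair of up- and down-regulated
gene sets obtained by applying inclusive fold-change cutoffs to a profile:
genes with FC >= ``up_threshold`` are "up", genes with FC <= ``down_threshold``
are "down", and everything strictly in between belongs to neither set.

The default cutoffs used throughout the pipeline are 1.50 / 0.67 for the
disease signature and 2.0 / 0.5 for differentially-expressed-gene (DEG)
lists.  Fold changes are stored on the linear scale internally; log2 input
is accepted at the I/O boundary only and exponentiated on load.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "FoldChangeProfile",
    "SignatureConfig",
    "GeneSignature",
    "DISEASE_SIGNATURE_CONFIG",
    "DEG_CONFIG",
    "load_fc_profile",
    "extract_signature",
    "invert_signature",
]


def _normalize_symbol(gene: str) -> str:
    # Human gene symbols are conventionally upper case; mixed-case duplicates
    # are a common artifact of re-annotated public expression tables.
    return str(gene).strip().upper()


@dataclass(frozen=True)
class FoldChangeProfile:
    """Linear-scale fold changes for one contrast.

    Parameters
    ----------
    contrast_id
        Free-text label for the contrast (e.g. ``"disease_vs_normal"``).
    entries
        Mapping of gene symbol to fold change.  Symbols are case-normalized
        to upper case; every fold change must be finite and strictly
        positive (linear scale).
    """

    contrast_id: str
    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        normalized: dict[str, float] = {}
        for gene, fc in self.entries.items():
            sym = _normalize_symbol(gene)
            if sym in normalized:
                raise ValidationError(
                    f"duplicate gene symbol {sym!r} in profile {self.contrast_id!r}"
                )
            fc = float(fc)
            if not math.isfinite(fc) or fc <= 0.0:
                raise ValidationError(
                    f"gene {sym!r} in profile {self.contrast_id!r} has invalid "
                    f"linear fold change {fc!r} (must be finite and > 0)"
                )
            normalized[sym] = fc
        object.__setattr__(self, "entries", normalized)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return _normalize_symbol(gene) in self.entries

    def __getitem__(self, gene: str) -> float:
        return self.entries[_normalize_symbol(gene)]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.entries)

    def reciprocal(self, contrast_id: str | None = None) -> "FoldChangeProfile":
        """Elementwise 1/FC profile — the exact expression reversal."""
        return FoldChangeProfile(
            contrast_id or f"{self.contrast_id}:reciprocal",
            {g: 1.0 / fc for g, fc in self.entries.items()},
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.entries, name="fc", dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"gene": list(self.entries), "fc": list(self.entries.values())}
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class SignatureConfig:
    """Inclusive fold-change cutoffs defining a signature.

    ``up_threshold`` must exceed 1 and ``down_threshold`` must lie in (0, 1),
    so a fold change of exactly 1 can never enter either set.
    """

    up_threshold: float = 1.50
    down_threshold: float = 0.67

    def __post_init__(self) -> None:
        up, down = float(self.up_threshold), float(self.down_threshold)
        if not (math.isfinite(up) and up > 1.0):
            raise ValidationError(f"up_threshold must be > 1, got {up!r}")
        if not (math.isfinite(down) and 0.0 < down < 1.0):
            raise ValidationError(f"down_threshold must be in (0, 1), got {down!r}")
        object.__setattr__(self, "up_threshold", up)
        object.__setattr__(self, "down_threshold", down)


#: Cutoffs used to define the disease signature (FC >= 1.50 or <= 0.67).
DISEASE_SIGNATURE_CONFIG = SignatureConfig(1.50, 0.67)
#: Stricter cutoffs used to call differentially expressed genes (FC >= 2.0 or <= 0.5).
DEG_CONFIG = SignatureConfig(2.0, 0.5)


@dataclass(frozen=True)
class GeneSignature:
    """Disjoint up/down gene sets plus the thresholds that produced them."""

    source_contrast: str
    up: frozenset[str]
    down: frozenset[str]
    config: SignatureConfig
    inverted: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        up = frozenset(_normalize_symbol(g) for g in self.up)
        down = frozenset(_normalize_symbol(g) for g in self.down)
        if up & down:
            raise ValidationError(
                f"up and down sets overlap: {sorted(up & down)[:5]}"
            )
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def to_dict(self) -> dict:
        return {
            "contrast": self.source_contrast,
            "up": sorted(self.up),
            "down": sorted(self.down),
            "up_threshold": self.config.up_threshold,
            "down_threshold": self.config.down_threshold,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneSignature":
        d = json.loads(Path(path).read_text())
        return cls(
            source_contrast=d["contrast"],
            up=frozenset(d["up"]),
            down=frozenset(d["down"]),
            config=SignatureConfig(d["up_threshold"], d["down_threshold"]),
        )


def load_fc_profile(
    path: str | Path,
    scale: str = "linear",
    *,
    contrast_id: str | None = None,
    duplicate_policy: str = "error",
) -> FoldChangeProfile:
    """Read a two-column fold-change TSV into a linear-scale profile.

    The table must have a ``gene`` column and either ``fc`` (linear) or
    ``log2fc`` — or a generic ``value`` column interpreted per ``scale``.
    ``#``-prefixed lines are comments.  Log2 input is exponentiated so the
    in-memory profile is always linear.

    Parameters
    ----------
    scale
        ``"linear"`` or ``"log2"``.
    duplicate_policy
        ``"error"`` (default) rejects duplicated gene symbols;
        ``"keep-max"`` keeps, per gene, the row with the largest \\|log2 FC\\|.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"fold-change table not found: {path}")
    if scale not in ("linear", "log2"):
        raise ValidationError(f"scale must be 'linear' or 'log2', got {scale!r}")
    if duplicate_policy not in ("error", "keep-max"):
        raise ValidationError(f"unknown duplicate_policy {duplicate_policy!r}")

    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty fold-change table: {path}") from None
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "gene" not in df.columns:
        raise FormatError(f"{path}: missing required 'gene' column")
    value_col = next((c for c in ("fc", "log2fc", "value") if c in df.columns), None)
    if value_col is None:
        raise FormatError(
            f"{path}: missing fold-change column (expected 'fc', 'log2fc' or 'value')"
        )
    if value_col == "log2fc":
        scale = "log2"
    if df.empty:
        raise ValidationError(f"empty fold-change table: {path}")

    values = pd.to_numeric(df[value_col], errors="coerce")
    bad = df.loc[values.isna(), "gene"]
    if len(bad):
        raise ValidationError(
            f"{path}: non-numeric fold change for gene {bad.iloc[0]!r}"
        )
    genes = df["gene"].map(_normalize_symbol)
    fc = values.astype(float)
    if scale == "log2":
        fc = 2.0 ** fc

    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        if duplicate_policy == "error":
            raise FormatError(f"{path}: duplicate gene symbol {dup!r}")
        # keep-max: retain the row with the largest |log2 FC| per gene
        order = fc.map(lambda v: abs(math.log2(v)) if v > 0 else math.inf)
        keep = order.groupby(genes).idxmax()
        genes, fc = genes.loc[keep.values], fc.loc[keep.values]

    for g, v in zip(genes, fc):
        if not math.isfinite(v) or v <= 0:
            raise ValidationError(
                f"{path}: gene {g!r} has non-positive or non-finite linear FC {v!r}"
            )
    return FoldChangeProfile(contrast_id or path.stem, dict(zip(genes, fc)))


def extract_signature(
    profile: FoldChangeProfile, config: SignatureConfig = DISEASE_SIGNATURE_CONFIG
) -> GeneSignature:
    """Apply inclusive FC cutoffs to a profile.

    ``up = {g : FC >= up_threshold}``; ``down = {g : FC <= down_threshold}``.
    An empty result is legal (warned, not an error): a profile may simply
    contain no gene beyond the cutoffs.
    """
    if len(profile) == 0:
        raise ValidationError("cannot extract a signature from an empty profile")
    up = frozenset(
        g for g, fc in profile.entries.items() if fc >= config.up_threshold
    )
    down = frozenset(
        g for g, fc in profile.entries.items() if fc <= config.down_threshold
    )
    if not up and not down:
        warnings.warn(
            f"signature of {profile.contrast_id!r} is empty at thresholds "
            f"({config.up_threshold}, {config.down_threshold})",
            stacklevel=2,
        )
    return GeneSignature(profile.contrast_id, up, down, config)


def invert_signature(sig: GeneSignature) -> GeneSignature:
    """Swap the up and down sets (an involution)."""
    return GeneSignature(
        sig.source_contrast, sig.down, sig.up, sig.config, inverted=not sig.inverted
    )


def extract_degs(
    profile: FoldChangeProfile, config: SignatureConfig = DEG_CONFIG
) -> frozenset[str]:
    """Differentially expressed genes: union of both signature directions
    at the stricter DEG cutoffs (FC >= 2.0 or <= 0.5 by default)."""
    sig = extract_signature(profile, config)
    return sig.genes


def signature_from_sets(
    contrast: str,
    up: Iterable[str],
    down: Iterable[str],
    config: SignatureConfig = DISEASE_SIGNATURE_CONFIG,
) -> GeneSignature:
    return GeneSignature(contrast, frozenset(up), frozenset(down), config)
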