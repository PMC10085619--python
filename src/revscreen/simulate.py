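"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the statistical shape the screen operates on:

* a case/control expression matrix on a log-normal scale with a planted
  fraction of differentially expressed genes (log2 fold changes drawn
  around a configurable effect size, random sign);
* an agent library containing *reversers* (agent effect = -beta times the
  disease effect plus noise), *mimickers* (+beta times), and *nulls*
  (disease effect magnitudes permuted across genes with random signs);
* random gene-set collections, optionally with one set that over-samples a
  given DEG list so enrichment recovery can be tested.

Everything is deterministic given the config seed; independent substreams
are derived for the matrix, the library and the gene sets so adding agents
does not perturb the expression draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .enrichment import GeneSetCollection
from .errors import ValidationError
from .reversal import AgentLibrary
from .signatures import FoldChangeProfile

__all__ = [
    "SimulationConfig",
    "simulate_expression",
    "simulate_agent_library",
    "simulate_gene_sets",
    "simulate_correlated_fc",
    "truth_profile",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the synthetic study.

    Defaults describe a bulk-transcriptome-scale contrast (5,000 genes,
    10 case vs 10 control samples, 10% of genes differentially expressed at
    a mean |log2 FC| of 1.5) screened against a 200-agent library in which
    20 agents reverse and 20 mimic the disease at strength 0.8 with 0.3
    log2 units of profile noise.  All log-scale dispersions are in log2
    units; ``seed`` is mandatory.
    """

    n_genes: int = 5000
    n_case: int = 10
    n_control: int = 10
    de_fraction: float = 0.10
    de_log2fc_mean: float = 1.5
    de_log2fc_sd: float = 0.5
    noise_sd: float = 0.5
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    n_agents: int = 200
    n_reversers: int = 20
    n_mimickers: int = 20
    reversal_strength: float = 0.8
    agent_noise_sd: float = 0.3
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("SimulationConfig requires an explicit seed")
        for name in ("n_genes", "n_case", "n_control", "n_agents"):
            if int(getattr(self, name)) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must be in [0, 1]")
        if self.n_reversers < 0 or self.n_mimickers < 0:
            raise ValidationError("planted agent counts must be >= 0")
        if self.n_reversers + self.n_mimickers > self.n_agents:
            raise ValidationError("n_reversers + n_mimickers exceeds n_agents")
        if not 0.0 < self.reversal_strength <= 1.0:
            raise ValidationError("reversal_strength must be in (0, 1]")
        for name in ("de_log2fc_sd", "noise_sd", "agent_noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substreams per stage, all reproducible from the one seed
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a case/control matrix with planted differential expression.

    Baseline log2 expression per gene is Normal(baseline_mean, baseline_sd);
    a ``de_fraction`` subset is shifted in cases by log2 FC drawn as
    Normal(de_log2fc_mean, de_log2fc_sd) with random sign; per-sample noise
    is Normal(0, noise_sd) on the log2 scale.  Values are returned on the
    linear scale.  The truth table has one row per gene with the planted
    ``log2fc`` (0 for null genes) and an ``is_de`` flag.
    """
    rng = _rng(config, 0)
    genes = _gene_names(config.n_genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)

    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    log2fc = np.zeros(config.n_genes)
    if n_de:
        magnitudes = rng.normal(config.de_log2fc_mean, config.de_log2fc_sd, n_de)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        log2fc[de_idx] = magnitudes * signs

    n_samples = config.n_case + config.n_control
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    log2_expr = baseline[:, None] + noise
    log2_expr[:, : config.n_case] += log2fc[:, None]

    samples = [f"case_{i+1:02d}" for i in range(config.n_case)] + [
        f"control_{i+1:02d}" for i in range(config.n_control)
    ]
    values = pd.DataFrame(2.0 ** log2_expr, index=genes, columns=samples)
    labels = {s: ("case" if s.startswith("case") else "control") for s in samples}
    truth = pd.DataFrame(
        {"gene": genes, "log2fc": log2fc, "is_de": log2fc != 0.0}
    ).set_index("gene")
    return ExpressionMatrix(values, labels), truth


def truth_profile(truth: pd.DataFrame, contrast_id: str = "disease_truth") -> FoldChangeProfile:
    """The noiseless disease FC profile implied by a truth table."""
    return FoldChangeProfile(
        contrast_id, {g: float(2.0 ** l) for g, l in truth["log2fc"].items()}
    )


def simulate_agent_library(
    disease_truth: pd.DataFrame, config: SimulationConfig
) -> tuple[AgentLibrary, dict[str, str]]:
    """Build an agent library around a disease truth table.

    Reversers apply ``-beta * log2fc`` plus Normal(0, agent_noise_sd) noise,
    mimickers ``+beta * log2fc`` plus noise, and nulls carry the disease
    effect magnitudes permuted over genes with random signs (no relation to
    which genes are actually disease-regulated).  Returns the library and a
    label per agent id (``reverser`` / ``mimicker`` / ``null``).
    """
    rng = _rng(config, 1)
    genes = list(disease_truth.index)
    t = disease_truth["log2fc"].to_numpy(dtype=float)
    beta = config.reversal_strength
    n_null = config.n_agents - config.n_reversers - config.n_mimickers

    profiles: list[FoldChangeProfile] = []
    labels: dict[str, str] = {}

    def add(agent_id: str, log2fc_vec: np.ndarray, label: str) -> None:
        profiles.append(
            FoldChangeProfile(agent_id, dict(zip(genes, 2.0 ** log2fc_vec)))
        )
        labels[agent_id] = label

    for i in range(config.n_reversers):
        noise = rng.normal(0.0, config.agent_noise_sd, len(genes)) if config.agent_noise_sd else 0.0
        add(f"reverser_{i+1:03d}", -beta * t + noise, "reverser")
    for i in range(config.n_mimickers):
        noise = rng.normal(0.0, config.agent_noise_sd, len(genes)) if config.agent_noise_sd else 0.0
        add(f"mimicker_{i+1:03d}", beta * t + noise, "mimicker")
    for i in range(n_null):
        permuted = np.abs(t)[rng.permutation(len(genes))]
        signs = rng.choice([-1.0, 1.0], size=len(genes))
        add(f"null_{i+1:03d}", permuted * signs, "null")

    return AgentLibrary.from_profiles(profiles), labels


def simulate_gene_sets(
    n_sets: int,
    set_size_range: tuple[int, int],
    universe: Sequence[str],
    *,
    enriched_in: set[str] | None = None,
    oversample_rate: float = 5.0,
    seed: int,
    name: str = "synthetic_sets",
) -> GeneSetCollection:
    """Random gene sets drawn from a universe, optionally one enriched set.

    When ``enriched_in`` (a DEG list) is given, the first set — named
    ``enriched_set`` — samples DEG members with ``oversample_rate`` times
    the weight of other genes; remaining sets are uniform draws.
    """
    lo, hi = set_size_range
    universe = list(dict.fromkeys(str(g).strip().upper() for g in universe))
    if lo <= 0 or hi < lo:
        raise ValidationError(f"invalid set_size_range {set_size_range!r}")
    if hi > len(universe):
        raise ValidationError(
            f"set size {hi} exceeds universe size {len(universe)}"
        )
    if n_sets <= 0:
        raise ValidationError("n_sets must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    sets: dict[str, frozenset[str]] = {}
    uni_arr = np.array(universe)

    if enriched_in is not None:
        degs = {str(g).strip().upper() for g in enriched_in} & set(universe)
        if not degs:
            raise ValidationError("enriched_in shares no genes with the universe")
        weights = np.where(np.isin(uni_arr, list(degs)), oversample_rate, 1.0)
        weights = weights / weights.sum()
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(uni_arr, size=size, replace=False, p=weights)
        sets["enriched_set"] = frozenset(members)

    i = 1
    while len(sets) < n_sets:
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(uni_arr, size=size, replace=False)
        sets[f"set_{i:03d}"] = frozenset(members)
        i += 1

    return GeneSetCollection(name, sets, frozenset(universe))


def simulate_correlated_fc(
    reference: FoldChangeProfile,
    target_rho: float,
    *,
    seed: int,
    contrast_id: str = "correlated_contrast",
) -> FoldChangeProfile:
    """A synthetic FC profile with a planted Spearman correlation.

    Uses a Gaussian copula: the reference profile's values are mapped to
    normal scores, a second normal variate is generated at the Pearson
    correlation ``r = 2 sin(pi * rho_s / 6)`` that yields Spearman rho_s
    for a bivariate normal, and the result is exponentiated back to a
    positive linear-FC scale (Spearman rho is invariant to that monotone
    map).  Useful for emulating a treatment contrast with a known degree
    of anti-correlation to a disease contrast.
    """
    if not -1.0 < target_rho < 1.0:
        raise ValidationError("target_rho must be in (-1, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    genes = sorted(reference.entries)
    x = np.array([reference.entries[g] for g in genes])
    n = len(genes)
    if n < 3:
        raise ValidationError("reference profile too small")
    # normal scores of the reference ranks
    from scipy import stats as _stats

    ranks = _stats.rankdata(x)
    z_x = _stats.norm.ppf((ranks - 0.5) / n)
    r = 2.0 * math.sin(math.pi * target_rho / 6.0)
    z_y = r * z_x + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return FoldChangeProfile(contrast_id, dict(zip(genes, 2.0 ** z_y)))
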