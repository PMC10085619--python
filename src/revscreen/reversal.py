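"""Anti-correlation scoring of agent profiles against a disease signature.

The screen asks, for each candidate agent: does the agent push the genes of
the disease signature in the *opposite* direction?  Two complementary
statistics are computed per agent:

* a Fisher exact test on the signed 2x2 overlap of the disease and agent
  signatures — counting genes that are (disease-up, agent-up),
  (disease-up, agent-down), (disease-down, agent-up) and
  (disease-down, agent-down).  An odds ratio below 1 means the agent tends
  to flip the disease directions (signature reversal);
* Spearman's rank correlation between the two fold-change profiles over
  their shared genes — rho < 0 means the agent's whole expression response
  anti-correlates with the disease contrast.

Agents are ranked by ascending rho (most negative first), ties broken by
ascending odds ratio, then agent id.  Benjamini–Hochberg adjustment is
applied across agents within one screen, separately for the Fisher and
Spearman p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import OverlapError, UndefinedStatisticError, ValidationError
from .signatures import (
    FoldChangeProfile,
    GeneSignature,
    SignatureConfig,
    extract_signature,
    load_fc_profile,
)

__all__ = [
    "ContingencyTable2x2",
    "FisherResult",
    "SpearmanResult",
    "ReversalScore",
    "ScreenResult",
    "AgentLibrary",
    "signed_overlap_table",
    "fisher_exact",
    "spearman_reversal",
    "screen_library",
    "validate_reversal",
]

_SIDED = {"two": "two-sided", "less": "less", "greater": "greater"}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Signed signature-overlap counts.

    ``a`` = disease-up & agent-up, ``b`` = disease-up & agent-down,
    ``c`` = disease-down & agent-up, ``d`` = disease-down & agent-down.
    A reversing agent concentrates mass in ``b`` and ``c`` (odds ratio < 1).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 0:
                raise ValidationError(
                    f"cell {name} must be a non-negative integer, got {v!r}"
                )
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # Haldane–Anscombe-corrected when any cell is zero
    p: float
    raw_odds_ratio: float  # uncorrected cross-ratio; may be 0 or inf

    def __iter__(self) -> Iterator[float]:  # allows `or_, p = fisher_exact(...)`
        yield self.odds_ratio
        yield self.p


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n_shared: int
    label: str | None = None

    def __iter__(self) -> Iterator[float]:
        yield self.rho
        yield self.p
        yield self.n_shared


def signed_overlap_table(
    disease: GeneSignature, agent: GeneSignature
) -> ContingencyTable2x2:
    """Cross-tabulate signature directions; genes outside both signatures
    are ignored, and a completely disjoint pair is an error."""
    table = ContingencyTable2x2(
        a=len(disease.up & agent.up),
        b=len(disease.up & agent.down),
        c=len(disease.down & agent.up),
        d=len(disease.down & agent.down),
    )
    if table.total == 0:
        raise OverlapError(
            f"no shared signature genes between {disease.source_contrast!r} "
            f"and {agent.source_contrast!r}"
        )
    return table


def fisher_exact(table: ContingencyTable2x2, sided: str = "two") -> FisherResult:
    """Fisher's exact test on a signed-overlap table.

    The p-value is the exact conditional (hypergeometric) probability for the
    chosen sidedness.  The reported odds ratio is the cross-ratio
    ``(a*d)/(b*c)``; when any cell is zero the Haldane–Anscombe correction
    (+0.5 to every cell) is applied so the ratio stays finite, and the raw
    (possibly 0 or infinite) ratio is kept alongside.
    """
    if sided not in _SIDED:
        raise ValidationError(f"sided must be one of {sorted(_SIDED)}, got {sided!r}")
    if table.total == 0:
        raise ValidationError("cannot test an all-zero table")
    a, b, c, d = table.a, table.b, table.c, table.d
    _, p = stats.fisher_exact(table.as_array(), alternative=_SIDED[sided])
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        if b * c == 0 and a * d == 0:
            raw = math.nan
        elif b * c == 0:
            raw = math.inf
        else:
            raw = 0.0
    else:
        odds = (a * d) / (b * c)
        raw = odds
    return FisherResult(odds_ratio=float(odds), p=float(p), raw_odds_ratio=raw)


def _shared_vectors(
    disease_fc: FoldChangeProfile,
    agent_fc: FoldChangeProfile,
    universe: str,
    signature: GeneSignature | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    shared = disease_fc.genes & agent_fc.genes
    if universe == "signature":
        if signature is None:
            raise ValidationError(
                "universe='signature' requires a disease GeneSignature"
            )
        shared &= signature.genes
    elif universe != "shared":
        raise ValidationError(f"universe must be 'shared' or 'signature', got {universe!r}")
    genes = sorted(shared)
    x = np.array([disease_fc.entries[g] for g in genes], dtype=float)
    y = np.array([agent_fc.entries[g] for g in genes], dtype=float)
    return x, y, genes


def spearman_reversal(
    disease_fc: FoldChangeProfile,
    agent_fc: FoldChangeProfile,
    universe: str = "shared",
    *,
    signature: GeneSignature | None = None,
    permutations: int | None = None,
    seed: int | None = None,
) -> SpearmanResult:
    """Spearman correlation between two FC profiles on their shared genes.

    Ranks use the average-rank (midrank) convention for ties.  The p-value
    comes from the t-distribution approximation; pass ``permutations`` for a
    seeded permutation p-value, recommended when fewer than ~10 genes are
    shared.
    """
    x, y, genes = _shared_vectors(disease_fc, agent_fc, universe, signature)
    n = len(genes)
    if n < 3:
        raise OverlapError(
            f"only {n} shared genes between {disease_fc.contrast_id!r} and "
            f"{agent_fc.contrast_id!r}; need at least 3"
        )
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedStatisticError(
            "Spearman rho is undefined for a constant fold-change vector"
        )
    rho, p = stats.spearmanr(x, y)
    if permutations is not None:
        if permutations <= 0:
            raise ValidationError("permutations must be positive")
        rng = np.random.default_rng(seed)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = abs(rho)
        hits = 0
        for _ in range(permutations):
            r = abs(_pearson(rx, ry[rng.permutation(n)]))
            hits += r >= obs - 1e-12
        p = (hits + 1) / (permutations + 1)
    return SpearmanResult(rho=float(rho), p=float(p), n_shared=n)


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    return float(u @ v / math.sqrt((u @ u) * (v @ v)))


def validate_reversal(
    treatment_fc: FoldChangeProfile,
    disease_fc: FoldChangeProfile,
    *,
    alpha: float = 0.05,
) -> SpearmanResult:
    """Test whether a treatment contrast reverses the disease contrast.

    Spearman correlation over the full shared-gene universe, labelled
    ``"reversal"`` when rho < 0 with p < alpha, ``"concordant"`` when
    rho > 0 with p < alpha, and ``"indeterminate"`` otherwise.
    """
    res = spearman_reversal(disease_fc, treatment_fc, universe="shared")
    if res.p < alpha and res.rho < 0:
        label = "reversal"
    elif res.p < alpha and res.rho > 0:
        label = "concordant"
    else:
        label = "indeterminate"
    return replace(res, label=label)


@dataclass(frozen=True)
class ReversalScore:
    """Per-agent screen record."""

    agent_id: str
    table: ContingencyTable2x2
    odds_ratio: float
    fisher_p: float
    rho: float
    rho_p: float
    n_shared: int
    fisher_q: float = math.nan
    rho_q: float = math.nan
    rank: int | None = None

    @property
    def is_reversal(self) -> bool:
        return self.rho < 0


@dataclass(frozen=True)
class ScreenResult:
    """Ranked scores plus the agents excluded for zero signature overlap."""

    scores: tuple[ReversalScore, ...]
    excluded: tuple[str, ...]
    disease_contrast: str

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self) -> Iterator[ReversalScore]:
        return iter(self.scores)

    def top(self, n: int) -> tuple[ReversalScore, ...]:
        return self.scores[:n]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "rank": s.rank,
                "agent_id": s.agent_id,
                "rho": s.rho,
                "rho_p": s.rho_p,
                "rho_q": s.rho_q,
                "odds_ratio": s.odds_ratio,
                "fisher_p": s.fisher_p,
                "fisher_q": s.fisher_q,
                "a": s.table.a,
                "b": s.table.b,
                "c": s.table.c,
                "d": s.table.d,
                "n_shared": s.n_shared,
            }
            for s in self.scores
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "rank", "agent_id", "rho", "rho_p", "rho_q", "odds_ratio",
                "fisher_p", "fisher_q", "a", "b", "c", "d", "n_shared",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class AgentLibrary:
    """Ordered, uniquely-named collection of agent fold-change profiles."""

    agents: tuple[tuple[str, FoldChangeProfile], ...]

    def __post_init__(self) -> None:
        ids = [a for a, _ in self.agents]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate agent_id {dup!r} in library")
        object.__setattr__(self, "agents", tuple(self.agents))

    def __len__(self) -> int:
        return len(self.agents)

    def __iter__(self) -> Iterator[tuple[str, FoldChangeProfile]]:
        return iter(self.agents)

    @property
    def agent_ids(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.agents)

    def __getitem__(self, agent_id: str) -> FoldChangeProfile:
        for aid, prof in self.agents:
            if aid == agent_id:
                return prof
        raise KeyError(agent_id)

    @classmethod
    def from_profiles(
        cls, profiles: Sequence[FoldChangeProfile]
    ) -> "AgentLibrary":
        return cls(tuple((p.contrast_id, p) for p in profiles))

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "AgentLibrary":
        """Long-format TSV with columns ``agent_id, gene, fc``."""
        df = pd.read_csv(path, sep="\t", comment="#")
        df.columns = [str(c).strip().lower() for c in df.columns]
        required = {"agent_id", "gene", "fc"}
        if not required <= set(df.columns):
            from .errors import FormatError

            raise FormatError(
                f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
            )
        agents = []
        for aid, grp in df.groupby("agent_id", sort=False):
            agents.append(
                (str(aid), FoldChangeProfile(str(aid), dict(zip(grp["gene"], grp["fc"]))))
            )
        return cls(tuple(agents))

    @classmethod
    def from_directory(cls, directory: str | Path, scale: str = "linear") -> "AgentLibrary":
        """One FC TSV per agent; agent id = file stem."""
        files = sorted(Path(directory).glob("*.tsv"))
        if not files:
            raise ValidationError(f"no .tsv agent profiles found in {directory}")
        return cls(tuple((f.stem, load_fc_profile(f, scale)) for f in files))

    def to_long_tsv(self, path: str | Path) -> None:
        frames = [
            pd.DataFrame(
                {"agent_id": aid, "gene": list(p.entries), "fc": list(p.entries.values())}
            )
            for aid, p in self.agents
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


def screen_library(
    disease_fc: FoldChangeProfile,
    library: AgentLibrary,
    sig_config: SignatureConfig = SignatureConfig(),
    *,
    sided: str = "two",
    universe: str = "shared",
) -> ScreenResult:
    """Score every agent in the library against the disease contrast.

    Each agent's signature is extracted with the same thresholds as the
    disease signature; agents sharing no signature gene with the disease
    are excluded from ranking and reported separately.  Ranking is by
    ascending rho, then ascending odds ratio, then agent id — fully
    deterministic and invariant to the library's input order.
    """
    if len(library) == 0:
        raise ValidationError("agent library is empty")
    disease_sig = extract_signature(disease_fc, sig_config)
    if len(disease_sig) == 0:
        raise ValidationError(
            f"disease profile {disease_fc.contrast_id!r} yields an empty "
            f"signature at ({sig_config.up_threshold}, {sig_config.down_threshold})"
        )

    scored: list[ReversalScore] = []
    excluded: list[str] = []
    for agent_id, agent_fc in library:
        agent_sig = extract_signature(agent_fc, sig_config)
        try:
            table = signed_overlap_table(disease_sig, agent_sig)
        except OverlapError:
            excluded.append(agent_id)
            continue
        fisher = fisher_exact(table, sided=sided)
        sp = spearman_reversal(
            disease_fc, agent_fc, universe=universe, signature=disease_sig
        )
        scored.append(
            ReversalScore(
                agent_id=agent_id,
                table=table,
                odds_ratio=fisher.odds_ratio,
                fisher_p=fisher.p,
                rho=sp.rho,
                rho_p=sp.p,
                n_shared=sp.n_shared,
            )
        )

    if scored:
        fisher_q = multipletests([s.fisher_p for s in scored], method="fdr_bh")[1]
        rho_q = multipletests([s.rho_p for s in scored], method="fdr_bh")[1]
        scored = [
            replace(s, fisher_q=float(fq), rho_q=float(rq))
            for s, fq, rq in zip(scored, fisher_q, rho_q)
        ]
    scored.sort(key=lambda s: (s.rho, s.odds_ratio, s.agent_id))
    scored = [replace(s, rank=i + 1) for i, s in enumerate(scored)]
    return ScreenResult(
        scores=tuple(scored),
        excluded=tuple(sorted(excluded)),
        disease_contrast=disease_fc.contrast_id,
    )
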