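"""Hypergeometric over-representation analysis (ORA) of gene lists.

For each gene set the test asks whether the differentially expressed genes
(restricted to the collection's universe) overlap the set more than expected
under random draws without replacement from the universe:

    p = P(X >= k),  X ~ Hypergeometric(N=universe, K=set, n=DEGs-in-universe)

Only over-representation is tested (upper tail); Benjamini–Hochberg
adjustment is applied across the sets of one collection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, ValidationError

__all__ = ["GeneSetCollection", "EnrichmentResult", "ora", "load_gmt"]


def _norm(g: str) -> str:
    return str(g).strip().upper()


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a defined gene universe.

    Members outside the universe are dropped with a warning (their count is
    kept in ``n_dropped``); sets emptied by the filter are removed.
    """

    name: str
    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        universe = frozenset(_norm(g) for g in self.universe)
        if not universe:
            raise ValidationError("gene universe is empty")
        cleaned: dict[str, frozenset[str]] = {}
        dropped = 0
        for name, members in self.sets.items():
            members = frozenset(_norm(g) for g in members)
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            inside = members & universe
            dropped += len(members) - len(inside)
            if inside:
                cleaned[str(name)] = inside
        if dropped:
            warnings.warn(
                f"collection {self.name!r}: dropped {dropped} gene-set members "
                f"outside the universe",
                stacklevel=2,
            )
        object.__setattr__(self, "sets", cleaned)
        object.__setattr__(self, "universe", universe)
        object.__setattr__(self, "n_dropped", self.n_dropped + dropped)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap_count: int
    set_size: int
    degs_in_universe: int
    universe_size: int
    p: float
    q: float
    overlap_genes: frozenset[str]


def load_gmt(
    path: str | Path, universe: Iterable[str] | None = None, *, name: str | None = None
) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Unless ``universe`` is supplied, the universe defaults to the union of
    all sets (a measured-genes universe is preferable when available).
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                f"(name, description, members...)"
            )
        set_name = fields[0].strip()
        if set_name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {set_name!r}")
        members = frozenset(_norm(g) for g in fields[2:] if g.strip())
        if not members:
            raise FormatError(f"{path}:{lineno}: set {set_name!r} has no members")
        sets[set_name] = members
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    if universe is None:
        universe_set = frozenset().union(*sets.values())
    else:
        universe_set = frozenset(_norm(g) for g in universe)
    return GeneSetCollection(name or path.stem, sets, universe_set)


def ora(degs: Iterable[str], collection: GeneSetCollection) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of every set against a DEG list.

    Results are sorted by ascending p, ties broken by set name; q is the
    Benjamini–Hochberg adjustment across the collection's sets.
    """
    if len(collection) == 0:
        raise ValidationError("gene-set collection is empty")
    degs_norm = frozenset(_norm(g) for g in degs)
    draws = degs_norm & collection.universe
    if not draws:
        raise ValidationError("no DEG overlaps the collection's universe")
    N, n = len(collection.universe), len(draws)

    rows = []
    for set_name, members in collection.sets.items():
        k = len(members & draws)
        K = len(members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((set_name, k, K, members & draws, min(p, 1.0)))

    qvals = multipletests([r[4] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            set_name=set_name,
            overlap_count=k,
            set_size=K,
            degs_in_universe=n,
            universe_size=N,
            p=p,
            q=float(q),
            overlap_genes=overlap,
        )
        for (set_name, k, K, overlap, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return results
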