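from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import settings

from revscreen import FoldChangeProfile, SignatureConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_profile(entries: dict[str, float], contrast: str = "test") -> FoldChangeProfile:
    return FoldChangeProfile(contrast, entries)


@pytest.fixture
def disease_profile() -> FoldChangeProfile:
    return make_profile(
        {"G1": 4.0, "G2": 2.0, "G3": 1.6, "G4": 1.0, "G5": 0.6, "G6": 0.4, "G7": 0.2},
        "disease",
    )


@pytest.fixture
def default_config() -> SignatureConfig:
    return SignatureConfig(1.50, 0.67)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full enumeration of tables with the
    observed margins, in rational arithmetic: sum of hypergeometric point
    probabilities no larger than the observed table's."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    return float(sum(p for x in range(lo, hi + 1) if (p := pmf(x)) <= p_obs))


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Average ranks by sorting, then Pearson correlation of the ranks."""

    def avg_ranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(np.asarray(x, float)), avg_ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def hypergeom_upper_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by explicit pmf summation in rational arithmetic."""
    denom = comb(N, n)
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), denom)
    return float(total)
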