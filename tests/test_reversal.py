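import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from revscreen import (
    AgentLibrary,
    ContingencyTable2x2,
    FoldChangeProfile,
    OverlapError,
    SignatureConfig,
    UndefinedStatisticError,
    ValidationError,
    extract_signature,
    fisher_exact,
    invert_signature,
    screen_library,
    signed_overlap_table,
    spearman_reversal,
    validate_reversal,
)
from revscreen.signatures import signature_from_sets

from conftest import fisher_two_sided_oracle, make_profile, spearman_oracle


class TestSignedOverlapTable:
    def test_cross_direction_counts(self):
        d = signature_from_sets("d", up={"x", "y"}, down={"z"})
        a = signature_from_sets("a", up={"z"}, down={"x", "y"})
        t = signed_overlap_table(d, a)
        assert (t.a, t.b, t.c, t.d) == (0, 2, 1, 0)

    def test_self_overlap_is_diagonal(self):
        d = signature_from_sets("d", up={"x", "y"}, down={"z", "w"})
        t = signed_overlap_table(d, d)
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 2)

    def test_inverted_signature_is_anti_diagonal(self):
        d = signature_from_sets("d", up={"x", "y"}, down={"z", "w", "v"})
        t = signed_overlap_table(d, invert_signature(d))
        assert (t.a, t.b, t.c, t.d) == (0, 2, 3, 0)

    def test_disjoint_signatures_raise_overlap_error(self):
        d = signature_from_sets("d", up={"x"}, down={"y"})
        a = signature_from_sets("a", up={"p"}, down={"q"})
        with pytest.raises(OverlapError, match="no shared"):
            signed_overlap_table(d, a)


class TestFisherExact:
    def test_balanced_table_has_unit_odds_ratio(self):
        res = fisher_exact(ContingencyTable2x2(5, 5, 5, 5))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_cross_ratio_arithmetic(self):
        res = fisher_exact(ContingencyTable2x2(1, 9, 9, 1))
        assert res.odds_ratio == pytest.approx(1 / 81)
        assert res.raw_odds_ratio == pytest.approx(1 / 81)

    def test_two_sided_p_matches_enumeration(self):
        res = fisher_exact(ContingencyTable2x2(1, 9, 9, 1), sided="two")
        assert res.p == pytest.approx(fisher_two_sided_oracle(1, 9, 9, 1), abs=1e-12)

    def test_zero_cell_uses_haldane_anscombe_correction(self):
        res = fisher_exact(ContingencyTable2x2(0, 8, 7, 0))
        assert res.odds_ratio == pytest.approx(0.25 / (8.5 * 7.5))
        assert res.raw_odds_ratio == 0.0
        res2 = fisher_exact(ContingencyTable2x2(8, 0, 0, 7))
        assert math.isinf(res2.raw_odds_ratio)

    @pytest.mark.parametrize("cells", [(-1, 1, 1, 1), (1.5, 1, 1, 1)])
    def test_invalid_cells_rejected(self, cells):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(*cells)

    def test_unknown_sidedness_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact(ContingencyTable2x2(1, 1, 1, 1), sided="both")

    @given(
        a=st.integers(1, 8), b=st.integers(1, 8),
        c=st.integers(1, 8), d=st.integers(1, 8),
    )
    def test_odds_ratio_of_inverted_agent_is_reciprocal(self, a, b, c, d):
        t = ContingencyTable2x2(a, b, c, d)
        t_inv = ContingencyTable2x2(b, a, d, c)  # agent directions swapped
        assert fisher_exact(t).odds_ratio * fisher_exact(t_inv).odds_ratio == \
            pytest.approx(1.0)


class TestSpearmanReversal:
    def test_identity_profile_gives_rho_one(self, disease_profile):
        res = spearman_reversal(disease_profile, disease_profile)
        assert res.rho == pytest.approx(1.0)
        assert res.n_shared == len(disease_profile)

    def test_reciprocal_profile_gives_rho_minus_one(self, disease_profile):
        res = spearman_reversal(disease_profile, disease_profile.reciprocal())
        assert res.rho == pytest.approx(-1.0)

    def test_tied_values_match_rank_then_pearson_oracle(self):
        x = make_profile({"A": 1.0, "B": 2.0, "C": 2.0, "D": 3.0, "E": 0.5})
        y = make_profile({"A": 4.0, "B": 1.0, "C": 2.0, "D": 2.0, "E": 3.0})
        res = spearman_reversal(x, y)
        xs = np.array([x.entries[g] for g in sorted(x.entries)])
        ys = np.array([y.entries[g] for g in sorted(y.entries)])
        assert res.rho == pytest.approx(spearman_oracle(xs, ys), abs=1e-14)

    def test_symmetry(self, disease_profile):
        other = make_profile({g: 1.0 / fc + 0.1 for g, fc in
                              disease_profile.entries.items()})
        assert spearman_reversal(disease_profile, other).rho == pytest.approx(
            spearman_reversal(other, disease_profile).rho
        )

    def test_invariant_under_monotone_transform(self, disease_profile):
        other = make_profile({"G1": 0.3, "G2": 0.9, "G3": 1.1, "G4": 2.0,
                              "G5": 2.5, "G6": 3.0, "G7": 5.0})
        base = spearman_reversal(disease_profile, other).rho
        squared = make_profile({g: fc ** 2 for g, fc in other.entries.items()})
        assert spearman_reversal(disease_profile, squared).rho == pytest.approx(base)

    def test_too_few_shared_genes(self):
        x = make_profile({"A": 1.0, "B": 2.0})
        y = make_profile({"A": 1.0, "B": 2.0})
        with pytest.raises(OverlapError, match="at least 3"):
            spearman_reversal(x, y)

    def test_constant_vector_is_undefined(self):
        x = make_profile({"A": 1.0, "B": 1.0, "C": 1.0})
        y = make_profile({"A": 1.0, "B": 2.0, "C": 3.0})
        with pytest.raises(UndefinedStatisticError):
            spearman_reversal(x, y)

    def test_signature_universe_restricts_genes(self, disease_profile, default_config):
        sig = extract_signature(disease_profile, default_config)
        other = make_profile({g: 2.0 ** i for i, g in
                              enumerate(sorted(disease_profile.entries))})
        res = spearman_reversal(disease_profile, other, universe="signature",
                                signature=sig)
        assert res.n_shared == len(sig)

    def test_permutation_p_is_valid_and_seeded(self, disease_profile):
        other = disease_profile.reciprocal()
        r1 = spearman_reversal(disease_profile, other, permutations=200, seed=0)
        r2 = spearman_reversal(disease_profile, other, permutations=200, seed=0)
        assert 0 < r1.p <= 1
        assert r1.p == r2.p


class TestValidateReversal:
    def test_reciprocal_treatment_labeled_reversal(self, disease_profile):
        res = validate_reversal(disease_profile.reciprocal(), disease_profile)
        assert res.rho == pytest.approx(-1.0)
        assert res.label == "reversal"

    def test_identical_treatment_labeled_concordant(self, disease_profile):
        res = validate_reversal(disease_profile, disease_profile)
        assert res.rho == pytest.approx(1.0)
        assert res.label == "concordant"

    def test_weak_association_is_indeterminate(self):
        x = make_profile({"A": 1.0, "B": 2.0, "C": 3.0, "D": 2.5})
        y = make_profile({"A": 2.0, "B": 1.0, "C": 3.0, "D": 2.5})
        assert validate_reversal(y, x).label == "indeterminate"


def _random_agent(rng, genes, contrast):
    return FoldChangeProfile(
        contrast, dict(zip(genes, 2.0 ** rng.normal(0, 1.5, len(genes))))
    )


class TestScreenLibrary:
    @pytest.fixture
    def disease(self):
        rng = np.random.default_rng(42)
        genes = [f"G{i:03d}" for i in range(200)]
        return FoldChangeProfile(
            "disease", dict(zip(genes, 2.0 ** rng.normal(0, 1.5, 200)))
        )

    def test_planted_perfect_reverser_ranks_first(self, disease):
        rng = np.random.default_rng(0)
        genes = sorted(disease.entries)
        agents = [disease.reciprocal("reverser")] + [
            _random_agent(rng, genes, f"rand_{i}") for i in range(5)
        ]
        result = screen_library(disease, AgentLibrary.from_profiles(agents))
        top = result.scores[0]
        assert top.agent_id == "reverser"
        assert top.rho == pytest.approx(-1.0)
        assert top.table.a == 0 and top.table.d == 0
        assert top.odds_ratio == min(s.odds_ratio for s in result)

    def test_self_screen_is_concordant_with_maximal_or(self, disease):
        result = screen_library(
            disease, AgentLibrary.from_profiles([disease])
        )
        only = result.scores[0]
        assert only.rho == pytest.approx(1.0)
        assert only.rank == 1
        assert not only.is_reversal
        assert only.table.b == 0 and only.table.c == 0

    def test_ranking_invariant_to_library_order(self, disease):
        rng = np.random.default_rng(1)
        genes = sorted(disease.entries)
        agents = [_random_agent(rng, genes, f"a{i}") for i in range(8)]
        fwd = screen_library(disease, AgentLibrary.from_profiles(agents))
        rev = screen_library(disease, AgentLibrary.from_profiles(agents[::-1]))
        assert [s.agent_id for s in fwd] == [s.agent_id for s in rev]
        assert [s.rank for s in fwd] == list(range(1, 9))

    def test_bh_adjustment_is_monotone_and_bounded(self, disease):
        rng = np.random.default_rng(2)
        genes = sorted(disease.entries)
        agents = [_random_agent(rng, genes, f"a{i}") for i in range(12)]
        result = screen_library(disease, AgentLibrary.from_profiles(agents))
        by_p = sorted(result, key=lambda s: s.rho_p)
        qs = [s.rho_q for s in by_p]
        assert all(q1 <= q2 + 1e-15 for q1, q2 in zip(qs, qs[1:]))
        assert all(0 <= s.rho_q <= 1 and 0 <= s.fisher_q <= 1 for s in result)
        assert all(s.rho_q >= s.rho_p for s in result)

    def test_zero_overlap_agents_excluded_not_ranked(self, disease):
        flat_genes = {f"X{i}": 1.0 + (i % 3) * 0.01 for i in range(50)}
        no_overlap = FoldChangeProfile("flat", flat_genes)
        result = screen_library(
            disease, AgentLibrary.from_profiles([disease.reciprocal("rev"), no_overlap])
        )
        assert result.excluded == ("flat",)
        assert len(result) == 1

    def test_empty_library_rejected(self, disease):
        with pytest.raises(ValidationError):
            screen_library(disease, AgentLibrary(()))

    def test_empty_disease_signature_rejected(self):
        narrow = make_profile({"A": 1.01, "B": 0.99, "C": 1.0})
        lib = AgentLibrary.from_profiles([make_profile({"A": 2.0, "B": 0.5, "C": 1.0}, "a")])
        with pytest.raises(ValidationError, match="empty"):
            screen_library(narrow, lib)


class TestAgentLibrary:
    def test_duplicate_ids_rejected(self, disease_profile):
        with pytest.raises(ValidationError, match="duplicate"):
            AgentLibrary.from_profiles([disease_profile, disease_profile])

    def test_long_tsv_round_trip(self, tmp_path, disease_profile):
        lib = AgentLibrary.from_profiles(
            [disease_profile, disease_profile.reciprocal("rec")]
        )
        path = tmp_path / "library.tsv"
        lib.to_long_tsv(path)
        loaded = AgentLibrary.from_long_tsv(path)
        assert loaded.agent_ids == lib.agent_ids
        # TSV output carries 6 significant digits
        assert loaded["rec"].entries == pytest.approx(lib["rec"].entries, rel=1e-5)

    def test_directory_loading(self, tmp_path, disease_profile):
        disease_profile.to_tsv(tmp_path / "agent_a.tsv")
        disease_profile.reciprocal().to_tsv(tmp_path / "agent_b.tsv")
        lib = AgentLibrary.from_directory(tmp_path)
        assert lib.agent_ids == ("agent_a", "agent_b")
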