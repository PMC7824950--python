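"""Consensus-index arithmetic, invariants and oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethnosurvey import (
    ConsistencyError,
    ParameterError,
    compute_all_indices,
    informant_agreement_ratio,
    informant_consensus_factor,
    rank_species,
    species_therapeutic_potential,
    use_value,
)

from conftest import brute_force_indices, make_dataset


class TestScalarFormulas:
    @pytest.mark.parametrize(
        "nr, na, expected", [(5, 1, 1.0), (5, 5, 0.0), (3, 2, 0.5), (2, 1, 1.0)]
    )
    def test_agreement_ratio(self, nr, na, expected):
        assert informant_agreement_ratio(nr, na) == pytest.approx(expected)

    @pytest.mark.parametrize("nr, na", [(0, 0), (1, 1)])
    def test_agreement_ratio_undefined_below_two_citations(self, nr, na):
        assert informant_agreement_ratio(nr, na) is None

    def test_agreement_ratio_inconsistent_counts(self):
        with pytest.raises(ConsistencyError):
            informant_agreement_ratio(2, 3)

    @pytest.mark.parametrize(
        "nuc, nt, expected", [(2, 1, 1.0), (10, 10, 0.0), (10, 6, 4 / 9)]
    )
    def test_consensus_factor(self, nuc, nt, expected):
        assert informant_consensus_factor(nuc, nt) == pytest.approx(expected)

    def test_consensus_factor_undefined_for_single_citation(self):
        assert informant_consensus_factor(1, 1) is None

    @pytest.mark.parametrize(
        "ni, nti, expected", [(1, 1, 0.0), (1, 7, 0.0), (5, 10, 0.4), (2, 2, 0.5)]
    )
    def test_therapeutic_potential(self, ni, nti, expected):
        assert species_therapeutic_potential(ni, nti) == pytest.approx(expected)

    def test_therapeutic_potential_requires_citation(self):
        with pytest.raises(ParameterError):
            species_therapeutic_potential(0, 5)

    @given(nr=st.integers(2, 500), na=st.integers(1, 500))
    @settings(derandomize=True, max_examples=60)
    def test_agreement_ratio_bounds(self, nr, na):
        na = min(na, nr)
        value = informant_agreement_ratio(nr, na)
        assert 0.0 <= value <= 1.0
        assert (value == 1.0) == (na == 1)
        assert (value == 0.0) == (na == nr)

    @given(ni=st.integers(1, 100), nti=st.integers(1, 200))
    @settings(derandomize=True, max_examples=60)
    def test_stp_monotone_and_bounded(self, ni, nti):
        nti = max(ni, nti)
        stp = species_therapeutic_potential(ni, nti)
        assert 0.0 <= stp < ni / nti or (stp == 0.0 and ni == 1)
        if ni < nti:
            assert species_therapeutic_potential(ni + 1, nti) > stp


class TestUseValue:
    def test_sum_of_informant_uses_over_roster(self):
        # A cites s for 2 diseases, B for 1; roster padded to 10.
        ds = make_dataset(
            [("a", "s", "d1"), ("a", "s", "d2"), ("b", "s", "d1")],
            extra_informants=[f"pad{k}" for k in range(8)],
        )
        assert use_value(ds, "s") == pytest.approx(0.3)

    def test_uncited_species_is_zero(self):
        ds = make_dataset([("a", "s1", "d1")], extra_species=("s2",))
        assert use_value(ds, "s2") == 0.0

    def test_unknown_species_rejected(self):
        ds = make_dataset([("a", "s1", "d1")])
        with pytest.raises(ParameterError):
            use_value(ds, "nope")

    def test_equals_nr_over_ns_for_random_data(self):
        rng = np.random.default_rng(0)
        triples = {
            (f"i{rng.integers(6)}", f"s{rng.integers(5)}", f"d{rng.integers(4)}")
            for _ in range(40)
        }
        ds = make_dataset(sorted(triples))
        species_idx, _, _ = compute_all_indices(ds)
        for _, row in species_idx.iterrows():
            assert use_value(ds, row["species_id"]) == pytest.approx(
                row["Nr"] / ds.n_informants
            )
            assert row["uv"] == pytest.approx(row["Nr"] / ds.n_informants)


class TestComputeAllIndices:
    def test_toy_disease_consensus_and_selection(self):
        # D cited by A:s1, B:s1, C:s2 -> Nuc=3, Nt=2, ICF=0.5;
        # s1 retained (Ni=2, Nti=3, STP=1/3), s2 discarded.
        ds = make_dataset([("a", "s1", "d"), ("b", "s1", "d"), ("c", "s2", "d")])
        _, diseases, potential = compute_all_indices(ds)
        row = diseases.set_index("disease").loc["d"]
        assert (row["Nuc"], row["Nt"]) == (3, 2)
        assert row["icf"] == pytest.approx(0.5)
        assert list(potential["species_id"]) == ["s1"]
        assert potential.iloc[0]["Ni"] == 2
        assert potential.iloc[0]["Nti"] == 3
        assert potential.iloc[0]["stp"] == pytest.approx(1 / 3)

    def test_all_unique_citations_select_nothing(self):
        ds = make_dataset([("a", "s1", "d1"), ("b", "s2", "d2"), ("c", "s3", "d3")])
        _, _, potential = compute_all_indices(ds)
        assert potential.empty

    def test_citation_conservation(self):
        rng = np.random.default_rng(1)
        triples = {
            (f"i{rng.integers(8)}", f"s{rng.integers(6)}", f"d{rng.integers(5)}")
            for _ in range(60)
        }
        ds = make_dataset(sorted(triples))
        species_idx, diseases, _ = compute_all_indices(ds)
        assert species_idx["Nr"].sum() == diseases["Nuc"].sum() == ds.n_reports

    def test_duplicate_citation_changes_nothing(self):
        triples = [("a", "s1", "d"), ("b", "s1", "d")]
        ds1 = make_dataset(triples)
        ds2 = make_dataset(triples + [("a", "s1", "d")])
        for left, right in zip(compute_all_indices(ds1), compute_all_indices(ds2)):
            assert left.equals(right)

    def test_icf_defined_iff_two_citations(self):
        rng = np.random.default_rng(2)
        triples = {
            (f"i{rng.integers(10)}", f"s{rng.integers(10)}", f"d{rng.integers(5)}")
            for _ in range(50)
        }
        ds = make_dataset(sorted(triples))
        _, diseases, _ = compute_all_indices(ds)
        assert (diseases["icf"].notna() == (diseases["Nuc"] >= 2)).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_i, n_s, n_d = rng.integers(2, 11), rng.integers(2, 11), rng.integers(1, 6)
        triples = sorted(
            {
                (f"i{rng.integers(n_i)}", f"s{rng.integers(n_s)}", f"d{rng.integers(n_d)}")
                for _ in range(rng.integers(5, 60))
            }
        )
        ds = make_dataset(triples)
        check_against_oracle(ds, triples)


def check_against_oracle(ds, triples):
    """Assert compute_all_indices agrees with the enumeration oracle."""
    species_idx, diseases, potential = compute_all_indices(ds)
    oracle_sp, oracle_dis, oracle_pot = brute_force_indices(
        triples, list(ds.informants["informant_id"]), list(ds.species["species_id"])
    )
    for _, row in species_idx.iterrows():
        exp = oracle_sp[row["species_id"]]
        assert row["Nr"] == exp["Nr"] and row["Na"] == exp["Na"]
        assert row["uv"] == pytest.approx(exp["uv"])
        if exp["iar"] is None:
            assert math.isnan(row["iar"])
        else:
            assert row["iar"] == pytest.approx(exp["iar"])
    assert set(diseases["disease"]) == set(oracle_dis)
    for _, row in diseases.iterrows():
        exp = oracle_dis[row["disease"]]
        assert row["Nuc"] == exp["Nuc"] and row["Nt"] == exp["Nt"]
        if exp["icf"] is None:
            assert math.isnan(row["icf"])
        else:
            assert row["icf"] == pytest.approx(exp["icf"])
    got_pairs = {
        (r["disease"], r["species_id"]): r for _, r in potential.iterrows()
    }
    assert set(got_pairs) == set(oracle_pot)
    for key, exp in oracle_pot.items():
        row = got_pairs[key]
        assert row["Ni"] == exp["Ni"] and row["Nti"] == exp["Nti"]
        assert row["stp"] == pytest.approx(exp["stp"])


class TestRankSpecies:
    def test_descending_by_uv(self):
        ds = make_dataset(
            [("a", "s1", "d1"), ("a", "s1", "d2"), ("b", "s1", "d1"),
             ("a", "s2", "d1"), ("b", "s2", "d1"), ("a", "s3", "d1")]
        )
        species_idx, _, _ = compute_all_indices(ds)
        ranked = rank_species(species_idx, by="uv", top_n=3)
        assert list(ranked["species_id"]) == ["s1", "s2", "s3"]

    def test_equal_values_fall_back_to_name_order(self):
        ds = make_dataset([("a", "s2", "d1"), ("a", "s1", "d2"), ("a", "s3", "d3")])
        species_idx, _, _ = compute_all_indices(ds)
        ranked = rank_species(species_idx, by="uv", top_n=3)
        assert list(ranked["species_id"]) == ["s1", "s2", "s3"]

    def test_top_n_zero_is_empty(self):
        ds = make_dataset([("a", "s1", "d1")])
        species_idx, _, _ = compute_all_indices(ds)
        assert rank_species(species_idx, by="uv", top_n=0).empty

    def test_missing_iar_sorts_last(self):
        ds = make_dataset([("a", "s1", "d1"), ("b", "s1", "d1"), ("a", "s2", "d1")])
        species_idx, _, _ = compute_all_indices(ds)
        ranked = rank_species(species_idx, by="iar", top_n=2)
        assert list(ranked["species_id"]) == ["s1", "s2"]

    def test_invalid_key_rejected(self):
        ds = make_dataset([("a", "s1", "d1")])
        species_idx, _, _ = compute_all_indices(ds)
        with pytest.raises(ParameterError):
            rank_species(species_idx, by="Nr")
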