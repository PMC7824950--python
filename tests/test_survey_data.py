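"""Loading, validation and descriptive summaries of the survey data model."""

import numpy as np
import pandas as pd
import pytest

from ethnosurvey import (
    IntegrityError,
    ParameterError,
    SchemaError,
    SyntheticConfig,
    VocabularyError,
    categorical_share,
    generate_survey,
    informant_profile_summary,
    load_survey,
    taxonomic_summary,
    write_survey,
)
from ethnosurvey.vocab import canonicalize, round_half_up

from conftest import DEFAULT_INFORMANT, make_dataset


class TestCanonicalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("  Curing  Healer ", "curing_healer"),
            ("FEMALE", "female"),
            ("décoction", "decoction"),
            ("> 10", ">10"),
            ("0–5", "0-5"),
            ("traditional health practitioner", "traditional_health_practitioner"),
            ("", ""),
            (None, ""),
        ],
    )
    def test_canonical_forms(self, raw, expected):
        assert canonicalize(raw) == expected

    @pytest.mark.parametrize(
        "value, expected", [(16.666666, 16.7), (8.125, 8.1), (10.9375, 10.9), (42.55, 42.6), (57.45, 57.5)]
    )
    def test_round_half_up(self, value, expected):
        assert round_half_up(value, 1) == expected


class TestLoadSurvey:
    def test_duplicate_triples_collapse(self):
        ds = make_dataset(
            [("i1", "s1", "fever"), ("i1", "s1", "fever"), ("i2", "s1", "fever")]
        )
        assert ds.n_reports == 2

    def test_case_and_accent_variants_collapse(self):
        ds = make_dataset(
            [("i1", "s1", "Fièvre"), ("i1", "s1", "fievre"), ("i1", "s1", "FIEVRE ")]
        )
        assert ds.n_reports == 1

    def test_orphan_informant_rejected(self):
        reports = pd.DataFrame(
            [("ghost", "s1", "fever")], columns=["informant_id", "species_id", "disease"]
        )
        informants = pd.DataFrame([{"informant_id": "i1", **DEFAULT_INFORMANT}])
        species = pd.DataFrame(
            [{"species_id": "s1", "scientific_name": "X y", "family": "fabaceae", "genus": "x"}]
        )
        with pytest.raises(IntegrityError, match="informant_id"):
            load_survey(reports, informants, species)

    def test_missing_column_named_in_error(self):
        reports = pd.DataFrame([("i1", "fever")], columns=["informant_id", "disease"])
        informants = pd.DataFrame([{"informant_id": "i1", **DEFAULT_INFORMANT}])
        species = pd.DataFrame(
            [{"species_id": "s1", "scientific_name": "X y", "family": "f", "genus": "x"}]
        )
        with pytest.raises(SchemaError, match="species_id"):
            load_survey(reports, informants, species)

    def test_unknown_category_label_rejected(self):
        with pytest.raises(VocabularyError, match="gender"):
            make_dataset(
                [("i1", "s1", "fever")], informant_attrs={"i1": {"gender": "unknown_level"}}
            )

    def test_zero_report_informants_counted(self, toy_ds):
        assert toy_ds.n_informants == 4

    def test_full_scale_roster(self):
        ds, _ = generate_survey(SyntheticConfig(seed=0))
        assert ds.n_informants == 188
        assert ds.n_species == 227


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_write_then_load_is_identity(self, tmp_path, seed):
        ds, _ = generate_survey(SyntheticConfig(seed=seed, n_informants=40, n_species=30))
        paths = write_survey(ds, tmp_path / str(seed))
        ds2 = load_survey(paths["reports"], paths["informants"], paths["species"])
        pd.testing.assert_frame_equal(ds.informants, ds2.informants)
        pd.testing.assert_frame_equal(ds.species, ds2.species)
        pd.testing.assert_frame_equal(ds.reports, ds2.reports)


class TestInformantProfile:
    def test_single_level_is_100_percent(self, toy_ds):
        prof = informant_profile_summary(toy_ds, "residence")
        assert list(prof["percent"]) == [100.0]
        assert prof["count"].sum() == toy_ds.n_informants

    def test_counts_sum_to_roster_for_every_factor(self):
        ds, _ = generate_survey(SyntheticConfig(seed=3))
        for factor in ("gender", "age_class", "education", "category", "residence"):
            prof = informant_profile_summary(ds, factor)
            assert prof["count"].sum() == ds.n_informants
            assert abs(prof["percent"].sum() - 100.0) <= 0.15

    def test_knowledge_means_include_zero_report_informants(self, toy_ds):
        prof = informant_profile_summary(toy_ds, "gender")
        # i1 -> (1 sp, 2 dis), i2 -> (1, 1), i3 -> (1, 1), i4 -> (0, 0)
        assert prof.loc[0, "mean_species"] == pytest.approx(3 / 4)
        assert prof.loc[0, "mean_diseases"] == pytest.approx(1.0)

    def test_sample_sd(self):
        ds = make_dataset(
            [("i1", "s1", "fever"), ("i2", "s1", "fever"), ("i2", "s2", "fever")]
        )
        prof = informant_profile_summary(ds, "gender")
        assert prof.loc[0, "sd_species"] == pytest.approx(np.std([1, 2], ddof=1))

    def test_unknown_factor_rejected(self, toy_ds):
        with pytest.raises(ParameterError):
            informant_profile_summary(toy_ds, "shoe_size")


class TestTaxonomicSummary:
    def test_single_family_is_total(self):
        ds = make_dataset([("i1", "s1", "fever")])
        tab = taxonomic_summary(ds)
        assert list(tab["pct_species"]) == [100.0]
        assert list(tab["pct_genera"]) == [100.0]

    def test_species_and_genus_conservation(self):
        ds, _ = generate_survey(SyntheticConfig(seed=4))
        tab = taxonomic_summary(ds)
        identified = ds.species[ds.species["family"] != ""]
        assert tab["n_species"].sum() == len(identified)
        assert tab["n_genera"].sum() == identified["genus"].nunique()

    def test_sorted_by_species_desc_with_tail_pooled(self):
        ds, _ = generate_survey(SyntheticConfig(seed=4))
        tab = taxonomic_summary(ds, min_species=3)
        named = tab[tab["family"] != "other_families"]
        assert list(named["n_species"]) == sorted(named["n_species"], reverse=True)
        assert (named["n_species"] >= 3).all()
        assert tab["family"].iloc[-1] == "other_families"


class TestCategoricalShare:
    def test_all_one_level(self):
        ds = make_dataset([("i1", "s1", "fever")])
        ds.reports["organ"] = "leaf"
        tab = categorical_share(ds, "organ")
        assert list(tab["percent"]) == [100.0]

    def test_two_level_split(self):
        triples = [(f"i{k}", f"s{k}", "fever") for k in range(10)]
        ds = make_dataset(triples)
        ds.reports["organ"] = ["leaf"] * 4 + ["root"] * 6
        tab = categorical_share(ds, "organ").set_index("level")
        assert tab.loc["root", "percent"] == 60.0
        assert tab.loc["leaf", "percent"] == 40.0

    def test_missing_values_excluded_from_denominator(self):
        triples = [(f"i{k}", f"s{k}", "fever") for k in range(4)]
        ds = make_dataset(triples)
        ds.reports["organ"] = ["leaf", "leaf", "", ""]
        tab = categorical_share(ds, "organ").set_index("level")
        assert tab.loc["leaf", "percent"] == 100.0
        assert tab.loc["unspecified", "count"] == 2
        tab_inc = categorical_share(ds, "organ", include_missing=True).set_index("level")
        assert tab_inc.loc["leaf", "percent"] == 50.0

    def test_species_attribute_denominator_is_species(self):
        ds, _ = generate_survey(SyntheticConfig(seed=5))
        tab = categorical_share(ds, "biological_form")
        assert tab["count"].sum() == ds.n_species

    def test_percents_sum_to_100(self):
        ds, _ = generate_survey(SyntheticConfig(seed=6))
        for attr in ("organ", "preparation", "administration", "habitat_class"):
            tab = categorical_share(ds, attr)
            assert abs(tab["percent"].dropna().sum() - 100.0) <= 0.15

    def test_unknown_attribute_rejected(self, toy_ds):
        with pytest.raises(ParameterError):
            categorical_share(toy_ds, "flavour")
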