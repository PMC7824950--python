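"""Shared fixtures: hand-built datasets and a brute-force index oracle."""

from __future__ import annotations

from collections import defaultdict

import pandas as pd
import pytest

from ethnosurvey import SurveyDataset, load_survey

DEFAULT_INFORMANT = {
    "gender": "female",
    "age_class": "adult",
    "education": "primary",
    "experience_class": ">10",
    "category": "traditional_health_practitioner",
    "marital_status": "married",
    "residence": "kisantu",
}


def make_dataset(
    triples,
    extra_informants=(),
    informant_attrs: dict | None = None,
    extra_species=(),
    species_attrs: dict | None = None,
) -> SurveyDataset:
    """Build a validated dataset from (informant, species, disease) triples.

    ``extra_informants`` adds zero-report informants; ``informant_attrs``
    overrides attribute values per informant id; ``species_attrs`` maps
    species id -> {family, genus, ...} overrides.
    """
    informant_ids = sorted({t[0] for t in triples} | set(extra_informants))
    species_ids = sorted({t[1] for t in triples} | set(extra_species))
    inf_rows = []
    for iid in informant_ids:
        row = {"informant_id": iid, **DEFAULT_INFORMANT}
        row.update((informant_attrs or {}).get(iid, {}))
        inf_rows.append(row)
    sp_rows = []
    for sid in species_ids:
        row = {
            "species_id": sid,
            "scientific_name": f"Plantus {sid}",
            "family": "fabaceae",
            "genus": f"genus_{sid}",
            "biological_form": "herb",
            "habitat_class": "anthropized",
        }
        row.update((species_attrs or {}).get(sid, {}))
        sp_rows.append(row)
    reports = pd.DataFrame(triples, columns=["informant_id", "species_id", "disease"])
    return load_survey(reports, pd.DataFrame(inf_rows), pd.DataFrame(sp_rows))


def brute_force_indices(triples, informant_ids, species_ids):
    """Direct-enumeration oracle for all four indices.

    Works from the raw triple set with nested loops and explicit set
    algebra; independent of the pandas group-by implementation.
    """
    trips = sorted(set(triples))
    ns = len(informant_ids)
    species = {}
    for s in species_ids:
        cites = [(i, d) for (i, s2, d) in trips if s2 == s]
        nr = len(cites)
        na = len({d for _, d in cites})
        uis_total = sum(
            len({d for (i2, d) in cites if i2 == i}) for i in informant_ids
        )
        species[s] = {
            "Nr": nr,
            "Na": na,
            "uv": uis_total / ns if ns else 0.0,
            "iar": (nr - na) / (nr - 1) if nr >= 2 else None,
        }
    diseases = {}
    for dlab in sorted({d for _, _, d in trips}):
        cites = [(i, s) for (i, s, d2) in trips if d2 == dlab]
        nuc = len(cites)
        nt = len({s for _, s in cites})
        diseases[dlab] = {
            "Nuc": nuc,
            "Nt": nt,
            "icf": (nuc - nt) / (nuc - 1) if nuc >= 2 else None,
        }
    potential = {}
    informants_by_disease = defaultdict(set)
    for i, s, d in trips:
        informants_by_disease[d].add(i)
    for dlab in diseases:
        nti = len(informants_by_disease[dlab])
        for s in {s for (i, s, d) in trips if d == dlab}:
            ni = len({i for (i, s2, d) in trips if d == dlab and s2 == s})
            if ni >= 2:
                potential[(dlab, s)] = {"Ni": ni, "Nti": nti, "stp": (ni - 1) / nti}
    return species, diseases, potential


@pytest.fixture
def toy_ds() -> SurveyDataset:
    """Three informants, two species, two diseases; informant i4 has no reports."""
    return make_dataset(
        [
            ("i1", "s1", "fever"),
            ("i1", "s1", "cough"),
            ("i2", "s1", "fever"),
            ("i3", "s2", "fever"),
        ],
        extra_informants=("i4",),
    )
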