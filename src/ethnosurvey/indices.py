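"""Consensus indices for medicinal-plant use reports.

All four indices are built on one counting unit, the *citation*: one
informant naming one species for one disease.

* **Use value** ``UV = sum_i(U_is) / ns`` — ``U_is`` is the number of
  distinct diseases informant *i* cites species *s* for, ``ns`` the roster
  size; under this counting unit ``UV = Nr / ns``.
* **Informant agreement ratio** ``IAR = (Nr - Na) / (Nr - 1)`` — ``Nr``
  citations of the species, ``Na`` distinct diseases it treats; 1 when every
  citation concerns the same disease, 0 when every citation names a new one.
* **Informant consensus factor** ``ICF = (Nuc - Nt) / (Nuc - 1)`` — ``Nuc``
  citations of the disease, ``Nt`` distinct species used for it.
* **Species therapeutic potential** ``STP = (Ni - 1) / Nti`` — ``Ni``
  informants citing the species for the disease, ``Nti`` informants citing
  any species for it; species cited once (``Ni = 1``, ``STP = 0``) are
  discarded from the therapeutic-potential selection.

IAR and ICF are undefined (returned as missing) for fewer than two
citations.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError
from .survey_data import SurveyDataset

__all__ = [
    "use_value",
    "informant_agreement_ratio",
    "informant_consensus_factor",
    "species_therapeutic_potential",
    "compute_all_indices",
    "rank_species",
]


def use_value(ds: SurveyDataset, species_id: str) -> float:
    """Use value of one species: per-informant distinct-disease counts summed
    over informants, divided by the roster size (zero for an uncited species)."""
    if species_id not in set(ds.species["species_id"]):
        raise ParameterError(f"unknown species '{species_id}'")
    cited = ds.reports[ds.reports["species_id"] == species_id]
    uis = cited.groupby("informant_id")["disease"].nunique()
    return float(uis.sum()) / ds.n_informants


def informant_agreement_ratio(nr: int, na: int) -> Optional[float]:
    """(Nr - Na) / (Nr - 1); ``None`` when Nr < 2 (undefined)."""
    if na > nr or na < 0 or nr < 0:
        raise ConsistencyError(f"Na={na} inconsistent with Nr={nr}")
    if nr < 2:
        return None
    return (nr - na) / (nr - 1)


def informant_consensus_factor(nuc: int, nt: int) -> Optional[float]:
    """(Nuc - Nt) / (Nuc - 1); ``None`` when Nuc < 2 (undefined)."""
    if nt > nuc or nt < 0 or nuc < 0:
        raise ConsistencyError(f"Nt={nt} inconsistent with Nuc={nuc}")
    if nuc < 2:
        return None
    return (nuc - nt) / (nuc - 1)


def species_therapeutic_potential(ni: int, nti: int) -> float:
    """(Ni - 1) / Nti as a proportion; Ni = 1 gives 0 (species discarded)."""
    if ni < 1:
        raise ParameterError("a species not cited for the disease has no STP (Ni >= 1)")
    if nti < ni:
        raise ParameterError(f"Nti={nti} must be >= Ni={ni}")
    return (ni - 1) / nti


def compute_all_indices(
    ds: SurveyDataset,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Compute every per-species and per-disease index in one pass.

    Returns ``(species_indices, disease_consensus, therapeutic_potential)``:

    * species_indices — one row per species (uncited included):
      species_id, scientific_name, family, Nr, Na, uv, iar;
    * disease_consensus — one row per cited disease: disease, Nuc, Nt, icf;
    * therapeutic_potential — the selected (disease, species) pairs with
      Ni >= 2: disease, species_id, scientific_name, Ni, Nti, stp.
    """
    rep = ds.reports
    ns = ds.n_informants

    per_species = rep.groupby("species_id").agg(
        Nr=("disease", "size"), Na=("disease", "nunique")
    )
    species_idx = ds.species[["species_id", "scientific_name", "family"]].merge(
        per_species, on="species_id", how="left"
    )
    species_idx[["Nr", "Na"]] = species_idx[["Nr", "Na"]].fillna(0).astype(int)
    species_idx["uv"] = species_idx["Nr"] / ns if ns else 0.0
    nr = species_idx["Nr"].to_numpy(float)
    na = species_idx["Na"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        iar = np.where(nr >= 2, (nr - na) / np.where(nr >= 2, nr - 1, 1), np.nan)
    species_idx["iar"] = iar

    per_disease = rep.groupby("disease").agg(
        Nuc=("species_id", "size"), Nt=("species_id", "nunique")
    ).reset_index()
    nuc = per_disease["Nuc"].to_numpy(float)
    nt = per_disease["Nt"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        icf = np.where(nuc >= 2, (nuc - nt) / np.where(nuc >= 2, nuc - 1, 1), np.nan)
    per_disease["icf"] = icf
    per_disease = per_disease.sort_values("disease").reset_index(drop=True)

    # Therapeutic potential: Ni distinct informants per (disease, species),
    # Nti distinct informants citing anything for the disease.
    pair = rep.groupby(["disease", "species_id"]).agg(
        Ni=("informant_id", "nunique")
    ).reset_index()
    nti = rep.groupby("disease")["informant_id"].nunique().rename("Nti")
    pair = pair.merge(nti, on="disease")
    pair = pair[pair["Ni"] >= 2].copy()
    pair["stp"] = (pair["Ni"] - 1) / pair["Nti"]
    pair = pair.merge(ds.species[["species_id", "scientific_name"]], on="species_id")
    pair = pair.sort_values(["disease", "stp", "species_id"], ascending=[True, False, True])
    pair = pair[["disease", "species_id", "scientific_name", "Ni", "Nti", "stp"]]

    return species_idx, per_disease, pair.reset_index(drop=True)


def rank_species(records: pd.DataFrame, by: str = "uv", top_n: int = 10) -> pd.DataFrame:
    """Rank the species-index table by ``uv`` or ``iar``.

    Descending on the chosen index, ties broken by Nr descending then
    scientific name ascending; species with a missing IAR sort last.
    """
    if by not in ("uv", "iar"):
        raise ParameterError(f"rank key must be 'uv' or 'iar', got '{by}'")
    if top_n < 0:
        raise ParameterError("top_n must be non-negative")
    name_col = "scientific_name" if "scientific_name" in records.columns else "species_id"
    ordered = records.sort_values(
        [by, "Nr", name_col],
        ascending=[False, False, True],
        na_position="last",
    )
    return ordered.head(top_n).reset_index(drop=True)
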