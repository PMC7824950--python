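"""Survey data model: load, validate and summarise use-report tables.

The data model has three tables:

* ``informants`` — one row per interviewed phytotherapist, with categorical
  sociological attributes (gender, age class, education, experience class,
  therapist category, marital status, residence community);
* ``species`` — one row per medicinal plant, with taxonomic placement
  (family, genus, scientific name) and attributes (biological form, habitat
  class);
* ``reports`` — the long-format use reports, one row per *citation*: one
  informant naming one species for one disease, optionally with the plant
  organ used, the preparation and the administration route.

The citation triple (informant, species, disease) is the atomic counting
unit for every downstream index; exact duplicate triples are collapsed at
load time (the collapse count is logged).  The roster size ``n_informants``
includes informants with zero reports — it is the denominator of the use
value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParameterError, SchemaError, VocabularyError
from .vocab import (
    DEFAULT_VOCABULARIES,
    INFORMANT_FIELDS,
    REPORT_ATTRIBUTES,
    SPECIES_FIELDS,
    canonicalize,
    canonicalize_series,
    round_half_up,
)

logger = logging.getLogger("ethnosurvey")

REPORT_COLUMNS = ("informant_id", "species_id", "disease")
OPTIONAL_REPORT_COLUMNS = REPORT_ATTRIBUTES
INFORMANT_COLUMNS = ("informant_id",) + INFORMANT_FIELDS
SPECIES_COLUMNS = (
    "species_id",
    "scientific_name",
    "family",
    "genus",
    "biological_form",
    "habitat_class",
)


@dataclass(frozen=True)
class SurveyDataset:
    """A validated survey: informant roster, species table and use reports."""

    informants: pd.DataFrame
    species: pd.DataFrame
    reports: pd.DataFrame

    @property
    def n_informants(self) -> int:
        """Roster size, including informants with zero reports."""
        return len(self.informants)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def subset_by_informants(self, informant_ids) -> "SurveyDataset":
        """Restrict roster and reports to the given informants (species kept)."""
        ids = set(informant_ids)
        inf = self.informants[self.informants["informant_id"].isin(ids)]
        rep = self.reports[self.reports["informant_id"].isin(ids)]
        return SurveyDataset(
            inf.reset_index(drop=True), self.species, rep.reset_index(drop=True)
        )


def _as_frame(source, name: str) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    try:
        return pd.read_csv(source, dtype=str, keep_default_na=False, na_values=[])
    except FileNotFoundError:
        raise SchemaError(f"{name} table not found: {source}") from None


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing required column '{col}'")


def _check_vocab(series: pd.Series, field: str, vocab, table: str, required: bool) -> None:
    allowed = vocab.get(field, DEFAULT_VOCABULARIES.get(field))
    values = series[series != ""] if not required else series
    if required and (series == "").any():
        bad = series.index[series == ""].tolist()[:10]
        raise VocabularyError(f"{table}.{field}: empty value in rows {bad}")
    if allowed is None:
        return
    unknown = sorted(set(values) - set(allowed))
    if unknown:
        raise VocabularyError(
            f"{table}.{field}: unknown labels {unknown}; allowed: {sorted(allowed)}"
        )


def load_survey(
    reports_table,
    informants_table,
    species_table,
    vocabularies: dict | None = None,
) -> SurveyDataset:
    """Load and validate the three survey tables (paths or DataFrames).

    All labels are canonicalized before validation; closed-vocabulary fields
    reject unknown labels.  Duplicate (informant, species, disease) triples
    are collapsed (first occurrence wins for the optional attributes) and the
    collapse count is logged.

    Raises
    ------
    SchemaError
        if a required column is missing.
    IntegrityError
        if a report references an unknown informant or species, or an
        identifier is duplicated.
    VocabularyError
        if a categorical value is outside its declared vocabulary.
    """
    vocab = dict(DEFAULT_VOCABULARIES)
    if vocabularies:
        vocab.update({k: tuple(v) if v is not None else None for k, v in vocabularies.items()})

    informants = _as_frame(informants_table, "informants")
    species = _as_frame(species_table, "species")
    reports = _as_frame(reports_table, "reports")

    _require_columns(informants, INFORMANT_COLUMNS, "informants")
    _require_columns(species, ("species_id", "scientific_name", "family", "genus"), "species")
    for col in SPECIES_FIELDS:
        if col not in species.columns:
            species[col] = ""
    _require_columns(reports, REPORT_COLUMNS, "reports")
    for col in OPTIONAL_REPORT_COLUMNS:
        if col not in reports.columns:
            reports[col] = ""

    # Canonicalize identifiers and categorical labels.
    for col in ("informant_id",) + INFORMANT_FIELDS:
        informants[col] = canonicalize_series(informants[col])
    species["species_id"] = canonicalize_series(species["species_id"])
    species["scientific_name"] = species["scientific_name"].astype(str).str.strip()
    species["family"] = canonicalize_series(species["family"])
    species["genus"] = canonicalize_series(species["genus"])
    for col in SPECIES_FIELDS:
        species[col] = canonicalize_series(species[col])
    for col in REPORT_COLUMNS + OPTIONAL_REPORT_COLUMNS:
        reports[col] = canonicalize_series(reports[col])

    # Identifier uniqueness.
    for df, key, table in ((informants, "informant_id", "informants"), (species, "species_id", "species")):
        if (df[key] == "").any():
            raise IntegrityError(f"{table}: empty {key}")
        dup = df[key][df[key].duplicated()].unique()
        if len(dup):
            raise IntegrityError(f"{table}: duplicated {key} values {sorted(dup)[:10]}")

    # Vocabulary checks.
    for field in INFORMANT_FIELDS:
        _check_vocab(informants[field], field, vocab, "informants", required=True)
    for field in SPECIES_FIELDS:
        _check_vocab(species[field], field, vocab, "species", required=False)
    for field in OPTIONAL_REPORT_COLUMNS:
        _check_vocab(reports[field], field, vocab, "reports", required=False)
    _check_vocab(reports["disease"], "disease", vocab, "reports", required=True)

    # genus non-empty when family non-empty
    bad_genus = species.index[(species["family"] != "") & (species["genus"] == "")]
    if len(bad_genus):
        raise IntegrityError(
            f"species: genus missing for rows with a family: {bad_genus.tolist()[:10]}"
        )

    # Referential integrity.
    known_inf = set(informants["informant_id"])
    known_sp = set(species["species_id"])
    orphan_inf = reports.index[~reports["informant_id"].isin(known_inf)]
    if len(orphan_inf):
        raise IntegrityError(
            f"reports: unknown informant_id in rows {orphan_inf.tolist()[:20]}"
        )
    orphan_sp = reports.index[~reports["species_id"].isin(known_sp)]
    if len(orphan_sp):
        raise IntegrityError(
            f"reports: unknown species_id in rows {orphan_sp.tolist()[:20]}"
        )

    # Collapse duplicate citation triples.
    before = len(reports)
    reports = reports.drop_duplicates(subset=list(REPORT_COLUMNS), keep="first")
    collapsed = before - len(reports)
    if collapsed:
        logger.info("collapsed %d duplicate citation triples", collapsed)

    return SurveyDataset(
        informants.reset_index(drop=True),
        species.reset_index(drop=True),
        reports.reset_index(drop=True),
    )


def write_survey(ds: SurveyDataset, outdir) -> dict[str, Path]:
    """Write the three survey tables as UTF-8 CSV; missing values as ''."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "informants": outdir / "informants.csv",
        "species": outdir / "species.csv",
        "reports": outdir / "reports.csv",
    }
    ds.informants.to_csv(paths["informants"], index=False)
    ds.species.to_csv(paths["species"], index=False)
    ds.reports.to_csv(paths["reports"], index=False)
    return paths


def _knowledge_by_informant(ds: SurveyDataset) -> pd.DataFrame:
    """Per-informant distinct species and distinct diseases (zeros included)."""
    grouped = ds.reports.groupby("informant_id").agg(
        n_species=("species_id", "nunique"), n_diseases=("disease", "nunique")
    )
    out = grouped.reindex(ds.informants["informant_id"], fill_value=0).reset_index()
    return out.astype({"n_species": int, "n_diseases": int})


def informant_profile_summary(ds: SurveyDataset, factor: str) -> pd.DataFrame:
    """Per-level counts and knowledge summaries for one informant factor.

    Returns a frame with columns ``level, count, percent, mean_species,
    sd_species, mean_diseases, sd_diseases`` where ``percent`` is
    count / n_informants x 100 (half-up, 1 decimal) and the means/SDs are
    over per-informant distinct species and disease counts (sample SD,
    informants with zero reports contribute zeros).
    """
    if factor not in INFORMANT_FIELDS:
        raise ParameterError(f"unknown informant factor '{factor}'")
    counts = _knowledge_by_informant(ds)
    merged = ds.informants[["informant_id", factor]].merge(counts, on="informant_id")
    n = ds.n_informants
    vocab_order = DEFAULT_VOCABULARIES.get(factor)
    levels = (
        [lv for lv in vocab_order if lv in set(merged[factor])]
        if vocab_order
        else sorted(merged[factor].unique())
    )
    rows = []
    for level in levels:
        sub = merged[merged[factor] == level]
        rows.append(
            {
                "level": level,
                "count": len(sub),
                "percent": round_half_up(len(sub) / n * 100, 1),
                "mean_species": float(sub["n_species"].mean()),
                "sd_species": float(sub["n_species"].std(ddof=1)) if len(sub) > 1 else float("nan"),
                "mean_diseases": float(sub["n_diseases"].mean()),
                "sd_diseases": float(sub["n_diseases"].std(ddof=1)) if len(sub) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def taxonomic_summary(ds: SurveyDataset, min_species: int = 3) -> pd.DataFrame:
    """Family-level taxonomic diversity of the species table.

    Families with fewer than ``min_species`` species are pooled into an
    ``other_families`` row.  Percent shares (half-up, 1 decimal) are over the
    total identified species (non-empty family) and total distinct genera;
    each genus belongs to exactly one family, so genus shares add to 100.
    """
    sp = ds.species[ds.species["family"] != ""]
    if sp.empty:
        raise ParameterError("species table has no identified species")
    total_species = len(sp)
    total_genera = sp["genus"].nunique()
    per_family = sp.groupby("family").agg(
        n_species=("species_id", "size"), n_genera=("genus", "nunique")
    )
    per_family = per_family.sort_values(
        ["n_species", "family"], ascending=[False, True], key=None
    )
    per_family = per_family.reset_index()
    major = per_family[per_family["n_species"] >= min_species].copy()
    minor = per_family[per_family["n_species"] < min_species]
    rows = major.to_dict("records")
    if len(minor):
        rows.append(
            {
                "family": "other_families",
                "n_species": int(minor["n_species"].sum()),
                "n_genera": int(minor["n_genera"].sum()),
            }
        )
    out = pd.DataFrame(rows)
    out["pct_species"] = [round_half_up(v / total_species * 100, 1) for v in out["n_species"]]
    out["pct_genera"] = [round_half_up(v / total_genera * 100, 1) for v in out["n_genera"]]
    return out[["family", "n_species", "pct_species", "n_genera", "pct_genera"]]


def categorical_share(
    ds: SurveyDataset, attribute: str, include_missing: bool = False
) -> pd.DataFrame:
    """Share table for a report attribute or a species attribute.

    For report attributes (organ, preparation, administration) the
    denominator is the number of use reports carrying a non-missing value;
    for species attributes (biological_form, habitat_class) it is the number
    of species with a non-missing value.  Missing values appear as an
    ``unspecified`` row, excluded from the denominator unless
    ``include_missing`` is set.
    """
    if attribute in REPORT_ATTRIBUTES:
        values = ds.reports[attribute]
    elif attribute in SPECIES_FIELDS:
        values = ds.species[attribute]
    else:
        raise ParameterError(f"unknown attribute '{attribute}'")
    present = values[values != ""]
    n_missing = int((values == "").sum())
    denom = len(values) if include_missing else len(present)
    counts = present.value_counts().sort_values(ascending=False)
    rows = [
        {"level": lv, "count": int(c), "percent": round_half_up(c / denom * 100, 1) if denom else float("nan")}
        for lv, c in counts.items()
    ]
    if n_missing:
        rows.append(
            {
                "level": "unspecified",
                "count": n_missing,
                "percent": round_half_up(n_missing / denom * 100, 1) if include_missing else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["level", "count", "percent"])
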