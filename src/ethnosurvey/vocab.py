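"""Controlled vocabularies and label canonicalization.

Every label that enters the data model — categorical informant attributes,
species attributes, report attributes, disease names and identifiers — is
first canonicalized (accent-fold, case-fold, whitespace collapse) so that
"Curing healer", "curing  HEALER" and "curing_healer" all denote the same
level.  Closed vocabularies are enforced at load time; ``residence`` and
``disease`` are open by default (any non-empty canonical label) but can be
closed through a config.
"""

from __future__ import annotations

import math
import re
import unicodedata
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

#: Categorical informant attributes (everything except the identifier).
INFORMANT_FIELDS = (
    "gender",
    "age_class",
    "education",
    "experience_class",
    "category",
    "marital_status",
    "residence",
)

#: Categorical species attributes.
SPECIES_FIELDS = ("biological_form", "habitat_class")

#: Optional per-report attributes.
REPORT_ATTRIBUTES = ("organ", "preparation", "administration")

#: Closed vocabularies; ``None`` marks an open vocabulary.
DEFAULT_VOCABULARIES: dict[str, tuple[str, ...] | None] = {
    "gender": ("female", "male"),
    "age_class": ("young", "adult", "old"),
    "education": ("illiterate", "primary", "secondary", "superior"),
    "experience_class": ("0-5", "5-10", ">10"),
    "category": ("herbalist", "curing_healer", "traditional_health_practitioner"),
    "marital_status": ("single", "married", "widowed"),
    "residence": None,
    "disease": None,
    "organ": ("leaf", "root", "bark", "fruit", "seed", "whole_plant", "other"),
    "preparation": ("decoction", "maceration", "infusion", "powder", "other"),
    "administration": ("oral", "topical", "bath", "other"),
    "biological_form": ("herb", "shrub", "tree", "liana", "other"),
    "habitat_class": ("anthropized", "forest", "savannah", "aquatic", "other"),
}

_WS = re.compile(r"\s+")
_PUNCT_SPACE = re.compile(r"\s*([^\w\s])\s*")


def canonicalize(label: object) -> str:
    """Return the canonical form of a label.

    Strips accents (NFKD), case-folds, trims, collapses internal whitespace,
    removes whitespace around punctuation ("> 10" -> ">10") and replaces the
    remaining spaces with underscores.  ``None``/NaN and empty strings map to
    ``""`` (the missing marker on disk).
    """
    if label is None or (isinstance(label, float) and math.isnan(label)) or label is pd.NA:
        return ""
    s = unicodedata.normalize("NFKD", str(label))
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    s = s.replace("–", "-").replace("—", "-")
    s = _WS.sub(" ", s.casefold().strip())
    s = _PUNCT_SPACE.sub(r"\1", s)
    return s.replace(" ", "_")


def canonicalize_series(values: pd.Series) -> pd.Series:
    """Canonicalize a pandas Series, mapping each unique raw label once."""
    uniques = values.dropna().unique()
    mapping = {u: canonicalize(u) for u in uniques}
    return values.map(mapping).fillna("")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (presentation rule)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
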