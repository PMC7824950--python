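"""Cross-community similarity of medicinal-plant knowledge.

Two communities are compared on the species they *cite* (at least one use
report), with the bookkeeping

* ``a`` — species cited only in community A,
* ``b`` — species cited only in community B,
* ``c`` — species cited in both,
* ``d`` — common species used for at least one identical disease in both,
* ``e`` — diseases reported in both communities,

and the similarity index ``RSI (%) = d / (a + b + c - d) x 100``: two
communities are culturally closer when they use the same species against
the same diseases.  ``d <= c`` always, and the index is symmetric in the
two communities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .errors import ParameterError, UndefinedResultError
from .survey_data import SurveyDataset
from .vocab import INFORMANT_FIELDS, round_half_up

logger = logging.getLogger("ethnosurvey")

__all__ = ["PairSimilarity", "rsi_from_counts", "rahman_similarity", "pairwise_similarity_table"]


@dataclass(frozen=True)
class PairSimilarity:
    """Species-set bookkeeping and similarity for one pair of communities."""

    community_a: str
    community_b: str
    a: int
    b: int
    c: int
    d: int
    e: int
    rsi_percent: float
    n_species_a: int = 0
    n_species_b: int = 0
    n_diseases_a: int = 0
    n_diseases_b: int = 0


def rsi_from_counts(a: int, b: int, c: int, d: int, ndigits: int | None = 1) -> float:
    """Similarity percent d / (a + b + c - d) x 100 from the four counts.

    Rounded half-up to ``ndigits`` decimals (default 1, the reporting
    precision); pass ``ndigits=None`` for full precision.
    """
    if min(a, b, c, d) < 0:
        raise ParameterError("counts must be non-negative")
    if d > c:
        raise ParameterError(f"d={d} cannot exceed c={c}")
    denom = a + b + c - d
    if denom <= 0:
        # denom = 0 iff a+b = 0 and c = d: either no species anywhere
        # (undefined), or two identical repertoires in full agreement, the
        # d -> c limit of the formula (100%).
        if d > 0:
            return 100.0
        raise UndefinedResultError("no species in either community: RSI undefined")
    value = d / denom * 100.0
    return value if ndigits is None else round_half_up(value, ndigits)


def _community_sets(ds: SurveyDataset):
    """Cited-species set, per-species disease sets and disease set."""
    rep = ds.reports
    species = set(rep["species_id"])
    diseases_by_species = rep.groupby("species_id")["disease"].agg(set).to_dict()
    return species, diseases_by_species, set(rep["disease"])


def rahman_similarity(
    ds_a: SurveyDataset,
    ds_b: SurveyDataset,
    label_a: str = "community_a",
    label_b: str = "community_b",
) -> PairSimilarity:
    """Compare two communities' cited-species repertoires.

    A species counts toward ``d`` when the disease sets it is cited for in
    the two communities intersect (at least one identical disease label).
    """
    sp_a, dis_a, diseases_a = _community_sets(ds_a)
    sp_b, dis_b, diseases_b = _community_sets(ds_b)
    common = sp_a & sp_b
    a = len(sp_a - sp_b)
    b = len(sp_b - sp_a)
    c = len(common)
    d = sum(1 for s in common if dis_a[s] & dis_b[s])
    e = len(diseases_a & diseases_b)
    rsi = rsi_from_counts(a, b, c, d)
    return PairSimilarity(
        community_a=label_a,
        community_b=label_b,
        a=a,
        b=b,
        c=c,
        d=d,
        e=e,
        rsi_percent=rsi,
        n_species_a=len(sp_a),
        n_species_b=len(sp_b),
        n_diseases_a=len(diseases_a),
        n_diseases_b=len(diseases_b),
    )


def pairwise_similarity_table(
    ds: SurveyDataset,
    partition: str = "residence",
    pools: dict[str, list[str]] | None = None,
) -> list[PairSimilarity]:
    """All pairwise community comparisons under one informant partition.

    ``pools`` maps a pooled-community label to the partition levels it
    merges (union of informants before any counting); each pool is compared
    against every level outside it.  Levels without a single citation are
    skipped with a warning.
    """
    if partition not in INFORMANT_FIELDS:
        raise ParameterError(f"unknown informant factor '{partition}'")
    by_level = ds.informants.groupby(partition)["informant_id"].agg(list).to_dict()
    levels = sorted(by_level)
    if len(levels) < 2 and not pools:
        raise ParameterError(f"partition '{partition}' has fewer than 2 levels")

    cited_informants = set(ds.reports["informant_id"])

    def has_citations(ids) -> bool:
        return bool(set(ids) & cited_informants)

    subsets: dict[str, SurveyDataset] = {}
    for level in levels:
        subsets[level] = ds.subset_by_informants(by_level[level])
    for pool_label, members in (pools or {}).items():
        unknown = [m for m in members if m not in by_level]
        if unknown:
            raise ParameterError(f"pool '{pool_label}' references unknown levels {unknown}")
        ids = [i for m in members for i in by_level[m]]
        subsets[pool_label] = ds.subset_by_informants(ids)

    results: list[PairSimilarity] = []
    for la, lb in combinations(levels, 2):
        if not (has_citations(by_level[la]) and has_citations(by_level[lb])):
            logger.warning("skipping pair (%s, %s): a community has no citations", la, lb)
            continue
        results.append(rahman_similarity(subsets[la], subsets[lb], la, lb))
    for pool_label, members in (pools or {}).items():
        member_set = set(members)
        for level in levels:
            if level in member_set:
                continue
            pool_ids = [i for m in members for i in by_level[m]]
            if not (has_citations(by_level[level]) and has_citations(pool_ids)):
                logger.warning(
                    "skipping pair (%s, %s): a community has no citations", level, pool_label
                )
                continue
            results.append(rahman_similarity(subsets[level], subsets[pool_label], level, pool_label))
    return results


def similarity_frame(pairs: list[PairSimilarity]) -> pd.DataFrame:
    """Tabular view of a list of pairwise comparisons."""
    return pd.DataFrame([vars(p) for p in pairs])
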