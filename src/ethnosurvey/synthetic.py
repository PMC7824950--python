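"""Synthetic survey generator with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
roster of phytotherapists with categorical sociological attributes, a
species table with a realistic family/genus composition, and long-format
use reports whose per-informant citation counts follow a Poisson law whose
mean is a product of planted group rate multipliers.  Default parameters
target the study-area margins a field survey of this kind reports: 188
informants with the observed gender / age / education / experience /
category / marital / residence mix, 227 species in 192 genera and 79
families (Fabaceae leading), leaf 39.4% of organ mentions, decoction 41.7%
of preparations, oral 71.7% of administrations, herbs 36.4% of biological
forms, anthropized habitats 45.0%, an overall mean of 4.2 distinct species
per informant, and planted rate ratios of 0.75 (female vs male), 1.53
(Kisantu) and 1.75 (Mbanza-Ngungu urban) vs rural, 0.44 (herbalist) and
1.47 (curing healer) vs traditional health practitioner.

Every dataset the generator emits passes :func:`~ethnosurvey.survey_data.load_survey`
validation, and a fixed seed reproduces the dataset byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .survey_data import SurveyDataset, load_survey
from .vocab import INFORMANT_FIELDS

__all__ = ["SyntheticConfig", "OverlapSpec", "GroundTruth", "generate_survey", "generate_paired_communities"]

# Informant margins of the emulated study population (proportions of 188).
DEFAULT_GROUP_PROPORTIONS = {
    "gender": {"female": 80 / 188, "male": 108 / 188},
    "age_class": {"young": 8 / 188, "adult": 136 / 188, "old": 44 / 188},
    "education": {
        "illiterate": 28 / 188,
        "primary": 62 / 188,
        "secondary": 78 / 188,
        "superior": 20 / 188,
    },
    "experience_class": {"0-5": 12 / 188, "5-10": 28 / 188, ">10": 148 / 188},
    "category": {
        "herbalist": 13 / 188,
        "curing_healer": 21 / 188,
        "traditional_health_practitioner": 154 / 188,
    },
    "marital_status": {"single": 19 / 188, "married": 132 / 188, "widowed": 37 / 188},
    "residence": {
        "kisantu": 81 / 188,
        "mbanza_ngungu_urban": 39 / 188,
        "mbanza_ngungu_rural": 68 / 188,
    },
}

# Species-per-family margins of the emulated flora (sums to 227).  The
# long tail of small families is stood in for by 37 synthetic 2-species
# families so the pooled "other families" share (74 species, 67 genera)
# is preserved.
_MAJOR_FAMILY_SPECIES = {
    "fabaceae": 27, "euphorbiaceae": 13, "rubiaceae": 12, "asteraceae": 11,
    "lamiaceae": 11, "solanaceae": 10, "poaceae": 8, "apocynaceae": 7,
    "malvaceae": 7, "cucurbitaceae": 5, "anacardiaceae": 5, "moraceae": 5,
    "zingiberaceae": 5, "annonaceae": 4, "araceae": 4, "myrtaceae": 4,
    "amaryllidaceae": 3, "arecaceae": 3, "cyperaceae": 3, "dioscoreaceae": 3,
    "phyllanthaceae": 3,
}
_MAJOR_FAMILY_GENERA = {
    "fabaceae": 21, "euphorbiaceae": 12, "rubiaceae": 10, "asteraceae": 11,
    "lamiaceae": 6, "solanaceae": 7, "poaceae": 8, "apocynaceae": 6,
    "malvaceae": 7, "cucurbitaceae": 5, "anacardiaceae": 4, "moraceae": 4,
    "zingiberaceae": 4, "annonaceae": 3, "araceae": 4, "myrtaceae": 3,
    "amaryllidaceae": 1, "arecaceae": 3, "cyperaceae": 2, "dioscoreaceae": 1,
    "phyllanthaceae": 3,
}


def _default_family_species_counts() -> dict[str, int]:
    counts = dict(_MAJOR_FAMILY_SPECIES)
    for i in range(1, 38):
        counts[f"family{i:02d}"] = 2
    return counts


def _default_family_genus_counts() -> dict[str, int]:
    counts = dict(_MAJOR_FAMILY_GENERA)
    # 67 genera across the 37 small families: 30 families of 2, 7 of 1.
    for i in range(1, 38):
        counts[f"family{i:02d}"] = 2 if i <= 30 else 1
    return counts


DEFAULT_ATTRIBUTE_PROBABILITIES = {
    "organ": {
        "leaf": 0.394, "root": 0.22, "bark": 0.14, "fruit": 0.09,
        "seed": 0.06, "whole_plant": 0.06, "other": 0.036,
    },
    "preparation": {
        "decoction": 0.417, "maceration": 0.24, "infusion": 0.16,
        "powder": 0.12, "other": 0.063,
    },
    "administration": {"oral": 0.717, "topical": 0.16, "bath": 0.08, "other": 0.043},
    "biological_form": {
        "herb": 0.364, "shrub": 0.24, "tree": 0.24, "liana": 0.12, "other": 0.036,
    },
    "habitat_class": {
        "anthropized": 0.45, "forest": 0.24, "savannah": 0.22,
        "aquatic": 0.04, "other": 0.05,
    },
}

DEFAULT_RATE_MULTIPLIERS = {
    "gender": {"female": 0.75, "male": 1.0},
    "residence": {"kisantu": 1.53, "mbanza_ngungu_urban": 1.75, "mbanza_ngungu_rural": 1.0},
    "category": {
        "herbalist": 0.44,
        "curing_healer": 1.47,
        "traditional_health_practitioner": 1.0,
    },
}


@dataclass(frozen=True)
class OverlapSpec:
    """Planted species-set overlap for a pair of communities."""

    n_unique_a: int
    n_unique_b: int
    n_common: int
    n_shared_indications: int  # d: common species sharing >= 1 disease


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic survey; defaults emulate the study margins."""

    n_informants: int = 188
    n_species: int = 227
    n_diseases: int = 103
    group_proportions: dict = field(default_factory=lambda: _deepcopy(DEFAULT_GROUP_PROPORTIONS))
    family_species_counts: dict = field(default_factory=_default_family_species_counts)
    family_genus_counts: dict = field(default_factory=_default_family_genus_counts)
    attribute_probabilities: dict = field(
        default_factory=lambda: _deepcopy(DEFAULT_ATTRIBUTE_PROBABILITIES)
    )
    #: Mean citations per informant, unconditionally on group membership.
    target_mean_citations: float = 4.2
    #: Baseline Poisson rate (reference levels); resolved from the target
    #: mean and the planted multipliers when left as None.
    base_citation_rate: float | None = None
    rate_multipliers: dict = field(default_factory=lambda: _deepcopy(DEFAULT_RATE_MULTIPLIERS))
    #: Power-law exponent of species citation weights (weight ~ rank^-q);
    #: 0.55 yields a long-tailed use-value profile with a top share of ~3%.
    species_weight_exponent: float = 0.55
    #: Zipf exponent of disease popularity.
    disease_weight_exponent: float = 1.1
    #: Negative-binomial dispersion knob for robustness tests; None = Poisson.
    nb_dispersion: float | None = None
    #: Probability that a species is part of a residence community's
    #: repertoire (communities overlap but are not identical).
    community_species_prob: float = 0.8
    community_overlap: OverlapSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for factor, probs in self.group_proportions.items():
            if factor not in INFORMANT_FIELDS:
                raise ConfigError(f"unknown informant factor '{factor}'")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"group_proportions[{factor}] sums to {total}, not 1")
        for attr, probs in self.attribute_probabilities.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"attribute_probabilities[{attr}] sums to {total}, not 1")
        for factor, mults in self.rate_multipliers.items():
            if any(m <= 0 for m in mults.values()):
                raise ConfigError(f"rate_multipliers[{factor}] must be positive")
        if self.target_mean_citations <= 0:
            raise ConfigError("target_mean_citations must be positive")
        if not (0 < self.community_species_prob <= 1):
            raise ConfigError("community_species_prob must be in (0, 1]")
        if self.community_overlap is not None:
            ov = self.community_overlap
            if not isinstance(ov, OverlapSpec):
                ov = OverlapSpec(*ov)
                self.community_overlap = ov
            if min(ov.n_unique_a, ov.n_unique_b, ov.n_common, ov.n_shared_indications) < 0:
                raise ConfigError("overlap counts must be non-negative")
            if ov.n_shared_indications > ov.n_common:
                raise ConfigError(
                    f"d={ov.n_shared_indications} cannot exceed c={ov.n_common}"
                )
            if ov.n_unique_a + ov.n_unique_b + ov.n_common > self.n_species:
                raise ConfigError("planted species counts exceed n_species")

    def mixture_factor(self) -> float:
        """Expected multiplier product over the informant population."""
        factor = 1.0
        for f, mults in self.rate_multipliers.items():
            probs = self.group_proportions[f]
            factor *= sum(p * mults.get(level, 1.0) for level, p in probs.items())
        return factor

    def resolved_base_rate(self) -> float:
        if self.base_citation_rate is not None:
            return self.base_citation_rate
        return self.target_mean_citations / self.mixture_factor()

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "community_overlap" in raw and raw["community_overlap"] is not None:
            raw["community_overlap"] = OverlapSpec(**raw["community_overlap"])
        return cls(**raw)


def _deepcopy(d: dict) -> dict:
    return {k: dict(v) if isinstance(v, dict) else v for k, v in d.items()}


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests downstream."""

    planted_rate_ratios: dict
    planted_attribute_shares: dict
    planted_group_proportions: dict
    expected_mean_citations: float
    planted_pair_counts: dict | None = None


def _apportion(weights: dict[str, int], total: int) -> dict[str, int]:
    """Largest-remainder apportionment of `total` across keys by weight."""
    wsum = sum(weights.values())
    quotas = {k: total * w / wsum for k, w in weights.items()}
    counts = {k: int(q) for k, q in quotas.items()}
    short = total - sum(counts.values())
    by_rem = sorted(weights, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def _species_table(cfg: SyntheticConfig, rng: np.random.Generator, n_species: int) -> pd.DataFrame:
    counts = (
        dict(cfg.family_species_counts)
        if n_species == sum(cfg.family_species_counts.values())
        else _apportion(cfg.family_species_counts, n_species)
    )
    rows = []
    sp = 0
    for family in counts:
        n_sp = counts[family]
        if n_sp == 0:
            continue
        n_gen = min(max(1, cfg.family_genus_counts.get(family, 1)), n_sp)
        genera = [f"genus_{family}_{g + 1:02d}" for g in range(n_gen)]
        for j in range(n_sp):
            sp += 1
            genus = genera[j % n_gen]
            rows.append(
                {
                    "species_id": f"sp{sp:04d}",
                    "scientific_name": f"{genus.capitalize()} medicinalis{sp:04d} Auct.",
                    "family": family,
                    "genus": genus,
                }
            )
    table = pd.DataFrame(rows)
    for attr in ("biological_form", "habitat_class"):
        probs = cfg.attribute_probabilities[attr]
        levels = list(probs)
        table[attr] = rng.choice(levels, size=len(table), p=list(probs.values()))
    return table


def _informant_table(cfg: SyntheticConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    table = pd.DataFrame({"informant_id": [f"inf{i:05d}" for i in range(1, n + 1)]})
    for factor in INFORMANT_FIELDS:
        probs = cfg.group_proportions[factor]
        levels = list(probs)
        table[factor] = rng.choice(levels, size=n, p=list(probs.values()))
    return table


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** -exponent
    return w / w.sum()


def _citation_counts(cfg: SyntheticConfig, rng: np.random.Generator, informants: pd.DataFrame) -> np.ndarray:
    base = cfg.resolved_base_rate()
    rates = np.full(len(informants), base)
    for factor, mults in cfg.rate_multipliers.items():
        rates *= informants[factor].map(lambda lv: mults.get(lv, 1.0)).to_numpy()
    if cfg.nb_dispersion is None:
        return rng.poisson(rates)
    # Gamma-Poisson mixture: mean preserved, variance mu + mu^2/k.
    k = cfg.nb_dispersion
    return rng.poisson(rng.gamma(k, rates / k))


def _sample_report_attributes(cfg: SyntheticConfig, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    out = {}
    for attr in ("organ", "preparation", "administration"):
        probs = cfg.attribute_probabilities[attr]
        out[attr] = rng.choice(list(probs), size=n, p=list(probs.values()))
    return out


def generate_survey(cfg: SyntheticConfig) -> tuple[SurveyDataset, GroundTruth]:
    """Draw one survey from the configured population.

    Each informant's number of cited species is Poisson with mean
    ``base_rate x product(multipliers)``; the species are drawn without
    replacement with long-tailed weights, and each cited species carries one
    disease from that species' repertoire, so every (informant, species,
    disease) triple is distinct by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    informants = _informant_table(cfg, rng, cfg.n_informants)
    species = _species_table(cfg, rng, cfg.n_species)
    n_sp = len(species)

    # Long-tailed citation weights over a random species permutation.
    perm = rng.permutation(n_sp)
    weights = np.empty(n_sp)
    weights[perm] = _zipf_weights(n_sp, cfg.species_weight_exponent)

    # Disease popularity (long-tailed: a few diseases dominate the
    # pharmacopeia) and community-specific repertoires.  Each residence
    # community draws on an overlapping subset of the species pool and
    # assigns each species its own small indication set, drawn
    # independently from the disease pool — so two communities agree on an
    # indication mostly through the popular diseases, keeping
    # cross-community similarity low as in real paired surveys.
    diseases = [f"disease{d:03d}" for d in range(1, cfg.n_diseases + 1)]
    dweights = _zipf_weights(cfg.n_diseases, cfg.disease_weight_exponent)
    communities = sorted(informants["residence"].unique())
    avail: dict[str, np.ndarray] = {}
    comm_repertoire: dict[str, list[np.ndarray]] = {}
    for comm in communities:
        mask = rng.random(n_sp) < cfg.community_species_prob
        if not mask.any():
            mask[rng.integers(n_sp)] = True
        avail[comm] = mask
        rep: list[np.ndarray] = []
        for _ in range(n_sp):
            n_d = 1 + min(int(rng.poisson(0.8)), 4)
            rep.append(
                rng.choice(cfg.n_diseases, size=min(n_d, cfg.n_diseases), replace=False, p=dweights)
            )
        comm_repertoire[comm] = rep

    counts = _citation_counts(cfg, rng, informants)

    # Weighted sampling without replacement per informant (Gumbel top-k),
    # restricted to the informant's community repertoire.
    gumbel = rng.gumbel(size=(len(informants), n_sp))
    keys = np.log(weights)[None, :] + gumbel
    residences = informants["residence"].to_numpy()
    for comm in communities:
        rows = residences == comm
        keys[np.ix_(rows, ~avail[comm])] = -np.inf
    order = np.argsort(-keys, axis=1)

    inf_col, sp_col, comm_col = [], [], []
    for i, k in enumerate(counts):
        k = int(min(k, avail[residences[i]].sum()))
        if k == 0:
            continue
        inf_col.extend([informants["informant_id"].iat[i]] * k)
        sp_col.extend(order[i, :k])
        comm_col.extend([residences[i]] * k)
    sp_col = np.asarray(sp_col, dtype=int)
    comm_col = np.asarray(comm_col, dtype=object)

    # One disease per citation, drawn from the species' repertoire as
    # retained by the informant's community.
    disease_col = np.empty(len(sp_col), dtype=object)
    for comm in communities:
        in_comm = comm_col == comm
        for s in np.unique(sp_col[in_comm]):
            mask = in_comm & (sp_col == s)
            rep = comm_repertoire[comm][s]
            w = dweights[rep] / dweights[rep].sum()
            picks = rng.choice(rep, size=int(mask.sum()), p=w)
            disease_col[mask] = [diseases[p] for p in picks]

    attrs = _sample_report_attributes(cfg, rng, len(sp_col))
    reports = pd.DataFrame(
        {
            "informant_id": inf_col,
            "species_id": species["species_id"].to_numpy()[sp_col],
            "disease": disease_col,
            **attrs,
        }
    )
    ds = load_survey(reports, informants, species)
    truth = GroundTruth(
        planted_rate_ratios={f: dict(m) for f, m in cfg.rate_multipliers.items()},
        planted_attribute_shares={a: dict(p) for a, p in cfg.attribute_probabilities.items()},
        planted_group_proportions={f: dict(p) for f, p in cfg.group_proportions.items()},
        expected_mean_citations=cfg.resolved_base_rate() * cfg.mixture_factor(),
    )
    return ds, truth


def generate_paired_communities(
    cfg: SyntheticConfig,
) -> tuple[SurveyDataset, SurveyDataset, GroundTruth]:
    """Two community surveys realising an exact planted species overlap.

    The planted (a, b, c, d) of ``cfg.community_overlap`` are realised
    exactly: every planted species receives at least one citation in its
    community, each of the d designated common species is cited for one
    identical disease on both sides, and the per-species disease pools of
    the two sides are otherwise disjoint, so no extra citation can create an
    accidental shared indication.
    """
    if cfg.community_overlap is None:
        raise ConfigError("community_overlap must be specified")
    ov = cfg.community_overlap
    a, b, c, d = ov.n_unique_a, ov.n_unique_b, ov.n_common, ov.n_shared_indications
    if a + b + c == 0:
        raise ConfigError("planted overlap has no species at all")
    rng = np.random.default_rng(cfg.seed)

    n_a = cfg.n_informants // 2
    n_b = cfg.n_informants - n_a
    inf_a = _informant_table(cfg, rng, max(n_a, 1))
    inf_b = _informant_table(cfg, rng, max(n_b, 1))
    inf_b["informant_id"] = [f"inf{n_a + i:05d}b" for i in range(1, len(inf_b) + 1)]
    inf_a["residence"] = "community_a"
    inf_b["residence"] = "community_b"

    species = _species_table(cfg, rng, max(cfg.n_species, a + b + c))
    ids = species["species_id"].to_numpy()
    perm = rng.permutation(len(ids))
    common = list(ids[perm[:c]])
    unique_a = list(ids[perm[c : c + a]])
    unique_b = list(ids[perm[c + a : c + a + b]])
    shared = common[:d]  # the d species planted with one identical indication

    # Disjoint side-specific disease pools plus one shared disease per
    # planted d-species: intersections are exactly where planted.
    pool_a = [f"disease_a_{i:03d}" for i in range(1, 31)]
    pool_b = [f"disease_b_{i:03d}" for i in range(1, 31)]
    shared_diseases = {s: f"shared_disease_{i:03d}" for i, s in enumerate(shared, 1)}

    def build_repertoire(side_species, pool, side: str) -> dict[str, list[str]]:
        rep = {}
        for s in side_species:
            extras = [pool[j] for j in rng.choice(len(pool), size=int(rng.integers(1, 4)), replace=False)]
            if s in shared_diseases:
                rep[s] = [shared_diseases[s]] + extras
            else:
                rep[s] = extras
        return rep

    rep_a = build_repertoire(unique_a + common, pool_a, "a")
    rep_b = build_repertoire(unique_b + common, pool_b, "b")

    def build_reports(rep: dict[str, list[str]], informants: pd.DataFrame) -> pd.DataFrame:
        inf_ids = informants["informant_id"].to_numpy()
        rows: list[tuple[str, str, str]] = []
        # Forced citations: one per planted species; the shared indication
        # for each d-species.
        for s, dis_list in rep.items():
            who = inf_ids[rng.integers(len(inf_ids))]
            rows.append((who, s, dis_list[0]))
        # Poisson extras from the side's repertoire.
        pairs = [(s, dis) for s, dis_list in rep.items() for dis in dis_list]
        k_extra = rng.poisson(3.0, size=len(inf_ids))
        for i, k in enumerate(k_extra):
            if k == 0 or not pairs:
                continue
            picks = rng.choice(len(pairs), size=min(int(k), len(pairs)), replace=False)
            for p in picks:
                rows.append((inf_ids[i], pairs[p][0], pairs[p][1]))
        df = pd.DataFrame(rows, columns=["informant_id", "species_id", "disease"])
        return df.drop_duplicates()

    reports_a = build_reports(rep_a, inf_a)
    reports_b = build_reports(rep_b, inf_b)
    for df in (reports_a, reports_b):
        for attr, vals in _sample_report_attributes(cfg, rng, len(df)).items():
            df[attr] = vals

    ds_a = load_survey(reports_a, inf_a, species)
    ds_b = load_survey(reports_b, inf_b, species)
    e_planted = len(shared_diseases)
    truth = GroundTruth(
        planted_rate_ratios={f: dict(m) for f, m in cfg.rate_multipliers.items()},
        planted_attribute_shares={k: dict(v) for k, v in cfg.attribute_probabilities.items()},
        planted_group_proportions={f: dict(p) for f, p in cfg.group_proportions.items()},
        expected_mean_citations=float("nan"),
        planted_pair_counts={("community_a", "community_b"): (a, b, c, d, e_planted)},
    )
    return ds_a, ds_b, truth
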