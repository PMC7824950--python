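"""End-to-end reporting pipeline: validate, summarise, index, compare, model.

``run_pipeline`` ties the stages together and emits a reproducible report
bundle: every module's CSV output plus a single ``summary.txt`` reproducing
the shapes of the study's descriptive tables (informant profiles, taxonomic
diversity, attribute shares, disease consensus with selected species,
pairwise community similarity, rate models) and the top-of-ranking lists by
use value and informant agreement.  Outputs are stamped with a config hash
and seed in ``run_manifest.json``; two runs with the same config and seed
produce identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import group_stats, indices, similarity, survey_data
from .errors import SurveyError
from .vocab import INFORMANT_FIELDS, REPORT_ATTRIBUTES, SPECIES_FIELDS

logger = logging.getLogger("ethnosurvey")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    reports: str = "reports.csv"
    informants: str = "informants.csv"
    species: str = "species.csv"
    out_dir: str = "ethnosurvey_out"
    seed: int = 0
    partition: str = "residence"
    pools: dict = field(default_factory=dict)
    factors: tuple = ("gender", "residence", "category")
    reference_levels: dict = field(default_factory=dict)
    min_family_species: int = 3
    vocabularies: dict = field(default_factory=dict)
    top_n: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "factors" in raw:
            raw["factors"] = tuple(raw["factors"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # analysis-relevant options only
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths.

    All results are computed before anything is written, so a stage failure
    leaves no partial outputs behind.
    """
    ds = survey_data.load_survey(
        cfg.reports, cfg.informants, cfg.species, vocabularies=cfg.vocabularies or None
    )

    profiles = []
    for factor in INFORMANT_FIELDS:
        prof = survey_data.informant_profile_summary(ds, factor)
        prof.insert(0, "factor", factor)
        profiles.append(prof)
    profile_table = pd.concat(profiles, ignore_index=True)

    taxonomy = survey_data.taxonomic_summary(ds, min_species=cfg.min_family_species)

    shares = []
    for attr in REPORT_ATTRIBUTES + SPECIES_FIELDS:
        tab = survey_data.categorical_share(ds, attr)
        tab.insert(0, "attribute", attr)
        shares.append(tab)
    share_table = pd.concat(shares, ignore_index=True)

    species_idx, disease_cons, potential = indices.compute_all_indices(ds)
    rank_uv = indices.rank_species(species_idx, by="uv", top_n=cfg.top_n)
    rank_iar = indices.rank_species(species_idx, by="iar", top_n=cfg.top_n)

    try:
        pairs = similarity.pairwise_similarity_table(ds, cfg.partition, cfg.pools or None)
        sim_table = similarity.similarity_frame(pairs)
    except SurveyError as exc:
        logger.warning("similarity stage skipped: %s", exc)
        sim_table = pd.DataFrame()

    counts = group_stats.knowledge_counts(ds)
    rank_rows = []
    for factor in cfg.factors:
        for response in group_stats.RESPONSES:
            try:
                stat, p, method = group_stats.rank_test(counts, ds, factor, response)
            except (SurveyError, ValueError) as exc:
                logger.warning("rank test %s/%s skipped: %s", factor, response, exc)
                continue
            rank_rows.append(
                {"factor": factor, "response": response, "method": method,
                 "statistic": stat, "p_value": p}
            )
    rank_table = pd.DataFrame(rank_rows)

    models = {}
    for response in group_stats.RESPONSES:
        try:
            models[response] = group_stats.poisson_rate_model(
                counts, ds, response, tuple(cfg.factors), cfg.reference_levels or None
            )
        except SurveyError as exc:
            logger.warning("rate model for %s skipped: %s", response, exc)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        paths[name] = path

    emit("informant_profile.csv", profile_table)
    emit("taxonomic_summary.csv", taxonomy)
    emit("categorical_shares.csv", share_table)
    emit("species_indices.csv", species_idx)
    emit("disease_consensus.csv", disease_cons)
    emit("therapeutic_potential.csv", potential)
    emit("similarity.csv", sim_table)
    emit("group_summary.csv", counts)
    emit("rank_tests.csv", rank_table)
    for response, model in models.items():
        emit(f"rate_model_{response}.csv", model.terms)

    lines = [
        f"ethnosurvey report (config {cfg.config_hash()}, seed {cfg.seed})",
        f"informants: {ds.n_informants}  species: {ds.n_species}  reports: {ds.n_reports}",
        "",
        "== Informant profiles ==",
        profile_table.to_string(index=False),
        "",
        "== Taxonomic diversity ==",
        taxonomy.to_string(index=False),
        "",
        "== Attribute shares ==",
        share_table.to_string(index=False),
        "",
        f"== Top {cfg.top_n} species by use value ==",
        rank_uv.to_string(index=False),
        "",
        f"== Top {cfg.top_n} species by informant agreement ==",
        rank_iar.to_string(index=False),
        "",
        "== Disease consensus ==",
        disease_cons.to_string(index=False),
        "",
        "== Species with therapeutic potential ==",
        potential.to_string(index=False),
        "",
        "== Community similarity ==",
        sim_table.to_string(index=False) if len(sim_table) else "(not computed)",
        "",
        "== Rank tests ==",
        rank_table.to_string(index=False) if len(rank_table) else "(not computed)",
    ]
    for response, model in models.items():
        lines += [
            "",
            f"== Poisson rate model: {response} (Pearson dispersion "
            f"{model.pearson_dispersion:.2f}) ==",
            model.terms.to_string(index=False),
        ]
    summary_path = out / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    paths["summary.txt"] = summary_path

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_informants": ds.n_informants,
        "n_species": ds.n_species,
        "n_reports": ds.n_reports,
        "outputs": sorted(paths),
    }
    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["run_manifest.json"] = manifest_path
    return paths
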