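"""End-to-end pipeline orchestration with a structured config.

Stages: ``simulate`` (synthetic ontologies + corpus + reference),
``mine`` (propagation -> counts -> NPMI -> filters -> Monte Carlo null ->
p -> q -> significance flags), ``compare`` (novelty/laconic subsets,
reclassification AUC, facet composition).  Every stage is deterministic
given (config, seed) and writes plain-text TSV/JSON artifacts plus a run
manifest recording the config hash, seed and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import evaluation, mining, reference, significance, synthetic, transactions
from .mining import MiningConfig
from .ontology import OntologyGraph, load_ontology
from .significance import NullModelConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_simulate", "run_mine", "run_compare", "run_all"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    seed: int
    out_dir: Path
    ontology_disease: Optional[dict[str, Any]] = None
    ontology_phenotype: Optional[dict[str, Any]] = None
    corpus: Optional[dict[str, Any]] = None
    mining: MiningConfig = field(default_factory=MiningConfig)
    null_model: NullModelConfig = field(default_factory=NullModelConfig)
    reference_sources: dict[str, str] = field(default_factory=dict)
    disease_link: Optional[str] = None
    facets_phenotype: Optional[str] = None
    facets_disease: Optional[str] = None
    ic_min: float = 0.6
    n_boot: int = 2000
    simulate: dict[str, Any] = field(default_factory=dict)
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict[str, Any] | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if overrides:
            for key, value in overrides.items():
                if value is not None:
                    _set_dotted(raw, key, value)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        if "seed" not in raw:
            raise ConfigError("config must set a seed")
        if "out_dir" not in raw:
            raise ConfigError("config must set out_dir")
        mining_raw = dict(raw.get("mining", {}))
        blocklist_path = mining_raw.pop("blocklist_path", None)
        if blocklist_path:
            with open(blocklist_path) as fh:
                mining_raw["blocklist"] = frozenset(
                    line.strip() for line in fh if line.strip() and not line.startswith("#")
                )
        null_raw = dict(raw.get("null_model", {}))
        null_raw.setdefault("seed", int(raw["seed"]))
        ref_raw = raw.get("reference", {})
        try:
            cfg = cls(
                seed=int(raw["seed"]),
                out_dir=Path(raw["out_dir"]),
                ontology_disease=raw.get("ontology_disease"),
                ontology_phenotype=raw.get("ontology_phenotype"),
                corpus=raw.get("corpus"),
                mining=MiningConfig(**mining_raw),
                null_model=NullModelConfig(**null_raw),
                reference_sources=dict(ref_raw.get("sources", {})),
                disease_link=ref_raw.get("disease_link"),
                facets_phenotype=raw.get("evaluation", {}).get("facets_phenotype"),
                facets_disease=raw.get("evaluation", {}).get("facets_disease"),
                ic_min=float(raw.get("evaluation", {}).get("ic_min", 0.6)),
                n_boot=int(raw.get("evaluation", {}).get("n_boot", 2000)),
                simulate=dict(raw.get("simulate", {})),
                raw=raw,
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis settings (output location excluded)."""
        raw = {k: v for k, v in self.raw.items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _set_dotted(d: dict[str, Any], key: str, value: Any) -> None:
    parts = key.split(".")
    for p in parts[:-1]:
        d = d.setdefault(p, {})
    d[parts[-1]] = value


def _load_ontology_spec(spec: dict[str, Any], stage: str) -> OntologyGraph:
    if not spec or "path" not in spec:
        raise ConfigError(f"{stage}: ontology path missing from config")
    return load_ontology(spec["path"], spec.get("format", "obo"), spec.get("labels"))


def _read_facets(path: str) -> list[str]:
    with open(path) as fh:
        return [line.split("\t")[0].strip() for line in fh if line.strip() and not line.startswith("#")]


def _write_manifest(cfg: PipelineConfig, stage: str, counts: dict[str, Any]) -> None:
    path = cfg.out_dir / "manifest.json"
    manifest: dict[str, Any] = {}
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest.setdefault("config_hash", cfg.config_hash())
    manifest.setdefault("seed", cfg.seed)
    manifest.setdefault("stages", {})[stage] = counts
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------


def run_simulate(cfg: PipelineConfig) -> dict[str, Any]:
    """Generate synthetic ontologies, corpus, truth and reference files."""
    sim = cfg.simulate
    if not sim:
        raise ConfigError("simulate: no generator settings in config")
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)

    gen_fields = {
        k: v
        for k, v in sim.items()
        if k
        in {
            "n_docs",
            "n_diseases",
            "n_phenotypes",
            "mean_diseases_per_doc",
            "mean_phenotypes_per_doc",
            "marginal_exponent",
            "max_marginal",
            "confounder_marginal",
        }
    }
    try:
        gcfg = synthetic.GeneratorConfig(seed=cfg.seed, **gen_fields)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"simulate: {exc}") from exc

    depth = int(sim.get("ontology_depth", 3))
    branching = int(sim.get("branching", 3))
    g_dis = synthetic.generate_ontology(depth, branching, seed=cfg.seed + 1, prefix="SD")
    g_phe = synthetic.generate_ontology(depth, branching, seed=cfg.seed + 2, prefix="SP")

    n_planted = int(sim.get("n_planted", 0))
    if n_planted:
        gcfg.planted_pairs = synthetic.auto_plant(
            g_dis, g_phe, gcfg, n_planted, float(sim.get("lift", 5.0)),
            min_marginal=float(sim.get("planted_min_marginal", 0.005)),
        )
    if int(sim.get("n_confounders", 0)):
        dis_leaves = synthetic._leaves(g_dis)
        phe_leaves = synthetic._leaves(g_phe)
        planted_cls = {d for d, _, _ in gcfg.planted_pairs} | {p for _, p, _ in gcfg.planted_pairs}
        free_d = [d for d in dis_leaves if d not in planted_cls]
        free_p = [p for p in phe_leaves if p not in planted_cls]
        k = int(sim["n_confounders"])
        gcfg.confounder_pairs = list(zip(free_d[-k:], free_p[-k:]))

    records, truth = synthetic.generate_corpus(g_dis, g_phe, gcfg)

    g_dis.to_edge_tsv(out / "ontology_disease.tsv", out / "ontology_disease_labels.tsv")
    g_phe.to_edge_tsv(out / "ontology_phenotype.tsv", out / "ontology_phenotype_labels.tsv")
    transactions.write_corpus(records, out / "corpus.tsv")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("disease_id\tphenotype_id\tkind\tlift\n")
        for d, p in sorted(truth.planted):
            fh.write(f"{d}\t{p}\tplanted\t{truth.lifts[(d, p)]:g}\n")
        for d, p in sorted(truth.confounders):
            fh.write(f"{d}\t{p}\tconfounder\t\n")

    ref = synthetic.generate_reference(
        truth,
        g_phe,
        overlap=float(sim.get("reference_overlap", 1.0)),
        specificity_shift=sim.get("specificity_shift", "none"),
        seed=cfg.seed + 3,
    )
    with open(out / "reference.tsv", "w") as fh:
        fh.write("disease_id\tphenotype_id\n")
        for d, p in sorted(ref.associations):
            fh.write(f"{d}\t{p}\n")
    with open(out / "disease_link.tsv", "w") as fh:
        for d in sorted({d for d, _ in ref.associations} | {d for d, _, _ in gcfg.planted_pairs}):
            fh.write(f"{d}\t{d}\n")
    # facet lists: the top-level branches of each ontology
    with open(out / "facets_phenotype.tsv", "w") as fh:
        for c in sorted(g_phe.children(g_phe.roots[0])):
            fh.write(c + "\n")
    with open(out / "facets_disease.tsv", "w") as fh:
        for c in sorted(g_dis.children(g_dis.roots[0])):
            fh.write(c + "\n")

    counts = {
        "n_docs": len(records),
        "n_planted": len(truth.planted),
        "n_confounders": len(truth.confounders),
        "n_reference": len(ref.associations),
    }
    _write_manifest(cfg, "simulate", counts)
    return counts


def run_mine(cfg: PipelineConfig) -> dict[str, Any]:
    """Propagate, count, score, filter, and test associations; write tables."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    if not cfg.corpus or "path" not in cfg.corpus:
        raise ConfigError("mine: corpus path missing from config")
    g_phe = _load_ontology_spec(cfg.ontology_phenotype, "mine")
    g_dis = _load_ontology_spec(cfg.ontology_disease, "mine")

    records = transactions.load_corpus(
        cfg.corpus["path"],
        cfg.corpus.get("format", "tsv"),
        ontologies=[g_dis, g_phe],
        dedupe=bool(cfg.corpus.get("dedupe", False)),
    )
    if not records:
        raise StageError("count_cooccurrence: empty corpus")
    propagated = transactions.propagate_phenotypes(records, g_phe)
    counts = transactions.count_cooccurrence(propagated)
    scores = mining.score_all(counts, cfg.mining)
    stage_counts = {
        "n_docs": counts.n_tot,
        "n_pairs_observed": len(scores),
        "n_low_frequency": sum(1 for s in scores if s.excluded_by == "low_frequency"),
        "n_nonpositive": sum(1 for s in scores if s.excluded_by == "nonpositive"),
        "n_collinear": sum(1 for s in scores if s.excluded_by == "collinear"),
        "n_blocklist": sum(1 for s in scores if s.excluded_by == "blocklist"),
        "n_candidates": sum(1 for s in scores if s.candidate),
    }
    logger.info("mining stage counts: %s", stage_counts)
    significance.assign_significance(scores, records, g_phe, cfg.null_model)
    stage_counts["n_significant"] = sum(1 for s in scores if s.significant)
    mining.write_associations(scores, out / "associations.tsv")
    _write_manifest(cfg, "mine", stage_counts)
    return stage_counts


def run_compare(cfg: PipelineConfig) -> dict[str, Any]:
    """Novelty/laconic annotation, reclassification AUC, facet composition."""
    out = cfg.out_dir
    assoc_path = out / "associations.tsv"
    if not assoc_path.exists():
        raise StageError("compare: associations.tsv not found; run mine first")
    scores = mining.read_associations(assoc_path)
    g_phe = _load_ontology_spec(cfg.ontology_phenotype, "compare")
    g_dis = _load_ontology_spec(cfg.ontology_disease, "compare")

    if not cfg.reference_sources:
        raise ConfigError("compare: no reference sources configured")
    link = reference.load_disease_link(cfg.disease_link) if cfg.disease_link else None
    ref = reference.consolidate(cfg.reference_sources, link)

    rows = reference.write_novelty(scores, ref, g_phe, out / "novelty.tsv")
    counts: dict[str, Any] = {
        "n_candidates": len(rows),
        "n_novel": sum(1 for r in rows if r[2]),
        "n_novel_significant": sum(1 for r in rows if r[2] and r[4]),
        "n_laconic": sum(1 for r in rows if r[3]),
    }

    # reclassification AUC: significant profiles vs reference profiles
    sig = [s for s in scores if s.significant]
    mined_profiles = _profiles_from_pairs([(s.disease, s.phenotype) for s in sig])
    ref_profiles = _profiles_from_pairs(sorted(ref.associations))
    shared = sorted({p.disease for p in mined_profiles} & {p.disease for p in ref_profiles})
    auc_report: dict[str, Any]
    if len(shared) >= 2:
        result = evaluation.reclassification_auc(
            [p for p in mined_profiles if p.disease in shared],
            [p for p in ref_profiles if p.disease in shared],
            matched={d: d for d in shared},
            g=g_phe,
            n_boot=cfg.n_boot,
            seed=cfg.seed,
        )
        auc_report = {
            "auc": result.auc,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "n_diseases": result.n_diseases,
        }
        counts["auc"] = result.auc
    else:
        auc_report = {"error": "fewer than 2 matched diseases"}
    (out / "auc.json").write_text(json.dumps(auc_report, indent=2, sort_keys=True) + "\n")

    if cfg.facets_phenotype:
        facets = _read_facets(cfg.facets_phenotype)
        pairs = [(s.disease, s.phenotype) for s in sig]
        ic = evaluation.ic_from_profiles(mined_profiles + ref_profiles, g_phe)
        _write_facets(
            out / "facet_inclusion.tsv",
            evaluation.facet_inclusion(pairs, facets, g_phe, ic, ic_min=cfg.ic_min),
        )
        _write_facets(
            out / "facet_expression.tsv",
            evaluation.facet_expression(pairs, facets, g_phe),
        )
    if cfg.facets_disease:
        dis_facets = _read_facets(cfg.facets_disease)
        _write_facets(
            out / "category_proportions.tsv",
            evaluation.category_proportions(sorted({s.disease for s in sig}), dis_facets, g_dis),
        )
    _write_manifest(cfg, "compare", counts)
    return counts


def _profiles_from_pairs(pairs: list[tuple[str, str]]) -> list[evaluation.PhenotypeProfile]:
    by_disease: dict[str, set[str]] = {}
    for d, p in pairs:
        by_disease.setdefault(d, set()).add(p)
    return [
        evaluation.PhenotypeProfile(disease=d, phenotypes=frozenset(ps))
        for d, ps in sorted(by_disease.items())
    ]


def _write_facets(path: Path, comps: list[evaluation.FacetComposition]) -> None:
    with open(path, "w") as fh:
        fh.write("facet_id\tvalue\tcount\n")
        for c in comps:
            fh.write(f"{c.facet}\t{c.inclusion:.10g}\t{c.count}\n")


def run_all(cfg: PipelineConfig) -> dict[str, Any]:
    """simulate (when configured) -> mine -> compare."""
    result: dict[str, Any] = {}
    if cfg.simulate:
        result["simulate"] = run_simulate(cfg)
        out = cfg.out_dir
        cfg.ontology_disease = {"path": str(out / "ontology_disease.tsv"), "format": "edge_tsv",
                                "labels": str(out / "ontology_disease_labels.tsv")}
        cfg.ontology_phenotype = {"path": str(out / "ontology_phenotype.tsv"), "format": "edge_tsv",
                                  "labels": str(out / "ontology_phenotype_labels.tsv")}
        cfg.corpus = {"path": str(out / "corpus.tsv"), "format": "tsv"}
        cfg.reference_sources = {"synthetic_truth": str(out / "reference.tsv")}
        cfg.disease_link = str(out / "disease_link.tsv")
        cfg.facets_phenotype = str(out / "facets_phenotype.tsv")
        cfg.facets_disease = str(out / "facets_disease.tsv")
    result["mine"] = run_mine(cfg)
    result["compare"] = run_compare(cfg)
    return result
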