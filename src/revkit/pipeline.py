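"""End-to-end pipeline: simulate -> DE -> reversal -> ORA -> network -> annotate.

One configured, seeded run producing a machine-readable summary with the
counts the analysis is about: per-drug reversed genes, the union (reversed
by at least one drug), the common set (reversed by all drugs), the number of
significantly over-represented gene sets, the PPI cluster sizes, and the
permutation edge-enrichment p-value.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from revkit import annotate as _annotate
from revkit import de as _de
from revkit import enrichment as _enrichment
from revkit import network as _network
from revkit import reversal as _reversal
from revkit import synthetic as _synthetic

logger = logging.getLogger(__name__)

SUMMARY_KEYS = {"per_drug_counts", "union", "common", "ora_significant", "components", "enrichment_p", "seed"}


@dataclass
class RunConfig:
    """Thresholds and study conditions for one pipeline run.

    Defaults carry the analysis constants: disease FDR 0.1, drug FDR 0.05,
    CPM filter at 1, STRING score cutoff 0.7, ORA FDR 0.05.
    """

    q_disease: float = 0.1
    q_drug: float = 0.05
    min_cpm: float = 1.0
    filter_mode: str = "smallest_group"
    filter_threshold: float | None = None
    min_score: float = 0.7
    ora_q_cut: float = 0.05
    ora_min_size: int = 10
    ora_max_size: int = 500
    component_min_size: int = 3
    n_perm: int = 10_000
    seed: int = 0
    sim: _synthetic.SimulationParams = field(default_factory=_synthetic.SimulationParams)

    def __post_init__(self) -> None:
        for name in ("q_disease", "q_drug", "ora_q_cut"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if not (0 <= self.min_score <= 1):
            raise ValueError("min_score must lie in [0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        # one seed drives simulation and permutation
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        """Build from a flat key-value mapping; unknown keys must be
        SimulationParams fields and configure the generator."""
        mapping = dict(mapping or {})
        own = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        cfg_kwargs = {k: mapping.pop(k) for k in list(mapping) if k in own}
        sim_fields = {f.name for f in dataclasses.fields(_synthetic.SimulationParams)}
        sim_kwargs = {k: mapping.pop(k) for k in list(mapping) if k in sim_fields}
        if mapping:
            raise ValueError(f"unknown config keys: {sorted(mapping)}")
        if "drug_labels" in sim_kwargs:
            sim_kwargs["drug_labels"] = tuple(sim_kwargs["drug_labels"])
        if "n_drugs" not in sim_kwargs and "drug_labels" in sim_kwargs:
            sim_kwargs["n_drugs"] = len(sim_kwargs["drug_labels"])
        return cls(sim=_synthetic.SimulationParams(**sim_kwargs), **cfg_kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a flat YAML or JSON config file."""
        text = Path(path).read_text()
        mapping = yaml.safe_load(text) or {}
        if not isinstance(mapping, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_mapping(mapping)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["drug_labels"] = list(d["sim"]["drug_labels"])
        return d


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def run_pipeline(config: RunConfig, out_dir, force: bool = False) -> dict:
    """Execute every stage and return the summary record.

    Writes all stage outputs under ``out_dir``; refuses a non-empty output
    directory unless ``force`` is set. Any stage failure aborts with the
    stage name while preserving outputs of completed stages.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force to overwrite)")
    out.mkdir(parents=True, exist_ok=True)

    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    logger.error("stage %s: FAILED after %.1fs (%s)", name, timings[name], exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed") from exc
                logger.info("stage %s: done in %.1fs", name, timings[name])
                return False

        return _Stage()

    with stage("simulate"):
        inputs = _synthetic.write_inputs(config.sim, out / "inputs")

    with stage("disease_signature"):
        disease = _reversal.load_signature(inputs["disease"], label="disease")
        n_disease_sig = len(disease.significant(config.q_disease))
        logger.info("disease signature: %d genes, %d significant at q<=%.3g", len(disease.table), n_disease_sig, config.q_disease)

    drug_sigs: dict[str, _de.DESignature] = {}
    analyzed: dict[str, set] = {}
    with stage("drug_de"):
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        for label, (cpath, gpath) in inputs["counts"].items():
            cm = _de.read_counts(cpath, gpath)
            cm = _de.filter_low_expression(cm, config.min_cpm, config.filter_mode, config.filter_threshold)
            factors = _de.tmm_factors(cm)
            sig = _de.de_welch(cm, factors, label=label, q_threshold=config.q_drug)
            _de.write_signature(sig, de_dir / f"{label}.tsv")
            drug_sigs[label] = sig
            analyzed[label] = set(sig.table.index)
            logger.info("drug %s: %d genes analyzed, %d significant at q<=%.3g", label, len(sig.table), len(sig.significant()), config.q_drug)

    with stage("reversal"):
        per_drug = {
            label: _reversal.reversed_genes(disease, sig, config.q_disease, config.q_drug)
            for label, sig in drug_sigs.items()
        }
        result = _reversal.intersect_across_drugs(per_drug)
        _reversal.write_reversal(result, disease, drug_sigs, out / "reversal")
        logger.info("reversal: union %d, common %d", len(result.union_set), len(result.common_set))

    # measured background: genes in the disease table and every drug analysis
    universe = set(disease.table.index).intersection(*analyzed.values())

    with stage("ora"):
        collection = _enrichment.read_gmt(inputs["gmt"])
        if result.common_set:
            ora_df = _enrichment.ora(
                result.common_set,
                universe,
                collection,
                min_size=config.ora_min_size,
                max_size=config.ora_max_size,
                q_cut=config.ora_q_cut,
            )
            _enrichment.write_ora(ora_df, out / "ora_results.tsv")
            ora_significant = int(ora_df["significant"].sum())
        else:
            logger.warning("common reversed set is empty; ORA skipped")
            ora_significant = 0

    with stage("network"):
        edges = _network.read_edges(inputs["edges"])
        if result.common_set:
            graph = _network.induced_subgraph(edges, result.common_set, config.min_score)
            report = _network.components(graph, config.component_min_size)
            enr = _network.edge_enrichment_p(
                result.common_set, edges, universe, config.min_score, config.n_perm, seed=config.seed
            )
            enr.to_json(out / "enrichment.json")
            _network.write_clusters(report, out / "clusters.tsv")
            annotations = _annotate.annotate_genes(sorted(result.common_set), list(drug_sigs.values()), inputs["eqtl"])
            _annotate.write_annotations(annotations, out / "annotations.tsv")
            _network.write_graphml(graph, report, annotations, out / "network.graphml")
            component_sizes = report.sizes()
            enrichment_p = enr.pvalue
        else:
            component_sizes = []
            enrichment_p = None

    summary = {
        "per_drug_counts": result.per_drug_counts(),
        "union": len(result.union_set),
        "common": len(result.common_set),
        "ora_significant": ora_significant,
        "components": {"count": len(component_sizes), "sizes": component_sizes},
        "enrichment_p": enrichment_p,
        "seed": config.seed,
    }
    write_reports(summary, out, config=config, timings=timings, force=True)
    return summary


def write_reports(summary: dict, out_dir, config: RunConfig | None = None, timings: dict | None = None, force: bool = False) -> None:
    """Write summary.json, a plain-text report, and a config echo sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    target = out / "summary.json"
    if target.exists() and not force:
        raise FileExistsError(f"{target} already exists (use force to overwrite)")
    if set(summary) != SUMMARY_KEYS:
        raise ValueError(f"summary keys {sorted(summary)} != expected {sorted(SUMMARY_KEYS)}")
    _atomic_write_text(target, json.dumps(summary, sort_keys=True, indent=2) + "\n")
    if config is not None:
        sidecar = {"config": config.to_jsonable()}
        if timings:
            sidecar["stage_seconds"] = {k: round(v, 3) for k, v in timings.items()}
        _atomic_write_text(out / "run_config.json", json.dumps(sidecar, sort_keys=True, indent=2) + "\n")
    lines = [
        "revkit pipeline summary",
        "=======================",
        f"seed: {summary['seed']}",
        "per-drug reversed genes: " + ", ".join(f"{d}={n}" for d, n in summary["per_drug_counts"].items()),
        f"reversed by >=1 drug (union): {summary['union']}",
        f"reversed by all drugs (common): {summary['common']}",
        f"over-represented gene sets (FDR-significant): {summary['ora_significant']}",
        f"PPI clusters (connected components): {summary['components']['count']} with sizes {summary['components']['sizes']}",
        f"PPI edge-enrichment permutation p: {summary['enrichment_p']}",
    ]
    _atomic_write_text(out / "report.txt", "\n".join(lines) + "\n")
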