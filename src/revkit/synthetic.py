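"""Synthetic pipeline inputs with planted ground truth.

Emulates, at desk scale, the data a disease-drug reversal study consumes:

* a disease differential-expression summary table (a few hundred significant
  genes at FDR < 0.1 out of tens of thousands, as in a large post-mortem
  brain cohort),
* per-drug gene-by-sample RNA-seq count matrices (drug vs vehicle, 4-6
  replicates per group, negative-binomial counts),
* a GMT gene-set collection containing one set enriched in the planted
  reversed genes plus uniform decoys,
* a STRING-style protein-protein-interaction edge list with dense planted
  modules among the commonly reversed genes, and
* a flat eQTL gene list biased toward module members.

The ground truth (`SimulationTruth`) records which genes carry a disease
effect, how each drug responds per gene, and therefore which genes are truly
reversed — so every downstream stage can be scored for recovery.

All randomness flows from ``SimulationParams.seed`` through per-stage
`numpy` SeedSequence streams; identical parameters reproduce every output
byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from revkit.de import TREATED, VEHICLE, CountMatrix, DESignature, bh_adjust, write_counts, write_signature
from revkit.enrichment import GeneSetCollection, write_gmt

logger = logging.getLogger(__name__)

DEFAULT_DRUGS = ("amisulpride", "aripiprazole", "clozapine", "risperidone")

# per-stage stream keys so stages can be regenerated independently
_STREAM_TRUTH = 1
_STREAM_DISEASE = 2
_STREAM_DRUG = 100  # + drug_index
_STREAM_PPI = 3
_STREAM_SETS = 4


@dataclass
class SimulationParams:
    """Study conditions for the synthetic inputs.

    Core conditions (sample sizes, fractions, effect scales) mirror the
    emulated study design; the remaining knobs parameterize the generator
    itself and are documented in docs/methods.md.
    """

    n_genes: int = 20_000
    frac_disease_de: float = 0.05
    disease_effect_scale: float = 1.5  # mean |logFC| of disease effects, log2 units
    reversal_prob: float = 0.6  # P(drug opposes disease sign | disease gene), per drug
    concordant_prob: float = 0.1  # P(drug matches disease sign | disease gene)
    n_drugs: int = 4
    reps_per_group: int = 6
    nb_dispersion: float = 0.05
    mean_log_expression: float = 5.0  # natural-log baseline mean count
    seed: int = 0
    # generator knobs beyond the core design
    drug_effect_scale: float = 2.0  # mean |logFC| of drug effects, log2 units
    drug_effect_min: float = 0.5
    disease_effect_min: float = 0.25
    baseline_log_sd: float = 1.5  # spread of gene baseline expression
    disease_noise_sd: float = 1.0
    disease_pseudo_n: int = 100  # pseudo cohort size behind the disease p-model
    n_ppi_modules: int = 2
    ppi_module_size: int = 14
    module_edge_prob: float = 0.6
    background_edges_per_gene: float = 3.0
    n_gene_sets: int = 50
    set_size_min: int = 20
    set_size_max: int = 200
    enrichment_factor: float = 1000.0  # sampling weight of truly reversed genes in the planted set
    planted_noise_frac: float = 0.2
    n_eqtl: int = 3
    drug_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_genes < 100:
            raise ValueError("n_genes must be at least 100")
        if not (0 < self.frac_disease_de < 1):
            raise ValueError("frac_disease_de must lie in (0, 1)")
        if self.disease_effect_scale <= 0 or self.drug_effect_scale <= 0:
            raise ValueError("effect scales must be positive")
        if not (0 <= self.reversal_prob <= 1) or not (0 <= self.concordant_prob <= 1):
            raise ValueError("reversal_prob and concordant_prob must lie in [0, 1]")
        if self.reversal_prob + self.concordant_prob > 1:
            raise ValueError("reversal_prob + concordant_prob must not exceed 1")
        if self.n_drugs < 1:
            raise ValueError("n_drugs must be positive")
        if self.reps_per_group < 2:
            raise ValueError("reps_per_group must be at least 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not self.drug_labels:
            if self.n_drugs <= len(DEFAULT_DRUGS):
                self.drug_labels = DEFAULT_DRUGS[: self.n_drugs]
            else:
                self.drug_labels = tuple(f"drug{i + 1}" for i in range(self.n_drugs))
        elif len(self.drug_labels) != self.n_drugs:
            raise ValueError("drug_labels length must equal n_drugs")
        else:
            self.drug_labels = tuple(self.drug_labels)

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), *key]))


@dataclass
class SimulationTruth:
    """Planted ground truth: directions, reversal events, modules, set ids."""

    gene_ids: list[str]
    disease_direction: np.ndarray  # (n_genes,) in {-1, 0, +1}
    drug_direction: np.ndarray  # (n_genes, n_drugs) in {-1, 0, +1}
    true_reversed: np.ndarray  # (n_genes, n_drugs) bool
    enriched_set_ids: list[str] = field(default_factory=list)
    module_members: list[list[str]] = field(default_factory=list)

    def reversed_by_all(self) -> list[str]:
        mask = self.true_reversed.all(axis=1)
        return [g for g, m in zip(self.gene_ids, mask) if m]

    def reversed_by_drug(self, drug_index: int) -> set[str]:
        mask = self.true_reversed[:, drug_index]
        return {g for g, m in zip(self.gene_ids, mask) if m}

    def to_json(self, path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "disease_direction": self.disease_direction.tolist(),
            "drug_direction": self.drug_direction.tolist(),
            "true_reversed": self.true_reversed.astype(int).tolist(),
            "enriched_set_ids": self.enriched_set_ids,
            "module_members": self.module_members,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            gene_ids=payload["gene_ids"],
            disease_direction=np.asarray(payload["disease_direction"], dtype=np.int8),
            drug_direction=np.asarray(payload["drug_direction"], dtype=np.int8),
            true_reversed=np.asarray(payload["true_reversed"], dtype=bool),
            enriched_set_ids=payload["enriched_set_ids"],
            module_members=payload["module_members"],
        )


def make_truth(params: SimulationParams) -> SimulationTruth:
    """Draw disease directions and per-drug responses.

    Exactly round(n_genes * frac_disease_de) genes carry a disease effect,
    with a random +/-1 sign. Conditional on a nonzero disease direction each
    drug independently opposes it with probability ``reversal_prob``, matches
    it with probability ``concordant_prob``, and is silent otherwise; drugs
    never perturb disease-null genes in this truth model.
    """
    rng = params.rng(_STREAM_TRUTH)
    n, d = params.n_genes, params.n_drugs
    disease = np.zeros(n, dtype=np.int8)
    n_de = int(round(n * params.frac_disease_de))
    de_idx = rng.choice(n, size=n_de, replace=False)
    disease[de_idx] = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_de)

    drug = np.zeros((n, d), dtype=np.int8)
    u = rng.random((n_de, d))
    rev = u < params.reversal_prob
    conc = (~rev) & (u < params.reversal_prob + params.concordant_prob)
    signs = disease[de_idx][:, None]
    drug[de_idx] = (-signs) * rev + signs * conc

    reversed_ = (disease[:, None] != 0) & (drug == -disease[:, None])
    truth = SimulationTruth(
        gene_ids=params.gene_ids(),
        disease_direction=disease,
        drug_direction=drug,
        true_reversed=reversed_,
    )
    _plant_modules(truth, params)
    return truth


def _plant_modules(truth: SimulationTruth, params: SimulationParams) -> None:
    """Partition commonly reversed genes into dense PPI modules."""
    rng = params.rng(_STREAM_TRUTH, 7)
    common = truth.reversed_by_all()
    pool = list(rng.permutation(common))
    modules: list[list[str]] = []
    for _ in range(params.n_ppi_modules):
        take = pool[: params.ppi_module_size]
        pool = pool[params.ppi_module_size :]
        if len(take) >= 2:
            modules.append(sorted(take))
    truth.module_members = modules


def _shifted_gamma(rng: np.random.Generator, size: int, mean: float, minimum: float) -> np.ndarray:
    """|logFC| magnitudes: minimum + Gamma(shape=2) with the stated mean."""
    scale = max(mean - minimum, 1e-6) / 2.0
    return minimum + rng.gamma(shape=2.0, scale=scale, size=size)


def make_disease_table(truth: SimulationTruth, params: SimulationParams) -> DESignature:
    """Disease summary table: logFC, normal-model p-value, BH q per gene.

    logFC = direction * |effect| + noise with standard error
    disease_noise_sd / sqrt(disease_pseudo_n), the p-value the two-sided
    normal tail of logFC / SE — a minimal model of a summary table inherited
    from a large cohort, where small effects can still be highly significant.
    """
    rng = params.rng(_STREAM_DISEASE)
    n = params.n_genes
    effects = _shifted_gamma(rng, n, params.disease_effect_scale, params.disease_effect_min)
    se = params.disease_noise_sd / np.sqrt(params.disease_pseudo_n)
    logfc = truth.disease_direction * effects + rng.normal(0.0, se, size=n)
    from scipy.stats import norm

    pvalue = 2.0 * norm.sf(np.abs(logfc) / se)
    table = pd.DataFrame(
        {"logfc": logfc, "pvalue": pvalue, "qvalue": bh_adjust(pvalue)},
        index=pd.Index(truth.gene_ids, name="gene"),
    )
    return DESignature(label="disease", table=table, q_threshold=0.1, meta={"model": "normal_summary"})


def make_drug_counts(truth: SimulationTruth, params: SimulationParams, drug_index: int) -> CountMatrix:
    """Negative-binomial drug-vs-vehicle counts for one drug.

    Vehicle gene means are exp(mean_log_expression + baseline effect); the
    treated group mean is scaled by 2^(drug_direction * |effect|). Counts are
    drawn as a gamma-Poisson mixture with gene-common dispersion
    ``nb_dispersion`` (variance = mu + dispersion * mu^2).
    """
    if not (0 <= drug_index < params.n_drugs):
        raise ValueError(f"drug_index {drug_index} out of range for {params.n_drugs} drugs")
    rng = params.rng(_STREAM_DRUG + drug_index)
    n, r = params.n_genes, params.reps_per_group
    baseline = params.mean_log_expression + rng.normal(0.0, params.baseline_log_sd, size=n)
    effects = _shifted_gamma(rng, n, params.drug_effect_scale, params.drug_effect_min)
    mu_vehicle = np.exp(baseline)
    mu_treated = mu_vehicle * np.exp2(truth.drug_direction[:, drug_index] * effects)
    mu = np.concatenate([np.repeat(mu_treated[:, None], r, axis=1), np.repeat(mu_vehicle[:, None], r, axis=1)], axis=1)
    shape = 1.0 / params.nb_dispersion
    lam = rng.gamma(shape=shape, scale=mu / shape)
    counts = rng.poisson(lam)

    label = params.drug_labels[drug_index]
    samples = [f"{label}_T{i + 1}" for i in range(r)] + [f"{label}_V{i + 1}" for i in range(r)]
    groups = pd.Series([TREATED] * r + [VEHICLE] * r, index=pd.Index(samples, name="sample"), name="group")
    counts_df = pd.DataFrame(counts, index=pd.Index(truth.gene_ids, name="gene"), columns=samples)
    return CountMatrix(counts=counts_df, groups=groups)


def make_ppi_edges(truth: SimulationTruth, params: SimulationParams) -> pd.DataFrame:
    """STRING-style undirected edge list with scores in [0, 1].

    Planted-module pairs appear with probability ``module_edge_prob`` and
    high-confidence scores uniform on [0.7, 1]; background pairs are sparse
    with sub-threshold scores uniform on [0.15, 0.7). No self-loops, no
    duplicate undirected pairs.
    """
    rng = params.rng(_STREAM_PPI)
    genes = np.asarray(truth.gene_ids)
    edges: dict[tuple[str, str], float] = {}
    for module in truth.module_members:
        mem = sorted(module)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                if rng.random() < params.module_edge_prob:
                    edges[(mem[i], mem[j])] = float(rng.uniform(0.7, 1.0))
    n_background = int(round(params.background_edges_per_gene * params.n_genes))
    # oversample, then drop self-loops and duplicates
    a = rng.integers(0, params.n_genes, size=2 * n_background)
    b = rng.integers(0, params.n_genes, size=2 * n_background)
    scores = rng.uniform(0.15, 0.7, size=2 * n_background)
    kept = 0
    for i in range(a.size):
        if kept >= n_background:
            break
        if a[i] == b[i]:
            continue
        g1, g2 = genes[a[i]], genes[b[i]]
        pair = (g1, g2) if g1 < g2 else (g2, g1)
        if pair in edges:
            continue
        edges[pair] = float(scores[i])
        kept += 1
    df = pd.DataFrame(
        [(p[0], p[1], s) for p, s in edges.items()],
        columns=["protein1", "protein2", "combined_score"],
    )
    return df.sort_values(["protein1", "protein2"], ignore_index=True)


def make_gene_sets_and_eqtl(
    truth: SimulationTruth, params: SimulationParams
) -> tuple[GeneSetCollection, list[str]]:
    """Gene-set collection (one planted enriched set + decoys) and eQTL list.

    The planted set samples genes without replacement with weight
    ``enrichment_factor`` on truly commonly-reversed genes and 1 elsewhere
    (factor 1 therefore reduces the planted set to a decoy). Its size is the
    common-reversed count inflated by ``planted_noise_frac``. The eQTL list
    prefers planted PPI-module members. Records the planted id in
    ``truth.enriched_set_ids``.
    """
    rng = params.rng(_STREAM_SETS)
    genes = np.asarray(truth.gene_ids)
    common = set(truth.reversed_by_all())
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    truth.enriched_set_ids = []
    if len(common) >= 2:
        size = min(params.n_genes, len(common) + int(round(params.planted_noise_frac * len(common))))
        weights = np.where(np.isin(genes, sorted(common)), params.enrichment_factor, 1.0)
        # Gumbel-max trick: weighted sampling without replacement
        keys = np.log(weights) + rng.gumbel(size=params.n_genes)
        chosen = genes[np.argsort(-keys)[:size]]
        sets["GS_PLANTED"] = set(chosen)
        names["GS_PLANTED"] = "planted set enriched in commonly reversed genes"
        truth.enriched_set_ids = ["GS_PLANTED"]
    n_decoys = params.n_gene_sets - len(sets)
    for i in range(n_decoys):
        size = int(rng.integers(params.set_size_min, params.set_size_max + 1))
        members = genes[rng.choice(params.n_genes, size=size, replace=False)]
        set_id = f"GS_D{i + 1:03d}"
        sets[set_id] = set(members)
        names[set_id] = f"decoy set {i + 1}"
    collection = GeneSetCollection(sets=sets, names=names, source="synthetic")

    module_pool = sorted({g for mod in truth.module_members for g in mod})
    eqtl: list[str] = []
    if module_pool:
        take = min(params.n_eqtl, len(module_pool))
        eqtl = sorted(rng.choice(np.asarray(module_pool), size=take, replace=False).tolist())
    if len(eqtl) < params.n_eqtl:
        extra = rng.choice(params.n_genes, size=params.n_eqtl - len(eqtl), replace=False)
        eqtl = sorted(set(eqtl) | {genes[i] for i in extra})
    return collection, eqtl


def write_inputs(params: SimulationParams, out_dir) -> dict:
    """Generate and write every pipeline input; returns paths and the truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = make_truth(params)
    collection, eqtl = make_gene_sets_and_eqtl(truth, params)

    disease = make_disease_table(truth, params)
    write_signature(disease, out / "disease.tsv")

    count_paths = {}
    for d, label in enumerate(params.drug_labels):
        cm = make_drug_counts(truth, params, d)
        cpath, gpath = out / f"counts_{label}.tsv", out / f"groups_{label}.tsv"
        write_counts(cm, cpath, gpath)
        count_paths[label] = (cpath, gpath)

    edges = make_ppi_edges(truth, params)
    # STRING exports integer scores on a 0-1000 scale
    edges_out = edges.assign(combined_score=(edges["combined_score"] * 1000).round().astype(int))
    edges_out.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)

    write_gmt(collection, out / "gene_sets.gmt")
    (out / "eqtl_genes.txt").write_text("".join(f"{g}\n" for g in eqtl))
    truth.to_json(out / "truth.json")
    logger.info(
        "simulated %d genes, %d drugs, %d PPI edges, %d gene sets (%d truly reversed by all drugs)",
        params.n_genes, params.n_drugs, len(edges), len(collection.sets), len(truth.reversed_by_all()),
    )
    return {
        "truth": truth,
        "disease": out / "disease.tsv",
        "counts": count_paths,
        "edges": out / "ppi_edges.tsv",
        "gmt": out / "gene_sets.gmt",
        "eqtl": out / "eqtl_genes.txt",
        "truth_json": out / "truth.json",
    }
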