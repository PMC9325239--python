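"""Count-matrix differential expression.

Implements the normalization and testing chain applied to each drug-vs-vehicle
RNA-seq count matrix: counts-per-million (CPM), low-expression filtering, TMM
(weighted trimmed mean of M-values) normalization factors, a per-gene Welch
test on normalized log2-CPM, and Benjamini-Hochberg adjustment.

The Welch test on log2-CPM is a deliberate, documented substitute for a
negative-binomial framework: it is adequate for well-replicated designs on
moderately expressed genes and keeps the chain free of dispersion-estimation
machinery. The interface (`de_welch`) is the swap point if a different
per-gene test is ever needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TREATED = "treated"
VEHICLE = "vehicle"


@dataclass
class CountMatrix:
    """Non-negative integer gene-by-sample matrix with group labels.

    ``counts`` is genes x samples (index = gene ids, columns = sample ids);
    ``groups`` maps each sample id to ``"treated"`` or ``"vehicle"``.
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("duplicate gene ids in count matrix")
        if not self.counts.columns.is_unique:
            raise ValueError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative entries")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group assignment: {sorted(missing)}")
        self.groups = self.groups.loc[self.counts.columns]
        labels = set(self.groups.unique())
        if not labels <= {TREATED, VEHICLE}:
            raise ValueError(f"unknown group labels: {sorted(labels - {TREATED, VEHICLE})}")
        if len(labels) < 2:
            raise ValueError("both treated and vehicle groups must be non-empty")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def group_samples(self, label: str) -> list[str]:
        return list(self.groups.index[self.groups == label])


@dataclass
class DESignature:
    """Per-gene differential-expression records.

    ``table`` is indexed by gene id with columns ``logfc`` (log2 fold change),
    ``pvalue`` and ``qvalue`` (BH-adjusted). ``q_threshold`` records the FDR
    cut used downstream of this signature.
    """

    label: str
    table: pd.DataFrame
    q_threshold: float = 0.05
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValueError(f"duplicate gene ids in signature '{self.label}'")
        for col in ("logfc", "pvalue", "qvalue"):
            if col not in self.table.columns:
                raise ValueError(f"signature '{self.label}' missing column '{col}'")

    def significant(self, q: float | None = None) -> set[str]:
        q = self.q_threshold if q is None else q
        return set(self.table.index[self.table["qvalue"] <= q])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def cpm(counts: CountMatrix | pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: count * 1e6 / (library size * normalization factor)."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = mat.sum(axis=0).astype(float)
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero)}")
    if factors is not None:
        factors = pd.Series(factors, index=mat.columns).astype(float)
        if (factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        lib = lib * factors
    return mat / lib * 1e6


def filter_low_expression(
    cm: CountMatrix,
    min_cpm: float = 1.0,
    mode: str = "smallest_group",
    threshold: float | None = None,
) -> CountMatrix:
    """Drop lowly expressed genes; gene order is preserved.

    mode="fraction": keep a gene iff CPM > min_cpm in strictly more than
    ``threshold`` of the samples (threshold in (0, 1]).
    mode="smallest_group": keep a gene iff CPM >= min_cpm in at least n
    samples, where n is the size of the smallest group.
    """
    x = cpm(cm)
    if mode == "fraction":
        if threshold is None or not (0 < threshold <= 1):
            raise ValueError("fraction mode requires threshold in (0, 1]")
        keep = (x > min_cpm).sum(axis=1) > threshold * x.shape[1]
    elif mode == "smallest_group":
        n = int(cm.groups.value_counts().min())
        keep = (x >= min_cpm).sum(axis=1) >= n
    else:
        raise ValueError(f"unknown filter mode: {mode!r}")
    dropped = int((~keep).sum())
    logger.info("filter_low_expression: kept %d of %d genes (dropped %d)", int(keep.sum()), len(keep), dropped)
    if keep.sum() == 0:
        logger.warning("filter_low_expression removed every gene")
    return CountMatrix(counts=cm.counts.loc[keep], groups=cm.groups.copy())


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_trim: float,
    sample_name: str,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    shared = (obs > 0) & (ref > 0)
    if not shared.any():
        raise ValueError(f"sample {sample_name!r} shares no expressed gene with the reference")
    o = obs[shared] / lib_obs
    r = ref[shared] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # inverse asymptotic variance of M under binomial sampling
    w = (lib_obs - obs[shared]) / (lib_obs * obs[shared]) + (lib_ref - ref[shared]) / (lib_ref * ref[shared])
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    denom = np.sum(1.0 / w[keep])
    f = np.sum(m[keep] / w[keep]) / denom
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(
    cm: CountMatrix,
    ref_sample: str | None = None,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """TMM normalization factors, rescaled to geometric mean 1.

    For each sample against the reference, per-gene log-ratios M and average
    log-abundances A are computed over genes expressed in both; the top and
    bottom ``logratio_trim`` of M and ``abs_trim`` of A are trimmed, and the
    factor is 2 to the precision-weighted mean of the surviving M values.
    The automatic reference is the sample whose upper quartile of relative
    expression is closest to the mean upper quartile.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = list(cm.sample_ids[lib == 0])
        raise ValueError(f"zero library size for sample(s): {bad}")
    if ref_sample is None:
        uq = np.quantile(counts / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if ref_sample not in cm.sample_ids:
            raise ValueError(f"unknown reference sample {ref_sample!r}")
        ref_idx = int(cm.sample_ids.get_loc(ref_sample))
    log_f = np.zeros(counts.shape[1])
    for j, name in enumerate(cm.sample_ids):
        if j == ref_idx:
            continue
        log_f[j] = _tmm_pair(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx], logratio_trim, abs_trim, name)
    factors = np.exp2(log_f)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="tmm_factor")


def log2_cpm(cm: CountMatrix, factors: pd.Series | None = None, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 CPM with a pseudocount guard against log(0)."""
    mat = cm.counts.astype(float)
    lib = mat.sum(axis=0)
    if factors is not None:
        lib = lib * pd.Series(factors, index=mat.columns).astype(float)
    return np.log2((mat + pseudocount) / lib * 1e6)


def de_welch(cm: CountMatrix, factors: pd.Series | None = None, label: str = "drug", q_threshold: float = 0.05) -> DESignature:
    """Per-gene Welch (unequal-variance) test on normalized log2-CPM.

    logfc = mean(treated) - mean(vehicle) of log2-CPM. Degenerate genes with
    zero variance in both groups get p = 1 when the difference is zero, and
    the smallest positive float (flagged in the log) otherwise.
    """
    lc = log2_cpm(cm, factors).to_numpy()
    t_cols = [cm.sample_ids.get_loc(s) for s in cm.group_samples(TREATED)]
    v_cols = [cm.sample_ids.get_loc(s) for s in cm.group_samples(VEHICLE)]
    n1, n2 = len(t_cols), len(v_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("de_welch requires at least two samples per group")
    x1, x2 = lc[:, t_cols], lc[:, v_cols]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    diff = m1 - m2
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = diff / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        pvalue = 2.0 * stats.t.sf(np.abs(tstat), df)
    degenerate = se2 == 0
    if degenerate.any():
        zero_diff = degenerate & (diff == 0)
        pvalue[zero_diff] = 1.0
        flagged = degenerate & (diff != 0)
        pvalue[flagged] = np.nextafter(0.0, 1.0)
        if flagged.any():
            logger.warning("de_welch: %d gene(s) with zero variance but nonzero difference", int(flagged.sum()))
    table = pd.DataFrame(
        {"logfc": diff, "pvalue": pvalue, "qvalue": bh_adjust(pvalue)},
        index=cm.gene_ids,
    )
    return DESignature(label=label, table=table, q_threshold=q_threshold, meta={"test": "welch_log2cpm", "n_treated": n1, "n_vehicle": n2})


def read_counts(counts_path, groups_path) -> CountMatrix:
    """Read a gene-by-sample count TSV plus a sample->group sidecar TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t")
    if not {"sample", "group"} <= set(groups_df.columns):
        raise ValueError("groups file must have columns 'sample' and 'group'")
    groups = groups_df.set_index("sample")["group"]
    return CountMatrix(counts=counts, groups=groups)


def write_counts(cm: CountMatrix, counts_path, groups_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.groups.rename("group").rename_axis("sample").to_csv(groups_path, sep="\t")


def write_signature(sig: DESignature, path) -> None:
    """Write a signature TSV with columns gene, logFC, pvalue, fdr."""
    out = sig.table.rename(columns={"logfc": "logFC", "qvalue": "fdr"})
    out.to_csv(path, sep="\t", index_label="gene")
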