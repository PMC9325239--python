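"""CPM, filtering, TMM, Welch DE and BH adjustment."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revkit.de import (
    CountMatrix,
    bh_adjust,
    cpm,
    de_welch,
    filter_low_expression,
    read_counts,
    tmm_factors,
    write_counts,
)
from revkit.synthetic import SimulationParams, make_drug_counts, make_truth


def matrix(data, groups=None):
    df = pd.DataFrame(data)
    df.index = [f"G{i+1}" for i in range(len(df))]
    if groups is None:
        half = df.shape[1] // 2
        groups = ["treated"] * half + ["vehicle"] * (df.shape[1] - half)
    return CountMatrix(counts=df, groups=pd.Series(groups, index=df.columns))


class TestCpm:
    def test_hand_formula(self):
        cm = matrix({"T1": [3, 7], "V1": [3, 7]})
        x = cpm(cm)
        assert x["T1"].tolist() == [3e6 / 10, 7e6 / 10]

    def test_single_column_split(self):
        x = cpm(pd.DataFrame({"s": [1, 1]}))
        assert x["s"].tolist() == [500000.0, 500000.0]

    def test_zero_count_zero_cpm(self):
        cm = matrix({"T1": [0, 5], "V1": [1, 4]})
        assert cpm(cm).iloc[0, 0] == 0.0

    def test_zero_library_errors_with_sample_name(self):
        with pytest.raises(ValueError, match="V1"):
            cpm(pd.DataFrame({"T1": [1, 1], "V1": [0, 0]}))

    def test_factors_scale_library(self):
        cm = matrix({"T1": [5, 5], "V1": [5, 5]})
        x = cpm(cm, factors=pd.Series({"T1": 2.0, "V1": 1.0}))
        assert x["T1"].tolist() == [250000.0, 250000.0]
        assert x["V1"].tolist() == [500000.0, 500000.0]


class TestFilterLowExpression:
    def make(self, cpms):
        # library size 1e7 per sample makes CPM = count / 10 exactly
        counts = np.asarray(cpms) * 10
        filler = 1e7 - counts.sum(axis=0)
        data = np.vstack([counts, filler]).astype(int)
        return matrix({f"S{j+1}": data[:, j] for j in range(data.shape[1])},
                      groups=["treated", "treated", "vehicle", "vehicle"])

    def test_fraction_mode_is_strict(self):
        cm = self.make(np.array([[1.5, 1.5, 0.2, 0.2]]))
        kept = filter_low_expression(cm, min_cpm=1, mode="fraction", threshold=0.5)
        assert "G1" not in kept.counts.index  # 2 of 4 samples is not > 50%

    def test_fraction_mode_keeps_three_of_four(self):
        cm = self.make(np.array([[1.5, 1.5, 1.5, 0.2]]))
        kept = filter_low_expression(cm, min_cpm=1, mode="fraction", threshold=0.5)
        assert "G1" in kept.counts.index

    def test_smallest_group_mode_counts_at_least_n(self):
        # groups of 4 and 6: n = 4; gene at >=1 CPM in exactly 4 samples kept
        cpms = np.zeros((1, 10))
        cpms[0, :4] = 2.0
        filler = 1e6 - cpms.sum(axis=0)
        data = np.vstack([cpms, filler]).astype(int)
        cm = matrix(
            {f"S{j+1}": data[:, j] for j in range(10)},
            groups=["treated"] * 4 + ["vehicle"] * 6,
        )
        kept = filter_low_expression(cm, min_cpm=1, mode="smallest_group")
        assert "G1" in kept.counts.index

    def test_idempotent(self, desk_truth, desk_params):
        cm = make_drug_counts(desk_truth, desk_params, 1)
        once = filter_low_expression(cm)
        twice = filter_low_expression(once)
        assert once.counts.equals(twice.counts)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        cm = matrix({"A": [10, 20, 30, 5], "B": [10, 20, 30, 5]})
        factors = tmm_factors(cm)
        assert factors.tolist() == [1.0, 1.0]

    def test_doubled_column_gives_unit_factors(self):
        cm = matrix({"A": [10, 20, 30, 5], "B": [20, 40, 60, 10]})
        assert tmm_factors(cm).tolist() == [1.0, 1.0]

    def test_composition_bias_hand_oracle(self):
        """One gene consuming half of sample B's reads: B's factor drops below
        A's, and both match a directly evaluated doubly-trimmed weighted mean."""
        a = np.full(20, 100)
        b = np.full(20, 100)
        b[-1] = 1900  # half of B's library
        cm = matrix({"A": a, "B": b})
        factors = tmm_factors(cm, ref_sample="A")
        assert factors["B"] < 1 < factors["A"]

        # independent direct evaluation (B against reference A)
        lib_a, lib_b = a.sum(), b.sum()
        pa, pb = a / lib_a, b / lib_b
        m = np.log2(pb / pa)
        av = 0.5 * np.log2(pb * pa)
        w = (lib_b - b) / (lib_b * b) + (lib_a - a) / (lib_a * a)
        n = len(m)
        lo_m, hi_m = int(np.floor(n * 0.3)) + 1, n - int(np.floor(n * 0.3))
        lo_a, hi_a = int(np.floor(n * 0.05)) + 1, n - int(np.floor(n * 0.05))
        from scipy.stats import rankdata

        keep = (
            (rankdata(m) >= lo_m) & (rankdata(m) <= hi_m)
            & (rankdata(av) >= lo_a) & (rankdata(av) <= hi_a)
        )
        f_b = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
        expected = np.array([1.0, f_b])
        expected = expected / np.exp(np.mean(np.log(expected)))
        assert abs(factors["A"] - expected[0]) < 1e-9
        assert abs(factors["B"] - expected[1]) < 1e-9

    def test_geometric_mean_is_one_and_permutation_equivariant(self, rng):
        counts = rng.negative_binomial(10, 0.1, size=(300, 5)) + 1
        cm = matrix({f"S{j+1}": counts[:, j] for j in range(5)},
                    groups=["treated"] * 2 + ["vehicle"] * 3)
        factors = tmm_factors(cm)
        assert abs(np.mean(np.log(factors))) < 1e-12
        perm = [3, 0, 4, 1, 2]
        cols = [f"S{j+1}" for j in perm]
        cm_p = CountMatrix(counts=cm.counts[cols], groups=cm.groups[cols])
        factors_p = tmm_factors(cm_p)
        assert np.allclose(factors_p.to_numpy(), factors[cols].to_numpy(), atol=1e-12)

    def test_matches_edger_calcnormfactors(self, rng, tmp_path):
        """Cross-check against the Bioconductor reference implementation."""
        counts = rng.negative_binomial(5, 0.05, size=(400, 6)) + 1
        cm = matrix({f"S{j+1}": counts[:, j] for j in range(6)},
                    groups=["treated"] * 3 + ["vehicle"] * 3)
        ours = tmm_factors(cm, ref_sample="S1")
        mat = tmp_path / "counts.tsv"
        cm.counts.to_csv(mat, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim("{mat}", row.names=1))
            f <- calcNormFactors(x, method="TMM", refColumn=1)
            cat(sprintf("%.12f\\n", f))
        """)
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        theirs = np.array([float(v) for v in res.stdout.split()])
        assert np.allclose(ours.to_numpy(), theirs, atol=1e-8)

    def test_disjoint_support_errors(self):
        cm = matrix({"A": [5, 0, 3, 0], "B": [0, 4, 0, 2]})
        with pytest.raises(ValueError, match="share"):
            tmm_factors(cm, ref_sample="A")


class TestWelch:
    def test_identical_groups_null(self):
        cm = matrix({"T1": [10, 50], "T2": [20, 60], "V1": [10, 50], "V2": [20, 60]})
        sig = de_welch(cm)
        assert np.allclose(sig.table["logfc"], 0.0)
        assert np.allclose(sig.table["pvalue"], 1.0)

    def test_group_swap_negates_logfc(self, desk_truth, desk_params):
        cm = make_drug_counts(desk_truth, desk_params, 0)
        swapped = CountMatrix(
            counts=cm.counts.copy(),
            groups=cm.groups.map({"treated": "vehicle", "vehicle": "treated"}),
        )
        a, b = de_welch(cm), de_welch(swapped)
        assert np.allclose(a.table["logfc"], -b.table["logfc"])
        assert np.allclose(a.table["pvalue"], b.table["pvalue"], atol=1e-12)

    def test_planted_twofold_recovered(self, rng):
        """100 genes with a true 2-fold change among 1000 nulls: median
        estimated logFC within 0.2 of 1."""
        n, reps = 1000, 5
        mu = np.full(n, 200.0)
        mu_t = mu.copy()
        mu_t[:100] *= 2.0
        phi = 0.02
        t = rng.poisson(rng.gamma(1 / phi, mu_t[:, None] * phi, (n, reps)))
        v = rng.poisson(rng.gamma(1 / phi, mu[:, None] * phi, (n, reps)))
        counts = np.hstack([t, v])
        cm = matrix({f"S{j+1}": counts[:, j] for j in range(2 * reps)},
                    groups=["treated"] * reps + ["vehicle"] * reps)
        sig = de_welch(cm, tmm_factors(cm))
        assert abs(np.median(sig.table["logfc"][:100]) - 1.0) < 0.2

    def test_type_one_error_calibration(self):
        """Null synthetic counts: fraction of genes at p<0.05 is 0.05 +/- 0.01."""
        p = SimulationParams(n_genes=10000, frac_disease_de=0.3, reversal_prob=0.0, concordant_prob=0.0, seed=3)
        t = make_truth(p)
        cm = filter_low_expression(make_drug_counts(t, p, 0))
        sig = de_welch(cm, tmm_factors(cm))
        frac = float((sig.table["pvalue"] < 0.05).mean())
        assert abs(frac - 0.05) <= 0.01

    def test_zero_variance_handling(self):
        # equal library sizes so the constant gene has zero logFC exactly
        cm = matrix({"T1": [10, 5, 35], "T2": [10, 5, 35], "V1": [10, 35, 5], "V2": [10, 35, 5]})
        sig = de_welch(cm)
        assert sig.table["pvalue"].iloc[0] == 1.0  # no difference, no variance
        assert 0 < sig.table["pvalue"].iloc[1] < 1e-300  # difference, no variance


class TestBhAdjust:
    def test_step_up_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert bh_adjust([0.3]).tolist() == [0.3]
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=60))
    def test_q_monotone_in_p_and_at_least_p(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestIo:
    def test_counts_round_trip(self, toy_counts, tmp_path):
        write_counts(toy_counts, tmp_path / "c.tsv", tmp_path / "g.tsv")
        back = read_counts(tmp_path / "c.tsv", tmp_path / "g.tsv")
        assert back.counts.equals(toy_counts.counts)
        assert (back.groups == toy_counts.groups).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            matrix({"T1": [-1, 2], "V1": [1, 2]})
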