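"""TMM factors, dispersion estimation, the exact NB test, DEG calling,
Venn accounting, and the chromosome-ordered export."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from immlncnet.data import ExpressionMatrix, ImmLncError, SampleMeta, SchemaError
from immlncnet.de import (
    call_degs,
    circos_export,
    deg_counts,
    estimate_dispersion,
    exact_nb_pvalue,
    nb_exact_test,
    overlap_sets,
    tmm_factors,
)
from immlncnet.simulate import SimulationConfig, simulate_experiment, simulate_null


def _matrix(counts: np.ndarray, n_wt: int, n_ko: int) -> ExpressionMatrix:
    samples = [SampleMeta(f"w{i}", "WT", "vehicle", 0, i + 1) for i in range(n_wt)]
    samples += [SampleMeta(f"k{i}", "KO", "vehicle", 0, i + 1) for i in range(n_ko)]
    df = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(counts.shape[0])],
        columns=[s.sample_id for s in samples],
    )
    return ExpressionMatrix(df, samples)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 2))
        f = tmm_factors(_matrix(counts, 1, 1))
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_absorbed(self):
        base = np.arange(1, 101)
        counts = np.column_stack([base, 2 * base])
        f = tmm_factors(_matrix(counts, 1, 1))
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_matches_bruteforce_trim_rule(self):
        # 5% of genes 8-fold up in sample B; compare the B factor against an
        # independent literal implementation of the trim-and-weight rule
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=1000).astype(float)
        b = base.copy()
        b[:50] *= 8
        counts = np.column_stack([base, b]).astype(int)
        mat = _matrix(counts, 1, 1)
        f = tmm_factors(mat, ref_sample="w0")

        y, yr = counts[:, 1].astype(float), counts[:, 0].astype(float)
        n, nr = y.sum(), yr.sum()
        both = (y > 0) & (yr > 0)
        y, yr = y[both], yr[both]
        m = np.log2((y / n) / (yr / nr))
        a = 0.5 * np.log2((y / n) * (yr / nr))

        def keep_mask(x, frac):
            cut = int(np.floor(len(x) * frac))
            ranks = scipy.stats.rankdata(x, method="ordinal") - 1
            return (ranks >= cut) & (ranks < len(x) - cut)

        kk = keep_mask(m, 0.3) & keep_mask(a, 0.05)
        w = 1.0 / ((n - y[kk]) / (n * y[kk]) + (nr - yr[kk]) / (nr * yr[kk]))
        expected_b = 2 ** (np.sum(w * m[kk]) / np.sum(w))
        # both outputs are rescaled to geometric mean 1
        expected = np.array([1.0, expected_b])
        expected /= np.exp(np.mean(np.log(expected)))
        assert abs(f["k0"] - expected[1]) / expected[1] < 0.02

    def test_all_zero_sample_raises(self):
        counts = np.column_stack([np.arange(1, 11), np.zeros(10, dtype=int)])
        with pytest.raises(ImmLncError):
            tmm_factors(_matrix(counts, 1, 1))


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

class TestDispersion:
    def test_poisson_data_yields_small_dispersion(self):
        rng = np.random.default_rng(1)
        mu = 2.0 ** rng.uniform(3, 10, 2000)
        counts = rng.poisson(mu[:, None], size=(2000, 6))
        mat = _matrix(counts, 3, 3)
        phi = estimate_dispersion(mat, [["w0", "w1", "w2"], ["k0", "k1", "k2"]])
        assert float(phi.median()) <= 0.05

    def test_constant_counts_give_zero(self):
        counts = np.tile([[5], [9], [100]], (1, 6))
        mat = _matrix(counts, 3, 3)
        phi = estimate_dispersion(mat, [["w0", "w1", "w2"], ["k0", "k1", "k2"]])
        assert np.allclose(phi, 0.0)

    def test_recovers_moderate_dispersion_at_ten_replicates(self):
        rng = np.random.default_rng(2)
        mu = 2.0 ** rng.uniform(5, 10, 2000)
        r = 1 / 0.4
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 10))
        samples = [SampleMeta(f"w{i}", "WT", "vehicle", 0, i + 1) for i in range(10)]
        mat = ExpressionMatrix(
            pd.DataFrame(counts, index=[f"g{i}" for i in range(2000)],
                         columns=[s.sample_id for s in samples]),
            samples,
        )
        phi = estimate_dispersion(mat, [[s.sample_id for s in samples]])
        assert 0.25 <= float(phi.median()) <= 0.55

    def test_single_replicate_total_raises(self):
        counts = np.arange(1, 11)[:, None]
        samples = [SampleMeta("w0", "WT", "vehicle", 0, 1),
                   SampleMeta("k0", "KO", "vehicle", 0, 1)]
        mat = ExpressionMatrix(
            pd.DataFrame(np.column_stack([counts, counts]),
                         index=[f"g{i}" for i in range(10)],
                         columns=["w0", "k0"]),
            samples,
        )
        with pytest.raises(ImmLncError):
            estimate_dispersion(mat, [["w0"], ["k0"]])


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

def _equal_libs(mat):
    return pd.Series(1.0, index=mat.counts.columns)


class TestExactTest:
    def test_identical_groups_give_null_result(self):
        counts = np.array([[10, 10, 10, 10]] * 3)
        mat = _matrix(counts, 2, 2)
        res = nb_exact_test(
            mat, ["w0", "w1"], ["k0", "k1"],
            dispersions=pd.Series(0.0, index=mat.counts.index),
            effective_lib_sizes=_equal_libs(mat), min_cpm=None,
        )
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p_value"], 1.0)

    def test_poisson_case_equals_binomial_split(self):
        # phi = 0 conditional on the total is Binomial(t, 1/2) for equal
        # group sizes: totals 0 vs 20 give p = 2 * 0.5^20
        p = exact_nb_pvalue(0, 20, 2, 2, 0.0)
        assert p == pytest.approx(2 * 0.5**20, rel=1e-9)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_independent_enumeration(self, phi):
        # spot-check vs a scipy.stats-based enumeration oracle
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = int(rng.integers(1, 31))
            sa = int(rng.integers(0, t + 1))
            ours = exact_nb_pvalue(sa, t - sa, 2, 2, phi)
            m = t / 4
            x = np.arange(t + 1)
            if phi == 0.0:
                pa = scipy.stats.poisson.pmf(x, 2 * m)
                pb = scipy.stats.poisson.pmf(t - x, 2 * m)
            else:
                r = 2 / phi
                pa = scipy.stats.nbinom.pmf(x, r, r / (r + 2 * m))
                pb = scipy.stats.nbinom.pmf(t - x, r, r / (r + 2 * m))
            probs = pa * pb
            probs /= probs.sum()
            expected = probs[probs <= probs[sa] * (1 + 1e-10)].sum()
            assert ours == pytest.approx(expected, abs=1e-12)

    def test_label_swap_negates_lfc_and_preserves_p(self):
        cfg = SimulationConfig(seed=9, n_pc_genes=200, n_lnc_genes=20,
                               markers_per_celltype=3, n_imm_lnc=2,
                               arms=("WT_vehicle", "KO_vehicle"))
        mat, _, _, _ = simulate_experiment(cfg)
        ga = mat.which_samples(genotype="WT", timepoint_days=1)
        gb = mat.which_samples(genotype="KO", timepoint_days=1)
        fwd = nb_exact_test(mat, ga, gb)
        rev = nb_exact_test(mat, gb, ga)
        merged = fwd.merge(rev, on="gene_id", suffixes=("_f", "_r"))
        assert np.allclose(merged["log2fc_f"], -merged["log2fc_r"], atol=1e-9)
        assert np.allclose(merged["p_value_f"], merged["p_value_r"], atol=1e-12)

    def test_empty_group_raises(self, two_arm_experiment):
        _, mat, _, _, _ = two_arm_experiment
        with pytest.raises(ImmLncError):
            nb_exact_test(mat, [], mat.sample_ids[:3])


class TestBenjaminiHochberg:
    def test_matches_reference_step_up(self):
        # the adjustment used throughout must equal the literal step-up rule
        def step_up(p):
            n = len(p)
            order = np.argsort(p, kind="stable")
            ranked = p[order] * n / np.arange(1, n + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            out = np.empty(n)
            out[order] = np.minimum(ranked, 1.0)
            return out

        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 60))
            ours = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, step_up(p), atol=1e-12)


class TestCallDegs:
    @pytest.mark.parametrize(
        "lfc,p,expected",
        [
            (0.5, 0.049, "up"),       # inclusive fold-change threshold
            (-0.5, 0.049, "down"),
            (3.0, 0.2, "ns"),
            (0.49, 0.001, "ns"),
            (-2.0, 0.04, "down"),
        ],
    )
    def test_threshold_rules(self, lfc, p, expected):
        res = pd.DataFrame(
            {"gene_id": ["g"], "log2fc": [lfc], "p_value": [p],
             "p_adjusted": [min(1.0, p * 2)], "mean_cpm": [10.0]}
        )
        assert call_degs(res)["direction"].iloc[0] == expected

    def test_adjusted_flag_switches_criterion(self):
        res = pd.DataFrame(
            {"gene_id": ["g"], "log2fc": [2.0], "p_value": [0.01],
             "p_adjusted": [0.2], "mean_cpm": [10.0]}
        )
        assert call_degs(res)["direction"].iloc[0] == "up"
        assert call_degs(res, use_adjusted=True)["direction"].iloc[0] == "ns"

    def test_empty_input_gives_empty_table(self):
        out = call_degs(pd.DataFrame(columns=["gene_id", "log2fc", "p_value",
                                              "p_adjusted"]))
        assert out.empty and deg_counts(out) == {"n_up": 0, "n_down": 0, "n_total": 0}


class TestOverlap:
    def test_two_set_example(self):
        out = overlap_sets({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        lookup = out.set_index("region")["n"]
        assert lookup["A"] == 1 and lookup["B"] == 1 and lookup["A&B"] == 2

    def test_disjoint_sets_share_nothing(self):
        out = overlap_sets({"A": {"a"}, "B": {"b"}})
        assert out.set_index("region")["n"]["A&B"] == 0

    def test_matches_bruteforce_membership_tally(self):
        rng = np.random.default_rng(7)
        pool = [f"g{i}" for i in range(1000)]
        sets = {k: set(rng.choice(pool, 100, replace=False)) for k in "ABC"}
        out = overlap_sets(sets).set_index("region")
        for g in pool:
            inside = frozenset(k for k in "ABC" if g in sets[k])
            if inside:
                region = "&".join(sorted(inside))
                assert g in out.loc[region, "members"]
        assert int(out["n"].sum()) == len(set.union(*sets.values()))

    def test_six_sets_unsupported(self):
        with pytest.raises(ImmLncError):
            overlap_sets({str(i): {"x"} for i in range(6)})


class TestCircosExport:
    def _ann(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "biotype", "chromosome", "start"]
        ).set_index("gene_id")

    def test_position_ordering(self):
        ann = self._ann(
            [("a", "protein_coding", "2", 100),
             ("b", "protein_coding", "1", 500),
             ("c", "protein_coding", "1", 200)]
        )
        tab = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "log2fc": [1.0, 2.0, 3.0],
             "direction": ["up"] * 3}
        )
        out = circos_export({0: tab}, ann)
        assert out["gene_id"].tolist() == ["c", "b", "a"]

    def test_natural_chromosome_sort(self):
        ann = self._ann(
            [("a", "protein_coding", "10", 1), ("b", "protein_coding", "2", 1),
             ("c", "protein_coding", "X", 1)]
        )
        tab = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "log2fc": [1.0] * 3, "direction": ["up"] * 3}
        )
        out = circos_export({0: tab}, ann)
        assert out["gene_id"].tolist() == ["b", "a", "c"]

    def test_row_count_is_union_of_timepoints(self, two_arm_experiment):
        _, mat, ann, _, _ = two_arm_experiment
        tabs = {}
        union = set()
        for tp in (0, 1):
            ga = mat.which_samples(genotype="WT", timepoint_days=tp)
            gb = mat.which_samples(genotype="KO", timepoint_days=tp)
            tabs[tp] = call_degs(nb_exact_test(mat, ga, gb))
            union |= set(tabs[tp].loc[tabs[tp]["direction"] != "ns", "gene_id"])
        out = circos_export(tabs, ann)
        assert len(out) == len(union)

    def test_unannotated_deg_raises(self):
        ann = self._ann([("a", "protein_coding", "1", 1)])
        tab = pd.DataFrame(
            {"gene_id": ["zz"], "log2fc": [1.0], "direction": ["up"]}
        )
        with pytest.raises(SchemaError, match="zz"):
            circos_export({0: tab}, ann)


class TestNullBehaviour:
    def test_pvalues_uniform_under_null(self):
        cfg = SimulationConfig(seed=21, n_pc_genes=4700, n_lnc_genes=300,
                               arms=("WT_vehicle", "KO_vehicle"))
        mat = simulate_null(cfg)
        res = nb_exact_test(
            mat,
            mat.which_samples(genotype="WT", timepoint_days=1),
            mat.which_samples(genotype="KO", timepoint_days=1),
        )
        ks = scipy.stats.kstest(res["p_value"], "uniform").statistic
        assert ks < 0.03
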