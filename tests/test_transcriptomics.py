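"""CPM normalization, expression filtering, DEG calls, module summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from abneuro import transcriptomics as tx
from abneuro import synthetic_data as sd
from abneuro.stats import compare_groups


def toy_matrix(counts, groups=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(len(counts))]
    if groups is None:
        groups = pd.Series({c: "control" for c in counts.columns})
    return tx.CountMatrix(counts=counts, groups=pd.Series(groups))


class TestCpm:
    def test_unit_count_in_million(self):
        m = toy_matrix({"s1": [1, 999_999], "s2": [10, 999_990]})
        c = tx.cpm(m)
        assert c.loc["g0", "s1"] == pytest.approx(1.0)

    def test_column_sums_normalized(self, rng):
        m = toy_matrix({f"s{i}": rng.integers(0, 500, 50) for i in range(4)})
        np.testing.assert_allclose(tx.cpm(m).sum(axis=0), 1e6, rtol=1e-12)

    def test_duplicated_column_invariance(self, rng):
        counts = {f"s{i}": rng.integers(0, 500, 30) for i in range(3)}
        m = toy_matrix(counts)
        counts["s_dup"] = counts["s0"]
        m2 = toy_matrix(counts)
        pd.testing.assert_series_equal(
            tx.cpm(m)["s0"], tx.cpm(m2)["s0"], check_names=False
        )


class TestExpressionFilter:
    def make_six_by_six(self):
        # hand-enumerable gene patterns over 6 equal-library samples
        lib = 1_000_000
        rows = {
            "allzero": [0] * 6,
            "allhigh": [100] * 6,
            "low_in_1": [0] + [100] * 5,
            "low_in_2": [0, 0] + [100] * 4,
            "low_in_4": [0, 0, 0, 0, 100, 100],
            "boundary": [1] * 6,  # CPM ~= 1 after normalization
        }
        df = pd.DataFrame(rows).T
        df.columns = [f"s{i}" for i in range(6)]
        return tx.CountMatrix(
            counts=df, groups=pd.Series({f"s{i}": "control" for i in range(6)})
        )

    def test_literal_exclude_rule_matches_enumeration(self):
        m = self.make_six_by_six()
        kept = set(tx.expression_filter(m, rule="exclude").counts.index)
        # drop genes with CPM < 1 in >= 2 samples
        assert kept == {"allhigh", "low_in_1", "boundary"}

    def test_keep_rule_matches_enumeration(self):
        m = self.make_six_by_six()
        kept = set(tx.expression_filter(m, rule="keep").counts.index)
        # keep genes with CPM >= 1 in >= 2 samples
        assert kept == {"allhigh", "low_in_1", "low_in_2", "low_in_4", "boundary"}

    def test_idempotence(self, rng):
        res = sd.gen_counts(sd.CountSimSpec(n_genes=300, seed=3))
        once = tx.expression_filter(res.matrix)
        twice = tx.expression_filter(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestCallDegs:
    def make_grouped(self, control, kv, kir):
        data = {}
        labels = {}
        for g, cols in (("control", control), ("kv", kv), ("kir", kir)):
            for i, col in enumerate(cols):
                name = f"{g}_{i}"
                data[name] = col
                labels[name] = g
        df = pd.DataFrame(data)
        df.index = [f"g{i}" for i in range(len(df))]
        return tx.CountMatrix(counts=df, groups=pd.Series(labels))

    def test_identical_means_not_deg(self):
        m = self.make_grouped([[100, 50]] * 2, [[100, 50]] * 2, [[100, 50]] * 2)
        assert not tx.call_degs(m).is_deg.any()

    def test_union_rule(self):
        # gene 0: 4x up in kv only; gene 1: flat
        m = self.make_grouped(
            control=[[100, 1000], [100, 1000]],
            kv=[[400, 1000], [400, 1000]],
            kir=[[100, 1000], [100, 1000]],
        )
        calls = tx.call_degs(m)
        assert bool(calls.loc["g0", "is_deg"])
        assert calls.loc["g0", "log2fc_kv"] > 1.0

    def test_missing_group_rejected(self):
        m = toy_matrix({"s1": [1, 2], "s2": [3, 4]})
        with pytest.raises(ValueError, match="missing"):
            tx.call_degs(m)

    def test_sample_permutation_invariance(self):
        res = sd.gen_counts(sd.CountSimSpec(n_genes=200, frac_de=0.1, seed=5))
        m = res.matrix
        perm_cols = list(reversed(m.counts.columns))
        m2 = tx.CountMatrix(counts=m.counts[perm_cols], groups=m.groups)
        pd.testing.assert_series_equal(tx.call_degs(m).is_deg, tx.call_degs(m2).is_deg)

    def test_planted_sensitivity_and_fpr(self):
        res = sd.gen_counts(
            sd.CountSimSpec(n_genes=2000, frac_de=0.1, log2fc_de=2.0,
                            dispersion=0.1, n_samples_per_group=5, seed=6)
        )
        filt = tx.expression_filter(res.matrix)
        calls = tx.call_degs(filt)
        truth = res.truth.set_index("gene").loc[calls.index]
        sens = calls.is_deg[truth.is_de].mean()
        fpr = calls.is_deg[~truth.is_de].mean()
        assert sens >= 0.90
        assert fpr < 0.05

    def test_null_simulation_low_false_positive_rate(self):
        res = sd.gen_counts(
            sd.CountSimSpec(n_genes=2000, frac_de=0.0, dispersion=0.1,
                            n_samples_per_group=5, seed=7)
        )
        filt = tx.expression_filter(res.matrix)
        calls = tx.call_degs(filt)
        assert calls.is_deg.mean() < 0.05

    def test_zero_dispersion_equal_cpm(self):
        res = sd.gen_counts(
            sd.CountSimSpec(n_genes=50, frac_de=0.0, dispersion=0.0,
                            lib_size_range=(1e6, 1e6), seed=8)
        )
        c = tx.cpm(res.matrix).to_numpy()
        assert np.allclose(c, c[:, [0]], rtol=1e-9)


class TestDegPercentages:
    def test_complement_sums_to_hundred(self):
        pct, comp = tx.deg_percentages(885, 11_611)
        assert pct + comp == pytest.approx(100.0)

    @settings(derandomize=True, max_examples=30)
    @given(n_total=st.integers(1, 100_000), frac=st.floats(0, 1))
    def test_bounds(self, n_total, frac):
        n_deg = int(frac * n_total)
        pct, comp = tx.deg_percentages(n_deg, n_total)
        assert 0.0 <= pct <= 100.0 and 0.0 <= comp <= 100.0


class TestModuleSummary:
    def test_single_gene_module_equals_gene(self):
        res = sd.gen_counts(sd.CountSimSpec(n_genes=20, seed=9))
        c = tx.cpm(res.matrix)
        out = tx.module_summary(res.matrix, {"solo": ["gene00003"]})
        expected = np.log2(c.loc["gene00003"] + 0.5)
        got = out.set_index("sample").log2_cpm
        np.testing.assert_allclose(got[expected.index], expected, atol=1e-12)

    def test_empty_intersection_rejected(self):
        res = sd.gen_counts(sd.CountSimSpec(n_genes=10, seed=10))
        with pytest.raises(ValueError, match="missing"):
            tx.module_summary(res.matrix, {"ghost": ["nope1", "nope2"]})

    def test_housekeeping_null_not_significant(self):
        res = sd.gen_counts(
            sd.CountSimSpec(n_genes=400, frac_de=0.0, n_samples_per_group=4, seed=11)
        )
        out = tx.module_summary(res.matrix, {"hk": [f"gene{i:05d}" for i in range(30)]})
        per_sample = out.groupby(["sample", "group"], sort=True).log2_cpm.mean().reset_index()
        groups = {g: d.log2_cpm.to_numpy() for g, d in per_sample.groupby("group")}
        rep = compare_groups(groups)
        assert rep.p_value > 0.05

    def test_planted_downregulated_module_ordering(self):
        res = sd.gen_counts(
            sd.CountSimSpec(n_genes=500, frac_de=0.2, log2fc_de=2.0,
                            n_samples_per_group=4, seed=12)
        )
        truth = res.truth.set_index("gene")
        down = truth[(truth.is_de) & (truth.log2fc < 0)].index.tolist()[:20]
        out = tx.module_summary(res.matrix, {"down": down})
        med = out.groupby("group").log2_cpm.median()
        assert med["control"] > med["kv"] and med["control"] > med["kir"]
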