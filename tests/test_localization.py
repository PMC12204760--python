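import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracloc.errors import FormatError
from fracloc.localization import (
    LocalizationTable,
    average_li_across_replicates,
    classify_localization,
    consistency_by_breadth,
    li_error,
    li_table,
    localization_index,
    naive_li,
    strong_localization_sets,
)

from conftest import make_fraction_set


def make_table(li_values, ids=None, beta=0.7):
    ids = ids or [f"T{i}" for i in range(len(li_values))]
    data = pd.DataFrame(
        {"li": li_values, "naive_li": li_values, "class_label": "unassigned"},
        index=pd.Index(ids, name="transcript_id"),
    )
    return LocalizationTable(data=data, beta_used=beta)


class TestLocalizationIndex:
    def test_fig1_gene_a_cell2(self, fig1_worked_example):
        ex = fig1_worked_example["cell2"]
        # normalized depth-1000 read counts, equal lengths
        li = localization_index(ex["reads_n"][0], ex["reads_c"][0], beta=0.8)
        assert li == pytest.approx(0.6, abs=1e-12)

    def test_fig1_gene_b_cell2(self, fig1_worked_example):
        ex = fig1_worked_example["cell2"]
        li = localization_index(ex["reads_n"][1], ex["reads_c"][1], beta=0.8)
        assert li == pytest.approx(0.9, abs=1e-12)

    def test_half_beta_equals_naive(self):
        rng = np.random.default_rng(0)
        n, c = rng.uniform(0, 10, 50), rng.uniform(0, 10, 50)
        np.testing.assert_allclose(
            localization_index(n, c, 0.5), naive_li(n, c), rtol=1e-12
        )

    def test_zero_nuclear_boundary(self):
        assert localization_index(0.0, 5.0, 0.3) == 1.0

    def test_both_zero_is_missing(self):
        assert np.isnan(localization_index(0.0, 0.0, 0.5))

    def test_invalid_beta(self):
        with pytest.raises(FormatError):
            localization_index(1.0, 1.0, 0.0)

    @given(
        beta1=st.floats(0.01, 0.98),
        delta=st.floats(0.001, 0.01),
        n=st.floats(0.1, 100),
        c=st.floats(0.1, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_beta(self, beta1, delta, n, c):
        assert localization_index(n, c, beta1 + delta) > localization_index(n, c, beta1)

    @given(n=st.floats(0.1, 100), c=st.floats(0.1, 100), beta=st.floats(0.51, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_naive_underestimates_for_high_beta(self, n, c, beta):
        assert naive_li(n, c) < localization_index(n, c, beta)


class TestNaiveLi:
    def test_fig1_gene_a_cell2(self, fig1_worked_example):
        ex = fig1_worked_example["cell2"]
        value = naive_li(ex["reads_n"][0], ex["reads_c"][0])
        assert round(value, 2) == 0.27
        assert value == pytest.approx(250 / (666.6666666666666 + 250), abs=1e-9)

    def test_fig1_gene_b_cell1(self, fig1_worked_example):
        ex = fig1_worked_example["cell1"]
        value = naive_li(ex["reads_n"][1], ex["reads_c"][1])
        assert value == pytest.approx(0.45, abs=1e-12)

    def test_symmetry(self):
        assert naive_li(3.0, 3.0) == 0.5

    def test_both_zero_missing(self):
        assert np.isnan(naive_li(0.0, 0.0))


class TestLiTable:
    def test_fig1_cell2_pair(self, fig1_worked_example):
        ex = fig1_worked_example["cell2"]
        whole = ex["m_n"] + ex["m_c"]
        fqs = make_fraction_set(
            [whole / whole.sum() * 1000, ex["reads_n"], ex["reads_c"]],
            [1000.0, 1000.0],
            ids=["geneA", "geneB"],
        )
        table = li_table(fqs, beta=0.8)
        np.testing.assert_allclose(table.li.to_numpy(), [0.6, 0.9], atol=1e-12)
        assert table.beta_used == 0.8

    def test_half_beta_columns_equal(self, sim_beta06):
        fqs, _, _ = sim_beta06
        table = li_table(fqs, beta=0.5)
        pd.testing.assert_series_equal(
            table.li, table.naive_li, check_names=False
        )

    def test_empty_set(self, sim_beta06):
        fqs, _, _ = sim_beta06
        empty = fqs.subset([])
        assert len(li_table(empty, beta=0.5)) == 0

    def test_exact_reads_give_true_li(self, sim_beta08):
        """Noise-free expected reads + true volume-fraction beta recover the
        per-transcript molecule proportion to machine precision."""
        from fracloc.simulate import expected_reads, fpkm_from_reads, SimulatedReads

        _, tx, cfg = sim_beta08
        fn = tx.m_n * 1e9 / (np.sum(tx.m_n.astype(float) * tx.lengths))
        fc = tx.m_c * 1e9 / (np.sum(tx.m_c.astype(float) * tx.lengths))
        li = localization_index(fn, fc, tx.true_beta)
        expressed = tx.m_w > 0
        np.testing.assert_allclose(li[expressed], tx.true_li[expressed], atol=1e-9)


class TestAverageAcrossReplicates:
    def test_mean_of_two(self):
        t1, t2 = make_table([0.4]), make_table([0.6])
        avg = average_li_across_replicates([t1, t2])
        assert avg.li.iloc[0] == pytest.approx(0.5)
        assert avg.provenance["replicate_betas"] == [0.7, 0.7]

    def test_single_identity(self):
        t1 = make_table([0.4])
        assert average_li_across_replicates([t1]) is t1

    def test_mean_of_three(self):
        tables = [make_table([0.2]), make_table([0.2]), make_table([0.8])]
        assert average_li_across_replicates(tables).li.iloc[0] == pytest.approx(0.4)

    def test_index_mismatch(self):
        with pytest.raises(FormatError):
            average_li_across_replicates(
                [make_table([0.1], ids=["A"]), make_table([0.1], ids=["B"])]
            )


class TestClassify:
    @pytest.mark.parametrize(
        "li,scheme,label",
        [
            (0.5, "threshold_04_06", "unassigned"),
            (0.5, "halfline", "cytosolic"),
            (0.95, "threshold_04_06", "cytosolic"),
            (0.95, "halfline", "cytosolic"),
            (0.39, "threshold_04_06", "nuclear"),
            (0.4, "threshold_04_06", "unassigned"),
            (0.49, "halfline", "nuclear"),
            (np.nan, "halfline", "unassigned"),
        ],
    )
    def test_rules(self, li, scheme, label):
        out = classify_localization(make_table([li]), scheme)
        assert out.data["class_label"].iloc[0] == label

    def test_unknown_scheme(self):
        with pytest.raises(FormatError):
            classify_localization(make_table([0.5]), "bogus")


class TestConsistencyByBreadth:
    def test_always_cytosolic_at_breadth_three(self):
        tables = {
            "s1": make_table([0.6]),
            "s2": make_table([0.7]),
            "s3": make_table([0.9]),
        }
        out = consistency_by_breadth(tables)
        row = out[out.n_samples_expressed == 3].iloc[0]
        assert row.n_always_cytosolic == 1 and row.n_always_nuclear == 0

    def test_mixed_is_neither(self):
        tables = {"s1": make_table([0.6]), "s2": make_table([0.4])}
        row = consistency_by_breadth(tables).iloc[1]
        assert row.n_always_cytosolic == 0 and row.n_always_nuclear == 0

    def test_boundary_counted_in_both(self):
        tables = {"s1": make_table([0.5]), "s2": make_table([0.5])}
        row = consistency_by_breadth(tables).iloc[1]
        assert row.n_always_cytosolic == 1 and row.n_always_nuclear == 1

    def test_breadth_uses_expression_only(self):
        tables = {
            "s1": make_table([0.8, np.nan], ids=["A", "B"]),
            "s2": make_table([0.9, 0.2], ids=["A", "B"]),
        }
        out = consistency_by_breadth(tables)
        assert out[out.n_samples_expressed == 1].iloc[0].n_transcripts == 1
        assert out[out.n_samples_expressed == 2].iloc[0].n_always_cytosolic == 1


class TestStrongLocalizationSets:
    def test_strongly_cytosolic(self):
        lis = [0.95, 0.92, 0.91, 0.99, 0.93]
        tables = {f"s{i}": make_table([v]) for i, v in enumerate(lis)}
        cyt, nuc = strong_localization_sets(tables)
        assert cyt == ["T0"] and nuc == []

    def test_one_failure_excludes(self):
        lis = [0.95, 0.95, 0.95, 0.95, 0.89]
        tables = {f"s{i}": make_table([v]) for i, v in enumerate(lis)}
        cyt, _ = strong_localization_sets(tables)
        assert cyt == []

    def test_breadth_rule(self):
        lis = [0.99, 0.99, 0.99, 0.99]
        tables = {f"s{i}": make_table([v]) for i, v in enumerate(lis)}
        cyt, _ = strong_localization_sets(tables, min_samples=5)
        assert cyt == []

    def test_strongly_nuclear_strict(self):
        tables = {f"s{i}": make_table([v]) for i, v in enumerate([0.1, 0.2, 0.29, 0.01, 0.2])}
        _, nuc = strong_localization_sets(tables)
        assert nuc == ["T0"]
        tables["s0"] = make_table([0.3])  # not strictly below the cut
        _, nuc = strong_localization_sets(tables)
        assert nuc == []


class TestLiError:
    def test_identity(self):
        table = make_table([0.2, 0.6])
        truth = pd.Series([0.2, 0.6], index=["T0", "T1"])
        err, summary = li_error(table, truth)
        assert (err == 0).all() and summary["median"] == 0.0

    def test_signed_error(self):
        err, _ = li_error(make_table([0.7]), pd.Series([0.6], index=["T0"]))
        assert err.iloc[0] == pytest.approx(0.1)

    def test_missing_truth_errors(self):
        with pytest.raises(FormatError):
            li_error(make_table([0.7]), pd.Series(dtype=float))

    def test_naive_li_bias_on_beta08_simulation(self, sim_beta08):
        """Sign property: naive LI systematically underestimates at beta=0.8."""
        fqs, tx, _ = sim_beta08
        table = li_table(fqs, beta=tx.true_beta)
        truth = pd.Series(tx.true_li, index=tx.transcript_ids).dropna()
        truth = truth[truth.index.isin(table.data.index)]
        table = LocalizationTable(table.data.loc[truth.index], table.beta_used)
        _, naive_summary = li_error(table, truth, column="naive_li")
        _, li_summary = li_error(table, truth, column="li")
        assert naive_summary["median"] < 0
        assert abs(li_summary["median"]) < abs(naive_summary["median"])
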