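"""Relative → absolute transformation, copy-number correction, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmprofiler.qmp import (
    RANKS,
    CopyNumberTable,
    CountTable,
    QmpTable,
    aggregate_rank,
    copy_number_correct,
    estimate_absolute,
    functional_group_sum,
    prevalence_filter,
    relative_abundances,
)


def make_counts(arr, taxa=None, samples=None, lineage=None):
    arr = np.asarray(arr)
    taxa = taxa or [f"t{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountTable(pd.DataFrame(arr, index=taxa, columns=samples),
                      lineage=lineage)


class TestRelativeAbundances:
    def test_simple_fractions(self):
        rel = relative_abundances(make_counts([[60], [40]]))
        assert rel.data["s0"].tolist() == [0.6, 0.4]

    def test_uniform_counts(self):
        rel = relative_abundances(make_counts([[1], [1], [1], [1]]))
        assert np.allclose(rel.data["s0"], 0.25)

    def test_single_taxon_all_ones(self):
        rel = relative_abundances(make_counts([[5, 7, 2]]))
        assert np.allclose(rel.data.values, 1.0)

    def test_zero_read_sample_named_in_error(self):
        with pytest.raises(ValueError, match="s1"):
            relative_abundances(make_counts([[3, 0], [4, 0]]))

    @given(
        counts=st.lists(
            st.lists(st.integers(0, 1000), min_size=3, max_size=3),
            min_size=2, max_size=6,
        ),
        k=st.integers(2, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, counts, k):
        arr = np.asarray(counts)
        if (arr.sum(axis=0) == 0).any():
            arr[0] += 1
        rel1 = relative_abundances(make_counts(arr))
        scaled = arr.copy()
        scaled[:, 0] *= k
        rel2 = relative_abundances(make_counts(scaled))
        assert np.allclose(rel1.data["s0"], rel2.data["s0"])


class TestPrevalenceFilter:
    def test_rare_taxon_dropped(self):
        # 1 read among 100000 -> prevalence 1e-5 < 1e-4
        arr = np.array([[1], [99_999]])
        filtered, dropped = prevalence_filter(make_counts(arr))
        assert dropped == ["t0"]
        assert list(filtered.taxa) == ["t1"]

    def test_exact_threshold_retained(self):
        arr = np.array([[10], [99_990]])  # exactly 1e-4
        filtered, dropped = prevalence_filter(make_counts(arr), 1e-4)
        assert dropped == []

    def test_zero_threshold_identity(self):
        table = make_counts([[1], [2], [0]])
        filtered, dropped = prevalence_filter(table, 0.0)
        assert list(filtered.taxa) == list(table.taxa)


class TestEstimateAbsolute:
    def test_scaling_and_conservation(self):
        rel = relative_abundances(make_counts([[20], [80]]))
        qmp = estimate_absolute(rel, {"s0": 1e11})
        assert qmp.data.loc["t0", "s0"] == pytest.approx(2e10)
        assert qmp.sample_totals()["s0"] == pytest.approx(1e11, rel=1e-9)
        assert qmp.unit_state == "copies_per_g"

    def test_missing_load_named(self):
        rel = relative_abundances(make_counts([[1, 1], [1, 1]]))
        with pytest.raises(ValueError, match="s1"):
            estimate_absolute(rel, {"s0": 1e10})

    def test_zero_relative_stays_zero(self):
        rel = relative_abundances(make_counts([[0, 5], [10, 5]]))
        qmp = estimate_absolute(rel, {"s0": 1e10, "s1": 2e10})
        assert qmp.data.loc["t0", "s0"] == 0.0

    @given(
        counts=st.lists(
            st.lists(st.integers(1, 500), min_size=2, max_size=2),
            min_size=2, max_size=8,
        ),
        loads=st.lists(st.floats(1e9, 1e12), min_size=2, max_size=2),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, counts, loads):
        table = make_counts(np.asarray(counts))
        qmp = estimate_absolute(
            relative_abundances(table), dict(zip(table.samples, loads))
        )
        for s, load in zip(table.samples, loads):
            assert qmp.sample_totals()[s] == pytest.approx(load, rel=1e-9)


def _lineage(taxa, genus=None, family=None):
    lin = pd.DataFrame(index=taxa, columns=list(RANKS), dtype=object)
    lin["kingdom"] = "Bacteria"
    if family is not None:
        lin["family"] = family
    lin["genus"] = genus if genus is not None else list(taxa)
    return lin


class TestCopyNumberCorrection:
    def qmp(self):
        taxa = ["Faecalibacterium", "Roseburia"]
        data = pd.DataFrame({"s0": [2e10, 1e10]}, index=taxa)
        return QmpTable(data, lineage=_lineage(taxa))

    def test_division_and_unit_change(self):
        cn = CopyNumberTable(pd.DataFrame(
            {"taxon": ["Faecalibacterium", "Roseburia"], "rank": ["genus"] * 2,
             "copy_number": [5.0, 4.0]}))
        out = copy_number_correct(self.qmp(), cn)
        assert out.data.loc["Faecalibacterium", "s0"] == pytest.approx(4e9)
        assert out.unit_state == "genomes_per_g"

    def test_unit_copies_identity_and_round_trip(self):
        cn = CopyNumberTable(pd.DataFrame(
            {"taxon": ["Faecalibacterium", "Roseburia"], "rank": ["genus"] * 2,
             "copy_number": [1.0, 1.0]}))
        src = self.qmp()
        out = copy_number_correct(src, cn)
        assert np.allclose(out.data.values, src.data.values)
        # re-multiplying by c recovers the input exactly
        cn2 = CopyNumberTable(pd.DataFrame(
            {"taxon": ["Faecalibacterium", "Roseburia"], "rank": ["genus"] * 2,
             "copy_number": [5.0, 4.0]}))
        corrected = copy_number_correct(src, cn2)
        back = corrected.data.mul(pd.Series(
            {"Faecalibacterium": 5.0, "Roseburia": 4.0}), axis=0)
        assert np.allclose(back.values, src.data.values)

    def test_table_mean_fallback(self):
        cn = CopyNumberTable(pd.DataFrame(
            {"taxon": ["Faecalibacterium", "Other"], "rank": ["genus"] * 2,
             "copy_number": [4.0, 6.0]}))
        with pytest.warns(UserWarning, match="Roseburia"):
            out = copy_number_correct(self.qmp(), cn, fallback="table_mean")
        assert out.data.loc["Roseburia", "s0"] == pytest.approx(1e10 / 5.0)

    def test_error_fallback_lists_missing(self):
        cn = CopyNumberTable(pd.DataFrame(
            {"taxon": ["Faecalibacterium"], "rank": ["genus"],
             "copy_number": [4.0]}))
        with pytest.raises(KeyError, match="Roseburia"):
            copy_number_correct(self.qmp(), cn, fallback="error")

    def test_ancestor_fallback_walks_lineage(self):
        taxa = ["Faecalibacterium", "Roseburia"]
        lin = _lineage(taxa, family=["Ruminococcaceae", "Lachnospiraceae"])
        qmp = QmpTable(pd.DataFrame({"s0": [2e10, 1e10]}, index=taxa),
                       lineage=lin)
        cn = CopyNumberTable(pd.DataFrame(
            {"taxon": ["Faecalibacterium", "Lachnospiraceae"],
             "rank": ["genus", "family"], "copy_number": [4.0, 6.0]}))
        out = copy_number_correct(qmp, cn, fallback="ancestor")
        assert out.data.loc["Roseburia", "s0"] == pytest.approx(1e10 / 6.0)

    def test_case_insensitive_matching(self):
        cn = CopyNumberTable(pd.DataFrame(
            {"taxon": ["FAECALIBACTERIUM", "roseburia"], "rank": ["genus"] * 2,
             "copy_number": [5.0, 4.0]}))
        out = copy_number_correct(self.qmp(), cn)
        assert out.data.loc["Roseburia", "s0"] == pytest.approx(2.5e9)

    def test_copy_number_below_one_rejected(self):
        with pytest.raises(ValueError):
            CopyNumberTable(pd.DataFrame(
                {"taxon": ["x"], "rank": ["genus"], "copy_number": [0.5]}))

    def test_double_correction_is_type_error(self):
        cn = CopyNumberTable(pd.DataFrame(
            {"taxon": ["Faecalibacterium", "Roseburia"], "rank": ["genus"] * 2,
             "copy_number": [1.0, 1.0]}))
        out = copy_number_correct(self.qmp(), cn)
        with pytest.raises(ValueError, match="copies_per_g"):
            copy_number_correct(out, cn)


class TestAggregateRank:
    def table(self):
        taxa = ["g1", "g2", "g3"]
        lin = _lineage(taxa, family=["famA", "famA", "famB"])
        return QmpTable(
            pd.DataFrame({"s0": [3e9, 1e9, 2e9], "s1": [1e9, 1e9, 1e9]},
                         index=taxa),
            lineage=lin,
        )

    def test_family_sums(self):
        fam = aggregate_rank(self.table(), "family")
        assert fam.data.loc["famA", "s0"] == pytest.approx(4e9)
        assert fam.data.loc["famB", "s0"] == pytest.approx(2e9)

    def test_totals_conserved_at_every_rank(self):
        table = self.table()
        for rank in RANKS:
            agg = aggregate_rank(table, rank)
            assert np.allclose(
                agg.sample_totals().values, table.sample_totals().values,
                rtol=1e-12,
            )

    def test_own_rank_identity(self):
        table = self.table()
        agg = aggregate_rank(table, "genus")
        assert sorted(agg.taxa) == sorted(table.taxa)
        assert np.allclose(
            agg.data.sort_index().values, table.data.sort_index().values
        )

    def test_unclassified_grouped_under_parent(self):
        taxa = ["g1", "g2"]
        lin = _lineage(taxa, family=["famA", np.nan])
        table = QmpTable(
            pd.DataFrame({"s0": [1e9, 2e9]}, index=taxa), lineage=lin
        )
        fam = aggregate_rank(table, "family")
        assert "unclassified_Bacteria" in fam.taxa
        assert fam.data.loc["unclassified_Bacteria", "s0"] == pytest.approx(2e9)

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError):
            aggregate_rank(self.table(), "tribe")

    def test_taxon_permutation_invariance(self):
        table = self.table()
        perm = table.data.iloc[[2, 0, 1]]
        shuffled = QmpTable(perm, lineage=table.lineage.iloc[[2, 0, 1]])
        a = aggregate_rank(table, "family").data
        b = aggregate_rank(shuffled, "family").data
        assert np.allclose(a.values, b.loc[a.index, a.columns].values)


class TestFunctionalGroupSum:
    def qmp(self):
        taxa = ["Faecalibacterium", "Roseburia", "Bacteroides"]
        return QmpTable(
            pd.DataFrame({"s0": [2e9, 3e9, 5e9], "s1": [1e9, 1e9, 1e9]},
                         index=taxa),
            lineage=_lineage(taxa),
        )

    def test_butyrate_producer_style_sum(self):
        sums, unmatched = functional_group_sum(
            self.qmp(), ["Faecalibacterium", "Roseburia"]
        )
        assert sums["s0"] == pytest.approx(5e9)
        assert unmatched == []

    def test_all_members_equals_total(self):
        qmp = self.qmp()
        sums, _ = functional_group_sum(qmp, list(qmp.taxa))
        assert np.allclose(sums.values, qmp.sample_totals().values)

    def test_unmatched_reported(self):
        sums, unmatched = functional_group_sum(
            self.qmp(), ["Roseburia", "Subdoligranulum"]
        )
        assert unmatched == ["Subdoligranulum"]
        assert sums["s0"] == pytest.approx(3e9)

    def test_no_match_raises(self):
        with pytest.raises(KeyError):
            functional_group_sum(self.qmp(), ["Akkermansia"])
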