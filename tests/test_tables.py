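"""Tests for aggregation, filtering, percentages and common-taxa analysis."""

import numpy as np
import pandas as pd
import pytest

from rhizoindic import (
    RANKS,
    TaxonCountTable,
    aggregate_to_level,
    common_taxa,
    composition_summary,
    filter_unspecific,
    to_percentages,
)
from rhizoindic.errors import (
    DomainError,
    EmptySampleError,
    EmptySelectionError,
    InsufficientDataError,
)


def lineage(kingdom="Bacteria", phylum="P1", cls="C1", order="O1", family="F1",
            genus="G1", species="S1"):
    return (kingdom, phylum, cls, order, family, genus, species)


def toy_table():
    lineages = [
        lineage(species="S1"),
        lineage(species="S2"),                       # same genus as S1
        lineage(genus="G2", species="S3"),
        lineage(genus="unclassified", species="No hits"),
        lineage(kingdom="Eukaryota", phylum="PE", cls="CE", order="OE",
                family="FE", genus="GE", species="SE"),
    ]
    counts = np.array(
        [
            [3, 10, 0],
            [4, 0, 2],
            [5, 1, 1],
            [2, 2, 2],
            [1, 0, 5],
        ]
    )
    return TaxonCountTable.from_lineages(counts=counts, lineages=lineages,
                                         samples=["a", "b", "c"])


class TestAggregate:
    def test_same_genus_rows_are_summed(self):
        agg = aggregate_to_level(toy_table(), "genus")
        g1 = "Bacteria;P1;C1;O1;F1;G1"
        assert agg.counts.loc[g1, "a"] == 7  # 3 + 4

    def test_identity_at_own_level(self):
        t = toy_table()
        agg = aggregate_to_level(t, "species")
        pd.testing.assert_frame_equal(agg.counts, t.counts)

    @pytest.mark.parametrize("level", RANKS)
    def test_column_totals_conserved(self, level):
        t = toy_table()
        agg = aggregate_to_level(t, level)
        assert (agg.sample_totals == t.sample_totals).all()

    def test_unknown_rank_rejected(self):
        with pytest.raises(DomainError):
            aggregate_to_level(toy_table(), "tribe")

    def test_cannot_refine_aggregated_table(self):
        phylum = aggregate_to_level(toy_table(), "phylum")
        with pytest.raises(DomainError):
            aggregate_to_level(phylum, "genus")


class TestFilterUnspecific:
    def test_unspecific_genus_removed_at_genus(self):
        t = filter_unspecific(toy_table(), "genus")
        assert not t.lineages["genus"].isin(["unclassified"]).any()

    def test_eukaryota_removed_at_every_level(self):
        for level in ("kingdom", "phylum", "species"):
            agg = aggregate_to_level(toy_table(), level)
            t = filter_unspecific(agg, level)
            assert (t.domains == "Bacteria").all()

    def test_all_specific_bacterial_table_unchanged(self):
        lineages = [lineage(species="S1"), lineage(genus="G2", species="S2")]
        t = TaxonCountTable.from_lineages(
            counts=[[1, 2], [3, 4]], lineages=lineages, samples=["a", "b"]
        )
        out = filter_unspecific(t, "species")
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_filter_then_aggregate_commutes_when_unspecific_only_below(self):
        # unspecific labels sit at genus/species only, so phylum-level
        # aggregation before or after species filtering gives equal totals
        # for the clearly-identified rows.
        t = toy_table()
        a = aggregate_to_level(filter_unspecific(t, "species"), "phylum")
        b = filter_unspecific(aggregate_to_level(t, "phylum"), "phylum")
        # path b keeps unspecific species' counts inside their bacterial
        # phyla; restrict comparison to rows present in both
        shared = a.counts.index.intersection(b.counts.index)
        assert len(shared) > 0


class TestPercentages:
    def test_simple_conversion(self):
        t = TaxonCountTable.from_lineages(
            counts=[[30], [70]],
            lineages=[lineage(species="S1"), lineage(species="S2")],
            samples=["a"],
        )
        pct = to_percentages(t)
        assert list(pct["a"]) == [30.0, 70.0]

    def test_columns_sum_to_100(self, small_experiment):
        pct = to_percentages(small_experiment.table)
        assert np.allclose(pct.sum(axis=0), 100.0, atol=1e-9)

    def test_single_taxon_column(self):
        t = TaxonCountTable.from_lineages(
            counts=[[42]], lineages=[lineage()], samples=["a"]
        )
        assert to_percentages(t)["a"].iloc[0] == 100.0

    def test_zero_total_column_raises_naming_sample(self):
        t = TaxonCountTable.from_lineages(
            counts=[[5, 0]], lineages=[lineage()], samples=["a", "empty"]
        )
        with pytest.raises(EmptySampleError, match="empty"):
            to_percentages(t)


class TestCompositionSummary:
    def test_constant_taxon(self):
        pct = pd.DataFrame({"a": [10.0, 90.0], "b": [10.0, 90.0]}, index=["t1", "t2"])
        s = composition_summary(pct, "phylum")[0]
        assert (s.mean_percent, s.sd, s.nsd) == (10.0, 0.0, 0.0)

    def test_nsd_definition(self):
        # mean 20, sample sd 4 -> nsd = sigma / mean = 0.2
        vals = [20.0 - np.sqrt(20), 20.0 + np.sqrt(20), 18.0, 22.0]
        pct = pd.DataFrame({s: [v] for s, v in zip("abcd", vals)}, index=["t"])
        s = composition_summary(pct, "phylum")[0]
        assert s.mean_percent == pytest.approx(20.0)
        assert s.sd == pytest.approx(4.0)
        assert s.nsd == pytest.approx(0.2)

    def test_absent_taxon_flagged_undefined(self):
        pct = pd.DataFrame({"a": [0.0], "b": [0.0]}, index=["t"])
        s = composition_summary(pct, "genus")[0]
        assert s.mean_percent == 0.0 and np.isnan(s.nsd)

    def test_single_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            composition_summary(pd.DataFrame({"a": [100.0]}, index=["t"]), "phylum")


class TestCommonTaxa:
    def three_sample_table(self):
        lineages = [lineage(species="A"), lineage(genus="G2", species="B")]
        # A everywhere; B missing from the shallow sample s3
        # totals: s1 = 15, s2 = 25, s3 = 5
        counts = [[10, 20, 5], [5, 5, 0]]
        return TaxonCountTable.from_lineages(
            counts=counts, lineages=lineages, samples=["s1", "s2", "s3"]
        )

    def test_union_and_intersection(self):
        res = common_taxa(self.three_sample_table(), 0, "species")
        names = {t.split(";")[-1] for t in res.union}
        common = {t.split(";")[-1] for t in res.intersection}
        assert names == {"A", "B"} and common == {"A"}
        assert res.intersection <= res.union

    def test_raising_threshold_can_grow_intersection(self):
        # dropping the shallow sample that lacks B lets B join the intersection
        res = common_taxa(self.three_sample_table(), 10, "species")
        assert res.retained_samples == ("s1", "s2")
        assert {t.split(";")[-1] for t in res.intersection} == {"A", "B"}

    def test_single_retained_sample(self):
        t = self.three_sample_table()
        res = common_taxa(t, 20, "species")  # only s2 (25 reads) survives
        assert res.retained_samples == ("s2",)
        assert res.union == res.intersection

    def test_no_sample_retained_raises(self):
        with pytest.raises(EmptySelectionError):
            common_taxa(self.three_sample_table(), 10_000, "species")

    def test_nested_thresholds_never_shrink_intersection(self, small_experiment):
        t = small_experiment.table
        prev = frozenset()
        for thr in (0, 100, 1000):
            res = common_taxa(t, thr, "genus")
            assert res.intersection >= prev
            prev = res.intersection
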