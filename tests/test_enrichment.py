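"""Threshold-rule conformance and invariants for the set procedures."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnakit import CountTable
from srnakit.enrichment import (
    composite_union,
    differential,
    ectopic_targets,
    ip_enrichment,
    overlap_fraction,
    protein_enrichment,
    set_crosstab,
    suppression,
)


def table(sample_id, counts, total=None):
    s = pd.Series(counts, name="count")
    s.index.name = "gene_id"
    return CountTable(sample_id, s, total if total is not None else int(s.sum()))


def rpm_table(sample_id, rpm):
    """Counts scaled so RPM equals the given values with total=1e6."""
    return table(sample_id, {g: int(v) for g, v in rpm.items()}, total=1_000_000)


class TestIpEnrichment:
    def test_more_than_twofold_enriched(self):
        es = ip_enrichment(rpm_table("ip", {"g": 10}), rpm_table("in", {"g": 4}))
        assert es.members["g"] == pytest.approx(2.5)

    def test_exactly_twofold_excluded_when_strict(self):
        es = ip_enrichment(rpm_table("ip", {"g": 2}), rpm_table("in", {"g": 1}))
        assert "g" not in es
        nonstrict = ip_enrichment(
            rpm_table("ip", {"g": 2}), rpm_table("in", {"g": 1}), strict=False
        )
        assert "g" in nonstrict

    def test_zero_input_reports_infinite_fold(self):
        es = ip_enrichment(rpm_table("ip", {"g": 5}), rpm_table("in", {"g": 0}))
        assert math.isinf(es.members["g"])

    def test_zero_zero_excluded(self):
        es = ip_enrichment(rpm_table("ip", {"g": 0}), rpm_table("in", {"g": 0}))
        assert "g" not in es

    def test_min_rpm_floor_applies_to_ip(self):
        es = ip_enrichment(rpm_table("ip", {"g": 0.5}), rpm_table("in", {"g": 0.1}))
        assert "g" not in es

    def test_universe_mismatch_reported(self):
        with pytest.raises(ValueError, match="g2"):
            ip_enrichment(rpm_table("ip", {"g1": 1}), rpm_table("in", {"g2": 1}))

    @given(st.integers(min_value=0, max_value=500), st.integers(min_value=1, max_value=200))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_ip_count(self, c, bump):
        """Raising a gene's IP count (totals fixed) never removes it from the set."""
        base = table("ip", {"g": c, "h": 50}, total=1000)
        more = table("ip", {"g": c + bump, "h": 50}, total=1000)
        ref = table("in", {"g": 20, "h": 50}, total=1000)
        lo = ip_enrichment(base, ref)
        hi = ip_enrichment(more, ref)
        if "g" in lo:
            assert "g" in hi


class TestDifferential:
    def test_fourfold_up(self):
        d = differential(rpm_table("t", {"g": 8}), rpm_table("r", {"g": 2}))
        assert d.table.loc["g", "category"] == "up"

    def test_down_with_floor_on_reference(self):
        d = differential(rpm_table("t", {"g": 1}), rpm_table("r", {"g": 10}), floor_rpm=5)
        assert d.table.loc["g", "category"] == "down"

    def test_subthreshold_change_unchanged(self):
        d = differential(rpm_table("t", {"g": 3}), rpm_table("r", {"g": 2}))
        assert d.table.loc["g", "category"] == "unchanged"

    def test_exactly_twofold_is_up_nonstrict(self):
        d = differential(rpm_table("t", {"g": 4}), rpm_table("r", {"g": 2}))
        assert d.table.loc["g", "category"] == "up"

    def test_below_floor_category(self):
        d = differential(rpm_table("t", {"g": 1}), rpm_table("r", {"g": 2}), floor_rpm=5)
        assert d.table.loc["g", "category"] == "below_floor"

    def test_negative_floor_rejected(self):
        with pytest.raises(ValueError):
            differential(rpm_table("t", {"g": 1}), rpm_table("r", {"g": 1}), floor_rpm=-1)

    @given(
        st.lists(
            st.tuples(st.integers(0, 100), st.integers(0, 100)), min_size=1, max_size=20
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_antisymmetry_above_floor(self, pairs):
        """Swapping samples swaps up and down for genes above floor in both."""
        floor = 5.0
        genes = {f"g{i}": p for i, p in enumerate(pairs)}
        t = table("t", {g: a for g, (a, b) in genes.items()}, total=100)
        r = table("r", {g: b for g, (a, b) in genes.items()}, total=100)
        fwd = differential(t, r, floor_rpm=floor)
        rev = differential(r, t, floor_rpm=floor)
        above = {
            g for g in genes
            if fwd.table.loc[g, "test_rpm"] > floor and fwd.table.loc[g, "ref_rpm"] > floor
        }
        assert fwd.up & above == rev.down & above
        assert fwd.down & above == rev.up & above

    def test_categories_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        vals = {f"g{i}": int(v) for i, v in enumerate(rng.integers(0, 30, size=50))}
        refs = {f"g{i}": int(v) for i, v in enumerate(rng.integers(0, 30, size=50))}
        d = differential(table("t", vals, 500), table("r", refs, 500), floor_rpm=3)
        assert d.table["category"].isin(["up", "down", "unchanged", "below_floor"]).all()


class TestCrosstab:
    def test_counts_and_fractions(self):
        ct = set_crosstab({"g1", "g2", "g3"}, {"g2", "g3", "g4"}, {f"g{i}" for i in range(9)})
        assert (ct.n_a, ct.n_b, ct.n_intersection, ct.n_union) == (3, 3, 2, 4)
        assert ct.jaccard == pytest.approx(0.5)

    def test_identical_sets(self):
        ct = set_crosstab({"a"}, {"a"}, {"a", "b"})
        assert ct.jaccard == 1.0 and ct.shared_fraction_a == 1.0

    def test_disjoint_sets(self):
        assert set_crosstab({"a"}, {"b"}, {"a", "b"}).n_intersection == 0

    def test_intersection_bounded_and_fractions_unit_interval(self):
        ct = set_crosstab({"a", "b"}, {"b", "c", "d"}, set("abcdef"))
        assert ct.n_intersection <= min(ct.n_a, ct.n_b)
        for f in (ct.jaccard, ct.shared_fraction_a, ct.shared_fraction_b):
            assert 0.0 <= f <= 1.0

    def test_membership_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            set_crosstab({"a", "z"}, {"a"}, {"a", "b"})


def _diff_with_up(genes_up, universe):
    t = rpm_table("t", {g: (40 if g in genes_up else 10) for g in universe})
    r = rpm_table("r", {g: 10 for g in universe})
    return differential(t, r)


class TestEctopicTargets:
    universe = [f"g{i}" for i in range(8)]

    def _ip_sets(self, wago, csr1):
        mk = lambda name, genes: ip_enrichment(
            rpm_table(name, {g: (30 if g in genes else 1) for g in self.universe}),
            rpm_table("in", {g: 10 for g in self.universe}),
        )
        return {"WAGO1": mk("WAGO1", wago), "CSR1": mk("CSR1", csr1)}

    def test_up_wago_not_csr1_is_ectopic(self):
        diff = _diff_with_up({"g1"}, self.universe)
        sets = self._ip_sets(wago={"g1"}, csr1=set())
        assert ectopic_targets(diff, {"g1", "g2"}, sets) == {"g1"}

    def test_csr1_ip_enriched_excluded(self):
        diff = _diff_with_up({"g1"}, self.universe)
        sets = self._ip_sets(wago={"g1"}, csr1={"g1"})
        assert ectopic_targets(diff, {"g1"}, sets) == set()

    def test_no_up_genes_empty(self):
        diff = _diff_with_up(set(), self.universe)
        sets = self._ip_sets(wago={"g1"}, csr1=set())
        assert ectopic_targets(diff, {"g1"}, sets) == set()

    def test_not_on_csr1_list_excluded(self):
        diff = _diff_with_up({"g1"}, self.universe)
        sets = self._ip_sets(wago={"g1"}, csr1=set())
        assert ectopic_targets(diff, {"g2"}, sets) == set()

    def test_missing_wago_set_rejected(self):
        diff = _diff_with_up({"g1"}, self.universe)
        sets = self._ip_sets(wago={"g1"}, csr1=set())
        with pytest.raises(ValueError, match="WAGO"):
            ectopic_targets(diff, {"g1"}, {"CSR1": sets["CSR1"]})


class TestSuppression:
    def test_halved_criterion(self):
        # suppressed iff double <= mutant / 2
        mut = rpm_table("mut", {"a": 20, "b": 20, "c": 10})
        dbl = rpm_table("dbl", {"a": 5, "b": 12, "c": 2})
        sup, (n, tot) = suppression({"a", "b", "c"}, mut, dbl)
        assert sup == {"a", "c"} and (n, tot) == (2, 3)

    def test_not_suppressed(self):
        mut = rpm_table("mut", {"a": 20})
        dbl = rpm_table("dbl", {"a": 15})
        assert suppression({"a"}, mut, dbl)[0] == set()

    def test_empty_set_ok(self):
        mut = rpm_table("mut", {"a": 1})
        assert suppression(set(), mut, mut) == (set(), (0, 0))

    def test_restored_criterion_needs_wt(self):
        mut = rpm_table("mut", {"a": 20})
        dbl = rpm_table("dbl", {"a": 6})
        with pytest.raises(ValueError, match="wild-type"):
            suppression({"a"}, mut, dbl, criterion="restored")
        wt = rpm_table("wt", {"a": 4})
        sup, _ = suppression({"a"}, mut, dbl, criterion="restored", wt=wt)
        assert sup == {"a"}  # 6 <= 2*4


class TestCompositeUnion:
    def test_union_of_down_sets(self):
        d1 = differential(rpm_table("t1", {"a": 1, "b": 1, "c": 10}),
                          rpm_table("r", {"a": 10, "b": 10, "c": 10}))
        d2 = differential(rpm_table("t2", {"a": 10, "b": 1, "c": 1}),
                          rpm_table("r", {"a": 10, "b": 10, "c": 10}))
        assert composite_union([d1, d2]) == {"a", "b", "c"}

    def test_overlap_fraction(self):
        assert overlap_fraction({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(2 / 3)

    def test_empty_inputs(self):
        assert composite_union([]) == set()
        assert overlap_fraction(set(), {"a"}) == 0.0


class TestProteinEnrichment:
    def test_enriched_at_267_fold(self):
        got = protein_enrichment(pd.Series({"P": 4.0}), pd.Series({"P": 1.5}))
        assert got["P"] == pytest.approx(4.0 / 1.5)

    def test_below_twofold_excluded(self):
        assert protein_enrichment(pd.Series({"P": 1.9}), pd.Series({"P": 1.0})) == {}

    def test_exactly_twofold_included_nonstrict(self):
        assert "P" in protein_enrichment(pd.Series({"P": 2.0}), pd.Series({"P": 1.0}))

    def test_absent_from_background_enriched(self):
        got = protein_enrichment(pd.Series({"P": 0.5}), pd.Series(dtype=float))
        assert math.isinf(got["P"])

    def test_absent_from_ip_not_enriched(self):
        assert protein_enrichment(pd.Series(dtype=float), pd.Series({"P": 1.0})) == {}
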