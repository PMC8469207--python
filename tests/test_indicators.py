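import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from littoral.core import HabitatPartition, TaxonInfo, TaxonRegistry, ValidationError
from littoral.indicators import (
    SaprobicZone,
    build_trophic_report,
    classify_saprobic_zone,
    eo_ratio,
    format_ratio,
    me_ratio,
    saprobity_index,
    shannon_diversity,
)

from conftest import make_table


class TestShannon:
    def test_monoculture_is_zero(self):
        assert shannon_diversity([1, 0, 0]) == 0.0

    def test_even_community_closed_form(self):
        assert shannon_diversity([1, 1, 1, 1]) == pytest.approx(math.log(4))

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(size=30)
        p = v / v.sum()
        oracle = -sum(pi * math.log(pi) for pi in p)
        assert shannon_diversity(v) == pytest.approx(oracle, abs=1e-12)

    def test_log_base_option(self):
        assert shannon_diversity([1, 1], base=2) == pytest.approx(1.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValidationError):
            shannon_diversity([0.0, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1e3), min_size=2, max_size=20))
    def test_permutation_invariant_and_bounded_by_even(self, vals):
        h = shannon_diversity(vals)
        assert h == pytest.approx(shannon_diversity(vals[::-1]), abs=1e-12)
        assert h <= math.log(len(vals)) + 1e-12


class TestSaprobity:
    def test_constant_valence(self):
        assert saprobity_index([2.0, 2.0, 2.0], [5, 1, 9]) == 2.0

    def test_symmetric_pair(self):
        assert saprobity_index([1.0, 3.0], [1, 1]) == 2.0

    def test_hand_weighted_value(self):
        assert saprobity_index([1.0, 3.0], [3, 1]) == pytest.approx(1.5)

    def test_empty_list_errors(self):
        with pytest.raises(ValidationError, match="no indicator"):
            saprobity_index([], [])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0, 4.5), st.floats(0.01, 100)),
            min_size=1,
            max_size=15,
        ),
        st.floats(0.01, 100),
    )
    def test_bounded_and_h_scale_invariant(self, pairs, c):
        s = [p[0] for p in pairs]
        h = [p[1] for p in pairs]
        S = saprobity_index(s, h)
        assert min(s) - 1e-12 <= S <= max(s) + 1e-12
        assert S == pytest.approx(saprobity_index(s, [c * x for x in h]), rel=1e-9)


class TestZones:
    @pytest.mark.parametrize(
        "S,zone",
        [
            (1.47, SaprobicZone.OLIGOSAPROBIC),
            (1.60, SaprobicZone.BETA_MESOSAPROBIC),
            (2.17, SaprobicZone.BETA_MESOSAPROBIC),
            (0.10, SaprobicZone.OUT_OF_RANGE),
            (1.50, SaprobicZone.OLIGOSAPROBIC),
            (1.51, SaprobicZone.BETA_MESOSAPROBIC),
            (2.50, SaprobicZone.BETA_MESOSAPROBIC),
            (3.00, SaprobicZone.ALPHA_MESOSAPROBIC),
            (4.00, SaprobicZone.POLYSAPROBIC),
            (4.50, SaprobicZone.POLYSAPROBIC),
        ],
    )
    def test_classification(self, S, zone):
        assert classify_saprobic_zone(S) is zone

    def test_monotone_over_scale(self):
        order = [
            SaprobicZone.OLIGOSAPROBIC,
            SaprobicZone.BETA_MESOSAPROBIC,
            SaprobicZone.ALPHA_MESOSAPROBIC,
            SaprobicZone.POLYSAPROBIC,
        ]
        grid = np.arange(50, 451) / 100.0
        idx = [order.index(classify_saprobic_zone(s)) for s in grid]
        assert idx == sorted(idx)


def _info(tid, e=False, o=False, m=False, end=False, val=None):
    return TaxonInfo(
        taxon_id=tid,
        guild_eutrophic=e,
        guild_oligotrophic=o,
        guild_mesosaprobiont=m,
        guild_endemic=end,
        saprobic_valence=val,
    )


class TestRatios:
    @pytest.mark.parametrize(
        "e,o,raw,text",
        [(4, 2, 2.0, "2:1"), (2, 4, 0.5, "1:2"), (3, 1, 3.0, "3:1")],
    )
    def test_eo_counts(self, e, o, raw, text):
        taxa = [_info(f"e{i}", e=True) for i in range(e)]
        taxa += [_info(f"o{i}", o=True) for i in range(o)]
        taxa += [_info("plain")]
        res = eo_ratio(taxa)
        assert res.raw == pytest.approx(raw)
        assert res.text == text

    def test_eo_zero_denominator_and_undefined(self):
        inf_res = eo_ratio([_info("e1", e=True)])
        assert math.isinf(inf_res.raw) and inf_res.text == "1:0"
        na = eo_ratio([_info("plain")])
        assert math.isnan(na.raw) and na.text == "NA"

    @pytest.mark.parametrize(
        "m,e,raw,text",
        [(600.0, 100.0, 6.0, "6:1"), (100.0, 4700.0, 100 / 4700, "1:47"), (50.0, 50.0, 1.0, "1:1")],
    )
    def test_me_biomass(self, m, e, raw, text):
        table = make_table(
            [[m], [e]],
            taxa=[_info("mes", m=True), _info("end", end=True)],
        )
        res = me_ratio(table, ["s0"])
        assert res.raw == pytest.approx(raw)
        assert res.text == text

    def test_me_zero_endemic_sentinel(self):
        table = make_table([[10.0], [0.0]], taxa=[_info("mes", m=True), _info("end", end=True)])
        res = me_ratio(table, ["s0"])
        assert math.isinf(res.raw) and res.text == "M:0"

    def test_me_scale_invariant(self):
        t1 = make_table([[600.0], [100.0]], taxa=[_info("m", m=True), _info("e", end=True)])
        t2 = make_table([[6000.0], [1000.0]], taxa=[_info("m", m=True), _info("e", end=True)])
        assert me_ratio(t1, ["s0"]).raw == pytest.approx(me_ratio(t2, ["s0"]).raw)

    def test_format_rounds_half_away(self):
        assert format_ratio(2.5) == "3:1"
        assert format_ratio(1 / 2.5) == "1:3"


class TestTrophicReport:
    def _table(self):
        taxa = [
            _info("i1", val=1.0, m=True),
            _info("i2", val=1.0, end=True),
            _info("i3", val=1.0, e=True),
            _info("x1", o=True),
        ]
        biomass = [
            [5.0, 6.0],
            [2.0, 2.0],
            [1.0, 0.0],
            [4.0, 4.0],
        ]
        table = make_table(
            biomass, taxa=taxa, samples=["h1", "h2"], habitats={0: "H", 1: "H"}
        )
        return table, HabitatPartition({"H": ["h1", "h2"]})

    def test_constant_valence_gives_that_s(self):
        table, part = self._table()
        row = build_trophic_report(table, None, part).row("H")
        assert row.saprobity_S == 1.0
        assert row.saprobic_zone is SaprobicZone.OLIGOSAPROBIC
        assert row.n_indicator_species == 3

    def test_richness_and_shannon_bound(self):
        table, part = self._table()
        row = build_trophic_report(table, None, part).row("H")
        assert row.n_taxa == 4
        assert 0 <= row.shannon_H <= math.log(row.n_taxa)

    def test_registry_overrides_table_attributes(self):
        table, part = self._table()
        registry = TaxonRegistry(
            [_info(t.taxon_id, val=2.0) for t in table.taxa]
        )
        row = build_trophic_report(table, registry, part).row("H")
        assert row.saprobity_S == 2.0

    def test_no_indicators_flagged_missing(self):
        table = make_table([[1.0]], taxa=[_info("plain")])
        part = HabitatPartition({"s0": ["s0"]})
        row = build_trophic_report(table, None, part).row("s0")
        assert row.saprobity_S is None and row.saprobic_zone is None

    def test_occurrence_weights_count_samples(self):
        # i3 occurs in one of two samples: its h is 1 vs 2 for the others
        taxa = [_info("a", val=1.0), _info("b", val=3.0)]
        biomass = [[1.0, 1.0], [1.0, 0.0]]
        table = make_table(biomass, taxa=taxa, samples=["h1", "h2"], habitats={0: "H", 1: "H"})
        part = HabitatPartition({"H": ["h1", "h2"]})
        row = build_trophic_report(table, None, part).row("H")
        assert row.saprobity_S == pytest.approx((1.0 * 2 + 3.0 * 1) / 3)
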