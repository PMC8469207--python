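import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from littoral.core import (
    CommunityTable,
    HabitatPartition,
    Sample,
    TaxonInfo,
    ValidationError,
    integrate_strata,
    total_biomass,
)
from littoral.io import read_community_table, write_community_table

from conftest import make_table


class TestValidation:
    def test_negative_biomass_names_cell(self):
        with pytest.raises(ValidationError, match=r"tax1.*s0"):
            make_table([[1.0, 2.0], [-0.5, 1.0]])

    def test_conflicting_guild_flags_rejected(self):
        with pytest.raises(ValidationError):
            TaxonInfo(taxon_id="x", guild_eutrophic=True, guild_oligotrophic=True)

    def test_valence_out_of_scale_rejected(self):
        with pytest.raises(ValidationError):
            TaxonInfo(taxon_id="x", saprobic_valence=5.0)

    def test_partition_disjointness_enforced(self):
        with pytest.raises(ValidationError):
            HabitatPartition({"A": ["s1", "s2"], "B": ["s2"]})


class TestIO:
    def test_wide_zero_matrix_round_trip(self, tmp_path):
        table = make_table(np.zeros((3, 2)))
        p = tmp_path / "t.csv"
        write_community_table(table, p)
        back = read_community_table(p)
        assert back.biomass.shape == (3, 2)
        assert (back.biomass.to_numpy() == 0).all()

    def test_long_duplicate_pair_errors(self, tmp_path):
        p = tmp_path / "long.csv"
        p.write_text(
            "taxon_id,sample_id,value\nt1,s1,1.0\nt1,s1,2.0\n"
        )
        with pytest.raises(ValidationError, match=r"'t1'.*'s1'"):
            read_community_table(p, dialect="long")

    def test_long_missing_cells_are_zero(self, tmp_path):
        p = tmp_path / "long.csv"
        p.write_text(
            "taxon_id,sample_id,value\nt1,s1,1.5\nt2,s2,2.5\n"
        )
        t = read_community_table(p, dialect="long")
        assert t.biomass.loc["t1", "s2"] == 0.0
        assert t.biomass.loc["t2", "s1"] == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arr=arrays(
            np.float64,
            (4, 3),
            elements=st.floats(0, 1e6, allow_nan=False, width=32),
        )
    )
    def test_round_trip_preserves_values(self, arr, tmp_path_factory):
        table = make_table(arr)
        p = tmp_path_factory.mktemp("io") / "t.csv"
        write_community_table(table, p)
        back = read_community_table(p)
        np.testing.assert_array_equal(back.biomass.to_numpy(), arr.astype(float))


class TestIntegrateStrata:
    def _layered(self):
        samples = [
            Sample(f"st1-{z}", "H", station_id="st1", stratum=z)
            for z in ("0m", "5m", "10m", "15m")
        ]
        bio = pd.DataFrame(
            [[10.0, 20.0, 30.0, 40.0]],
            index=["t1"],
            columns=[s.sample_id for s in samples],
        )
        return CommunityTable(
            taxa=[TaxonInfo("t1")], samples=samples, biomass=bio
        )

    def test_depth_layers_average(self):
        out = integrate_strata(self._layered())
        assert out.biomass.shape == (1, 1)
        assert out.biomass.iloc[0, 0] == 25.0
        assert out.samples[0].stratum is None

    def test_single_sample_group_identity(self):
        table = make_table([[3.0], [7.0]])
        out = integrate_strata(table, by=("habitat_id",))
        np.testing.assert_array_equal(
            out.biomass.to_numpy(), table.biomass.to_numpy()
        )

    def test_idempotent(self):
        once = integrate_strata(self._layered())
        twice = integrate_strata(once)
        pd.testing.assert_frame_equal(once.biomass, twice.biomass)
        assert [s.sample_id for s in once.samples] == [
            s.sample_id for s in twice.samples
        ]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(
            np.float64,
            (3, 6),
            elements=st.floats(0, 1e4, allow_nan=False),
        )
    )
    def test_column_sums_are_groupwise_means(self, arr):
        # two stations x three strata: integral column sums must equal
        # the mean of the original per-sample column sums in each group
        samples = [
            Sample(f"st{g}-{z}", "H", station_id=f"st{g}", stratum=str(z))
            for g in (1, 2)
            for z in range(3)
        ]
        table = CommunityTable(
            taxa=[TaxonInfo(f"t{i}") for i in range(3)],
            samples=samples,
            biomass=pd.DataFrame(
                arr, index=[f"t{i}" for i in range(3)],
                columns=[s.sample_id for s in samples],
            ),
        )
        out = integrate_strata(table)
        for g, cols in (("st1", [0, 1, 2]), ("st2", [3, 4, 5])):
            expected = arr[:, cols].sum(axis=0).mean()
            got = out.biomass[f"{g}|H"].sum()
            assert got == pytest.approx(expected, rel=1e-12)


class TestTotalBiomass:
    def test_textbook_se(self):
        table = make_table(
            [[100.0, 200.0, 300.0]],
            samples=["s1", "s2", "s3"],
            habitats={0: "H", 1: "H", 2: "H"},
        )
        part = HabitatPartition({"H": ["s1", "s2", "s3"]})
        mean, se = total_biomass(table, part)["H"]
        assert mean == 200.0
        assert se == pytest.approx(57.73502691896258)

    def test_single_sample_has_no_se(self):
        table = make_table([[5.0]])
        part = HabitatPartition({"s0": ["s0"]})
        mean, se = total_biomass(table, part)["s0"]
        assert mean == 5.0
        assert se is None

    def test_invariant_under_taxon_reordering(self, two_habitat_table):
        table, part = two_habitat_table
        shuffled = make_table(
            table.biomass.iloc[::-1].to_numpy(),
            taxa=list(table.biomass.index[::-1]),
            samples=list(table.biomass.columns),
            habitats={j: s.habitat_id for j, s in enumerate(table.samples)},
        )
        assert total_biomass(table, part) == total_biomass(shuffled, part)

    def test_estimate_near_generator_truth(self):
        # n = 50 lognormal samples per replicate: the habitat mean should
        # fall within 3 SE of the generator truth in almost all replicates
        # (the totals are right-skewed, so a few exceedances are expected)
        truth = 4 * np.exp(2.0 + 0.5**2 / 2)
        sids = [f"s{j}" for j in range(50)]
        part = HabitatPartition({"H": sids})
        misses = 0
        for seed in range(40):
            vals = np.random.default_rng(seed).lognormal(2.0, 0.5, size=(4, 50))
            table = make_table(
                vals, samples=sids, habitats={j: "H" for j in range(50)}
            )
            mean, se = total_biomass(table, part)["H"]
            misses += abs(mean - truth) >= 3 * se
        assert misses <= 4
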