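import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phosremodel as pr
from phosremodel.lipidomics import CHAINS_PER_CLASS, LIPID_CLASSES


class TestParseSpecies:
    def test_resolved_diacyl(self):
        sp = pr.parse_species("PC(16:0/20:5)")
        assert sp.class_token == "PC" and sp.sn_resolved
        assert (sp.chains[0].carbons, sp.chains[0].double_bonds) == (16, 0)
        assert (sp.chains[1].carbons, sp.chains[1].double_bonds) == (20, 5)

    def test_triacyl_and_omega_tag(self):
        sp = pr.parse_species("TG(16:0/18:1/16:1)")
        assert sp.class_token == "TG" and len(sp.chains) == 3
        sp2 = pr.parse_species("PE(16:0/20:5n-3)")
        assert sp2.chains[1].omega_tag == "n-3"

    def test_unresolved_separator(self):
        sp = pr.parse_species("DGTS(16:0_18:1)")
        assert not sp.sn_resolved
        assert sp.name == "DGTS(16:0_18:1)"

    @pytest.mark.parametrize(
        "bad", ["PC(16:0)", "XXX(16:0/18:1)", "PC(16:0/18:1/16:0)", "FFA()",
                "PC(16:0/18)", "PC 16:0/18:1"],
    )
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(pr.FormatError):
            pr.parse_species(bad)

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_round_trip_is_identity(self, data):
        cls = data.draw(st.sampled_from(LIPID_CLASSES))
        n = CHAINS_PER_CLASS[cls]
        chains = data.draw(
            st.lists(
                st.tuples(st.integers(2, 26), st.integers(0, 6)),
                min_size=n, max_size=n,
            ).filter(lambda cs: all(d < c for c, d in cs))
        )
        sep = "/" if n == 1 else data.draw(st.sampled_from(["/", "_"]))
        name = f"{cls}({sep.join(f'{c}:{d}' for c, d in chains)})"
        assert pr.parse_species(name).name == name


class TestNormalizePerCell:
    def test_per_million_cell_arithmetic(self):
        out = pr.normalize_per_cell([1e6], [2e6])
        assert out[0] == pytest.approx(5e5)

    def test_equal_inputs_give_equal_levels(self):
        out = pr.normalize_per_cell([3.0, 3.0, 3.0], [1e6, 1e6, 1e6])
        assert len(set(out)) == 1

    def test_doubling_counts_halves_levels(self):
        areas = np.array([10.0, 20.0, 30.0])
        cells = np.array([1e6, 2e6, 4e6])
        np.testing.assert_allclose(
            pr.normalize_per_cell(areas, 2 * cells),
            pr.normalize_per_cell(areas, cells) / 2,
        )

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(pr.InputError):
            pr.normalize_per_cell([1.0], [0.0])


class TestClassifyOrigin:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("PG(18:1/16:1)", "prokaryotic"),   # C16:X at sn2 -> plastid
            ("PC(16:0/18:1)", "eukaryotic"),    # C18:X at sn2 -> ER
            ("PC(16:0/20:5)", "unassigned"),
            ("DGTS(16:0_18:1)", "unassigned"),  # unresolved
            ("TG(18:1/16:0/18:1)", "prokaryotic"),  # middle chain treated as sn2
        ],
    )
    def test_sn2_rule(self, name, expected):
        assert pr.classify_origin(pr.parse_species(name)) == expected

    def test_single_chain_species_not_applicable(self):
        with pytest.raises(pr.InputError):
            pr.classify_origin(pr.parse_species("LPC(16:0)"))


class TestClassLevels:
    def test_class_sum_is_exact(self, toy_lipid_table):
        summaries = {c.class_token: c for c in pr.class_levels(toy_lipid_table)}
        np.testing.assert_allclose(
            summaries["DGTS"].levels,
            np.array([15, 16, 14, 46, 45, 44, 15, 15, 15], dtype=float),
        )
        assert summaries["DGTS"].n_species == 2

    def test_two_tier_calls_on_planted_shifts(self, toy_lipid_table):
        summaries = {c.class_token: c for c in pr.class_levels(toy_lipid_table)}
        dgts = summaries["DGTS"].stats["PD/PR"]
        assert dgts.tier_2x == "up" and dgts.tier_1p5x == "up"
        pc = summaries["PC"].stats["PD/PR"]
        assert pc.tier_2x == "down"
        restored = summaries["DGTS"].stats["PDR/PD"]
        assert restored.tier_2x == "down"

    def test_planted_remodeling_recovered(self, default_lipidome):
        table, truth = default_lipidome
        stats = {c.class_token: c.stats["PD/PR"] for c in pr.class_levels(table)}
        assert stats["DGTS"].tier_2x == "up"
        assert stats["TG"].tier_2x == "up"
        for cls in ("PC", "PE", "PG", "PA", "PI"):
            assert stats[cls].tier_2x == "down"
        # thylakoid lipids: planted 0.6x — below the 2-fold tier, caught at 1.5
        assert stats["MGDG"].tier_2x == "none"
        assert stats["MGDG"].tier_1p5x == "down"

    def test_tier_monotonicity(self, default_lipidome):
        table, _ = default_lipidome
        for c in pr.class_levels(table):
            for s in c.stats.values():
                if s.tier_2x != "none":
                    assert s.tier_1p5x == s.tier_2x


class TestOriginStratified:
    def test_strata_partition_class_sums(self, default_lipidome):
        table, _ = default_lipidome
        classes = {c.class_token: c.levels for c in pr.class_levels(table)}
        strata = pr.origin_stratified_levels(table)
        recomposed = {}
        for s in strata:
            recomposed[s.class_token] = recomposed.get(s.class_token, 0) + s.levels
        for cls, levels in classes.items():
            np.testing.assert_allclose(recomposed[cls], levels, rtol=1e-12)

    def test_planted_origin_dependent_remodeling(self):
        remodeling = dict(pr.LipidomeSimConfig().remodeling_map)
        remodeling["PE"] = {"prokaryotic": 0.5, "eukaryotic": 1.8, "unassigned": 1.0}
        table, _ = pr.generate_lipidome(
            pr.LipidomeSimConfig(remodeling_map=remodeling, seed=4)
        )
        strata = {
            (s.class_token, s.origin): s.stats["PD/PR"]
            for s in pr.origin_stratified_levels(table)
        }
        assert strata[("PE", "eukaryotic")].tier_1p5x == "up"
        assert strata[("PE", "prokaryotic")].tier_1p5x == "down"

    def test_all_unassigned_single_stratum(self, design):
        sp = pr.parse_species("PC(16:0_18:1)")
        sp.levels = np.arange(9.0) + 1
        table = pr.LipidTable([sp], design)
        strata = pr.origin_stratified_levels(table)
        assert [(s.class_token, s.origin) for s in strata] == [("PC", "unassigned")]


class TestFattyAcidTotals:
    def test_single_species_splits_evenly(self, design):
        sp = pr.parse_species("PC(16:0/20:5)")
        sp.levels = np.full(9, 10.0)
        totals, percent = pr.fatty_acid_totals(pr.LipidTable([sp], design))
        np.testing.assert_allclose(totals.loc["16:0"], 10.0)
        np.testing.assert_allclose(totals.loc["20:5"], 10.0)
        np.testing.assert_allclose(percent.loc["16:0"], 50.0)

    def test_chain_multiplicity_counts_twice(self, design):
        sp = pr.parse_species("TG(16:0/16:0/18:1)")
        sp.levels = np.full(9, 6.0)
        totals, _ = pr.fatty_acid_totals(pr.LipidTable([sp], design))
        np.testing.assert_allclose(totals.loc["16:0"], 12.0)
        np.testing.assert_allclose(totals.loc["18:1"], 6.0)

    def test_epa_share_falls_under_depletion(self, default_lipidome):
        """EPA-bearing phospholipids shrink under depletion, so the 20:5
        share of total acyl chains drops in PD and recovers in PDR."""
        table, _ = default_lipidome
        _, percent = pr.fatty_acid_totals(table)
        cond = {s.sample_id: s.condition for s in table.samples}
        epa = percent.loc[[i for i in percent.index if i.startswith("20:5")]].sum()
        pr_mean = epa[[k for k, c in cond.items() if c == "PR"]].mean()
        pd_mean = epa[[k for k, c in cond.items() if c == "PD"]].mean()
        pdr_mean = epa[[k for k, c in cond.items() if c == "PDR"]].mean()
        assert pd_mean < pr_mean
        assert pdr_mean > pd_mean


def test_epa_ara_species_filter(design):
    names = ["PC(16:0/20:5)", "PE(16:0/20:4)", "PE(16:0/18:1)", "DGTS(16:0/20:5)"]
    species = []
    for n in names:
        sp = pr.parse_species(n)
        sp.levels = np.ones(9)
        species.append(sp)
    table = pr.LipidTable(species, design)
    assert [s.name for s in pr.epa_ara_species(table)] == [
        "PC(16:0/20:5)", "PE(16:0/20:4)"
    ]


def test_conservation_classes_equal_species_totals(default_lipidome):
    table, _ = default_lipidome
    summaries = pr.class_levels(table)
    # each class level is bitwise the sum of its member species
    for c in summaries:
        members = [sp.levels for sp in table.species if sp.class_token == c.class_token]
        np.testing.assert_array_equal(c.levels, np.sum(members, axis=0))
    # grand totals agree up to float re-association across classes
    class_total = np.sum([c.levels for c in summaries], axis=0)
    species_total = np.sum([sp.levels for sp in table.species], axis=0)
    np.testing.assert_allclose(class_total, species_total, rtol=1e-12)
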