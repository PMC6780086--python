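import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import phosremodel as pr


def sign_tail_exact(n_majority, n) -> Fraction:
    """Independent oracle: exact rational one-sided fair-coin tail."""
    return Fraction(sum(math.comb(n, i) for i in range(n_majority, n + 1)), 2**n)


def _tiers(n_down, n_up, contrast="PD/PR"):
    mk = lambda i, tier: pr.EnzymeTier(f"1.1.1.{i}", contrast, 1.0, 0.5, tier)
    tiers = [mk(i, "moderate_down") for i in range(n_down)]
    tiers += [mk(100 + i, "moderate_up") for i in range(n_up)]
    return tiers


class TestAggregateEnzymes:
    @staticmethod
    def _matrix(rows, design):
        df = pd.DataFrame(
            rows, columns=[s.sample_id for s in design]
        )
        df.index = [f"g{i}" for i in range(len(rows))]
        return pr.ExpressionMatrix(df.astype(float), design)

    def test_copies_sum_per_sample(self, design):
        m = self._matrix([[10.0] * 9, [5.0] * 9, [7.0] * 9], design)
        ann = pr.AnnotationTable(
            ec_numbers={"g0": ("1.1.1.1",), "g1": ("1.1.1.1",), "g2": ()},
            pathways={"g0": (), "g1": (), "g2": ()},
        )
        (profile,) = pr.aggregate_enzymes(m, ann)
        assert profile.copy_number == 2
        np.testing.assert_allclose(profile.values, 15.0)

    def test_single_copy_equals_gene_row(self, design):
        row = np.arange(1.0, 10.0)
        m = self._matrix([row], design)
        ann = pr.AnnotationTable(
            ec_numbers={"g0": ("2.2.2.2",)}, pathways={"g0": ()}
        )
        (profile,) = pr.aggregate_enzymes(m, ann)
        np.testing.assert_allclose(profile.values, row)

    def test_multi_ec_gene_contributes_to_each_enzyme(self, design):
        m = self._matrix([[4.0] * 9, [6.0] * 9], design)
        ann = pr.AnnotationTable(
            ec_numbers={"g0": ("1.1.1.1", "2.2.2.2"), "g1": ("2.2.2.2",)},
            pathways={"g0": (), "g1": ()},
        )
        profiles = {p.ec_number: p for p in pr.aggregate_enzymes(m, ann)}
        np.testing.assert_allclose(profiles["1.1.1.1"].values, 4.0)
        np.testing.assert_allclose(profiles["2.2.2.2"].values, 10.0)

    def test_conservation_over_single_ec_genes(self, default_transcriptome):
        """Summed enzyme profiles conserve the member-gene TPM totals."""
        matrix, annotation, _ = default_transcriptome
        profiles = pr.aggregate_enzymes(matrix, annotation)
        covered = sorted({g for p in profiles for g in p.copy_gene_ids})
        total_profiles = np.sum([p.values for p in profiles], axis=0)
        total_genes = matrix.data.loc[covered].to_numpy().sum(axis=0)
        np.testing.assert_allclose(total_profiles, total_genes, rtol=1e-9)


class TestClassifyEnzymeChange:
    @staticmethod
    def _profile(pr_vals, pd_vals, design):
        values = np.array(list(pr_vals) + list(pd_vals) + list(pr_vals), dtype=float)
        return pr.EnzymeProfile("1.2.3.4", ("g0",), values, design)

    def test_clear_strong_shift_is_significant(self, design):
        # exact 1.6-fold with tiny replicate scatter -> p below alpha
        p = self._profile([99, 100, 101], [159, 160, 161], design)
        tier = pr.classify_enzyme_change(p, "PR", "PD")
        assert tier.tier == "significant_up"
        assert tier.direction == "up"
        assert tier.fold_change == pytest.approx(161 / 101)

    def test_noisy_small_shift_is_moderate(self, design):
        # ~1.2-fold mean shift with large scatter -> beyond the 10% band, not significant
        p = self._profile([100, 100, 100], [60, 120, 180], design)
        tier = pr.classify_enzyme_change(p, "PR", "PD")
        assert tier.p_value >= 0.05
        assert tier.tier == "moderate_up"

    def test_within_band_is_unchanged(self, design):
        p = self._profile([100, 100, 100], [105, 105, 105], design)
        assert pr.classify_enzyme_change(p, "PR", "PD").tier == "unchanged"

    def test_band_mode_switch(self, design):
        # fold 0.92: inside the symmetric ratio band (1/1.1 = 0.909) but
        # below 0.9+... the 'fraction' reading calls down only under 0.9
        p = self._profile([100, 100, 100], [85, 85, 85], design)
        ratio = pr.classify_enzyme_change(
            p, "PR", "PD", pr.ConcordanceConfig(alpha=1e-9)
        )
        assert ratio.tier == "moderate_down"  # 0.857 < 1/1.1
        p2 = self._profile([100, 100, 100], [91, 92, 93], design)
        cfgf = pr.ConcordanceConfig(alpha=1e-9, band_mode="fraction")
        assert pr.classify_enzyme_change(p2, "PR", "PD", cfgf).tier == "unchanged"

    def test_every_enzyme_gets_exactly_one_tier(self, default_transcriptome):
        matrix, annotation, _ = default_transcriptome
        profiles = pr.aggregate_enzymes(matrix, annotation)[:200]
        tiers = [pr.classify_enzyme_change(p, "PR", "PD") for p in profiles]
        valid = {"significant_up", "significant_down", "moderate_up",
                 "moderate_down", "unchanged"}
        assert all(t.tier in valid for t in tiers)
        assert len(tiers) == len(profiles)


class TestConcordanceTest:
    @pytest.mark.parametrize(
        "n_down,n_up,expected",
        [
            (9, 1, Fraction(11, 1024)),     # 9 of 10 down -> 0.0107 (prints 0.011)
            (1, 8, Fraction(10, 512)),      # 8 of 9 up -> 0.0195
            (3, 11, Fraction(470, 16384)),  # 11 of 14 up -> 0.0287
            (12, 1, Fraction(14, 8192)),    # 12 of 13 down -> 0.0017
            (1, 0, Fraction(1, 2)),         # single altered enzyme
        ],
    )
    def test_worked_sign_test_values(self, n_down, n_up, expected):
        res = pr.concordance_test(_tiers(n_down, n_up), "calvin")
        assert res.p_value == pytest.approx(float(expected), rel=1e-12)
        assert res.p_value == pytest.approx(
            float(sign_tail_exact(res.n_majority, res.n_altered)), rel=1e-12
        )
        assert res.majority_direction == ("down" if n_down > n_up else "up")

    def test_closed_forms(self):
        for n in range(1, 21):
            unanimous = pr.concordance_test(_tiers(n, 0))
            assert unanimous.p_value == pytest.approx(2.0**-n, rel=1e-12)
            if n >= 2:
                near = pr.concordance_test(_tiers(n - 1, 1))
                assert near.p_value == pytest.approx((n + 1) * 2.0**-n, rel=1e-12)

    def test_matches_monte_carlo_fair_coin(self):
        rng = np.random.default_rng(7)
        n, n_maj = 12, 9
        draws = rng.binomial(n, 0.5, size=1_000_000)
        mc = (draws >= n_maj).mean()
        exact = pr.concordance_test(_tiers(n_maj, n - n_maj)).p_value
        se = np.sqrt(exact * (1 - exact) / 1_000_000)
        assert abs(mc - exact) < 4 * se

    def test_tie_reported_as_up_with_flag(self):
        res = pr.concordance_test(_tiers(2, 2))
        assert res.tied and res.majority_direction == "up"
        assert res.p_value == pytest.approx(float(sign_tail_exact(2, 4)), rel=1e-12)

    def test_significant_enzymes_count_with_moderate_ones(self):
        tiers = _tiers(4, 1) + [
            pr.EnzymeTier("9.9.9.9", "PD/PR", 0.4, 0.001, "significant_down")
        ]
        res = pr.concordance_test(tiers)
        assert res.n_altered == 6 and res.n_down == 5

    def test_unchanged_excluded_and_empty_rejected(self):
        tiers = _tiers(3, 0) + [pr.EnzymeTier("u", "PD/PR", 1.0, 0.9, "unchanged")]
        assert pr.concordance_test(tiers).n_altered == 3
        with pytest.raises(pr.InputError):
            pr.concordance_test([])
        with pytest.raises(pr.InputError):
            pr.concordance_test(
                [pr.EnzymeTier("u", "PD/PR", 1.0, 0.9, "unchanged")]
            )


def test_planted_concordant_pathways_detected(default_transcriptome):
    """Pathways whose member enzymes all shift one way score small sign-test p."""
    matrix, annotation, truth = default_transcriptome
    _, results = pr.pathway_concordance(matrix, annotation)
    by_key = {(r.pathway_id, r.contrast): r for r in results}
    for pw, direction in truth.concordant_pathways.items():
        res = by_key[(pw, "PD/PR")]
        assert res.majority_direction == direction
        assert res.p_value < 0.05
        # restoration mirrors depletion for planted pathways
        mirror = by_key[(pw, "PDR/PD")]
        assert mirror.majority_direction == ("up" if direction == "down" else "down")
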