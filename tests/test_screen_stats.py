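"""LFC, robust Z-scores, significance and phenotype classification."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from mirscreen.screen_stats import (
    DivisionDomainError,
    InhibitorProfile,
    ScreenStatsConfig,
    call_hits,
    classify_category,
    compute_lfc,
    robust_zscores,
    significance_pvalue,
)
from mirscreen.synthetic_data import ScreenScenario, gen_screen_table, make_planted_scenario


def profile(m, t, l, inh="x"):
    return InhibitorProfile(inh, m, t, l)


class TestComputeLfc:
    @pytest.mark.parametrize(
        "m,t,l,expected",
        [
            (0.3, 0.3, 0.3, 0.0),  # identical scores: ratio 1
            (0.25, 0.5, 0.5, 1.0),  # resistant twice parental: log2 = 1
            (0.5, 0.25, 0.25, -1.0),
        ],
    )
    def test_exact_log2_ratios_without_pseudocount(self, m, t, l, expected):
        cfg = ScreenStatsConfig(pseudocount=0.0)
        assert compute_lfc(profile(m, t, l), cfg) == pytest.approx(expected)

    def test_zero_parental_without_pseudocount_names_inhibitor(self):
        with pytest.raises(DivisionDomainError, match="miR-inh-0042"):
            compute_lfc(profile(0.0, 0.5, 0.5, "miR-inh-0042"), ScreenStatsConfig(pseudocount=0.0))

    def test_pseudocount_guards_zero_parental(self):
        assert np.isfinite(compute_lfc(profile(0.0, 0.5, 0.5)))


class TestRobustZscores:
    def test_constant_vector_has_undefined_scores(self, caplog):
        with caplog.at_level("WARNING"):
            med, mad, rz = robust_zscores([0.4, 0.4, 0.4])
        assert mad == 0.0 and np.isnan(rz).all()
        assert "MAD is zero" in caplog.text

    def test_majority_tie_degenerates_even_with_outlier(self):
        _, mad, rz = robust_zscores([0, 0, 0, 0, 1])
        assert mad == 0.0 and np.isnan(rz).all()

    def test_symmetric_vector_matches_hand_computation(self):
        med, mad, rz = robust_zscores([-2, -1, 0, 1, 2])
        assert med == 0.0 and mad == 1.0
        np.testing.assert_allclose(rz, 0.6745 * np.array([-2, -1, 0, 1, 2]))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            robust_zscores([])

    def test_matches_brute_force_oracle(self):
        """Sort-based median/MAD oracle over many random small vectors."""

        def oracle(vals):
            def med(v):
                s = sorted(v)
                k = len(s) // 2
                return s[k] if len(s) % 2 else (s[k - 1] + s[k]) / 2.0

            m = med(vals)
            mad = med([abs(v - m) for v in vals])
            if mad == 0:
                return m, mad, [float("nan")] * len(vals)
            return m, mad, [0.6745 * (v - m) / mad for v in vals]

        rng = np.random.default_rng(12345)
        for _ in range(200):
            n = int(rng.integers(3, 51))
            x = rng.normal(0, 2, size=n)
            em, emad, erz = oracle(list(x))
            m, mad, rz = robust_zscores(x)
            assert m == pytest.approx(em, abs=1e-12)
            assert mad == pytest.approx(emad, abs=1e-12)
            np.testing.assert_allclose(rz, erz, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        x=st.lists(st.floats(-10, 10), min_size=3, max_size=30),
        a=st.floats(0.1, 50),
        b=st.floats(-100, 100),
    )
    def test_invariant_under_positive_affine_transform(self, x, a, b):
        _, mad, rz = robust_zscores(x)
        assume(mad > 1e-3)  # near-degenerate spreads amplify float cancellation
        _, _, rz2 = robust_zscores([a * v + b for v in x])
        np.testing.assert_allclose(rz2, rz, rtol=1e-6, atol=1e-6)


class TestSignificance:
    def test_half_at_zero(self):
        assert significance_pvalue(0.0) == pytest.approx(0.5)

    def test_screen_threshold_tail_probability(self):
        # |RZ| >= 2.5 corresponds to a one-sided normal tail of 0.00621
        assert significance_pvalue(2.5) == pytest.approx(0.00621, abs=5e-6)

    def test_unit_z_matches_numeric_normal_tail(self):
        # oracle: numerically integrate the standard normal density on [1, 40]
        from scipy.integrate import quad

        tail, _ = quad(lambda t: np.exp(-t * t / 2) / np.sqrt(2 * np.pi), 1.0, 40.0)
        assert significance_pvalue(1.0) == pytest.approx(tail, abs=1e-10)
        assert round(significance_pvalue(1.0), 4) == 0.1587

    def test_strictly_decreasing_in_z(self):
        zs = np.linspace(-3, 5, 30)
        ps = [significance_pvalue(z) for z in zs]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestClassifyCategory:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ((0.6, 0.6, 0.6), "pan"),
            ((0.05, 0.25, 0.25), "resistant_only"),
            ((0.12, 0.05, 0.05), "responsive_only"),
            ((0.05, 0.05, 0.05), "none"),
            ((0.6, 0.6, 0.4), "none"),  # fails pan, MCF7 too high for resistant_only
            ((0.12, 0.25, 0.25), "resistant_only"),  # resistant wins over responsive
        ],
    )
    def test_fig_style_threshold_rules(self, scores, expected):
        assert classify_category(profile(*scores)) == expected

    def test_pan_takes_precedence(self):
        # all three above every threshold: must label pan, not resistant_only
        assert classify_category(profile(0.7, 0.9, 0.9)) == "pan"


class TestCallHits:
    def test_noiseless_planted_screen_recovered_exactly(self, noiseless_screen):
        _, table, truth = noiseless_screen
        hits = call_hits(table)
        assert len(hits) == 954
        pred = hits.set_index("inhibitor_id")["category"]
        assert all(pred[inh] == cat for inh, cat in truth.items())
        counts = hits["category"].value_counts()
        assert counts.get("responsive_only", 0) == 4
        assert counts.get("resistant_only", 0) == 9
        assert counts.get("pan", 0) == 13

    def test_zero_planted_noiseless_screen_has_no_category_hits(self):
        table, _ = gen_screen_table(ScreenScenario(n_inhibitors=50, noise_sd=0.0), seed=3)
        hits = call_hits(table)
        assert (hits["category"] == "none").all()
        assert not hits["significant"].any()  # degenerate MAD: nothing flagged

    def test_controls_never_scored_as_inhibitors(self, noiseless_screen):
        _, table, _ = noiseless_screen
        hits = call_hits(table)
        assert not set(hits.inhibitor_id) & {"mock", "neg_ctrl", "death_ctrl"}

    def test_rz_scores_invariant_to_log_base(self):
        sc = make_planted_scenario(n_inhibitors=100, n_responsive=1, n_resistant=1, n_pan=1, seed=2, noise_sd=0.02)
        table, _ = gen_screen_table(sc, seed=2)
        rz2 = call_hits(table, ScreenStatsConfig(log_base=2)).set_index("inhibitor_id").rz_score
        rz10 = call_hits(table, ScreenStatsConfig(log_base=10)).set_index("inhibitor_id").rz_score
        rze = call_hits(table, ScreenStatsConfig(log_base=np.e)).set_index("inhibitor_id").rz_score
        np.testing.assert_allclose(rz2, rz10.loc[rz2.index], atol=1e-12)
        np.testing.assert_allclose(rz2, rze.loc[rz2.index], atol=1e-12)

    def test_sorted_by_absolute_rz(self):
        sc = make_planted_scenario(n_inhibitors=100, n_responsive=1, n_resistant=1, n_pan=1, seed=9, noise_sd=0.02)
        table, _ = gen_screen_table(sc, seed=9)
        hits = call_hits(table)
        absrz = hits.rz_score.abs().to_numpy()
        assert (np.diff(absrz[np.isfinite(absrz)]) <= 1e-12).all()

    def test_inhibitor_missing_a_cell_line_excluded(self, caplog):
        table, _ = gen_screen_table(ScreenScenario(n_inhibitors=10, noise_sd=0.0), seed=0)
        table = table[~((table.inhibitor_id == "miR-inh-0001") & (table.cell_line == "LTED"))]
        with caplog.at_level("WARNING"):
            hits = call_hits(table)
        assert "miR-inh-0001" not in set(hits.inhibitor_id) and len(hits) == 9


def test_robust_z_converges_to_classical_z_under_normality():
    """The 0.6745 constant makes MAD a consistent sigma estimate."""
    x = np.random.default_rng(0).standard_normal(10_000)
    _, _, rz = robust_zscores(x)
    classical = (x - x.mean()) / x.std(ddof=1)
    assert np.abs(rz - classical).max() <= 0.05
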