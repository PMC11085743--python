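"""Gray relational analysis: formulas, bounds, invariances, screening."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import gra_oracle
from specfx.errors import ConfigError, ValidationError
from specfx.gra import (
    GraConfig,
    gra_analysis,
    gra_screen,
    normalize_series,
    relational_grade,
)
from specfx.panel import INDICATORS


class TestNormalizeSeries:
    @pytest.mark.parametrize(
        "series, method, expected",
        [
            ((2, 4, 6), "mean", (0.5, 1.0, 1.5)),
            ((1, 1, 1), "mean", (1.0, 1.0, 1.0)),
            ((1, 3), "minmax", (0.0, 1.0)),
            ((5, 7), "none", (5.0, 7.0)),
        ],
    )
    def test_examples(self, series, method, expected):
        np.testing.assert_allclose(
            normalize_series(np.array(series, dtype=float), method), expected
        )

    def test_degenerate_series_raise(self):
        with pytest.raises(ValidationError, match="mean"):
            normalize_series(np.array([-1.0, 1.0]), "mean")
        with pytest.raises(ValidationError, match="constant"):
            normalize_series(np.array([2.0, 2.0]), "minmax")


class TestRelationalGrade:
    def test_identity_grade_is_exactly_one(self):
        ref = np.array([1.0, 2.0, 3.0])
        comps = np.array([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        grades, _, dmin, _ = relational_grade(ref, comps, GraConfig(normalization="none"))
        assert grades[0] == 1.0
        assert dmin == 0.0

    def test_hand_worked_reversed_series(self):
        """ref=(1,2,3) vs comp=(3,2,1), rho=0.5: deltas (2,0,2) -> grade 5/9."""
        grades, coeffs, dmin, dmax = relational_grade(
            np.array([1.0, 2.0, 3.0]),
            np.array([[3.0, 2.0, 1.0]]),
            GraConfig(rho=0.5, normalization="none"),
        )
        assert (dmin, dmax) == (0.0, 2.0)
        np.testing.assert_allclose(coeffs[0], [1 / 3, 1.0, 1 / 3])
        assert grades[0] == pytest.approx(5 / 9, abs=1e-15)

    def test_all_identical_comparisons_grade_one_with_warning(self, caplog):
        ref = np.array([1.0, 2.0])
        with caplog.at_level("WARNING", logger="specfx.gra"):
            grades, coeffs, _, dmax = relational_grade(
                ref, np.vstack([ref, ref]), GraConfig(normalization="none")
            )
        assert dmax == 0.0
        np.testing.assert_array_equal(grades, [1.0, 1.0])
        assert "identical" in caplog.text

    @given(st.integers(0, 10_000))
    def test_coefficient_bound_when_dmin_zero(self, seed):
        """With dmin=0 and rho=0.5 every coefficient lies in [1/3, 1]."""
        rng = np.random.default_rng(seed)
        ref = rng.uniform(0.1, 10, size=6)
        comps = np.vstack([ref, rng.uniform(0.1, 10, size=(3, 6))])  # row 0 forces dmin=0
        _g, coeffs, dmin, _ = relational_grade(ref, comps, GraConfig(normalization="none"))
        assert dmin == 0.0
        assert np.all(coeffs >= 1 / 3 - 1e-12) and np.all(coeffs <= 1.0)

    @given(st.integers(0, 10_000))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(1.0, 5.0, size=12)
        comps = rng.uniform(1.0, 5.0, size=(9, 12))
        for norm in ("none", "mean"):
            grades, _, dmin, dmax = relational_grade(
                ref, comps, GraConfig(normalization=norm)
            )
            og, odmin, odmax = gra_oracle(ref, comps, 0.5, norm)
            np.testing.assert_allclose(grades, og, atol=1e-12)
            assert dmin == pytest.approx(odmin, abs=1e-15)
            assert dmax == pytest.approx(odmax, abs=1e-15)

    @given(st.integers(0, 10_000))
    def test_batch_reordering_invariance(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(1, 5, size=8)
        comps = rng.uniform(1, 5, size=(4, 8))
        perm = rng.permutation(8)
        g1, *_ = relational_grade(ref, comps, GraConfig(normalization="none"))
        g2, *_ = relational_grade(ref[perm], comps[:, perm], GraConfig(normalization="none"))
        np.testing.assert_allclose(g1, g2, atol=1e-14)

    def test_increasing_a_delta_cannot_increase_grade(self):
        """Monotonicity for fixed extrema: larger deviation, lower grade."""
        ref = np.zeros(4)
        comps = np.array([[0.5, 0.2, 0.1, 1.0], [0.5, 0.4, 0.1, 1.0]])  # fixed dmax=1
        g, *_ = relational_grade(ref, comps, GraConfig(normalization="none"))
        assert g[1] < g[0]

    def test_rho_validation(self):
        with pytest.raises(ConfigError, match="rho"):
            GraConfig(rho=0.0)
        with pytest.raises(ConfigError, match="rho"):
            GraConfig(rho=1.0)


class TestGraAnalysis:
    def test_grades_shape_and_range(self, zero_noise_data):
        g = zero_noise_data["gra"]
        assert g.grades.shape == (4, 36)
        assert list(g.grades.index) == list(INDICATORS)
        vals = g.grades.to_numpy()
        assert np.all(vals > 0) and np.all(vals <= 1)

    def test_planted_actives_outrank_permuted_decoy(self, zero_noise_data):
        """An active's area series beats the same series with batches shuffled."""
        matrix = zero_noise_data["matrix"]
        panel = zero_noise_data["panel"]
        truth = zero_noise_data["truth"]
        rng = np.random.default_rng(0)
        for k, j in enumerate(sorted(truth.active_peaks)):
            ind = INDICATORS[k % 4]
            ref = (
                panel.protection_series(ind)
                if ind in ("ldh", "ros")
                else panel.series(ind)
            )
            series = matrix.areas[:, j - 1]
            decoy = series[rng.permutation(series.size)]
            comps = np.vstack([series, decoy])
            grades, *_ = relational_grade(ref, comps, GraConfig())
            assert grades[0] > grades[1]

    def test_protection_transform_changes_ldh_ranking(self, zero_noise_data):
        raw = gra_analysis(
            zero_noise_data["matrix"], zero_noise_data["panel"],
            GraConfig(orientation_handling="raw"),
        )
        prot = zero_noise_data["gra"]
        assert not np.allclose(raw.grades.loc["ldh"], prot.grades.loc["ldh"])
        # viability is higher-is-better: untouched by the transform
        np.testing.assert_allclose(
            raw.grades.loc["viability"], prot.grades.loc["viability"]
        )

    def test_batch_id_mismatch_rejected(self, zero_noise_data):
        panel = zero_noise_data["panel"]
        shuffled = panel.values.iloc[::-1]
        from specfx.panel import BioactivityPanel

        with pytest.raises(ValidationError, match="batch ids"):
            gra_analysis(
                zero_noise_data["matrix"],
                BioactivityPanel(values=shuffled, model_values=panel.model_values),
            )


class TestGraScreen:
    def test_strict_threshold(self):
        import pandas as pd

        from specfx.gra import GraResult

        grades = pd.DataFrame(
            [[0.95, 0.85], [0.9, 0.91], [0.2, 0.3], [0.99, 0.89]],
            index=list(INDICATORS), columns=[1, 2],
        )
        res = GraResult(grades=grades, coefficients={}, delta_min={}, delta_max={})
        hits = gra_screen(res, 0.9)
        assert hits == {("viability", 1), ("ldh", 2), ("ros", 1)}

    def test_threshold_extremes(self, zero_noise_data):
        g = zero_noise_data["gra"]
        assert gra_screen(g, 1.0) == set()          # grades < 1 on real data
        all_hits = gra_screen(g, 0.0)
        assert len(all_hits) == 4 * 36              # every grade > 0
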