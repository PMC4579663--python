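import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecoloc.indices import (
    aggregate_patient_score,
    dichotomize_abundance,
    immune_abundance,
    morisita_horn,
    pearson_colocalization,
)
from ecoloc.patterns import SlidePattern
from ecoloc.tessellation import QuadratCounts


def mh_by_hand(x, y):
    """Independent term-by-term evaluation of the similarity formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    X, Y = x.sum(), y.sum()
    num = 2 * sum(xi * yi for xi, yi in zip(x, y))
    den = (sum(xi * xi for xi in x) / X**2 + sum(yi * yi for yi in y) / Y**2) * X * Y
    return num / den


count_tables = st.lists(
    st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=2, max_size=12
).filter(lambda rows: sum(r[0] for r in rows) > 0 and sum(r[1] for r in rows) > 0)


class TestMorisitaHorn:
    def test_proportional_counts_give_one(self):
        c = QuadratCounts.from_arrays(x=[2, 2], y=[3, 3])
        assert morisita_horn(c) == pytest.approx(1.0)

    def test_disjoint_support_gives_zero(self):
        c = QuadratCounts.from_arrays(x=[5, 0], y=[0, 7])
        assert morisita_horn(c) == pytest.approx(0.0)

    def test_hand_computed_five_sevenths(self):
        c = QuadratCounts.from_arrays(x=[1, 2, 3], y=[3, 2, 1])
        assert morisita_horn(c) == pytest.approx(5 / 7)
        assert morisita_horn(c) == pytest.approx(mh_by_hand([1, 2, 3], [3, 2, 1]))

    def test_missing_when_class_absent(self):
        c = QuadratCounts.from_arrays(x=[1, 2], y=[0, 0])
        with pytest.warns(UserWarning):
            assert morisita_horn(c) is None

    def test_missing_with_single_polygon(self):
        c = QuadratCounts.from_arrays(x=[4], y=[5])
        with pytest.warns(UserWarning):
            assert morisita_horn(c) is None

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(count_tables)
    def test_range_and_symmetry(self, rows):
        x = [r[0] for r in rows]
        y = [r[1] for r in rows]
        v = morisita_horn(QuadratCounts.from_arrays(x=x, y=y))
        assert 0.0 <= v <= 1.0 + 1e-12
        v_swapped = morisita_horn(QuadratCounts.from_arrays(x=y, y=x))
        assert v == pytest.approx(v_swapped)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(count_tables, st.integers(2, 9))
    def test_scale_invariance(self, rows, c):
        x = np.array([r[0] for r in rows])
        y = np.array([r[1] for r in rows])
        v = morisita_horn(QuadratCounts.from_arrays(x=x, y=y))
        v_scaled = morisita_horn(QuadratCounts.from_arrays(x=c * x, y=y))
        assert v == pytest.approx(v_scaled)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(count_tables)
    def test_boundary_characterization(self, rows):
        # MH = 1 exactly on proportional tables; MH = 0 exactly on disjoint support
        x = np.array([r[0] for r in rows], float)
        y = np.array([r[1] for r in rows], float)
        v = morisita_horn(QuadratCounts.from_arrays(x=x.astype(int), y=y.astype(int)))
        proportional = np.allclose(x / x.sum(), y / y.sum())
        disjoint = np.dot(x, y) == 0
        assert (v == pytest.approx(1.0)) == proportional
        assert (v == pytest.approx(0.0, abs=1e-12)) == disjoint


class TestPearson:
    def test_perfect_linear_relation(self):
        c = QuadratCounts.from_arrays(x=[1, 2, 3], y=[2, 4, 6])
        assert pearson_colocalization(c) == pytest.approx(1.0)

    def test_anti_correlation(self):
        c = QuadratCounts.from_arrays(x=[1, 2, 3], y=[3, 2, 1])
        assert pearson_colocalization(c) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        c = QuadratCounts.from_arrays(x=[0, 1, 2, 5], y=[1, 0, 3, 4])
        assert pearson_colocalization(c) == pytest.approx(10 / np.sqrt(140))

    def test_zero_variance_is_missing(self):
        c = QuadratCounts.from_arrays(x=[2, 2, 2], y=[1, 5, 9])
        with pytest.warns(UserWarning):
            assert pearson_colocalization(c) is None


class TestImmuneAbundance:
    def test_fraction(self):
        pat = SlidePattern(
            "p", "s",
            x=np.arange(100, dtype=float), y=np.zeros(100),
            cell_class=np.array(["immune"] * 8 + ["cancer"] * 92, dtype=object),
        )
        assert immune_abundance(pat) == pytest.approx(0.08)

    def test_all_immune(self):
        pat = SlidePattern(
            "p", "s", x=[0.0, 1.0], y=[0.0, 1.0], cell_class=["immune", "immune"]
        )
        assert immune_abundance(pat) == pytest.approx(1.0)

    def test_default_cutoff_is_eight_percent(self):
        assert dichotomize_abundance(0.081) == "high"
        assert dichotomize_abundance(0.08) == "low"

    def test_empty_pattern_missing(self):
        pat = SlidePattern("p", "s", [], [], [], window=(0, 0, 1, 1))
        with pytest.warns(UserWarning):
            assert immune_abundance(pat) is None


class TestPatientAggregation:
    def _section(self, x, y):
        return QuadratCounts.from_arrays(x=x, y=y, t=np.asarray(x) + np.asarray(y))

    def test_single_section_identity(self):
        s = self._section([1, 2, 3], [3, 2, 1])
        score = aggregate_patient_score([s])
        assert score.morisita == pytest.approx(morisita_horn(s))

    def test_pooled_duplicate_sections_preserve_morisita(self):
        s = self._section([1, 2, 3], [3, 2, 1])
        dup = self._section([1, 2, 3], [3, 2, 1])
        score = aggregate_patient_score([s, dup], strategy="pool")
        assert score.morisita == pytest.approx(morisita_horn(s))
        assert score.n_polygons_used == 6

    def test_strategy_recorded_in_provenance(self):
        s = self._section([1, 2], [2, 1])
        assert aggregate_patient_score([s], strategy="pool").aggregation == "pool"
        assert aggregate_patient_score([s], strategy="mean").aggregation == "mean"

    def test_mean_strategy_averages_sections(self):
        a = self._section([2, 2], [3, 3])  # MH = 1
        b = self._section([5, 0], [0, 7])  # MH = 0
        score = aggregate_patient_score([a, b], strategy="mean")
        assert score.morisita == pytest.approx(0.5)

    def test_all_degenerate_gives_missing(self):
        bad = QuadratCounts.from_arrays(x=[3, 1], y=[0, 0])
        with pytest.warns(UserWarning):
            score = aggregate_patient_score([bad])
        assert score.morisita is None

    def test_no_sections_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient_score([])
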