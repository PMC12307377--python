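import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenodiv import (
    descriptive_stats,
    diversity_report,
    qualitative_cv,
    qualitative_profile,
    shannon_index,
    stratify_ten_classes,
)
from phenodiv.diversity import codes_from_counts, profile_from_counts
from phenodiv.errors import InsufficientDataError, UndefinedStatisticError
from phenodiv.reference import (
    QUALITATIVE_COUNTS,
    QUALITATIVE_CONSISTENT,
    QUALITATIVE_CV_CONSISTENT,
    QUALITATIVE_CV_PUBLISHED,
    QUALITATIVE_SHANNON,
    QUANTITATIVE_CV,
)
from phenodiv.traits import PhenotypeTable


def brute_force_classes(values):
    """Assign each value to its 10-class bin by linear scan over the 9
    boundaries - independent oracle for stratify_ten_classes."""
    x = np.asarray(values, dtype=float)
    mean, sd = x.mean(), x.std(ddof=1)
    bounds = [mean + k * sd for k in np.arange(-2.0, 2.01, 0.5)]
    counts = [0] * 10
    for v in x:
        if v <= bounds[0]:
            counts[0] += 1
        elif v >= bounds[-1]:
            counts[9] += 1
        else:
            for i in range(8):
                if bounds[i] <= v < bounds[i + 1]:
                    counts[i + 1] += 1
                    break
    return counts


class TestDescriptiveStats:
    def test_range_from_published_extremes(self):
        d = descriptive_stats([184.13, 67.50], trait="MTL")
        assert d.range == pytest.approx(116.63)

    def test_constant_vector(self):
        d = descriptive_stats([5, 5, 5])
        assert (d.sd, d.cv_percent, d.range) == (0.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        d = descriptive_stats([2, 4, 6, 8])
        assert d.mean == 5
        assert d.sd == pytest.approx(2.5820, abs=1e-4)
        assert d.cv_percent == pytest.approx(51.64, abs=0.01)
        assert d.range == 6

    def test_single_value_insufficient(self):
        with pytest.raises(InsufficientDataError):
            descriptive_stats([1.0])

    def test_zero_mean_cv_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            descriptive_stats([-1.0, 1.0])


class TestStratifyTenClasses:
    def test_identical_values_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="zero SD"):
            prof = stratify_ten_classes([7.0] * 20)
        assert prof.shannon_index == 0.0
        assert sum(c > 0 for c in prof.counts) == 1

    def test_worked_nine_value_example(self):
        prof = stratify_ten_classes([1, 2, 2, 3, 3, 3, 4, 4, 5])
        occupied = {
            lab: c for lab, c in zip(prof.class_labels, prof.counts) if c
        }
        assert occupied == {2: 1, 4: 2, 6: 3, 7: 2, 9: 1}
        assert prof.shannon_index == pytest.approx(1.523, abs=5e-4)

    def test_value_at_mean_lands_in_class_six(self):
        # mean 1, sd 1: the extremes sit exactly one SD out, i.e. on the
        # class-4/5 and class-8/9 boundaries, and half-open intervals put
        # them in classes 4 and 8
        prof = stratify_ten_classes([0.0, 1.0, 2.0])
        assert prof.counts[5] == 1  # the value at the mean
        assert prof.counts[3] == 1 and prof.counts[7] == 1

    def test_extreme_class_closures(self):
        # nine values with mean 0 and sample SD 1: the extremes sit exactly
        # at mean +/- 2 SD and must land in the closed classes 1 and 10
        x = [-2.0] + [0.0] * 7 + [2.0]
        prof = stratify_ten_classes(x)
        assert prof.counts[0] == 1 and prof.counts[9] == 1
        assert prof.counts[5] == 7

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(5, 60)
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 10), size=n)
            prof = stratify_ten_classes(x)
            assert list(prof.counts) == brute_force_classes(x)

    def test_counts_and_frequencies_are_consistent(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        prof = stratify_ten_classes(x)
        assert prof.n == 500
        assert sum(prof.relative_frequencies) == pytest.approx(1.0, abs=1e-9)
        occupied = sum(c > 0 for c in prof.counts)
        assert 0 <= prof.shannon_index <= np.log(occupied) + 1e-12


class TestQualitativeProfile:
    def test_stargazer_color_index(self, registry):
        sz = next(t for t in registry if t.abbreviation == "SZ")
        prof = profile_from_counts((989, 1, 568), sz)
        assert round(prof.shannon_index, 2) == 0.66

    def test_single_category_zero_entropy(self, registry):
        lsc = next(t for t in registry if t.abbreviation == "LSC")
        prof = qualitative_profile([1] * 50, lsc)
        assert prof.shannon_index == 0.0

    def test_two_equal_categories_ln2(self, registry):
        slc = next(t for t in registry if t.abbreviation == "SLC")
        prof = qualitative_profile([1, 2] * 25, slc)
        assert prof.shannon_index == pytest.approx(np.log(2), abs=1e-12)

    def test_empty_vector_raises(self, registry):
        with pytest.raises(InsufficientDataError):
            qualitative_profile([], registry[11])

    @pytest.mark.parametrize("abbr", QUALITATIVE_CONSISTENT)
    def test_published_indices_recompute_from_counts(self, registry, abbr):
        t = next(t for t in registry if t.abbreviation == abbr)
        prof = profile_from_counts(QUALITATIVE_COUNTS[abbr], t)
        assert round(prof.shannon_index, 2) == QUALITATIVE_SHANNON[abbr]

    def test_swapped_rows_assert_recomputed_values(self, registry):
        # the published table transposes these two rows; the formulas win
        lsc = next(t for t in registry if t.abbreviation == "LSC")
        slc = next(t for t in registry if t.abbreviation == "SLC")
        assert round(
            profile_from_counts(QUALITATIVE_COUNTS["LSC"], lsc).shannon_index, 2
        ) == 0.87
        assert round(
            profile_from_counts(QUALITATIVE_COUNTS["SLC"], slc).shannon_index, 2
        ) == 0.44

    def test_hull_color_recomputed_index(self, registry):
        # published 0.44 does not recompute from its own counts; the
        # entropy of the printed seven-class distribution is 0.48
        hc = next(t for t in registry if t.abbreviation == "HC")
        prof = profile_from_counts(QUALITATIVE_COUNTS["HC"], hc)
        assert round(prof.shannon_index, 2) == 0.48


class TestQualitativeCV:
    @pytest.mark.parametrize("abbr", QUALITATIVE_CV_CONSISTENT)
    def test_published_cv_recomputes_from_counts(self, registry, abbr):
        t = next(t for t in registry if t.abbreviation == abbr)
        codes = codes_from_counts(QUALITATIVE_COUNTS[abbr], t)
        assert round(qualitative_cv(codes), 2) == QUALITATIVE_CV_PUBLISHED[abbr]

    def test_constant_codes_zero(self):
        assert qualitative_cv([2, 2, 2]) == 0.0

    def test_two_code_hand_example(self):
        assert qualitative_cv([1, 2]) == pytest.approx(47.14, abs=0.01)

    @given(
        st.lists(st.integers(min_value=1, max_value=5), min_size=2, max_size=50),
        st.floats(min_value=0.01, max_value=100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_cv_scale_invariance(self, codes, c):
        x = np.asarray(codes, dtype=float)
        cv = descriptive_stats(x).cv_percent
        scaled = descriptive_stats(c * x)
        assert scaled.cv_percent == pytest.approx(cv, rel=1e-9, abs=1e-9)
        assert scaled.range == pytest.approx(c * descriptive_stats(x).range, rel=1e-9)


class TestDiversityReport:
    def test_cohort_cvs_match_published_within_two_points(self, panel_cohort):
        quant, _ = diversity_report(panel_cohort)
        for _, row in quant.iterrows():
            assert row["cv_percent"] == pytest.approx(
                QUANTITATIVE_CV[row["abbreviation"]], abs=2.0
            ), row["abbreviation"]

    def test_count_percentage_formatting(self, panel_cohort):
        _, qual = diversity_report(panel_cohort)
        cell = qual.loc[qual["abbreviation"] == "LSC", "class_1"].item()
        count, pct = cell.split(" ")
        frac = 100 * int(count) / panel_cohort.n
        assert pct == f"({frac:.2f}%)"

    def test_empty_table_raises(self, registry, small_table):
        empty = PhenotypeTable(
            registry=registry, data=small_table.data.iloc[0:0]
        )
        with pytest.raises(InsufficientDataError):
            diversity_report(empty)

    def test_entropy_bounds_hold_for_all_traits(self, panel_cohort):
        quant, qual = diversity_report(panel_cohort)
        assert (quant["shannon_index"] >= 0).all()
        assert (quant["shannon_index"] <= np.log(10) + 1e-9).all()
        assert (qual["shannon_index"] >= 0).all()


def test_shannon_index_handles_zero_classes():
    assert shannon_index([0.5, 0.5, 0.0]) == pytest.approx(np.log(2))
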