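import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cypred.chemio import RawRecord
from cypred.curate import (
    MeasurementGroup,
    RejectedValue,
    aggregate_group,
    clip_or_reject,
    curate_groups,
    curate_records,
    flag_outlier_group,
    run_sensitivity,
    scaffold_summary,
    CuratedRecord,
)


def brute_force_aggregate(values, lo=20.0, hi=70.0):
    """Independent restatement of the piecewise interval rule."""
    if len(values) == 1:
        return values[0], "single"
    m = sum(values) / len(values)
    if m < lo:
        return min(values), "min"
    elif m > hi:
        return max(values), "max"
    return m, "mean"


class TestClipOrReject:
    @pytest.mark.parametrize(
        "value,expected", [(103.5, 100.0), (-2.0, 0.0), (50.0, 50.0), (0.0, 0.0), (100.0, 100.0)]
    )
    def test_clip_inside_window(self, value, expected):
        assert clip_or_reject(value, (-10, 110)) == expected

    @pytest.mark.parametrize("value", [250, -11, 110.1])
    def test_out_of_window_rejected(self, value):
        with pytest.raises(RejectedValue) as exc:
            clip_or_reject(value, (-10, 110))
        assert exc.value.reason == "out_of_window"

    @pytest.mark.parametrize("value", ["abc", None, float("nan")])
    def test_non_numeric_rejected(self, value):
        with pytest.raises(RejectedValue) as exc:
            clip_or_reject(value, (-10, 110))
        assert exc.value.reason == "non_numeric"


class TestAggregate:
    @pytest.mark.parametrize(
        "values,label,branch",
        [
            ([2, 30], 2, "min"),  # mean 16 < 20
            ([60, 95], 95, "max"),  # mean 77.5 > 70
            ([30, 50], 40, "mean"),
            ([55.0], 55.0, "single"),
            ([10, 30], 20, "mean"),  # boundary mean == lo stays in mean branch
            ([60, 80], 70, "mean"),  # boundary mean == hi stays in mean branch
        ],
    )
    def test_piecewise_rule(self, values, label, branch):
        assert aggregate_group(values) == (label, branch)

    def test_agrees_with_bruteforce_on_random_groups(self, rng):
        for _ in range(1000):
            vals = list(rng.uniform(0, 100, size=rng.integers(1, 6)))
            label, branch = aggregate_group(vals)
            exp_label, exp_branch = brute_force_aggregate(vals)
            assert branch == exp_branch
            assert np.isclose(label, exp_label, rtol=1e-12, atol=1e-12)

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_label_within_replicate_interval_and_permutation_invariant(self, vals):
        label, _ = aggregate_group(vals)
        assert min(vals) - 1e-9 <= label <= max(vals) + 1e-9
        assert aggregate_group(sorted(vals, reverse=True)) == aggregate_group(sorted(vals))

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            aggregate_group([])


class TestOutlierFlag:
    def test_high_spread_flagged(self):
        assert flag_outlier_group([10, 90], max_sd=30)  # sample sd 56.57
        assert np.isclose(np.std([10, 90], ddof=1), 56.5685, atol=1e-3)

    def test_low_spread_and_singletons_pass(self):
        assert not flag_outlier_group([40, 42], max_sd=30)
        assert not flag_outlier_group([50], max_sd=0.001)

    def test_retained_count_monotone_in_max_sd(self, rng):
        groups = [
            MeasurementGroup(f"m{i}", list(rng.uniform(0, 100, size=3))) for i in range(50)
        ]
        counts = [len(curate_groups(groups, max_sd=s)) for s in (60, 40, 20, 10, 5)]
        assert counts == sorted(counts, reverse=True)


class TestSensitivity:
    def test_singleton_dataset_is_threshold_invariant(self):
        groups = [MeasurementGroup(f"m{i}", [float(v)]) for i, v in enumerate([5, 30, 60, 95])]
        rep = run_sensitivity(groups, [10, 20, 30], [60, 70, 80])
        ns = {row[2] for row in rep.grid}
        means = {round(row[3], 9) for row in rep.grid}
        assert ns == {4} and len(means) == 1

    def test_baseline_cell_matches_direct_curation(self, rng):
        groups = [
            MeasurementGroup(f"m{i}", list(rng.uniform(0, 100, size=int(rng.integers(1, 4)))))
            for i in range(40)
        ]
        rep = run_sensitivity(groups, [10, 20, 30], [60, 70, 80])
        baseline = curate_groups(groups, 20, 70)
        cell = next(r for r in rep.grid if r[0] == 20 and r[1] == 70)
        assert cell[2] == len(baseline)
        assert np.isclose(cell[3], np.mean([r.label for r in baseline]))

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            run_sensitivity([], [50], [40])


class TestScaffoldSummary:
    def test_shared_benzene_scaffold(self):
        recs = [
            CuratedRecord(k, 50.0, 1, "single")
            for k in ["c1ccccc1", "Cc1ccccc1", "CCc1ccccc1"]
        ]
        assert scaffold_summary(recs) == (3, 1)

    def test_acyclic_molecules_form_one_class(self):
        recs = [CuratedRecord(k, 10.0, 1, "single") for k in ["CCCC", "CCCCC"]]
        assert scaffold_summary(recs) == (2, 1)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            scaffold_summary([])


def test_curate_records_end_to_end():
    records = [
        RawRecord("a1", "CCO", 30.0),
        RawRecord("a2", "OCC", 50.0),  # same molecule, different serialization
        RawRecord("b1", "c1ccccc1", 103.0),  # clips to 100
        RawRecord("c1", "invalid((", 50.0),  # structure rejection
        RawRecord("d1", "CCN", 400.0),  # value rejection
        RawRecord("e1", "CCCC", 10.0),
        RawRecord("e2", "CCCC", 95.0),  # sd 60 -> group flagged
    ]
    curated, rejections = curate_records(records, max_sd=30)
    by_key = {r.molecule_key: r for r in curated}
    eto = by_key["CCO"]
    assert eto.label == 40.0 and eto.branch == "mean" and eto.n_replicates == 2
    assert by_key["c1ccccc1"].label == 100.0
    assert "CCCC" not in by_key
    reasons = {r["reason"] for r in rejections}
    assert "unparseable" in reasons and "out_of_window" in reasons
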