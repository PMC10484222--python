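"""The 20-method menu, its application, and oracle equivalence."""

import statistics

import numpy as np
import pandas as pd
import pytest

from rtmv._masked import apply_treatment_masked, subject_values
from rtmv.datagen import sample_trial_arrays
from rtmv.specs import ContaminationSpec, DesignSpec, ExGaussianSpec
from rtmv.treatments import (
    TreatmentDomainError,
    TreatmentSpec,
    apply_treatment,
    menu_from_json,
    menu_to_json,
    parse_method_selection,
    select_methods,
    standard_table1_menu,
)

from conftest import make_table, random_balanced_table


def one_subject_table(rts):
    return make_table({(1, 1): rts, (1, 2): rts})


def test_menu_composition(menu):
    assert len(menu) == 20
    assert [s.id for s in menu] == list(range(1, 21))
    assert menu[0].family == "ignore"
    assert menu[1].family == "median" and menu[1].aggregation == "median"
    assert menu[2].family == "transform" and menu[2].transform_fn == "log"
    assert menu[3].transform_fn == "inverse"
    # ids 5-7: experiment scope, k = 2 / 2.5 / 3
    assert [(s.scope, s.sd_multiplier) for s in menu[4:7]] == [
        ("experiment", 2.0), ("experiment", 2.5), ("experiment", 3.0)
    ]
    # ids 8-11: subject scope, k = 1.5 / 2 / 2.5 / 3
    assert [(s.scope, s.sd_multiplier) for s in menu[7:11]] == [
        ("subject", 1.5), ("subject", 2.0), ("subject", 2.5), ("subject", 3.0)
    ]
    # ids 12-14: condition scope, k = 2 / 2.5 / 3
    assert [(s.scope, s.sd_multiplier) for s in menu[11:14]] == [
        ("condition", 2.0), ("condition", 2.5), ("condition", 3.0)
    ]
    # ids 15-20: fixed cutoffs, shared low bound of 100 ms
    assert all(s.low_cutoff == 100.0 for s in menu[14:])
    assert [s.high_cutoff for s in menu[14:]] == [800, 1000, 1200, 1500, 1750, 2000]
    # only the median-aggregation method departs from mean aggregation
    assert [s.id for s in menu if s.aggregation == "median"] == [2]


def test_spec_validation():
    with pytest.raises(ValueError):
        TreatmentSpec(1, "winsorize")
    with pytest.raises(ValueError):
        TreatmentSpec(1, "transform", transform_fn="sqrt")
    with pytest.raises(ValueError):  # both SD and fixed parameters
        TreatmentSpec(1, "truncate", sd_multiplier=2.0, scope="subject", low_cutoff=100.0)
    with pytest.raises(ValueError):
        TreatmentSpec(1, "truncate", sd_multiplier=2.0, scope="galaxy")


def test_ignore_and_median_are_identity(menu, small_table):
    for spec in menu[:2]:
        res = apply_treatment(small_table, spec)
        pd.testing.assert_frame_equal(res.table, small_table)
        assert res.n_removed == 0 and res.prop_removed == 0.0
    assert apply_treatment(small_table, menu[0]).aggregation == "mean"
    assert apply_treatment(small_table, menu[1]).aggregation == "median"


def test_transforms_preserve_rows_and_transform_rt(menu, small_table):
    res = apply_treatment(small_table, menu[2])
    assert len(res.table) == len(small_table) and res.n_removed == 0
    np.testing.assert_allclose(res.table["rt"], np.log(small_table["rt"]))
    res = apply_treatment(small_table, menu[3])
    np.testing.assert_allclose(res.table["rt"], 1.0 / small_table["rt"])


def test_transform_rejects_nonpositive_rt(menu):
    table = one_subject_table([100.0, -5.0, 300.0])
    for spec in menu[2:4]:
        with pytest.raises(TreatmentDomainError):
            apply_treatment(table, spec)


def test_fixed_cutoff_keeps_boundaries(menu):
    # method 16: keep 100 <= rt <= 1000
    table = one_subject_table([50.0, 100.0, 500.0, 900.0, 2500.0])
    res = apply_treatment(table, menu[15])
    kept = sorted(res.table.loc[res.table["condition"] == 1, "rt"])
    assert kept == [100.0, 500.0, 900.0]
    assert res.n_removed == 4  # two per condition in this mirrored table
    assert res.prop_removed == pytest.approx(0.4)


def test_experiment_sd_removes_extreme_value(menu):
    # method 5: experiment mean +/- 2 SD; mean ~866.67, sample SD ~1045.5,
    # upper bound ~2957.7, so only the 3000 goes
    table = make_table({(1, 1): [400, 420, 440], (1, 2): [460, 480, 3000]})
    res = apply_treatment(table, menu[4])
    assert sorted(res.table["rt"]) == [400, 420, 440, 460, 480]
    assert res.n_removed == 1


def test_experiment_sd_outlier_masking(menu):
    # a single huge value inflates the SD enough to protect itself
    table = make_table({(1, 1): [400, 500], (1, 2): [600, 5000]})
    res = apply_treatment(table, menu[4])
    assert res.n_removed == 0
    assert sorted(res.table["rt"]) == [400, 500, 600, 5000]


def naive_truncate(table: pd.DataFrame, spec: TreatmentSpec) -> list[int]:
    """Brute-force oracle: indices kept, recomputing centers/SDs from scratch."""
    kept = []
    for idx, row in table.iterrows():
        if spec.sd_multiplier is None:
            ok = spec.low_cutoff <= row["rt"] <= spec.high_cutoff
        else:
            if spec.scope == "experiment":
                pool = [r["rt"] for _, r in table.iterrows()]
            elif spec.scope == "subject":
                pool = [
                    r["rt"] for _, r in table.iterrows()
                    if r["subject"] == row["subject"]
                ]
            elif spec.scope == "condition":
                pool = [
                    r["rt"] for _, r in table.iterrows()
                    if r["subject"] == row["subject"]
                    and r["condition"] == row["condition"]
                ]
            else:  # condition_pooled
                pool = [
                    r["rt"] for _, r in table.iterrows()
                    if r["condition"] == row["condition"]
                ]
            center = statistics.fmean(pool)
            spread = statistics.stdev(pool) if len(pool) > 1 else float("inf")
            lo = center - spec.sd_multiplier * spread
            hi = center + spec.sd_multiplier * spread
            ok = lo <= row["rt"] <= hi
        if ok:
            kept.append(idx)
    return kept


def test_truncation_matches_bruteforce_oracle(menu):
    """Every truncation rule equals an independent re-implementation."""
    rng = np.random.default_rng(4242)
    truncators = [s for s in menu if s.family == "truncate"] + [
        TreatmentSpec(99, "truncate", sd_multiplier=2.0, scope="condition_pooled")
    ]
    for _ in range(25):
        table = random_balanced_table(rng, n_subjects=2, n_obs=3)  # 12 rows
        for spec in truncators:
            res = apply_treatment(table, spec)
            expected = table.loc[naive_truncate(table, spec)]
            pd.testing.assert_frame_equal(res.table, expected)


def test_subject_scope_is_local_to_each_subject(menu):
    """One subject's truncation decisions ignore every other subject's data."""
    spec = menu[8]  # subject scope, 2 SD
    rng = np.random.default_rng(7)
    table = random_balanced_table(rng, n_subjects=3, n_obs=6)
    res_all = apply_treatment(table, spec)
    for subj in table["subject"].unique():
        sub = table[table["subject"] == subj].copy()
        res_sub = apply_treatment(sub, spec)
        kept_all = res_all.table[res_all.table["subject"] == subj]
        pd.testing.assert_frame_equal(
            kept_all.reset_index(drop=True), res_sub.table.reset_index(drop=True)
        )


def test_condition_scope_is_local_to_each_cell(menu):
    spec = menu[11]  # condition scope, 2 SD
    rng = np.random.default_rng(8)
    table = random_balanced_table(rng, n_subjects=3, n_obs=6)
    res_all = apply_treatment(table, spec)
    for (subj, cond), cell in table.groupby(["subject", "condition"]):
        res_cell = apply_treatment(cell.copy(), spec)
        kept = res_all.table[
            (res_all.table["subject"] == subj) & (res_all.table["condition"] == cond)
        ]
        pd.testing.assert_frame_equal(
            kept.reset_index(drop=True), res_cell.table.reset_index(drop=True)
        )


def test_masked_kernel_matches_dataframe_path(menu):
    """The vectorized array kernels agree with the DataFrame implementation."""
    rng = np.random.default_rng(31)
    for trial in range(10):
        design = DesignSpec(n_subjects=5, n_obs=8, mu_diff=30.0)
        rt, flag = sample_trial_arrays(
            design, ExGaussianSpec(), ContaminationSpec(p=0.2), rng
        )
        from rtmv.datagen import arrays_to_table

        table = arrays_to_table(rt, flag)
        for spec in menu:
            masked = apply_treatment_masked(rt, spec)
            res = apply_treatment(table, spec)
            # same multiset of retained/transformed values
            np.testing.assert_allclose(
                np.sort(masked[~np.isnan(masked)]),
                np.sort(res.table["rt"].to_numpy()),
            )
            # same subject-level aggregates
            v = subject_values(masked, spec.aggregation)
            from rtmv.frequentist import aggregate_by_subject

            summ = aggregate_by_subject(res)
            ok = ~np.isnan(v).any(axis=1)
            np.testing.assert_allclose(v[ok][:, 0], summ["value_c1"])
            np.testing.assert_allclose(v[ok][:, 1], summ["value_c2"])


def test_no_treatment_increases_rows(menu, small_table):
    for spec in menu:
        res = apply_treatment(small_table, spec)
        assert len(res.table) <= len(small_table)
        if spec.family != "truncate":
            assert len(res.table) == len(small_table)
        assert res.n_removed == len(small_table) - len(res.table)


def test_menu_json_roundtrip(menu):
    assert menu_from_json(menu_to_json(menu)) == menu


def test_method_selection():
    assert parse_method_selection("1,3,5-8") == (1, 3, 5, 6, 7, 8)
    menu = standard_table1_menu()
    subset = select_methods(menu, (2, 15))
    assert [s.id for s in subset] == [2, 15]
    with pytest.raises(KeyError):
        select_methods(menu, (42,))
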