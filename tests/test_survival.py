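"""Survival estimators vs closed forms, brute force, and lifelines oracles."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.utils import concordance_index as ll_concordance
from sklearn.metrics import roc_auc_score

from gatsurv.cohort import CohortConfig, SurvivalOutcome, generate_cohort
from gatsurv.exceptions import ConfigurationError
from gatsurv.survival import (
    accuracy_at_median,
    concordance_index,
    kaplan_meier,
    log_rank_test,
    roc_auc,
    stratify_km,
)


# --- Kaplan-Meier ---------------------------------------------------------------

def test_km_two_events():
    km = kaplan_meier(np.array([1.0, 2.0]), np.array([1, 1]))
    np.testing.assert_allclose(km.survival, [0.5, 0.0])


def test_km_all_censored_is_one():
    km = kaplan_meier(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
    assert km.event_times.size == 0
    np.testing.assert_allclose(km.survival_at([0.5, 2.5]), [1.0, 1.0])


def test_km_hand_worked_product_limit():
    """times [1, 1.5, 2, 3], events [1,0,1,0]: S(1)=3/4, S(2)=3/8."""
    km = kaplan_meier(np.array([1.0, 1.5, 2.0, 3.0]), np.array([1, 0, 1, 0]))
    np.testing.assert_allclose(km.survival_at([1.0, 2.0]), [0.75, 0.375])


def test_km_censored_at_event_time_stays_in_risk_set():
    # censoring at t=2 happens after the event at t=2
    km = kaplan_meier(np.array([2.0, 2.0, 3.0]), np.array([1, 0, 1]))
    assert km.at_risk[0] == 3


def test_km_no_censoring_equals_empirical_survival(rng):
    for _ in range(20):
        t = rng.exponential(5, size=rng.integers(5, 40))
        km = kaplan_meier(t, np.ones(len(t), dtype=int))
        grid = np.sort(t)
        empirical = 1.0 - np.searchsorted(np.sort(t), grid, side="right") / len(t)
        np.testing.assert_allclose(km.survival_at(grid), empirical, atol=1e-12)


def test_km_matches_lifelines(rng):
    t = rng.exponential(10, 60)
    e = rng.integers(0, 2, 60)
    e[0] = 1
    km = kaplan_meier(t, e)
    ll = KaplanMeierFitter().fit(t, e)
    ours = km.survival_at(km.event_times)
    theirs = ll.survival_function_at_times(km.event_times).to_numpy()
    np.testing.assert_allclose(ours, theirs, atol=1e-10)


def test_km_negative_times_raise():
    with pytest.raises(ConfigurationError):
        kaplan_meier(np.array([-1.0, 2.0]), np.array([1, 1]))


# --- log-rank -------------------------------------------------------------------

def test_logrank_identical_groups_statistic_zero():
    t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    e = np.array([1, 1, 0, 1, 1, 0])
    g = np.array([0, 0, 0, 1, 1, 1])
    res = log_rank_test(t, e, g)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_label_swap_symmetry(rng):
    t = rng.exponential(5, 30)
    e = rng.integers(0, 2, 30)
    e[:4] = 1
    g = rng.integers(0, 2, 30)
    a = log_rank_test(t, e, g)
    b = log_rank_test(t, e, 1 - g)
    assert a.statistic == pytest.approx(b.statistic, rel=1e-10)


def test_logrank_hand_worked_four_subjects():
    """A: times [1,3] both events; B: times [2,4], event at 2 only.

    O-E per event time: 0.5, -1/3, 0.5; variances 0.25, 2/9, 0.25,
    so chi2 = (2/3)^2 / (13/18) = 8/13.
    """
    t = np.array([1.0, 3.0, 2.0, 4.0])
    e = np.array([1, 1, 1, 0])
    g = np.array([0, 0, 1, 1])
    res = log_rank_test(t, e, g)
    assert res.statistic == pytest.approx(8.0 / 13.0, rel=1e-12)
    np.testing.assert_allclose(res.table["O1"], [1, 0, 1])
    np.testing.assert_allclose(res.table["E1"], [0.5, 1.0 / 3.0, 0.5])
    np.testing.assert_allclose(res.table["V1"], [0.25, 2.0 / 9.0, 0.25])


def test_logrank_matches_lifelines(rng):
    t = rng.exponential(5, 50)
    e = rng.integers(0, 2, 50)
    e[:6] = 1
    g = rng.integers(0, 2, 50)
    res = log_rank_test(t, e, g)
    ll = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
    assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-8)
    assert res.p_value == pytest.approx(ll.p_value, rel=1e-6)


def test_logrank_two_group_internal_identity(rng):
    """The statistic equals the squared standardized O-E sum."""
    t = rng.exponential(5, 40)
    e = rng.integers(0, 2, 40)
    e[:5] = 1
    g = rng.integers(0, 2, 40)
    res = log_rank_test(t, e, g)
    z = (res.table["O1"] - res.table["E1"]).sum() / np.sqrt(res.table["V1"].sum())
    assert res.statistic == pytest.approx(z**2, rel=1e-10)


def test_logrank_three_groups(rng):
    t = rng.exponential(5, 60)
    e = np.ones(60, dtype=int)
    g = rng.integers(0, 3, 60)
    res = log_rank_test(t, e, g)
    assert res.df == 2
    from lifelines.statistics import multivariate_logrank_test

    ll = multivariate_logrank_test(t, g, e)
    assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-8)


def test_logrank_empty_group_raises():
    with pytest.raises(ConfigurationError):
        log_rank_test(np.array([1.0, 2.0]), np.array([1, 1]), np.array([0, 0]))


# --- concordance ----------------------------------------------------------------

def brute_force_c(risk, time, event):
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (time[i] < time[j] and event[i]) or (
                time[i] == time[j] and event[i] and not event[j]
            ):
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def test_c_index_known_values():
    assert concordance_index([3.0, 2.0, 1.0], np.array([1.0, 2.0, 3.0]),
                             np.array([1, 1, 1])) == 1.0
    assert concordance_index([1.0, 1.0, 1.0], np.array([1.0, 2.0, 3.0]),
                             np.array([1, 1, 1])) == 0.5
    # pairs (1,2) ok, (1,3) ok, (2,3) wrong -> 2/3
    assert concordance_index([3.0, 1.0, 2.0], np.array([1.0, 2.0, 3.0]),
                             np.array([1, 1, 0])) == pytest.approx(2.0 / 3.0)


def test_c_index_equals_brute_force_and_lifelines(rng):
    for _ in range(50):
        n = int(rng.integers(5, 40))
        risk = np.round(rng.normal(size=n), 1)  # rounding forces ties
        time = np.round(rng.exponential(5, n), 1)
        event = rng.integers(0, 2, n)
        if not event.any():
            event[0] = 1
        ours = concordance_index(risk, time, event)
        assert ours == pytest.approx(brute_force_c(risk, time, event), abs=1e-12)
        theirs = ll_concordance(time, -risk, event)
        assert ours == pytest.approx(theirs, abs=1e-12)


def test_c_index_no_comparable_pairs_raises():
    with pytest.raises(ConfigurationError):
        concordance_index([1.0, 2.0], np.array([1.0, 2.0]), np.array([0, 0]))


# --- AUC / accuracy -------------------------------------------------------------

def test_auc_known_values():
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)


def test_auc_constant_score_is_half():
    assert roc_auc([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1]) == pytest.approx(0.5)


def test_auc_agrees_with_all_event_c_index(rng):
    """With every subject an event and time = 1 - label, C reduces to AUC."""
    for _ in range(10):
        score = rng.normal(size=20)
        label = rng.integers(0, 2, 20)
        if len(np.unique(label)) < 2:
            continue
        c = concordance_index(score, 1.0 - label, np.ones(20, dtype=int))
        assert roc_auc(score, label) == pytest.approx(c, abs=1e-12)


def test_accuracy_at_median():
    acc = accuracy_at_median([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert acc == 1.0
    with pytest.raises(ConfigurationError):
        accuracy_at_median([0.1, 0.2], [1, 1])


# --- stratification -------------------------------------------------------------

STRAT_BASE = dict(
    n_samples=220,
    block_sizes={"mrna": 80, "mirna": 20, "meth": 40},
    n_informative={"mrna": 8, "mirna": 3, "meth": 5},
)


def test_stratify_strong_signal_separates_groups():
    ds = generate_cohort(CohortConfig(seed=21, **STRAT_BASE))
    res = stratify_km(ds)
    assert res.log_rank.p_value < 1e-4
    assert res.c_index > 0.7
    # median split is balanced to within one sample
    assert abs(res.high_mask.sum() - (~res.high_mask).sum()) <= 1
    # high-risk survival curve lies at or below the low-risk curve
    grid = np.unique(
        np.concatenate([res.km_high.event_times, res.km_low.event_times])
    )
    assert (res.km_high.survival_at(grid) <= res.km_low.survival_at(grid) + 1e-12).all()


def test_stratify_null_signal_not_significant():
    cfg = CohortConfig(
        seed=22,
        effect_sizes=(0.0, 0.0),
        clinical_effect=0.0,
        **STRAT_BASE,
    )
    res = stratify_km(generate_cohort(cfg))
    assert res.log_rank.p_value >= 0.05


def test_stratify_with_and_without_screen_both_separate_groups():
    """The before/after-selection comparison: both stratify a strong cohort,
    the screened model with far fewer components."""
    ds = generate_cohort(CohortConfig(seed=23, **STRAT_BASE))
    after = stratify_km(ds, screen=True)
    before = stratify_km(ds, screen=False)
    assert before.log_rank.p_value < 1e-3
    assert after.log_rank.p_value < 1e-3
    assert after.n_selected < before.n_selected
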