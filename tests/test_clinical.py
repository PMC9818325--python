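"""Tests for the carrier vs non-carrier clinical comparison and survival
machinery."""

import numpy as np
import pytest

from cpgburden import PhenotypeRecord, compare_groups, kaplan_meier, logrank_p


def make_record(i, carrier, rng, age_shift=0.0):
    return PhenotypeRecord(
        sample_id=f"S{i}",
        group="case",
        carrier_flags={"established": carrier},
        age_at_dx=float(np.clip(rng.normal(62 + age_shift, 9), 25, 95)),
        sex="M" if rng.random() < 0.77 else "F",
        etiology=["alcoholic", "viral", "NASH"][rng.integers(3)],
        cirrhosis=bool(rng.random() < 0.985),
        microangioinvasion=bool(rng.random() < 0.456),
        cholangio_differentiation=bool(rng.random() < 0.054),
        recurrence_post_tx=bool(rng.random() < 0.1),
        multiple_primary_tumors=bool(rng.random() < 0.171),
        diabetes=bool(rng.random() < 0.413),
        obesity=bool(rng.random() < 0.281),
        smoking=bool(rng.random() < 0.575),
        family_history=bool(rng.random() < 0.392),
        survival_months=float(rng.exponential(120)),
        event=bool(rng.random() < 0.5),
    )


def null_cohort(seed, n=1000):
    rng = np.random.default_rng(seed)
    return [make_record(i, i < n // 2, rng) for i in range(n)]


# ---------------------------------------------------------------------------
# compare_groups

def test_null_cohort_rejection_rate_is_calibrated():
    """With carriers and non-carriers drawn from one distribution, the
    family of per-characteristic tests rejects at close to the nominal 5%:
    the total rejection count over 20 seeds stays inside a conservative
    binomial envelope. (With ~13 characteristics per seed, demanding zero
    rejections per seed would itself be miscalibrated.)"""
    from scipy.stats import binom

    rejections = trials = 0
    for seed in range(20):
        report = compare_groups(null_cohort(seed, n=1000), "established")
        for c in report.comparisons:
            if c.testable:
                trials += 1
                rejections += c.p_value < 0.05
    assert rejections <= binom.ppf(0.999, trials, 0.05)


def test_shifted_age_is_detected():
    """A +10-year age shift in carriers is overwhelmingly significant by
    Mann-Whitney at n=500 per group."""
    rng = np.random.default_rng(3)
    records = [make_record(i, False, rng) for i in range(500)] + [
        make_record(500 + i, True, rng, age_shift=10.0) for i in range(500)
    ]
    report = compare_groups(records, "established")
    age = next(c for c in report.comparisons if c.characteristic == "age_at_dx")
    assert age.test == "mann-whitney"
    assert age.p_value < 1e-3


def test_constant_characteristic_flagged_untestable():
    rng = np.random.default_rng(5)
    records = [
        make_record(i, i % 2 == 0, rng).model_copy(update={"cirrhosis": True})
        for i in range(40)
    ]
    report = compare_groups(records, "established")
    cirrhosis = next(c for c in report.comparisons if c.characteristic == "cirrhosis")
    assert not cirrhosis.testable
    assert cirrhosis.p_value is None


def test_empty_stratum_untestable_not_an_error():
    rng = np.random.default_rng(6)
    records = [make_record(i, False, rng) for i in range(20)]
    report = compare_groups(records, "established")
    assert report.n_carriers == 0
    assert all(not c.testable for c in report.comparisons)


def test_missing_flag_raises():
    rng = np.random.default_rng(7)
    with pytest.raises(KeyError, match="MRN"):
        compare_groups([make_record(0, True, rng)], "MRN")


def test_t_test_option_dispatch():
    records = null_cohort(1, n=200)
    report = compare_groups(records, "established", continuous_test="t")
    age = next(c for c in report.comparisons if c.characteristic == "age_at_dx")
    assert age.test == "t-test"


# ---------------------------------------------------------------------------
# Kaplan-Meier

def test_km_all_censored_stays_at_one():
    curve = kaplan_meier([3.0, 7.0, 12.0], [False, False, False])
    assert all(s == pytest.approx(1.0) for _, s in curve)


def test_km_no_censoring_equals_empirical_survival():
    curve = dict(kaplan_meier([1.0, 2.0, 3.0], [True, True, True]))
    assert curve[1.0] == pytest.approx(2 / 3)
    assert curve[2.0] == pytest.approx(1 / 3)
    assert curve[3.0] == pytest.approx(0.0)


def test_km_matches_hand_computed_product_limit():
    """Six subjects, three events at t=2,5,8 and censorings at t=3,10,12:
    S(2)=5/6, S(5)=5/8, S(8)=5/12; hand-derived product-limit values."""
    times = [2.0, 3.0, 5.0, 8.0, 10.0, 12.0]
    events = [True, False, True, True, False, False]
    curve = dict(kaplan_meier(times, events))
    assert curve[2.0] == pytest.approx(5 / 6)
    assert curve[5.0] == pytest.approx(5 / 6 * 3 / 4)
    assert curve[8.0] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
    assert curve[12.0] == pytest.approx(curve[8.0])  # censoring changes nothing


def test_km_is_monotone_step_function_in_unit_interval():
    rng = np.random.default_rng(9)
    times = rng.exponential(50, size=200)
    events = rng.random(200) < 0.6
    curve = kaplan_meier(times, events)
    values = [s for _, s in curve]
    assert curve[0] == (0.0, 1.0)
    assert all(0 <= s <= 1 for s in values)
    assert all(a >= b for a, b in zip(values, values[1:]))


def test_km_empty_input_rejected():
    with pytest.raises(ValueError):
        kaplan_meier([], [])


# ---------------------------------------------------------------------------
# Log-rank

def test_logrank_identical_groups_p_one():
    times = [1.0, 2.0, 3.0, 4.0] * 2
    events = [True, True, False, True] * 2
    groups = ["a"] * 4 + ["b"] * 4
    assert logrank_p(times, events, groups) == pytest.approx(1.0)


def test_logrank_invariances():
    """The p-value ignores group label names and a constant time shift."""
    rng = np.random.default_rng(10)
    times = rng.exponential(40, size=80)
    events = rng.random(80) < 0.7
    groups = np.where(rng.random(80) < 0.5, "x", "y")
    p = logrank_p(times, events, groups)
    relabeled = np.where(groups == "x", "beta", "alpha")
    assert logrank_p(times, events, relabeled) == pytest.approx(p, rel=1e-9)
    assert logrank_p(times + 7.5, events, groups) == pytest.approx(p, rel=1e-9)


def test_logrank_single_group_rejected():
    with pytest.raises(ValueError, match="two non-empty groups"):
        logrank_p([1.0, 2.0], [True, True], ["a", "a"])


def _two_group_logrank_stat(order_labels, order_events):
    """Chi-square log-rank statistic for distinct event times (no ties),
    computed from scratch for the permutation oracle."""
    n = order_labels.shape[-1]
    at_risk = np.arange(n, 0, -1)
    n1 = np.flip(np.cumsum(np.flip(order_labels, axis=-1), axis=-1), axis=-1)
    frac = n1 / at_risk
    ev = order_events.astype(bool)
    u = (order_labels[..., ev] - frac[..., ev]).sum(axis=-1)
    v = (frac[..., ev] * (1 - frac[..., ev])).sum(axis=-1)
    return u**2 / v


def test_logrank_matches_permutation_oracle():
    """The asymptotic log-rank p agrees with a 20,000-draw permutation
    distribution of the independently coded statistic."""
    rng = np.random.default_rng(12)
    n = 60
    times = rng.exponential(30, size=n)
    times[: n // 2] *= 1.6  # moderate group difference
    events = rng.random(n) < 0.8
    labels = np.zeros(n)
    labels[: n // 2] = 1
    order = np.argsort(times)
    ordered_events = events[order]
    obs = _two_group_logrank_stat(labels[order], ordered_events)

    n_perm = 20_000
    perms = np.empty((n_perm, n))
    base = labels[order]
    for i in range(n_perm):
        perms[i] = rng.permutation(base)
    perm_stats = _two_group_logrank_stat(perms, ordered_events)
    perm_p = (perm_stats >= obs - 1e-12).mean()

    p = logrank_p(times, events, labels)
    mc_err = 3 * np.sqrt(perm_p * (1 - perm_p) / n_perm)
    assert p == pytest.approx(perm_p, abs=max(0.02, mc_err + 0.015))


def test_logrank_type_I_error_under_equal_hazards():
    """Exponential survival with hazard ratio 1, n=200 per group: over 50
    seeds the 5%-level rejection count stays in the binomial 95% band."""
    from scipy.stats import binom

    rejections = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        times = rng.exponential(100, size=400)
        events = times <= 120
        times = np.minimum(times, 120)
        groups = np.repeat(["a", "b"], 200)
        rejections += logrank_p(times, events, groups) < 0.05
    assert binom.ppf(0.025, 50, 0.05) <= rejections <= binom.ppf(0.975, 50, 0.05)
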