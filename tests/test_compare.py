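"""Strategy comparison: dose assignment, rank-sum test, correlation."""

import itertools
import math
import warnings

import numpy as np
import pytest
import scipy.stats

import allodose as ad
from allodose import (
    AllometricStrategy,
    BandTableStrategy,
    Patient,
    RoundingPolicy,
    assign_doses,
    dose_distribution,
    mann_whitney_u,
    pearson_r,
    run_comparison,
)
from allodose.errors import ConfigError, DomainError


def brute_force_mw_p(x, y):
    """Independent oracle: exact two-sided p by enumerating index splits
    and counting pairwise wins (no ranks involved)."""
    values = np.concatenate([x, y])
    n_total, nx = len(values), len(x)
    gt = (values[:, None] > values[None, :]) + 0.5 * (values[:, None] == values[None, :])
    np.fill_diagonal(gt, 0.0)
    mu = nx * (n_total - nx) / 2.0
    u_obs = sum(
        gt[i, j] for i in range(nx) for j in range(nx, n_total)
    )
    count = total = 0
    for split in itertools.combinations(range(n_total), nx):
        rest = [j for j in range(n_total) if j not in split]
        u = sum(gt[i, j] for i in split for j in rest)
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-9
        total += 1
    return count / total


@pytest.mark.parametrize(
    "x, y, expected_u, expected_p",
    [
        ([1, 2, 3], [4, 5, 6], 0.0, 2 / 20),  # fully separated, C(6,3) splits
        ([1, 2], [3, 4], 0.0, 2 / 6),
        ([4, 5, 6], [1, 2, 3], 9.0, 2 / 20),  # symmetry: same p from either side
    ],
)
def test_exact_p_known_enumerations(x, y, expected_u, expected_p):
    res = mann_whitney_u(x, y)
    assert res.method == "exact"
    assert res.u == expected_u
    assert res.p_value == pytest.approx(expected_p, abs=1e-12)


def test_identical_multisets_give_central_u_and_p_one():
    x = [1.0, 2.0, 3.0, 4.0]
    res = mann_whitney_u(x, list(x))
    assert res.u == len(x) ** 2 / 2
    assert res.p_value == pytest.approx(1.0)


def test_degenerate_all_tied_warns_and_returns_one():
    with pytest.warns(UserWarning, match="identical"):
        res = mann_whitney_u([5, 5, 5], [5, 5])
    assert res.p_value == 1.0
    assert res.method == "degenerate"


def test_exact_p_equals_bruteforce_oracle_with_ties():
    rng = np.random.default_rng(2024)
    for _ in range(40):
        nx, ny = rng.integers(2, 8, size=2)
        x = rng.integers(1, 8, nx).astype(float)
        y = rng.integers(1, 8, ny).astype(float)
        res = mann_whitney_u(x, y)
        if res.method == "degenerate":
            continue
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)


def test_u_conservation_and_scipy_crosschecks():
    rng = np.random.default_rng(5)
    for _ in range(30):
        nx, ny = rng.integers(3, 30, size=2)
        x = rng.normal(0, 1, nx)
        y = rng.normal(0.5, 1, ny)
        res = mann_whitney_u(x, y, method="normal")
        res_flip = mann_whitney_u(y, x, method="normal")
        assert res.u + res_flip.u == pytest.approx(nx * ny)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic")
        assert res.p_normal == pytest.approx(ref.pvalue, rel=1e-9)
        if max(nx, ny) <= 12:  # tie-free exact against scipy's exact routine
            ours = mann_whitney_u(x, y, method="exact")
            ref_exact = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                                 method="exact")
            assert ours.p_value == pytest.approx(ref_exact.pvalue, rel=1e-9)


def test_mw_input_validation():
    with pytest.raises(DomainError):
        mann_whitney_u([], [1.0])
    with pytest.raises(ConfigError):
        mann_whitney_u([1.0], [2.0], method="bootstrap")


def test_pearson_known_values():
    a = np.arange(10.0)
    assert pearson_r(a, 2 * a + 1).r == pytest.approx(1.0)
    assert pearson_r(a, -a).r == pytest.approx(-1.0)
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=50), rng.normal(size=50)
    ours = pearson_r(x, y)
    ref = scipy.stats.pearsonr(x, y)
    assert ours.r == pytest.approx(ref.statistic, rel=1e-12)
    assert ours.r_squared == pytest.approx(ours.r**2)


def test_pearson_null_distribution():
    """Independent pairs at n=1000: |r| < 0.1 in >= 95% of seeds."""
    rng = np.random.default_rng(0)
    hits = sum(
        abs(pearson_r(rng.normal(size=1000), rng.normal(size=1000)).r) < 0.1
        for _ in range(100)
    )
    assert hits >= 95


def test_pearson_domain_errors():
    with pytest.raises(DomainError):
        pearson_r([1, 2], [3, 4])  # too short
    with pytest.raises(DomainError):
        pearson_r([1, 2, 3], [3, 4])  # unequal
    with pytest.raises(DomainError):
        pearson_r([1, 1, 1], [3, 4, 5])  # zero variance


# --- dose assignment & full comparison ---


def test_assignment_examples(model, formulary, who_table):
    child = Patient("k", 9, 25.0)
    who = BandTableStrategy(who_table, formulary.unit_strength_mg)
    allo = AllometricStrategy(model, formulary)
    a_who = who.assign(child)
    assert (a_who.assigned_dose_mg, a_who.tablet_label) == (600.0, "adult")
    a_allo = allo.assign(child)
    assert (a_allo.assigned_dose_mg, a_allo.tablet_label) == (300.0, "2.5")
    assert a_allo.exact_dose_mg == pytest.approx(277.1932987750289)
    assert a_allo.tablets == 2.5


def test_assignment_via_reference_table(reference_table, formulary):
    strat = BandTableStrategy(reference_table, formulary.unit_strength_mg,
                              name="allometric-bands")
    res = strat.assign(Patient("k", 3, 8.2))
    assert res.assigned_dose_mg == 120.0


def test_dose_distribution_extremes(model, formulary, reference_table):
    heavy = [Patient(str(i), 12, 70.0) for i in range(5)]
    allo = AllometricStrategy(model, formulary)
    dist = dose_distribution(assign_doses(heavy, allo), adult_dose_mg=600.0)
    assert dist["allometric"].adult_fraction == 1.0
    light = [Patient(str(i), 2, 7.0 + 0.1 * i) for i in range(5)]
    table = BandTableStrategy(reference_table, 120.0, name="bands")
    dist = dose_distribution(assign_doses(light, table), adult_dose_mg=600.0)
    assert dist["bands"].counts == {"1": 5}
    assert dist["bands"].adult_fraction == 0.0


def test_allometric_assignment_within_one_step_of_exact(model, formulary, spec):
    cohort = ad.generate_cohort(spec, seed=17)
    steps = [s.dose_mg for s in formulary.steps]
    for a in assign_doses(cohort, AllometricStrategy(model, formulary)):
        idx = steps.index(a.assigned_dose_mg)
        neighbours = steps[max(idx - 1, 0): idx + 2]
        assert min(neighbours) <= a.exact_dose_mg <= max(neighbours)


def test_agreeing_strategies_give_null_result(reference_table, small_cohort):
    s1 = BandTableStrategy(reference_table, 120.0, name="one")
    s2 = BandTableStrategy(reference_table, 120.0, name="two")
    comparison = run_comparison(small_cohort, [s1, s2])
    assert comparison.mean_tablets["one"] == comparison.mean_tablets["two"]
    assert comparison.test.p_value == pytest.approx(1.0)


def test_single_patient_skips_test_with_warning(model, formulary, who_table):
    cohort = [Patient("solo", 8, 24.0)]
    with pytest.warns(UserWarning, match="skipped"):
        comparison = run_comparison(
            cohort,
            [BandTableStrategy(who_table, 120.0), AllometricStrategy(model, formulary)],
        )
    assert comparison.test is None
    assert any("skipped" in n for n in comparison.notes)
    assert comparison.correlation is None  # < 3 pairs


def test_run_comparison_structure(model, formulary, who_table, spec):
    cohort = ad.generate_cohort(spec, seed=1)
    comparison = run_comparison(
        cohort,
        [BandTableStrategy(who_table, 120.0), AllometricStrategy(model, formulary)],
    )
    for name, dist in comparison.distributions.items():
        assert sum(dist.counts.values()) == len(cohort)
    payload = comparison.to_dict()
    assert set(payload["strategies"]) == {"weight-band", "allometric"}
    assert 0 <= payload["mann_whitney"]["p_value"] <= 1
    assert -1 <= payload["age_weight_correlation"]["r"] <= 1
    report = ad.render_report(comparison)
    assert "Mann-Whitney" in report and "adult dose" in report
    with pytest.raises(ConfigError):
        run_comparison(cohort, [BandTableStrategy(who_table, 120.0)])
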