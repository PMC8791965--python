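"""Agreement statistics: R², MAE, Lin's CCC + CI, McBride classes, and the
modified Bland–Altman quantile curves."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gestage.evaluation import bland_altman_quantiles, evaluate, lin_ccc, \
    mae_days, mcbride_class, r2_score


def brute_r2(y, p):
    ybar = sum(y) / len(y)
    ss_res = sum((yi - pi) ** 2 for yi, pi in zip(y, p))
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    return 1 - ss_res / ss_tot


def brute_ccc(y, p):
    n = len(y)
    my, mp = sum(y) / n, sum(p) / n
    vy = sum((v - my) ** 2 for v in y) / n
    vp = sum((v - mp) ** 2 for v in p) / n
    cov = sum((a - my) * (b - mp) for a, b in zip(y, p)) / n
    return 2 * cov / (vy + vp + (my - mp) ** 2)


def test_r2_perfect_and_mean_predictor():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    assert r2_score(y, y) == 1.0
    assert r2_score(y, np.full(4, y.mean())) == 0.0


def test_r2_matches_two_pass_oracle_and_is_asymmetric():
    rng = np.random.default_rng(0)
    y, p = rng.normal(200, 30, 50), rng.normal(200, 30, 50)
    assert r2_score(y, p) == pytest.approx(brute_r2(list(y), list(p)),
                                           abs=1e-10)
    assert r2_score(y, p) != pytest.approx(r2_score(p, y), abs=1e-6)


def test_r2_rejects_constant_truth():
    with pytest.raises(ValueError):
        r2_score([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def test_mae_examples_and_oracle():
    y = np.array([210.0, 220.0, 230.0])
    assert mae_days(y, y + np.array([1.0, -2.0, 3.0])) == pytest.approx(2.0)
    assert mae_days(y, y) == 0.0
    rng = np.random.default_rng(1)
    a, b = rng.normal(size=40), rng.normal(size=40)
    assert mae_days(a, b) == pytest.approx(
        sum(abs(x - z) for x, z in zip(a, b)) / 40, abs=1e-12)


def test_ccc_worked_example_four_sevenths():
    """Unit-shifted sequence: cov=2/3, both variances 2/3, mean gap 1,
    hence rho_c = (4/3)/(7/3) = 4/7."""
    ccc, lo, hi = lin_ccc((1.0, 2.0, 3.0), (2.0, 3.0, 4.0))
    assert ccc == pytest.approx(4.0 / 7.0, abs=1e-12)
    assert lo <= ccc <= hi


def test_ccc_perfect_agreement_and_symmetry():
    rng = np.random.default_rng(3)
    y = rng.normal(210, 25, 30)
    ccc, lo, hi = lin_ccc(y, y)
    assert ccc == pytest.approx(1.0)
    assert lo <= ccc <= hi <= 1.0
    p = y + rng.normal(0, 5, 30)
    assert lin_ccc(y, p)[0] == pytest.approx(lin_ccc(p, y)[0], abs=1e-12)


def test_ccc_matches_definitional_oracle():
    rng = np.random.default_rng(4)
    for _ in range(20):
        y = rng.normal(200, 30, 25)
        p = 0.8 * y + rng.normal(5, 10, 25)
        assert lin_ccc(y, p)[0] == pytest.approx(
            brute_ccc(list(y), list(p)), abs=1e-10)


@given(st.integers(0, 10_000))
def test_ccc_never_exceeds_pearson_in_magnitude(seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=12)
    p = rng.normal(size=12)
    ccc = lin_ccc(y, p)[0]
    r = np.corrcoef(y, p)[0, 1]
    assert abs(ccc) <= abs(r) + 1e-12


def test_ccc_ci_narrows_with_sample_size():
    rng = np.random.default_rng(5)
    y = rng.normal(210, 25, 400)
    p = y + rng.normal(0, 8, 400)
    _, lo_big, hi_big = lin_ccc(y, p)
    _, lo_small, hi_small = lin_ccc(y[:30], p[:30])
    assert (hi_big - lo_big) < (hi_small - lo_small)


def test_ccc_rejects_constant_input():
    with pytest.raises(ValueError):
        lin_ccc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.mark.parametrize("ccc,expected", [
    (0.970, "substantial"),
    (0.89, "poor"),
    (0.995, "almost_perfect"),
    (0.90, "moderate"),
    (0.95, "substantial"),
    (0.99, "substantial"),
    (-0.5, "poor"),
])
def test_mcbride_bins(ccc, expected):
    assert mcbride_class(ccc) == expected


def test_mcbride_rejects_out_of_range():
    with pytest.raises(ValueError):
        mcbride_class(1.5)


def test_quantile_curves_constant_offset():
    rng = np.random.default_rng(6)
    y = np.sort(rng.uniform(130, 280, 60))
    curves = bland_altman_quantiles(y, y + 4.5)
    assert np.allclose(curves.curves, 4.5, atol=1e-9)


def test_quantile_curves_symmetric_noise_brackets_zero():
    rng = np.random.default_rng(7)
    y = rng.uniform(130, 280, 400)
    p = y + rng.normal(0, 6, 400)
    curves = bland_altman_quantiles(y, p)
    med = curves.curves[3]
    assert np.abs(med).mean() < 2.0
    assert np.all(curves.curves[0] < med) and np.all(med < curves.curves[-1])


def test_quantile_curves_detect_sign_change_at_knot():
    """Positive bias below a knot age and negative above it flips the sign
    of the median curve across the knot (the over-then-under-estimation
    pattern)."""
    rng = np.random.default_rng(8)
    y = np.sort(rng.uniform(140, 270, 300))
    knot = 34 * 7.0
    bias = np.where(y < knot, 5.0, -5.0)
    p = y + bias + rng.normal(0, 1.0, 300)
    curves = bland_altman_quantiles(y, p)
    med = curves.curves[3]
    assert med[curves.x < knot - 10][0] > 2.0
    assert med[-1] < -2.0


@given(st.integers(0, 10_000))
def test_quantile_curves_monotone_in_level(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(15, 80))
    y = rng.uniform(130, 280, n)
    p = y + rng.normal(0, rng.uniform(0.5, 20), n)
    curves = bland_altman_quantiles(y, p)
    assert np.all(np.diff(curves.curves, axis=0) >= -1e-12)


def test_quantile_curves_need_a_full_window():
    with pytest.raises(ValueError):
        bland_altman_quantiles(np.arange(10.0), np.arange(10.0))


def test_full_report_on_perfect_predictions():
    y = np.linspace(140, 270, 40)
    report = evaluate(y, y)
    assert report.r2 == 1.0
    assert report.mae == 0.0
    assert report.ccc == pytest.approx(1.0)
    assert report.mcbride == "almost_perfect"
    assert report.n == 40
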