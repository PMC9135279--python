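import numpy as np
import pytest

from cardiomea.heavytail import compare, fit_heavy_tails, histogram_spec
from cardiomea.synthetic import sample_quiescent_periods


def test_power_law_exponent_recovered():
    x = sample_quiescent_periods("power_law", {"alpha": 2.5, "xmin": 1.0}, 5000, 12345)
    rep = fit_heavy_tails(x)
    assert 2.4 <= rep.alpha <= 2.6


@pytest.mark.parametrize(
    "family,params,key,rel",
    [
        ("power_law", {"alpha": 2.5, "xmin": 1.0}, "alpha", 0.10),
        ("exponential", {"lam": 1.3, "xmin": 1.0}, "lam", 0.10),
        ("lognormal", {"mu": 0.5, "sigma": 0.8, "xmin": 0.5}, "sigma", 0.10),
        ("stretched_exponential", {"beta": 0.7, "lam": 2.0, "xmin": 0.3}, "beta", 0.10),
        ("truncated_power_law", {"alpha": 1.6, "lam": 0.05, "xmin": 1.0}, "alpha", 0.10),
    ],
)
def test_shape_parameter_recovery_per_family(family, params, key, rel):
    x = sample_quiescent_periods(family, params, 5000, 777)
    rep = fit_heavy_tails(x, xmin=params["xmin"], families=(family,))
    assert rep.fits[family].params[key] == pytest.approx(params[key], rel=rel)


def test_power_law_loses_to_exponential_on_exponential_data():
    x = sample_quiescent_periods("exponential", {"lam": 1.0, "xmin": 1.0}, 5000, 5)
    rep = fit_heavy_tails(x, xmin=1.0, families=("power_law", "exponential"))
    llr, p = compare(rep, "power_law", "exponential")
    assert llr < 0 and p < 0.05


def test_truncated_power_law_beats_exponential_on_its_own_data():
    x = sample_quiescent_periods(
        "truncated_power_law", {"alpha": 1.6, "lam": 0.02, "xmin": 1.0}, 5000, 9
    )
    rep = fit_heavy_tails(x, xmin=1.0,
                          families=("truncated_power_law", "exponential"))
    llr, p = compare(rep, "truncated_power_law", "exponential")
    assert llr > 0 and p < 0.05


def test_compare_is_antisymmetric_and_identity_is_null():
    x = sample_quiescent_periods("power_law", {"alpha": 2.2, "xmin": 1.0}, 2000, 3)
    rep = fit_heavy_tails(x, xmin=1.0)
    ab = compare(rep, "power_law", "lognormal")
    ba = compare(rep, "lognormal", "power_law")
    assert ab[0] == pytest.approx(-ba[0])
    assert ab[1] == pytest.approx(ba[1])
    assert compare(rep, "power_law", "power_law") == (0.0, 1.0)


def test_weibull_is_an_alias_for_stretched_exponential():
    x = sample_quiescent_periods("weibull", {"beta": 0.8, "lam": 1.5, "xmin": 0.5}, 1000, 4)
    rep = fit_heavy_tails(x, xmin=0.5, families=("weibull", "power_law"))
    assert "stretched_exponential" in rep.fits
    llr, _ = compare(rep, "weibull", "power_law")
    assert np.isfinite(llr)


def test_generating_family_wins_llr_in_most_replicates():
    """Power law vs exponential, 100 seeded replicates each way at n = 5000."""
    wins = 0
    for s in range(100):
        x = sample_quiescent_periods("power_law", {"alpha": 2.5, "xmin": 1.0}, 5000, 10_000 + s)
        rep = fit_heavy_tails(x, xmin=1.0, families=("power_law", "exponential"))
        llr, _ = compare(rep, "power_law", "exponential")
        wins += llr > 0
    assert wins >= 95


def test_small_sample_advises_pooling():
    with pytest.raises(ValueError, match="pool"):
        fit_heavy_tails(np.arange(1.0, 6.0))


def test_zeros_rejected():
    x = np.concatenate([np.zeros(3), np.arange(1.0, 20.0)])
    with pytest.raises(ValueError, match="positive"):
        fit_heavy_tails(x)


def test_sturges_rule_bins():
    edges, grid = histogram_spec(np.arange(1.0, 129.0), "auto")
    assert len(edges) - 1 == 8
    edges25, _ = histogram_spec(np.arange(1.0, 129.0), 25)
    assert len(edges25) - 1 == 25
    assert grid.size > 0


def test_single_value_cannot_be_binned():
    with pytest.raises(ValueError):
        histogram_spec(np.array([1.0]))


# --- sampler oracles -------------------------------------------------------


def test_power_law_sampler_matches_analytic_ccdf():
    x = sample_quiescent_periods("power_law", {"alpha": 2.5, "xmin": 1.0}, 5000, 2024)
    xs = np.sort(x)
    emp = 1.0 - np.arange(1, xs.size + 1) / xs.size
    model = (xs / 1.0) ** (1.0 - 2.5)
    assert np.max(np.abs(emp - model)) < 0.03


def test_exponential_sampler_mean_within_3_se():
    lam = 1.0
    x = sample_quiescent_periods("exponential", {"lam": lam, "xmin": 0.0}, 5000, 7)
    se = 1.0 / lam / np.sqrt(x.size)
    assert abs(x.mean() - 1.0 / lam) < 3 * se


def test_empty_sample_request():
    assert sample_quiescent_periods("power_law", {"alpha": 2.0}, 0, 1).size == 0


def test_sampler_deterministic_per_seed():
    a = sample_quiescent_periods("truncated_power_law", {"alpha": 1.5, "lam": 0.1}, 500, 11)
    b = sample_quiescent_periods("truncated_power_law", {"alpha": 1.5, "lam": 0.1}, 500, 11)
    np.testing.assert_array_equal(a, b)
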