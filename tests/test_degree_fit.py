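import math

import numpy as np
import pytest

from coprune.degree_fit import (
    FAMILIES,
    DegreeSample,
    DistributionFit,
    empirical_ccdf,
    fit_family,
    sample_degrees,
    select_best,
)
from coprune.errors import DegenerateInputError, FitDegenerateError


def test_ccdf_simple_example():
    ccdf = empirical_ccdf(DegreeSample(degrees=[1, 2, 3]))
    assert ccdf.x.tolist() == [1, 2, 3]
    assert ccdf.prob.tolist() == pytest.approx([1.0, 2 / 3, 1 / 3])


def test_ccdf_with_ties_and_offset_minimum():
    ccdf = empirical_ccdf(DegreeSample(degrees=[2, 2, 5, 7]))
    assert ccdf.x.tolist() == [2, 5, 7]
    assert ccdf.prob.tolist() == pytest.approx([1.0, 0.5, 0.25])
    assert ccdf.prob[0] == 1.0  # always 1 at the smallest observed degree


def test_degree_sample_rejects_zeros_and_empty():
    with pytest.raises(DegenerateInputError):
        DegreeSample(degrees=[0, 1, 2])
    with pytest.raises(DegenerateInputError):
        DegreeSample(degrees=[])


def test_exponential_closed_form():
    sample = DegreeSample(degrees=[1, 2, 3, 4])  # mean 2.5
    fit = fit_family(sample, "exponential")
    assert fit.params["lambda"] == pytest.approx(-math.log(1 - 1 / 2.5))
    # log-likelihood of the geometric law at the MLE
    p = 1 / 2.5
    ll = 4 * math.log(p) + (10 - 4) * math.log(1 - p)
    assert fit.log_likelihood == pytest.approx(ll)
    assert fit.aic == pytest.approx(2 - 2 * ll)


def test_all_ones_sample_is_unidentifiable():
    # with every degree equal to 1 no family has an interior MLE
    with pytest.raises(DegenerateInputError, match="no family"):
        select_best(DegreeSample(degrees=[1, 1, 1, 1]))


def test_partially_degenerate_sample_still_reports():
    # mean degree exactly 1 except a single 2: exponential fits, and families
    # that cannot be fit are recorded with reasons instead of aborting
    report = select_best(DegreeSample(degrees=[1, 1, 1, 2]))
    assert report.best_family in report.fits
    assert isinstance(report.degenerate, dict)


def test_truncated_family_nests_both_one_parameter_families():
    rng = np.random.default_rng(3)
    deg = rng.geometric(0.4, size=400)
    sample = DegreeSample(degrees=deg)
    ll_exp = fit_family(sample, "exponential").log_likelihood
    ll_pl = fit_family(sample, "power_law").log_likelihood
    ll_tpl = fit_family(sample, "truncated_power_law").log_likelihood
    assert ll_tpl >= max(ll_exp, ll_pl) - 1e-6


def test_aic_prefers_parsimony_on_exponential_data():
    rng = np.random.default_rng(11)
    deg = rng.geometric(0.35, size=2000)
    report = select_best(DegreeSample(degrees=deg))
    assert report.best_family == "exponential"
    assert report.delta_aic["exponential"] == 0.0


def test_distribution_fit_validates_aic():
    with pytest.raises(ValueError, match="aic"):
        DistributionFit(family="exponential", params={"lambda": 1.0},
                        log_likelihood=-10.0, n_params=1, aic=5.0)


def test_fit_family_unknown_name():
    with pytest.raises(ValueError, match="unknown family"):
        fit_family(DegreeSample(degrees=[1, 2]), "weibull")


@pytest.mark.parametrize("family,params", [
    ("exponential", {"lambda": 0.5}),
    ("power_law", {"gamma": 2.5}),
    ("truncated_power_law", {"gamma": 1.2, "kappa": 0.1}),
    ("log_normal", {"mu": 0.8, "sigma": 0.9}),
])
def test_samplers_respect_support(family, params):
    deg = sample_degrees(family, params, 500, np.random.default_rng(0))
    assert deg.shape == (500,)
    assert (deg >= 1).all()


def test_report_serializes():
    report = select_best(DegreeSample(degrees=[1, 1, 2, 3, 5, 8]))
    d = report.to_dict()
    assert d["best_family"] == report.best_family
    assert set(d["fits"]).issubset(set(FAMILIES))
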