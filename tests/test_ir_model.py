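import numpy as np
import pytest

from conftest import make_freq
from coprune import (
    calibrate_p,
    cooccurrence_network,
    ensemble,
    expected_links,
    interaction_probability,
    random_prune,
    realize_ir,
)
from coprune.errors import DegenerateInputError, InfeasibleTargetError


def test_interaction_probability_hand_values():
    assert interaction_probability(0.1, 1) == pytest.approx(0.1)
    assert interaction_probability(0.5, 2) == pytest.approx(0.75)
    assert interaction_probability(1.0, 3) == 1.0
    assert interaction_probability(1.0, 0) == 0.0
    assert interaction_probability(0.0, 5) == 0.0


def test_interaction_probability_vectorized_and_validated():
    out = interaction_probability(0.2, np.array([[0, 1], [2, 3]]))
    assert out.shape == (2, 2)
    assert out[0, 0] == 0.0
    assert np.all(np.diff(out.ravel()) > 0)  # increasing in shared-site count
    with pytest.raises(DegenerateInputError):
        interaction_probability(1.5, 1)
    with pytest.raises(DegenerateInputError):
        interaction_probability(0.5, 1.5)


def test_expected_links_single_consumer():
    # N = (2, 1), p = 0.5: (0.75 + 0.5) / (1 - 0.5^3) = 1.25 / 0.875
    freq = make_freq([[2, 1]])
    assert expected_links(freq, 0.5) == pytest.approx(1.25 / 0.875)


def test_expected_links_two_consumers():
    freq = make_freq([[1, 1], [0, 1]])
    p = 0.3
    # consumer 0: 2p / (1 - (1-p)^2); consumer 1 contributes exactly 1
    want = 2 * p / (1 - (1 - p) ** 2) + 1.0
    assert expected_links(freq, p) == pytest.approx(want)


def test_expected_links_rejects_isolated_consumer():
    with pytest.raises(DegenerateInputError, match="no co-occurring"):
        expected_links(make_freq([[1, 1], [0, 0]]), 0.5)


def test_expected_links_monotone_and_bounded():
    freq = make_freq([[3, 1, 0], [2, 2, 1]])
    grid = [1e-6, 1e-3, 0.05, 0.3, 0.8, 1.0]
    values = [expected_links(freq, p) for p in grid]
    assert all(a < b for a, b in zip(values, values[1:]))
    n_consumers, L_c = 2, 5
    assert values[0] == pytest.approx(n_consumers, abs=1e-3)
    assert values[-1] == pytest.approx(L_c)


def test_calibration_recovers_expected_links():
    freq = make_freq([[3, 1, 0], [2, 2, 1]])
    cal = calibrate_p(freq, 0.7)
    assert cal.converged
    assert expected_links(freq, cal.p) == pytest.approx(0.7 * cal.L_c, abs=1e-8)


def test_calibration_infeasible_targets():
    freq = make_freq([[1, 1], [0, 1]])  # L_c = 3, floor = 2 consumers
    with pytest.raises(InfeasibleTargetError, match="conditioning"):
        calibrate_p(freq, 2 / 3)  # target 2 links = the floor
    with pytest.raises(DegenerateInputError):
        calibrate_p(freq, 1.2)


def test_calibration_saturates_at_one():
    cal = calibrate_p(make_freq([[2, 1]]), 1.0)
    assert cal.p == 1.0 and cal.expected_L_at_p == cal.L_c


def test_ir_realization_keeps_every_consumer_connected():
    freq = make_freq([[1, 0, 0], [5, 3, 1]])
    for s in range(20):
        net = realize_ir(freq, 0.01, seed=s)
        assert (net.adjacency.sum(axis=1) >= 1).all()
        assert net.is_subset_of(cooccurrence_network(freq))


def test_ir_ensemble_mean_matches_expectation():
    freq = make_freq([[3, 1], [2, 2]])
    p = 0.3
    ens = ensemble(freq, p, "ir", n_realizations=3000, seed=42)
    want = expected_links(freq, p)
    links = np.array([net.n_links for net in ens.realizations])
    se = links.std() / np.sqrt(links.size)
    assert abs(links.mean() - want) < 4 * se + 1e-12


def test_random_prune_mean_matches_keep_fraction():
    cooc = cooccurrence_network(make_freq([[3, 1, 2], [2, 2, 0], [1, 0, 4]]))
    f = 0.4
    links = [random_prune(cooc, f, seed=s).n_links for s in range(2000)]
    # Binomial(L_c=7, 0.4): mean 2.8, sd ~1.30
    assert np.mean(links) == pytest.approx(7 * f, abs=4 * 1.30 / np.sqrt(2000))


def test_ensemble_reproducibility():
    freq = make_freq([[3, 1], [2, 2]])
    a = ensemble(freq, 0.3, "ir", n_realizations=5, seed=7)
    b = ensemble(freq, 0.3, "ir", n_realizations=5, seed=7)
    c = ensemble(freq, 0.3, "ir", n_realizations=5, seed=8)
    assert all(x == y for x, y in zip(a.realizations, b.realizations))
    assert any(x != y for x, y in zip(a.realizations, c.realizations))


def test_ensemble_rejects_unknown_mode():
    with pytest.raises(ValueError, match="mode"):
        ensemble(make_freq([[1]]), 0.3, "bootstrap", 2, seed=0)
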