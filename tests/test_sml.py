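import numpy as np
import pytest

from reactivepgg import (
    GameParams,
    PairPayoffTable,
    PopulationParams,
    classify_dominant_bits,
    decode_strategy,
    embedded_transition_matrix,
    enumerate_strategies,
    fixation_probability,
    level_of_cooperation,
    monomorphic_cooperation_rate,
    named_strategy,
    run_sml,
    stationary_bit_distribution,
    stationary_distribution,
    sweep,
)
from reactivepgg.sml import compute_pair_data


@pytest.fixture(scope="module")
def small_params():
    return GameParams.from_f_over_n(2, 0.85, w=0.96, eps=0.05)


def test_embedded_matrix_neutral_is_uniform(small_params):
    pop = PopulationParams(Z=30, beta=0.0)
    strategies = enumerate_strategies(2)
    L = embedded_transition_matrix(strategies, small_params, pop)
    off = L[~np.eye(16, dtype=bool)]
    np.testing.assert_allclose(off, 1.0 / (30 * 15), atol=1e-12)
    np.testing.assert_allclose(L.sum(axis=1), 1.0, atol=1e-12)


def test_embedded_matrix_half_error_rate_is_uniform(small_params):
    pop = PopulationParams(Z=30, beta=1.0)
    L = embedded_transition_matrix(
        enumerate_strategies(2), small_params.with_eps(0.5), pop
    )
    off = L[~np.eye(16, dtype=bool)]
    np.testing.assert_allclose(off, 1.0 / (30 * 15), atol=1e-12)


def test_batched_pair_pipeline_matches_game_engine(small_params):
    """The four-row indexed fast path must agree with the generic per-pair
    route through the exact round chain."""
    gp = GameParams(N=3, F=2.55, w=0.9, eps=0.07)
    strategies = enumerate_strategies(3)
    bits = np.array([s.bits for s in strategies], dtype=np.int8)
    pd_ = compute_pair_data(bits, gp, PopulationParams(Z=20, beta=1.0))
    rng = np.random.default_rng(5)
    for p in rng.integers(0, pd_.i_idx.size, size=12):
        a = strategies[pd_.i_idx[p]]
        b = strategies[pd_.j_idx[p]]
        table = PairPayoffTable.build(a, b, gp)
        np.testing.assert_allclose(pd_.pi_a[p, 1:], table.pi_a[1:], atol=1e-10)
        np.testing.assert_allclose(pd_.pi_b[p, :3], table.pi_b[:3], atol=1e-10)
        np.testing.assert_allclose(pd_.coop[p], table.coop_rate, atol=1e-10)


def test_batched_fixation_matches_direct(small_params):
    gp = GameParams(N=3, F=2.55, w=0.9, eps=0.07)
    pop = PopulationParams(Z=20, beta=1.0)
    strategies = enumerate_strategies(3)
    bits = np.array([s.bits for s in strategies], dtype=np.int8)
    pd_ = compute_pair_data(bits, gp, pop)
    rng = np.random.default_rng(9)
    for p in rng.integers(0, pd_.i_idx.size, size=8):
        a, b = strategies[pd_.i_idx[p]], strategies[pd_.j_idx[p]]
        assert pd_.rho_a[p] == pytest.approx(
            fixation_probability(a, b, gp, pop), rel=1e-9
        )
        assert pd_.rho_b[p] == pytest.approx(
            fixation_probability(b, a, gp, pop), rel=1e-9
        )


def test_stationary_distribution_uniform_chain():
    L = np.full((8, 8), 1.0 / 8)
    tau = stationary_distribution(L)
    np.testing.assert_allclose(tau, 1.0 / 8, atol=1e-12)


def test_stationary_distribution_concentrates_on_favored_state():
    # state 0 strongly absorbs: large rho into it, tiny out of it
    L = np.array([[0.999, 0.0005, 0.0005],
                  [0.2, 0.8, 0.0],
                  [0.2, 0.0, 0.8]])
    tau = stationary_distribution(L)
    assert tau[0] > 0.99


def test_stationary_is_fixed_point_on_full_system(headline_sml):
    """Self-consistency on the full 128-strategy chain at the headline
    parameters: residual below 1e-10 and tau sums to one."""
    from reactivepgg.sml import embedded_transition_matrix

    L = embedded_transition_matrix(
        headline_sml.strategy_set, headline_sml.game_params, headline_sml.pop,
        headline_sml.pair_data,
    )
    tau = headline_sml.tau
    assert tau.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.max(np.abs(tau @ L - tau)) < 1e-10


def test_two_strategy_chain_detailed_balance(small_params):
    """On a two-state chain the stationary ratio equals the fixation ratio."""
    gp = GameParams.from_f_over_n(5, 0.85, w=0.96, eps=0.05)
    pop = PopulationParams(Z=100, beta=1.0)
    aon = named_strategy("AoN", 5, first_move=0)
    alld = named_strategy("AllD", 5)
    res = run_sml(gp, pop, strategy_set=[aon, alld])
    rho_aon = fixation_probability(aon, alld, gp, pop)
    rho_alld = fixation_probability(alld, aon, gp, pop)
    assert res.tau[0] / res.tau[1] == pytest.approx(rho_aon / rho_alld, rel=1e-8)


def test_bit_distribution_uniform_tau(small_params):
    strategies = enumerate_strategies(2)
    tau = np.full(16, 1 / 16)
    np.testing.assert_allclose(
        stationary_bit_distribution(tau, strategies), 0.5, atol=1e-12
    )


def test_bit_distribution_delta_at_aon():
    strategies = [named_strategy("AoN", 5, first_move=0), named_strategy("AllD", 5)]
    tau = np.array([1.0, 0.0])
    np.testing.assert_allclose(
        stationary_bit_distribution(tau, strategies), [0, 1, 0, 0, 0, 0, 1]
    )


def test_classify_dominant_bits():
    call = classify_dominant_bits(np.array([0.8, 0.5, 0.2, 0.75, 0.25]))
    assert call.labels == (
        "cooperative", "undecided", "defective", "cooperative", "defective"
    )
    with pytest.raises(ValueError):
        classify_dominant_bits(np.array([0.5]), hi=0.2, lo=0.3)


def test_monomorphic_cooperation_rates():
    gp = GameParams(N=5, F=4.0, w=0.96, eps=0.0)
    assert monomorphic_cooperation_rate(named_strategy("AllC", 5), gp) == pytest.approx(1.0)
    assert monomorphic_cooperation_rate(named_strategy("AllD", 5), gp) == pytest.approx(0.0)
    aon = named_strategy("AoN", 5, first_move=0)
    assert monomorphic_cooperation_rate(aon, gp) == pytest.approx(0.96, abs=1e-12)


def test_level_of_cooperation_weights():
    assert level_of_cooperation(np.array([0.25, 0.75]), np.array([0.0, 1.0])) == 0.75


def test_neutral_limit_full_space(small_params):
    """beta = 0: uniform tau, B = 0.5 everywhere, eta = 0.5 by the
    cooperate/defect symmetry of the full strategy space."""
    res = run_sml(small_params, PopulationParams(Z=30, beta=0.0))
    np.testing.assert_allclose(res.tau, 1 / 16, atol=1e-10)
    np.testing.assert_allclose(res.bit_dist, 0.5, atol=1e-8)
    assert res.eta == pytest.approx(0.5, abs=1e-8)


def test_half_error_full_space_is_neutral(small_params):
    res = run_sml(small_params.with_eps(0.5), PopulationParams(Z=30, beta=1.0))
    np.testing.assert_allclose(res.bit_dist, 0.5, atol=1e-8)


def test_wsls_tops_stationary_distribution_at_n2(small_params):
    """At N = 2 the most visited strategy carries the Win-Stay-Lose-Shift
    response profile (cooperate after 0 or 2 cooperators, defect after 1)."""
    res = run_sml(small_params, PopulationParams(Z=100, beta=1.0))
    top = res.strategy_set[int(np.argmax(res.tau))]
    assert top.bits[1:] == (1, 0, 1)


def test_subset_with_random_strategist(small_params):
    sset = [
        named_strategy("AoN", 2, first_move=0),
        named_strategy("AllD", 2),
        named_strategy("AllC", 2),
        named_strategy("RS", 2),
    ]
    res = run_sml(small_params, PopulationParams(Z=30, beta=1.0), strategy_set=sset)
    assert res.tau.shape == (4,)
    assert res.tau.sum() == pytest.approx(1.0)
    assert res.coop_rates[3] == pytest.approx(0.5, abs=1e-10)  # RS flips coins


def test_sweep_eps_and_errors(small_params):
    pop = PopulationParams(Z=30, beta=1.0)
    df = sweep("eps", [0.05, 0.5], small_params, pop)
    assert list(df["eps"]) == [0.05, 0.5]
    np.testing.assert_allclose(
        df.loc[1, [f"B_{q}" for q in range(-1, 3)]].astype(float), 0.5, atol=1e-8
    )
    with pytest.raises(ValueError):
        sweep("eps", [], small_params, pop)
    with pytest.raises(ValueError):
        sweep("nope", [0.1], small_params, pop)


def test_sweep_n_holds_f_over_n(small_params):
    pop = PopulationParams(Z=30, beta=1.0)
    df = sweep("N", [2, 3], small_params, pop, f_over_n=0.85)
    assert "B_3" in df.columns
    assert df.loc[0, "B_2"] == pytest.approx(
        run_sml(small_params, pop).bit_dist[-1]
    )


def test_result_frames(headline_sml):
    sf = headline_sml.to_strategy_frame()
    assert len(sf) == 128
    assert sf["tau"].sum() == pytest.approx(1.0)
    bf = headline_sml.to_bit_frame()
    assert list(bf["q"]) == list(range(-1, 6))
    assert set(bf["call"]) <= {"cooperative", "defective", "undecided"}
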