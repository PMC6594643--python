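"""Per-variant functional-impact statistics and the empirical null."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from indelfx.features import PropertyTrack
from indelfx.impact import (NullDistribution, empirical_p, evaluate_impact,
                            fdr_from_rates, impact_score, is_single_residue,
                            naive_alpha_estimate, predicted_flag,
                            prior_correct, rank_mechanisms)
from indelfx.variants import IndelVariant, impacted_residues


def track_with_hits(L, hits, mechanism="m", alpha=None):
    scores = np.zeros(L)
    for h in hits:
        scores[h - 1] = 1.0
    return PropertyTrack(mechanism=mechanism, scores=scores,
                         confident_threshold=0.5, alpha=alpha)


def test_impact_score_intersects_window():
    v = IndelVariant("P", 5, 6, "AA", "")
    # impact window is {2..9}; confident residues at 5, 9 and 15
    track = track_with_hits(20, [5, 9, 15])
    assert impact_score(v, track) == 2


def test_impact_score_zero_track():
    v = IndelVariant("P", 5, 6, "AA", "")
    assert impact_score(v, track_with_hits(20, [])) == 0


def test_impact_score_saturated_track():
    v = IndelVariant("P", 5, 6, "AA", "")
    track = track_with_hits(20, range(1, 21))
    assert impact_score(v, track) == 8  # |{2..9}|


@settings(derandomize=True, max_examples=200)
@given(st.integers(0, 2**31 - 1))
def test_impact_score_matches_bruteforce_intersection(seed):
    rng = np.random.default_rng(seed)
    L = int(rng.integers(8, 60))
    scores = rng.uniform(size=L)
    track = PropertyTrack("m", scores, 0.5)
    start = int(rng.integers(1, L + 1))
    end = int(rng.integers(start, min(L, start + 5) + 1))
    v = IndelVariant("P", start, end, "A" * (end - start + 1), "")
    expected = sum(1 for r in impacted_residues(v, L, "impact")
                   if scores[r - 1] >= 0.5)
    assert impact_score(v, track) == expected


def test_empirical_p_conventions():
    null = NullDistribution("m", np.array([1, 2, 3, 4]))
    assert empirical_p(1, null) == 1.0
    assert empirical_p(3, null) == 0.5
    assert empirical_p(5, null) == 0.0
    assert empirical_p(5, null, add_one=True) == pytest.approx(1 / 5)


def test_null_distribution_validation():
    with pytest.raises(ValueError):
        NullDistribution("m", np.array([]))
    with pytest.raises(ValueError):
        NullDistribution("m", np.array([1.5]))


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 2**31 - 1))
def test_empirical_p_is_superuniform_on_null_draws(seed):
    rng = np.random.default_rng(seed)
    null = NullDistribution("m", rng.poisson(2.0, size=500))
    draws = null.scores[rng.integers(0, 500, size=200)]
    for q in (0.1, 0.3):
        frac = np.mean([empirical_p(s, null) <= q for s in draws])
        assert frac <= q + 0.08  # super-uniform up to sampling noise


def test_prior_correct_values_and_ordering():
    assert prior_correct(0.04, 0.0) == 0.04
    assert prior_correct(0.04, 0.25) == pytest.approx(0.03)
    assert prior_correct(0.04, 0.999) < 1e-4
    # ordering preserved within a mechanism
    assert prior_correct(0.02, 0.3) <= prior_correct(0.04, 0.3)
    with pytest.raises(ValueError):
        prior_correct(0.04, 1.0)


def test_fdr_from_rates():
    assert fdr_from_rates(0.0, 0.2, 0.8) == 1.0
    assert fdr_from_rates(0.3, 0.5, 0.5) == pytest.approx(0.7)  # TPR == FPR
    assert fdr_from_rates(0.5, 0.1, 0.8) == pytest.approx(0.1 / 0.9)
    with pytest.raises(ZeroDivisionError):
        fdr_from_rates(0.5, 0.0, 0.0)


def make_mechanisms(n_sig, L=40):
    """n_sig mechanisms whose impact is significant for a deletion at 10."""
    v = IndelVariant("P", 10, 10, "A", "")
    tracks, nulls = {}, {}
    for i in range(n_sig):
        name = f"sig{i}"
        tracks[name] = track_with_hits(L, [10], mechanism=name)
        # null: almost no neutral variant reaches score 1
        nulls[name] = NullDistribution(name, np.array([0] * 99 + [1]))
    tracks["dull"] = track_with_hits(L, [], mechanism="dull")
    nulls["dull"] = NullDistribution("dull", np.array([0] * 100))
    return v, tracks, nulls


def test_rank_mechanisms_top_five():
    v, tracks, nulls = make_mechanisms(7)
    out = rank_mechanisms(v, tracks, nulls)
    assert len(out) == 5
    assert all(r.significant and r.p_prime < 0.05 for r in out)


def test_rank_mechanisms_none_significant():
    v, tracks, nulls = make_mechanisms(0)
    assert rank_mechanisms(v, tracks, nulls) == []


def test_rank_mechanisms_tiebreak_and_order_invariance():
    v = IndelVariant("P", 10, 10, "A", "")
    t_big = track_with_hits(40, [9, 10, 11], mechanism="b_big")
    t_small = track_with_hits(40, [10], mechanism="a_small")
    null = np.array([0] * 99 + [3])
    tracks = {"b_big": t_big, "a_small": t_small}
    nulls = {"b_big": NullDistribution("b_big", null),
             "a_small": NullDistribution("a_small", null)}
    out = rank_mechanisms(v, tracks, nulls)
    # equal P-values: larger impact score first
    assert [r.mechanism for r in out] == ["b_big", "a_small"]
    reordered = rank_mechanisms(
        v, dict(reversed(tracks.items())), nulls)
    assert [r.mechanism for r in reordered] == ["b_big", "a_small"]


def test_rank_mechanisms_missing_null():
    v, tracks, nulls = make_mechanisms(2)
    del nulls["sig0"]
    with pytest.raises(KeyError):
        rank_mechanisms(v, tracks, nulls)


def test_evaluate_impact_alpha_precedence():
    v, tracks, nulls = make_mechanisms(1)
    tracks["sig0"].alpha = 0.4
    r = evaluate_impact(v, tracks["sig0"], nulls["sig0"])
    assert r.alpha == 0.4
    assert r.p_prime == pytest.approx(0.6 * r.p_value)
    r2 = evaluate_impact(v, tracks["sig0"], nulls["sig0"], alpha=0.0)
    assert r2.p_prime == r2.p_value  # explicit argument wins; alpha=0 => P'=P


def test_naive_alpha_limits():
    rng = np.random.default_rng(0)
    pos = rng.uniform(0.6, 1.0, size=500)
    assert naive_alpha_estimate(pos, pos) == pytest.approx(0.99)
    neg = np.full(500, 1e-6)
    assert naive_alpha_estimate(neg, pos) < 0.01


def test_naive_alpha_recovers_mixture_proportion():
    estimates = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0.9, 1.0, size=400)     # strong separation
        neg = rng.uniform(0.0, 0.1, size=400)
        mix = np.concatenate([rng.uniform(0.9, 1.0, size=200),
                              rng.uniform(0.0, 0.1, size=200)])
        estimates.append(naive_alpha_estimate(mix, pos))
    assert abs(np.mean(estimates) - 0.5) < 0.1


def test_single_residue_filter_and_predicted_flag():
    assert is_single_residue(IndelVariant("P", 5, 5, "A", ""))
    assert not is_single_residue(IndelVariant("P", 5, 6, "AA", ""))
    assert not is_single_residue(IndelVariant("P", 5, 5, "", "QQ"))
    neutral = np.arange(100)
    assert predicted_flag(95, neutral)
    assert not predicted_flag(90, neutral)
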