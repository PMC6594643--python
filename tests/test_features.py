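"""Feature engineering: windows, repeats, conservation, counts, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from indelfx.features import (FeatureConfig, PropertyTrack,
                              assemble_feature_vector, conservation_feature,
                              feature_groups, feature_names, general_features,
                              functional_residue_counts,
                              homolog_count_features, repeat_run_length,
                              window_aa_frequency, MissingInputError)
from indelfx.variants import AA_ALPHABET, IndelVariant, ProteinRecord


@pytest.mark.parametrize("v,L,expected", [
    (IndelVariant("P", 3, 4, "AA", ""), 100, (0.03, 0, 2)),
    (IndelVariant("P", 50, 50, "", "QW"), 100, (0.5, 2, 0)),
    (IndelVariant("P", 3, 5, "KLG", "WW"), 5, (0.6, 2, 3)),
])
def test_general_features(v, L, expected):
    rel, n_ins, n_del = general_features(v, L)
    assert (round(rel, 10), n_ins, n_del) == expected


def test_window_frequency_poly_a():
    seq = "A" * 30
    v = IndelVariant("P", 15, 15, "A", "")
    freqs = window_aa_frequency(v, seq)
    assert freqs[AA_ALPHABET.index("A")] == 1.0
    assert freqs.sum() == 1.0


def test_window_frequency_terminal_deletion():
    # deleting residue 2 of MKKKKKKKKKKK: window is {1} and {3..12}
    seq = "MKKKKKKKKKKK"
    v = IndelVariant("P", 2, 2, "K", "")
    freqs = window_aa_frequency(v, seq)
    assert freqs[AA_ALPHABET.index("M")] == pytest.approx(1 / 11)
    assert freqs[AA_ALPHABET.index("K")] == pytest.approx(10 / 11)


def test_window_frequency_insertion_full_window():
    seq = "ACDEFGHIKLMNPQRSTVWY"
    v = IndelVariant("P", 10, 10, "", "Q")
    freqs = window_aa_frequency(v, seq)
    assert np.allclose(freqs, 1 / 20)


@settings(derandomize=True, max_examples=100)
@given(st.integers(0, 2**31 - 1))
def test_window_frequency_ignores_distant_residues(seed):
    """Shuffling residues outside the 20-residue window never changes the
    window composition."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AA_ALPHABET), size=80))
    v = IndelVariant("P", 40, 41, seq[39:41], "")
    far = list(range(0, 29)) + list(range(52, 80))
    perm = rng.permutation(far)
    shuffled = list(seq)
    for i, j in zip(far, perm):
        shuffled[i] = seq[j]
    assert np.array_equal(window_aa_frequency(v, seq),
                          window_aa_frequency(v, "".join(shuffled)))


@pytest.mark.parametrize("seq,v,expected", [
    ("MAKLG", IndelVariant("P", 3, 3, "K", ""), 1),
    ("MAAAKG", IndelVariant("P", 3, 3, "A", ""), 3),
    ("MAAAKG", IndelVariant("P", 2, 2, "", "A"), 3),
    ("MAAAKG", IndelVariant("P", 0, 0, "", "Q"), 1),
])
def test_repeat_run_length(seq, v, expected):
    assert repeat_run_length(v, seq) == expected


@pytest.mark.parametrize("v,cons,expected", [
    (IndelVariant("P", 3, 5, "KLG", ""), (.1, .2, .9, .4, .3), 0.9),
    (IndelVariant("P", 4, 4, "", "QW"), (.1, .2, .3, .4, .5), 0.5),
    (IndelVariant("P", 2, 3, "AK", "W"), (.7, .7, .7, .7, .7), 0.7),
])
def test_conservation_feature(v, cons, expected):
    assert conservation_feature(v, cons) == pytest.approx(expected)


@settings(derandomize=True, max_examples=200)
@given(st.integers(0, 2**31 - 1))
def test_conservation_matches_bruteforce_max(seed):
    rng = np.random.default_rng(seed)
    L = int(rng.integers(5, 50))
    cons = rng.uniform(size=L)
    seq = "".join(rng.choice(list(AA_ALPHABET), size=L))
    start = int(rng.integers(1, L + 1))
    end = int(rng.integers(start, min(L, start + 4) + 1))
    v = IndelVariant("P", start, end, seq[start - 1:end], "")
    assert conservation_feature(v, cons) == max(cons[start - 1:end])
    k = int(rng.integers(1, 4))
    p = int(rng.integers(1, L + 1))
    ins = IndelVariant("P", p, p, "", "A" * k)
    window = [cons[i - 1] for i in range(p, p + k) if 1 <= i <= L]
    assert conservation_feature(ins, cons) == max(window)


@pytest.mark.parametrize("identities,expected", [
    ([], [0] * 10),
    ([100.0], [1] * 10),
    ([52, 60, 97], [3, 2, 2, 1, 1, 1, 1, 1, 1, 1]),
])
def test_homolog_count_features(identities, expected):
    assert homolog_count_features(identities).tolist() == expected


def make_track(scores, threshold):
    return PropertyTrack(mechanism="m", scores=np.asarray(scores, float),
                         confident_threshold=threshold)


def test_functional_residue_counts_windows():
    track = make_track(np.ones(100), 0.5)
    v = IndelVariant("P", 50, 50, "A", "")
    assert functional_residue_counts(v, track) == (9, 41, 100)


def test_functional_residue_counts_zero_track():
    track = make_track(np.zeros(50), 0.5)
    v = IndelVariant("P", 10, 12, "AAA", "")
    assert functional_residue_counts(v, track) == (0, 0, 0)


def test_functional_residue_counts_unreachable_threshold():
    track = make_track(np.ones(50), 1.0)
    track.confident_threshold = 1.01  # beyond any score
    v = IndelVariant("P", 10, 12, "AAA", "")
    assert functional_residue_counts(v, track) == (0, 0, 0)


@settings(derandomize=True, max_examples=200)
@given(st.integers(0, 2**31 - 1))
def test_functional_counts_monotone_and_clipped(seed):
    rng = np.random.default_rng(seed)
    L = int(rng.integers(5, 60))
    track = make_track(rng.uniform(size=L), 0.5)
    # variants near the termini exercise clipping
    start = int(rng.choice([1, 2, L - 1, L, rng.integers(1, L + 1)]))
    start = min(max(1, start), L)
    seq = "A" * L
    v = IndelVariant("P", start, start, seq[start - 1], "")
    w4, w20, whole = functional_residue_counts(v, track)
    assert 0 <= w4 <= w20 <= whole <= L


def build_protein(n_mech=2, L=30):
    rng = np.random.default_rng(0)
    tracks = {f"m{i}": PropertyTrack(f"m{i}", rng.uniform(size=L), 0.5)
              for i in range(n_mech)}
    return ProteinRecord(
        protein_id="P", sequence="".join(rng.choice(list(AA_ALPHABET), L)),
        tracks=tracks, conservation={"c": rng.uniform(size=L)},
        homolog_identities_human=[80.0], homolog_identities_mouse=[])


def test_assemble_vector_size_and_groups():
    protein = build_protein()
    config = FeatureConfig(mechanisms=("m0", "m1"), conservation=("c",))
    v = IndelVariant("P", 5, 6, protein.sequence[4:6], "")
    vec = assemble_feature_vector(v, protein, config)
    # 3 general + 21 composition + 1 conservation + 20 homolog + 2x3 counts
    assert len(vec) == 51
    assert tuple(vec) == feature_names(config)
    groups = set(feature_groups(config).values())
    assert groups == {"general", "composition", "conservation", "homolog",
                      "functional_w4", "functional_w20", "functional_whole"}


def test_assemble_vector_deterministic_and_group_toggle():
    protein = build_protein()
    v = IndelVariant("P", 5, 6, protein.sequence[4:6], "")
    config = FeatureConfig(mechanisms=("m0", "m1"), conservation=("c",))
    assert assemble_feature_vector(v, protein, config) == \
        assemble_feature_vector(v, protein, config)
    no_hom = FeatureConfig(mechanisms=("m0", "m1"), conservation=("c",),
                           include_homologs=False)
    vec = assemble_feature_vector(v, protein, no_hom)
    assert not any(name.startswith("homolog_") for name in vec)
    assert len(vec) == 51 - 20


def test_assemble_vector_missing_track_raises():
    protein = build_protein()
    config = FeatureConfig(mechanisms=("m0", "nope"), conservation=("c",))
    v = IndelVariant("P", 5, 6, protein.sequence[4:6], "")
    with pytest.raises(MissingInputError, match="nope"):
        assemble_feature_vector(v, protein, config)
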