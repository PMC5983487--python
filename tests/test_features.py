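import numpy as np
import pytest

from crfalign.features import (FEATURE_DIMS, FeatureTracks, ResidueTrack,
                               apply_normalizer, build_feature_tracks,
                               factor_input, fit_normalizer, hydropathy_count,
                               profile_similarity, rsa_estimate,
                               sa_match_score, sequence_similarity,
                               ss3_match_score)
from crfalign.lattice import Label
from helpers import random_tracks

M, Iq, It = Label.M, Label.Iq, Label.It


def make_query(L, rng, disorder=None):
    profile = rng.dirichlet(np.ones(20), size=L)
    ss3 = rng.dirichlet(np.ones(3), size=L)
    sa = rng.dirichlet(np.ones(3), size=L)
    seq = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=L))
    dis = np.zeros(L, dtype=bool) if disorder is None else disorder
    return ResidueTrack(seq, profile, ss3, sa, dis)


def make_template(L, rng, disorder=None):
    profile = rng.normal(size=(L, 20))
    ss3 = "".join(rng.choice(list("HEC"), size=L))
    sa = rng.uniform(0, 100, size=L)
    seq = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=L))
    dis = np.zeros(L, dtype=bool) if disorder is None else disorder
    return ResidueTrack(seq, profile, ss3, sa, dis)


class TestRsaEstimate:
    @pytest.mark.parametrize("probs, expected", [
        ((0, 1, 0), 42.0),
        ((0, 0, 1), 100.0),
        ((1, 0, 0), 10.0),
        ((0.5, 0.5, 0), 26.0),
    ])
    def test_values(self, probs, expected):
        assert rsa_estimate(*probs) == pytest.approx(expected)

    def test_bounded_on_simplex(self, rng):
        for p in rng.dirichlet(np.ones(3), size=50):
            assert 10.0 <= rsa_estimate(*p) <= 100.0

    def test_rejects_non_distribution(self):
        with pytest.raises(ValueError):
            rsa_estimate(0.5, 0.5, 0.5)


class TestScalarScores:
    def test_profile_similarity_is_inner_product(self, rng):
        q, t = rng.normal(size=20), rng.normal(size=20)
        assert profile_similarity(q, t) == pytest.approx(sum(a * b for a, b in zip(q, t)))
        onehot = np.zeros(20)
        onehot[3] = 1.0
        assert profile_similarity(onehot, t) == pytest.approx(t[3])
        assert profile_similarity(q, np.zeros(20)) == 0.0

    def test_blosum50_canonical_entries_and_symmetry(self):
        assert sequence_similarity("A", "A") == 5
        assert sequence_similarity("W", "W") == 15
        assert sequence_similarity("X", "Q") == 0
        for a in "ARND":
            for b in "WYVH":
                assert sequence_similarity(a, b) == sequence_similarity(b, a)
        with pytest.raises(ValueError):
            sequence_similarity("B", "A")

    def test_ss3_match_selects_template_class_probability(self):
        assert ss3_match_score(np.array([1, 0, 0]), "H") == 1.0
        assert ss3_match_score(np.array([0.2, 0.5, 0.3]), "E") == 0.5
        assert ss3_match_score(np.full(3, 1 / 3), "C") == pytest.approx(1 / 3)

    @pytest.mark.parametrize("probs, rsa, expected", [
        ((1, 0, 0), 5.0, 1.0),     # buried template, buried-confident query
        ((0, 0, 1), 80.0, 1.0),    # exposed/exposed
        ((0.1, 0.6, 0.3), 20.0, 0.6),  # RSA 20 -> medium class
        ((0.1, 0.6, 0.3), 42.0, 0.3),  # boundary 42 is exposed
    ])
    def test_sa_match_uses_cutoff_classes(self, probs, rsa, expected):
        assert sa_match_score(np.array(probs), rsa) == pytest.approx(expected)

    def test_hydropathy_window_and_truncation(self):
        assert hydropathy_count("DDDDDDD", 4) == 7
        assert hydropathy_count("IIIIIII", 4) == 0
        assert hydropathy_count("DDDDDDD", 1) == 4  # window clipped to 1..4


class TestBuildFeatureTracks:
    def test_shapes_and_channel_counts(self, rng):
        tracks = build_feature_tracks(make_query(4, rng), make_template(6, rng))
        assert tracks.match_features.shape == (4, 6, 4)
        assert tracks.qins_features.shape == (4, 6, 3)
        assert tracks.tins_features.shape == (4, 6, 3)
        assert np.all(np.isfinite(tracks.match_features))

    def test_onehot_profiles_give_unit_diagonal_similarity(self, rng):
        L = 5
        q = make_query(L, rng)
        t = make_template(L, rng)
        q.profile = np.eye(L, 20)
        t.profile = np.eye(L, 20)
        tracks = build_feature_tracks(q, t)
        assert np.allclose(np.diagonal(tracks.match_features[:, :, 0]), 1.0)

    def test_disordered_query_zeroes_structural_insertion_channels(self, rng):
        dis = np.zeros(5, dtype=bool)
        dis[2] = True
        tracks = build_feature_tracks(make_query(5, rng, disorder=dis),
                                      make_template(4, rng))
        # x = 3 disordered: RSA and SS3 channels of the It vector vanish
        assert np.all(tracks.tins_features[2, :, 1:] == 0.0)
        # match structural channels at that x vanish too
        assert np.all(tracks.match_features[2, :, 2:] == 0.0)
        # hydropathy (sequence feature) survives
        assert np.any(tracks.tins_features[2, :, 0] != 0.0)


class TestNormalizer:
    def test_fit_standardizes_pooled_training_data(self, rng):
        pairs = [random_tracks(rng, 5, 4) for _ in range(3)]
        norm = fit_normalizer(pairs)
        normed = [apply_normalizer(norm, t) for t in pairs]
        for lab in FEATURE_DIMS:
            pooled = np.concatenate([t.grid(lab).reshape(-1, FEATURE_DIMS[lab])
                                     for t in normed])
            assert np.allclose(pooled.mean(axis=0), 0.0, atol=1e-9)
            assert np.allclose(pooled.var(axis=0), 1.0, atol=1e-6)

    def test_constant_channel_maps_to_zero(self):
        t = FeatureTracks(None, None, np.full((3, 3, 4), 7.0),
                          np.zeros((3, 3, 3)), np.zeros((3, 3, 3)))
        norm = fit_normalizer([t])
        assert np.all(apply_normalizer(norm, t).match_features == 0.0)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit_normalizer([])


class TestFactorInput:
    def test_triple_input_concatenates_three_vectors(self, rng):
        tracks = random_tracks(rng, 3, 2)
        vec = factor_input((M, Iq, M), (3, 2), tracks)
        assert vec.shape == (11,)
        expected = np.concatenate([tracks.match_features[0, 0],
                                   tracks.qins_features[1, 0],
                                   tracks.match_features[2, 1]])
        assert np.allclose(vec, expected)

    def test_edge_input_walks_back_one_step(self, rng):
        tracks = random_tracks(rng, 3, 2)
        vec = factor_input((Iq, M), (3, 2), tracks)
        assert vec.shape == (7,)
        assert np.allclose(vec, np.concatenate([tracks.qins_features[1, 0],
                                                tracks.match_features[2, 1]]))

    def test_out_of_lattice_segment_is_zero_filled(self, rng):
        tracks = random_tracks(rng, 2, 2)
        vec = factor_input((M, M), (1, 1), tracks)
        assert np.all(vec[:4] == 0.0)
        assert np.allclose(vec[4:], tracks.match_features[0, 0])

    def test_deterministic(self, rng):
        tracks = random_tracks(rng, 3, 3)
        a = factor_input((It, Iq, M), (2, 2), tracks)
        b = factor_input((It, Iq, M), (2, 2), tracks)
        assert np.array_equal(a, b)
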