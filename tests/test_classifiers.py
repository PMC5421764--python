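import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sobrenome.classifiers import (
    CTModel,
    NBModel,
    build_ct_profiles,
    ct_classify,
    make_ngrams,
    nb_classify,
    nb_train,
    out_of_place_distance,
    rank_ngrams,
)
from sobrenome.labels import AncestryLabel

IBR, ITA, GER, JPN, EAS = AncestryLabel


class TestNgrams:
    def test_lima_trigrams(self):
        assert make_ngrams("LIMA", 3) == ["__L", "_LI", "LIM", "IMA", "MA_", "A__"]

    def test_single_letter_padding(self):
        assert make_ngrams("A", 3) == ["__A", "_A_", "A__"]

    def test_unigrams_have_no_padding(self):
        assert make_ngrams("AB", 1) == ["A", "B"]

    def test_empty_surname_rejected(self):
        with pytest.raises(ValueError):
            make_ngrams("", 3)

    @given(st.text(alphabet="ABCDE", min_size=1, max_size=15),
           st.integers(min_value=1, max_value=5))
    @settings(max_examples=200, derandomize=True)
    def test_count_is_length_plus_n_minus_one(self, surname, n):
        grams = make_ngrams(surname, n)
        assert len(grams) == len(surname) + n - 1
        assert all(len(g) == n for g in grams)


class TestOutOfPlace:
    def test_identical_ranking_scores_zero(self):
        profile = ["AB", "BC", "CD"]
        assert out_of_place_distance(profile, profile, 1250) == 0

    def test_absent_ngram_pays_maximum_penalty(self):
        assert out_of_place_distance(["ZZ"], ["AB"], 1250) == 1250

    def test_hand_computed_offsets(self):
        # query ranks: AB=0, BC=1, CA=2; profile ranks: BC=0, AB=1, CA=3
        # displacements |0-1| + |1-0| + |2-3| = 3
        query = ["AB", "BC", "CA"]
        profile = ["BC", "AB", "XX", "CA", "YY"]
        assert out_of_place_distance(query, profile, 5) == 3
        # with one absent query n-gram the maximum penalty applies
        assert out_of_place_distance(["AB", "ZZ"], profile, 5) == 1 + 5

    def test_profile_rank_mode_sums_one_based_ranks(self):
        query = ["AB", "BC"]
        profile = ["BC", "AB"]
        assert out_of_place_distance(query, profile, 5, "profile_rank") == 2 + 1

    def test_never_exceeds_query_size_times_profile_size(self):
        query = rank_ngrams(make_ngrams("KOWALSKI", 3))
        bound = len(query) * 1250
        assert out_of_place_distance(query, ["XXX"], 1250) <= bound


class TestCTModel:
    def test_hand_tallied_profile_ranking(self):
        # two copies of ABA: 10 trigram tokens, every distinct trigram
        # appears twice, so ranking falls back to lexicographic order
        # (letters sort before the underscore pad in ASCII)
        model = build_ct_profiles([("ABA", IBR), ("ABA", IBR)], n=3,
                                  profile_size=1250)
        assert model.profiles[IBR] == ["ABA", "A__", "BA_", "_AB", "__A"]

    def test_profile_size_one_keeps_modal_ngram(self):
        model = build_ct_profiles(
            [("ABAB", IBR), ("ABAB", IBR)], n=2, profile_size=1
        )
        # AB occurs twice per surname, strictly the most common bigram
        assert model.profiles[IBR] == ["AB"]

    def test_disjoint_alphabets_yield_disjoint_profiles(self):
        model = build_ct_profiles([("ABCAB", IBR), ("FGHFG", ITA)], n=3,
                                  profile_size=1250)
        assert not set(model.profiles[IBR]) & set(model.profiles[ITA])

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            build_ct_profiles([("ABA", IBR)], classes=[IBR, ITA])

    def test_two_class_argmin_verified_by_hand(self):
        model = build_ct_profiles([("ABAB", IBR), ("CDCD", ITA)], n=2,
                                  profile_size=10)
        # query ACAC: bigrams _A AC CA AC C_ -> ranked AC, CA, C_, _A
        pred = ct_classify("ACAC", model)
        query = rank_ngrams(make_ngrams("ACAC", 2))
        for label in (IBR, ITA):
            expected = out_of_place_distance(query, model.profiles[label], 10)
            assert pred.distances[label] == expected
        assert pred.label == min(pred.distances, key=pred.distances.get)

    def test_single_class_model_always_wins(self):
        model = build_ct_profiles([("TANAKA", JPN)], n=3, profile_size=50)
        assert ct_classify("SUZUKI", model).label == JPN

    def test_surname_from_disjoint_class_wins_strictly(self):
        model = build_ct_profiles(
            [("ABCDE", IBR), ("FGHIJ", ITA)], n=3, profile_size=1250
        )
        pred = ct_classify("ABCDE", model)
        assert pred.label == IBR
        assert pred.distances[IBR] < pred.distances[ITA]

    def test_tie_break_is_fixed_class_order(self):
        model = build_ct_profiles([("AB", IBR), ("AB", EAS)], n=2,
                                  profile_size=10)
        pred = ct_classify("AB", model)
        assert pred.tie and pred.label == IBR  # IBR precedes EAS in the order

    def test_training_order_invariance(self):
        pairs = [("ABCD", IBR), ("BCDE", IBR), ("FGHI", ITA), ("GHIJ", ITA)]
        a = build_ct_profiles(pairs, n=3, profile_size=100)
        b = build_ct_profiles(list(reversed(pairs)), n=3, profile_size=100)
        assert a.profiles == b.profiles

    def test_json_round_trip(self, tmp_path):
        model = build_ct_profiles([("ABAB", IBR), ("CDCD", ITA)], n=2,
                                  profile_size=10)
        path = tmp_path / "ct.json"
        model.to_json(path)
        loaded = CTModel.from_json(path)
        assert loaded.n == model.n
        assert loaded.profile_size == model.profile_size
        assert loaded.profiles == model.profiles


class TestNaiveBayes:
    def test_priors_are_class_shares(self):
        model = nb_train(
            [("AB", IBR), ("CD", IBR), ("EF", IBR), ("GH", ITA)], n=2
        )
        assert model.priors == {IBR: 0.75, ITA: 0.25}

    def test_unseen_ngram_probability_positive_and_smoothed(self):
        model = nb_train([("AB", IBR)], n=1, alpha=1.0)
        # class IBR saw tokens A,B (N=2); vocabulary {A,B}, V+1 = 3
        assert math.isclose(model.log_unseen[IBR], math.log(1 / (2 + 3)))

    def test_two_class_posterior_equals_hand_applied_bayes_rule(self):
        # n=1, alpha=1: vocab {A,B,C,D}, V+1=5, priors 1/2 each.
        # P(A|IBR)=P(B|IBR)=(1+1)/(2+5)=2/7, P(A|ITA)=1/7.
        # Query AB: IBR mass 0.5*(2/7)^2, ITA mass 0.5*(1/7)^2
        # -> posterior IBR = 4/5.
        model = nb_train([("AB", IBR), ("CD", ITA)], n=1, alpha=1.0)
        pred = nb_classify("AB", model)
        assert pred.label == IBR
        assert math.isclose(pred.posteriors[IBR], 0.8, abs_tol=1e-12)
        assert math.isclose(pred.posteriors[ITA], 0.2, abs_tol=1e-12)

    def test_posteriors_normalize_over_all_classes(self):
        pairs = [(s, c) for c, s in zip(AncestryLabel, "ABCDE FGHIJ KLMNO PQRST UVWXY".split())]
        model = nb_train(pairs, n=3)
        pred = nb_classify("ABCFG", model)
        assert math.isclose(sum(pred.posteriors.values()), 1.0, abs_tol=1e-9)

    def test_symmetric_training_gives_symmetric_likelihoods(self):
        model = nb_train([("AB", IBR), ("AB", ITA)], n=2)
        assert model.log_likelihoods[IBR] == model.log_likelihoods[ITA]

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            nb_train([("AB", IBR)], alpha=0.0)

    def test_json_round_trip_lossless(self, tmp_path):
        model = nb_train([("ABAB", IBR), ("CDCD", ITA)], n=2, alpha=0.5)
        path = tmp_path / "nb.json"
        model.to_json(path)
        loaded = NBModel.from_json(path)
        assert loaded.priors == model.priors
        assert loaded.log_likelihoods == model.log_likelihoods
        assert loaded.log_unseen == model.log_unseen
        assert nb_classify("ABCD", loaded) == nb_classify("ABCD", model)
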