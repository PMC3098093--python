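import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zftarget.classifiers import (
    ClassifierConfig,
    NaiveBayesModel,
    SvmProtocolConfig,
    balanced_subsets,
    choose_threshold_max_cc,
    confidence_score,
    grid_search_rbf,
    nb_fit,
    nb_posterior,
    nb_predict,
    svm_averaged_posterior,
)
from zftarget.core import SiteDataset, TargetSite
from zftarget.encodings import encode_dataset, encode_site

dna9 = st.text(alphabet="GACT", min_size=9, max_size=9)


def brute_force_posterior(model: NaiveBayesModel, x) -> float:
    """Direct-product Bayes rule, no log space: the independent oracle."""
    joint = {}
    for c in ("active", "inactive"):
        p = model.priors[c]
        for i, v in enumerate(x.values):
            p *= model.conditionals[i][c][v]
        joint[c] = p
    return joint["active"] / (joint["active"] + joint["inactive"])


def _encoded(pairs):
    ds = SiteDataset("t", [TargetSite(s, l) for s, l in pairs])
    return encode_dataset(ds, "identity")


class TestNaiveBayesFit:
    def test_smoothed_priors_and_conditionals(self):
        model = nb_fit(
            _encoded([("GGGGGGGGG", "active"), ("TTTTTTTTT", "inactive")]),
            alpha=1.0,
        )
        assert model.priors == {"active": 0.5, "inactive": 0.5}
        # P(pos1 = G | active) = (1 + 1) / (1 + 4) = 0.4
        assert model.conditionals[0]["active"]["G"] == pytest.approx(0.4)
        # rows sum to 1 over the 4-base domain
        for attr in model.conditionals:
            for c in ("active", "inactive"):
                assert sum(attr[c].values()) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="no 'inactive'"):
            nb_fit(_encoded([("GGGGGGGGG", "active"), ("GGGGGGGGT", "active")]))

    def test_mixed_encodings_rejected(self):
        ds = SiteDataset(
            "m",
            [TargetSite("GGGGGGGGG", "active"), TargetSite("TTTTTTTTT", "inactive")],
        )
        mixed = [
            (encode_site(ds.sites[0], "identity"), "active"),
            (encode_site(ds.sites[1], "base_counts"), "inactive"),
        ]
        with pytest.raises(ValueError, match="mixed encodings"):
            nb_fit(mixed)

    def test_alpha_zero_allows_zero_conditionals(self):
        model = nb_fit(
            _encoded([("GGGGGGGGG", "active"), ("TTTTTTTTT", "inactive")]),
            alpha=0.0,
        )
        assert model.conditionals[0]["active"]["T"] == 0.0

    def test_count_arity_smoothing(self):
        """Whole-site count attributes smooth over a 10-value domain."""
        ds = SiteDataset(
            "c",
            [TargetSite("GGGGGGGGG", "active"), TargetSite("TTTTTTTTT", "inactive")],
        )
        model = nb_fit(encode_dataset(ds, "base_counts"), alpha=1.0)
        # P(count_G = 9 | active) = (1 + 1) / (1 + 10)
        assert model.conditionals[0]["active"][9] == pytest.approx(2 / 11)


class TestNaiveBayesPosterior:
    def test_symmetric_model_gives_half(self):
        model = nb_fit(
            _encoded([("GGGGGGGGG", "active"), ("TTTTTTTTT", "inactive")])
        )
        x = encode_site(TargetSite("AAAAAAAAA"), "identity")
        assert nb_posterior(model, x) == pytest.approx(0.5)

    def test_hand_computed_posterior(self, four_site_dataset):
        # posterior reduces to 1 / (1 + (1/3)^8) = 6561/6562
        model = nb_fit(encode_dataset(four_site_dataset, "identity"))
        x = encode_site(TargetSite("GGGGGGGGG"), "identity")
        assert nb_posterior(model, x) == pytest.approx(6561 / 6562, abs=1e-12)

    def test_schema_mismatch_rejected(self, four_site_dataset):
        model = nb_fit(encode_dataset(four_site_dataset, "identity"))
        x = encode_site(TargetSite("GGGGGGGGG"), "base_counts")
        with pytest.raises(ValueError, match="kind"):
            nb_posterior(model, x)

    @given(st.lists(st.tuples(dna9, st.sampled_from(["active", "inactive"])),
                    min_size=4, max_size=12), dna9)
    @settings(max_examples=150, deadline=None)
    def test_log_space_matches_brute_force(self, pairs, query):
        labels = {l for _, l in pairs}
        if labels != {"active", "inactive"}:
            return
        model = nb_fit(_encoded(pairs))
        x = encode_site(TargetSite(query), "identity")
        p = nb_posterior(model, x)
        assert p == pytest.approx(brute_force_posterior(model, x), abs=1e-10)
        # normalization: swapping class roles complements the posterior
        assert 0.0 < p < 1.0


class TestConfidenceScore:
    @pytest.mark.parametrize(
        "p,score",
        [(0.75, 5), (0.25, 5), (0.5, 0), (1.0, 9), (0.0, 9), (0.55, 1),
         (0.549999, 0), (0.45, 1), (0.94999, 8), (0.95, 9)],
    )
    def test_values(self, p, score):
        assert confidence_score(p) == score

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confidence_score(1.5)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=300)
    def test_step_function_properties(self, p):
        s = confidence_score(p)
        assert 0 <= s <= 9
        # symmetric about 0.5
        assert s == confidence_score(1.0 - p)

    def test_monotone_in_distance_from_half(self):
        grid = np.linspace(0.5, 1.0, 501)
        scores = [confidence_score(p) for p in grid]
        assert scores == sorted(scores)
        assert set(scores) == set(range(10))


class TestPredict:
    def test_threshold_rule_and_confidence(self, four_site_dataset):
        model = nb_fit(encode_dataset(four_site_dataset, "identity"))
        result = nb_predict(model, TargetSite("GGGGGGGGG"))
        assert result.label == "active"
        assert result.confidence == confidence_score(result.posterior_active)

    def test_boundary_inclusive(self):
        # a posterior of exactly theta classifies active
        model = nb_fit(
            _encoded([("GGGGGGGGG", "active"), ("TTTTTTTTT", "inactive")])
        )
        result = nb_predict(model, TargetSite("AAAAAAAAA"))  # posterior 0.5
        assert result.label == "active"
        assert result.confidence == 0


class TestModelSerialization:
    def test_round_trip_posteriors_bit_identical(self, four_site_dataset, tmp_path):
        model = nb_fit(encode_dataset(four_site_dataset, "identity"))
        path = tmp_path / "model.json"
        model.save(path)
        loaded = NaiveBayesModel.load(path)
        for seq in ("GGGGGGGGG", "GTTGACGGC", "TTTTTTTTT"):
            x = encode_site(TargetSite(seq), "identity")
            assert nb_posterior(loaded, x) == nb_posterior(model, x)

    def test_count_model_round_trip(self, four_site_dataset, tmp_path):
        model = nb_fit(encode_dataset(four_site_dataset, "base_counts"))
        path = tmp_path / "model.json"
        model.save(path)
        loaded = NaiveBayesModel.load(path)
        x = encode_site(TargetSite("GGGGGGGGT"), "base_counts")
        assert nb_posterior(loaded, x) == nb_posterior(model, x)


class TestBalancedSubsets:
    def _imbalanced(self, n_active=20, n_inactive=6):
        sites = [TargetSite("GGGGGGGGG", "active", id=f"a{i}") for i in range(n_active)]
        sites += [TargetSite("TTTTTTTTT", "inactive", id=f"i{i}") for i in range(n_inactive)]
        return SiteDataset("imb", sites)

    def test_sizes_and_balance(self):
        ds = self._imbalanced()
        for subset in balanced_subsets(ds, 10, seed=1):
            assert len(subset) == 12
            assert sum(1 for s in subset if s.label == "active") == 6

    def test_deterministic_given_seed(self):
        ds = self._imbalanced()
        a = balanced_subsets(ds, 5, seed=7)
        b = balanced_subsets(ds, 5, seed=7)
        c = balanced_subsets(ds, 5, seed=8)
        key = lambda sets: [[s.id for s in sub] for sub in sets]
        assert key(a) == key(b)
        assert key(a) != key(c)

    def test_already_balanced_returns_full_dataset(self):
        ds = self._imbalanced(6, 6)
        for subset in balanced_subsets(ds, 3, seed=1):
            assert sorted(s.id for s in subset) == sorted(s.id for s in ds.sites)

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            balanced_subsets(self._imbalanced(), 0, seed=1)


class TestSvmProtocol:
    def test_separable_toy_query_on_class_side(self, separable_dataset):
        subsets = balanced_subsets(separable_dataset, 3, seed=1)
        x = encode_site(TargetSite("GGGGGGGGG"), "identity")
        p = svm_averaged_posterior(x, subsets, SvmProtocolConfig(seed=1))
        assert p > 0.5

    def test_identical_sets_average_to_single_estimate(self, separable_dataset):
        subset = list(separable_dataset.sites)
        x = encode_site(TargetSite("TTTTTTTTT"), "identity")
        config = SvmProtocolConfig(seed=3)
        single = svm_averaged_posterior(x, [subset], config)
        # same seed per set index 0; replicate by calling with one set twice
        # using identical per-set seeds is not exposed, so check mean-of-equal
        p = svm_averaged_posterior(x, [subset], config)
        assert p == pytest.approx(single)
        assert p < 0.5

    def test_single_class_set_rejected(self):
        bad = [[TargetSite("GGGGGGGGG", "active"), TargetSite("GGGGGGGGT", "active")]]
        x = encode_site(TargetSite("GGGGGGGGG"), "identity")
        with pytest.raises(ValueError, match="single-class"):
            svm_averaged_posterior(x, bad)


class TestGridSearch:
    def test_single_point_grid(self, separable_dataset):
        pairs = encode_dataset(separable_dataset, "positional_base_counts")
        cost, gamma = grid_search_rbf(pairs, [2.0], [0.125], folds=3, seed=1)
        assert (cost, gamma) == (2.0, 0.125)

    def test_selects_higher_cc_point(self, separable_dataset):
        """Against a direct-CV oracle: the argmax-CC grid point is returned."""
        import numpy as np
        from sklearn.model_selection import StratifiedKFold
        from sklearn.svm import SVC

        from zftarget.classifiers import _cc_from_counts, _to_matrix

        pairs = encode_dataset(separable_dataset, "positional_base_counts")
        X = _to_matrix(v for v, _ in pairs)
        y = np.array([1 if l == "active" else 0 for _, l in pairs])

        def direct_cv_cc(gamma):
            skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=1)
            tp = fp = tn = fn = 0
            for tr, te in skf.split(X, y):
                clf = SVC(kernel="rbf", C=1.0, gamma=gamma).fit(X[tr], y[tr])
                pred = clf.predict(X[te])
                tp += int(((pred == 1) & (y[te] == 1)).sum())
                fp += int(((pred == 1) & (y[te] == 0)).sum())
                tn += int(((pred == 0) & (y[te] == 0)).sum())
                fn += int(((pred == 0) & (y[te] == 1)).sum())
            return _cc_from_counts(tp, fp, tn, fn)

        candidates = [1.0, 1e-9]
        expected = max(candidates, key=direct_cv_cc)
        cost, gamma = grid_search_rbf(pairs, [1.0], candidates, folds=3, seed=1)
        assert gamma == expected

    def test_single_class_rejected(self):
        pairs = _encoded([("GGGGGGGGG", "active"), ("GGGGGGGGT", "active")])
        with pytest.raises(ValueError):
            grid_search_rbf(pairs, [1.0], [1.0])


class TestThresholdSelection:
    def test_perfect_separation_returns_separating_midpoint(self):
        posts = [(0.9, "active"), (0.8, "active"), (0.2, "inactive"), (0.1, "inactive")]
        assert choose_threshold_max_cc(posts) == pytest.approx(0.5)

    def test_all_equal_returns_smallest_candidate(self):
        posts = [(0.5, "active"), (0.5, "inactive")]
        assert choose_threshold_max_cc(posts) == 0.0

    def test_label_swap_inverts_best_cc_sign(self):
        posts = [(0.9, "active"), (0.7, "active"), (0.3, "inactive"), (0.1, "inactive")]
        flipped = [(p, "inactive" if l == "active" else "active") for p, l in posts]
        from zftarget.evaluation import confusion, metrics

        theta = choose_threshold_max_cc(posts)
        theta_f = choose_threshold_max_cc(flipped)
        cc = metrics(confusion(posts, theta))["cc"]
        cc_f = metrics(confusion(flipped, theta_f))["cc"]
        assert cc == pytest.approx(1.0)
        # flipped labels: the best achievable CC is the negation landscape's max
        assert cc_f <= 0.0 or math.isnan(cc_f)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            choose_threshold_max_cc([(0.9, "active"), (0.8, "active")])
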