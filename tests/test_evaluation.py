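import numpy as np
import pytest
from scipy import stats as sps

import consortcheck as cc
from consortcheck.evaluation import (
    article_any,
    article_one_plus,
    decisions_vector,
    group_kfold,
    label_frequency_baseline,
    mcnemar_compare,
    mcnemar_from_counts,
    sentence_metrics,
)
from conftest import (
    oracle_article_scheme,
    oracle_sentence_metrics,
    random_case,
    units_to_predictions,
    units_to_records,
)


class TestGroupKfold:
    def test_partition_and_determinism(self, tiny_corpus):
        arts = cc.generate_corpus(cc.GeneratorSpec(n_articles=12, sentences_per_article=(10, 12), seed=0))
        plan1 = group_kfold(arts, k=4, seed=9)
        plan2 = group_kfold(arts, k=4, seed=9)
        assert plan1.assignment == plan2.assignment
        folds = [set(a.article_id for a in plan1.fold_articles(arts, f)) for f in range(4)]
        all_ids = set(a.article_id for a in arts)
        assert set.union(*folds) == all_ids
        for i in range(4):
            for j in range(i + 1, 4):
                assert folds[i].isdisjoint(folds[j])

    def test_balanced_fold_sizes(self):
        arts = cc.generate_corpus(cc.GeneratorSpec(n_articles=50, sentences_per_article=(10, 11), seed=0))
        plan = group_kfold(arts, k=5, seed=1)
        sizes = [len(plan.fold_articles(arts, f)) for f in range(5)]
        assert sizes == [10] * 5

    def test_too_few_articles(self, tiny_corpus):
        with pytest.raises(ValueError):
            group_kfold(tiny_corpus, k=5)


class TestSentenceMetricsWorkedExample:
    def make(self):
        gold = {("x", 0): {"a"}, ("x", 1): {"b"}, ("x", 2): set()}
        pred = {("x", 0): {"a"}, ("x", 1): {"a"}, ("x", 2): {"b"}}
        return gold, pred

    def test_hand_pooled_confusion(self):
        gold, pred = self.make()
        rep = sentence_metrics(
            units_to_records(gold), units_to_predictions(pred, ("a", "b")),
            ("a", "b"), compute_auc=False,
        )
        assert rep.micro_precision == pytest.approx(1 / 3)
        assert rep.micro_recall == pytest.approx(1 / 2)
        assert rep.micro_f1 == pytest.approx(0.4)

    def test_hand_macro(self):
        gold, pred = self.make()
        rep = sentence_metrics(
            units_to_records(gold), units_to_predictions(pred, ("a", "b")),
            ("a", "b"), compute_auc=False,
        )
        assert rep.per_label["a"].f1 == pytest.approx(2 / 3)
        assert rep.per_label["b"].f1 == 0.0
        assert rep.macro_f1 == pytest.approx(1 / 3)

    def test_perfect_predictions(self):
        gold, _ = self.make()
        rep = sentence_metrics(
            units_to_records(gold), units_to_predictions(gold, ("a", "b")),
            ("a", "b"), compute_auc=False,
        )
        assert rep.micro_f1 == 1.0
        assert rep.macro_f1 == 1.0

    def test_misaligned_units_rejected(self):
        gold, pred = self.make()
        del pred[("x", 2)]
        with pytest.raises(ValueError, match="misaligned"):
            sentence_metrics(
                units_to_records(gold), units_to_predictions(pred, ("a", "b")),
                ("a", "b"),
            )


class TestArticleSchemes:
    def test_any_worked_example(self):
        gold = {("A", 0): {"4a"}, ("B", 0): {"6a"}}
        pred = {("A", 0): {"4a", "6a"}, ("B", 0): set()}
        rep = article_any(units_to_records(gold),
                          units_to_predictions(pred, ("4a", "6a")), ("4a", "6a"))
        # TP=1 (A,4a), FP=1 (A,6a), FN=1 (B,6a), TN=1 (B,4a)
        assert rep.micro_precision == pytest.approx(0.5)
        assert rep.micro_recall == pytest.approx(0.5)
        assert rep.micro_f1 == pytest.approx(0.5)

    def test_any_ignores_extra_sentence_fp_on_reported_item(self):
        gold = {("A", 0): {"4a"}, ("A", 1): set()}
        pred = {("A", 0): {"4a"}, ("A", 1): {"4a"}}
        rep = article_any(units_to_records(gold),
                          units_to_predictions(pred, ("4a",)), ("4a",))
        assert rep.micro_f1 == 1.0

    def test_one_plus_requires_overlap(self):
        labels = ("4a",)
        gold = {("A", 1): {"4a"}, ("A", 2): {"4a"}, ("A", 7): set()}
        pred_overlap = {("A", 1): set(), ("A", 2): {"4a"}, ("A", 7): {"4a"}}
        rep = article_one_plus(units_to_records(gold),
                               units_to_predictions(pred_overlap, labels), labels)
        assert rep.per_label["4a"].tp == 1

        pred_disjoint = {("A", 1): set(), ("A", 2): set(), ("A", 7): {"4a"}}
        rep = article_one_plus(units_to_records(gold),
                               units_to_predictions(pred_disjoint, labels), labels)
        assert rep.per_label["4a"].tp == 0
        assert rep.per_label["4a"].fp == 1
        assert rep.per_label["4a"].fn == 1

    def test_one_plus_never_beats_any(self, rng):
        labels = ("a", "b", "c")
        for _ in range(100):
            gold, pred = random_case(rng, labels)
            recs = units_to_records(gold)
            preds = units_to_predictions(pred, labels)
            any_rep = article_any(recs, preds, labels)
            plus_rep = article_one_plus(recs, preds, labels)
            any_tp = sum(m.tp for m in any_rep.per_label.values())
            plus_tp = sum(m.tp for m in plus_rep.per_label.values())
            assert plus_tp <= any_tp
            assert plus_rep.micro_f1 <= any_rep.micro_f1 + 1e-12


class TestOracleEquivalence:
    def test_metrics_match_brute_force_enumeration(self, rng):
        labels = ("a", "b", "c", "d")
        for _ in range(300):
            gold, pred = random_case(rng, labels)
            recs = units_to_records(gold)
            preds = units_to_predictions(pred, labels)
            rep = sentence_metrics(recs, preds, labels, compute_auc=False)
            p, r, f1, macro = oracle_sentence_metrics(gold, pred, labels)
            assert rep.micro_precision == pytest.approx(p)
            assert rep.micro_recall == pytest.approx(r)
            assert rep.micro_f1 == pytest.approx(f1)
            assert rep.macro_f1 == pytest.approx(macro)
            for scheme, oracle_overlap in ((article_any, False), (article_one_plus, True)):
                rep_a = scheme(recs, preds, labels)
                pa, ra, fa = oracle_article_scheme(gold, pred, labels, oracle_overlap)
                assert rep_a.micro_precision == pytest.approx(pa)
                assert rep_a.micro_recall == pytest.approx(ra)
                assert rep_a.micro_f1 == pytest.approx(fa)

    def test_macro_f1_invariant_under_label_permutation(self, rng):
        labels = ("a", "b", "c")
        gold, pred = random_case(rng, labels)
        recs = units_to_records(gold)
        preds = units_to_predictions(pred, labels)
        r1 = sentence_metrics(recs, preds, labels, compute_auc=False)
        perm = ("c", "a", "b")
        preds_p = units_to_predictions(pred, perm)
        r2 = sentence_metrics(recs, preds_p, perm, compute_auc=False)
        assert r1.macro_f1 == pytest.approx(r2.macro_f1)
        assert r1.micro_f1 == pytest.approx(r2.micro_f1)


class TestMcNemar:
    def test_chi_square_branch_worked_example(self):
        stat, p = mcnemar_from_counts(15, 5)
        assert stat == pytest.approx((10 - 1) ** 2 / 20)
        assert stat == pytest.approx(4.05)
        assert p == pytest.approx(0.0442, abs=1e-3)

    def test_exact_binomial_branch(self):
        _, p = mcnemar_from_counts(3, 1)
        assert p == pytest.approx(0.625)

    def test_no_discordance(self):
        stat, p = mcnemar_from_counts(0, 0)
        assert p == 1.0

    def test_agreement_with_statsmodels(self, rng):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for _ in range(100):
            n01 = int(rng.integers(0, 60))
            n10 = int(rng.integers(0, 60))
            stat, p = mcnemar_from_counts(n01, n10)
            table = [[0, n01], [n10, 0]]
            if n01 + n10 >= 20:
                res = sm_mcnemar(table, exact=False, correction=True)
                assert stat == pytest.approx(res.statistic, abs=1e-8)
                assert p == pytest.approx(res.pvalue, abs=1e-8)
            elif n01 + n10 > 0:
                res = sm_mcnemar(table, exact=True)
                assert p == pytest.approx(res.pvalue, abs=1e-8)

    def test_compare_from_decisions(self):
        gold = np.array([1, 1, 1, 0, 0, 0, 1, 0], dtype=bool)
        a = np.array([1, 1, 0, 0, 0, 1, 1, 0], dtype=bool)  # wrong on 2,5
        b = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=bool)  # wrong on 1,4
        stat, p, n01, n10 = mcnemar_compare(a, b, gold)
        assert (n01, n10) == (2, 2)
        assert p == 1.0

    def test_identical_systems(self):
        gold = np.ones(10, dtype=bool)
        a = np.zeros(10, dtype=bool)
        stat, p, n01, n10 = mcnemar_compare(a, a, gold)
        assert (n01, n10) == (0, 0) and p == 1.0

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_compare([True], [True, False], [True, False])


class TestDecisionsVector:
    def test_pooled_units(self, tiny_corpus):
        model = cc.train(tiny_corpus, cc.ModelConfig(seed=0, epochs=1))
        preds = cc.predict(model, tiny_corpus)
        dec, gold = decisions_vector(tiny_corpus, preds, model.label_set)
        n_units = sum(a.n_sentences for a in tiny_corpus) * len(model.label_set)
        assert dec.shape == gold.shape == (n_units,)
        assert gold.sum() == 9  # one label per labeled sentence


class TestFrequencyBaseline:
    def test_probabilities_are_training_frequencies(self, tiny_corpus, label_set):
        preds = label_frequency_baseline(tiny_corpus, tiny_corpus, label_set, seed=0)
        n = sum(a.n_sentences for a in tiny_corpus)
        j = label_set.index("4a")
        assert preds[0].probabilities[j] == pytest.approx(1 / n)
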