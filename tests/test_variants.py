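"""Variant extraction, featurization, scoring, filtering, hard selection."""

import numpy as np
import pytest

from softgn.corpus import Sentence, tokenize_fine
from softgn.crf import TagSolution
from softgn.variants import (
    Variant,
    build_training_set,
    extract_variants,
    featurize,
    score_and_filter,
    select_nonoverlapping_max,
    train_scorer,
    variants_overlap,
)


def make_sentence(text: str) -> Sentence:
    return Sentence(text, 0, len(text), tokens=tokenize_fine(text))


def label_for_span(sentence: Sentence, start: int, end: int):
    labels = []
    inside = False
    for t in sentence.tokens:
        if t.start >= start and t.end <= end:
            labels.append("I" if inside else "B")
            inside = True
        else:
            labels.append("O")
            inside = False
    return tuple(labels)


WORKED_SENT_TEXT = ("Acetyl-CoA carboxylase from yeast is an essential enzyme and "
             "is regulated by factors that control phospholipid metabolism.")


def worked_solutions(sentence):
    """A 7-solution multiset mirroring the worked soft-tagging example:
    'Acetyl-CoA carboxylase' three times, 'CoA carboxylase' and 'essential
    enzyme' twice, 'carboxylase' and 'CoA carboxylase from yeast' once."""
    spans = {
        "Acetyl-CoA carboxylase": WORKED_SENT_TEXT.index("Acetyl"),
        "CoA carboxylase": WORKED_SENT_TEXT.index("CoA"),
        "essential enzyme": WORKED_SENT_TEXT.index("essential"),
        "carboxylase": WORKED_SENT_TEXT.index("carboxylase"),
        "CoA carboxylase from yeast": WORKED_SENT_TEXT.index("CoA"),
    }
    def sol(*mentions):
        labels = list(("O",) * len(sentence.tokens))
        for m in mentions:
            s = spans[m]
            span_labels = label_for_span(sentence, s, s + len(m))
            for i, lab in enumerate(span_labels):
                if lab != "O":
                    labels[i] = lab
        return TagSolution(tuple(labels), 0.0)

    return [
        sol("Acetyl-CoA carboxylase"),
        sol("Acetyl-CoA carboxylase", "essential enzyme"),
        sol("Acetyl-CoA carboxylase"),
        sol("CoA carboxylase"),
        sol("CoA carboxylase from yeast"),
        sol("carboxylase", "essential enzyme"),
        sol("CoA carboxylase"),
    ]


class TestExtractVariants:
    def test_frequency_counts_match_worked_example(self):
        sentence = make_sentence(WORKED_SENT_TEXT)
        variants = extract_variants(worked_solutions(sentence), sentence)
        by_text = {v.text: v for v in variants}
        counts = {t: round(v.frequency * 7) for t, v in by_text.items()}
        assert counts == {
            "Acetyl-CoA carboxylase": 3,
            "CoA carboxylase": 2,
            "essential enzyme": 2,
            "carboxylase": 1,
            "CoA carboxylase from yeast": 1,
        }

    def test_all_O_solutions_give_no_variants(self):
        sentence = make_sentence("nothing here")
        sols = [TagSolution(("O", "O"), 0.0)] * 4
        assert extract_variants(sols, sentence) == []

    def test_single_solution_single_mention_frequency_one(self):
        sentence = make_sentence("ABC binds")
        sols = [TagSolution(("B", "O"), 0.0)]
        (v,) = extract_variants(sols, sentence)
        assert v.frequency == 1.0 and v.text == "ABC"

    def test_frequency_conservation(self):
        """Raw occurrence counts over variants sum to the total mention count
        over all solutions."""
        sentence = make_sentence(WORKED_SENT_TEXT)
        sols = worked_solutions(sentence)
        variants = extract_variants(sols, sentence)
        from softgn.crf import ibo2_to_mentions
        total_mentions = sum(
            len(ibo2_to_mentions(s, sentence.tokens, sentence.text))
            for s in sols
        )
        assert round(sum(v.frequency for v in variants) * len(sols)) \
            == total_mentions


class TestFeaturize:
    def test_morphology_of_IL2R(self):
        sentence = make_sentence("the IL2R gene")
        v = Variant("IL2R", 4, 8, 0.5)
        f = featurize(v, sentence)
        assert f["starts_upper"] == 1.0
        assert f["ends_upper"] == 1.0
        assert f["has_digit"] == 1.0
        assert "starts_lower" not in f

    def test_content_token_gene_present(self):
        text = "the beta-galactosidase reporter gene was used"
        sentence = make_sentence(text)
        start = text.index("beta")
        v = Variant("beta-galactosidase reporter gene", start, start + 32, 0.5)
        f = featurize(v, sentence)
        assert f["content=beta"] == 1.0
        assert f["content=gene"] == 1.0

    def test_context_tokens_two_each_side(self):
        text = "with the cat gene of"
        sentence = make_sentence(text)
        v = Variant("cat", 9, 12, 0.5)
        f = featurize(v, sentence)
        assert f["ctx=with"] == 1.0 and f["ctx=the"] == 1.0
        assert f["ctx=gene"] == 1.0 and f["ctx=of"] == 1.0

    def test_variant_at_sentence_start_has_only_following_context(self):
        text = "ABC binds DNA here"
        sentence = make_sentence(text)
        f = featurize(Variant("ABC", 0, 3, 0.5), sentence)
        ctx = {k for k in f if k.startswith("ctx=")}
        assert ctx == {"ctx=binds", "ctx=dna"}

    def test_exactly_one_continuous_feature(self):
        sentence = make_sentence("the XYZ9 gene")
        f = featurize(Variant("XYZ9", 4, 8, 0.35), sentence)
        assert f["frequency"] == 0.35
        assert all(v == 1.0 for k, v in f.items() if k != "frequency")


class TestBuildTrainingSet:
    def test_acceptable_alternatives_labeled_positive(self):
        """Four nested boundary variants, two curator-acceptable: the full
        name and the canonical sub-span; the other two are negatives."""
        text = "high amniotic fluid alpha fetoprotein levels"
        sentence = make_sentence(text)
        full = (5, 5 + len("amniotic fluid alpha fetoprotein"))
        sub = (text.index("alpha"), full[1])           # alpha fetoprotein
        mid = (text.index("fluid"), full[1])           # fluid alpha fetoprotein
        just_alpha = (text.index("alpha"), text.index("alpha") + 5)
        sols = [
            TagSolution(label_for_span(sentence, *span), 0.0)
            for span in (full, sub, mid, just_alpha)
        ]
        X, y = build_training_set([(sentence, sols, {full, sub})])
        assert len(y) == 4
        assert sum(y) == 2

    def test_no_acceptables_means_exact_gold_only(self):
        text = "the ABC gene"
        sentence = make_sentence(text)
        gold = (4, 7)
        overlap = (4, 12)  # "ABC gene" overlaps but is not equal
        sols = [TagSolution(label_for_span(sentence, *s), 0.0)
                for s in (gold, overlap)]
        X, y = build_training_set([(sentence, sols, {gold})])
        assert sorted(y) == [0, 1]


def synthetic_logistic_data(n, rng, d=8):
    """Known generative model: dense morphological-style binary features plus
    one continuous frequency feature with a planted weight vector."""
    w = np.array([7.5, -5.0, 3.75, -2.5, 6.25, -3.75, 2.5, -1.25][:d])
    names = [f"f{i}" for i in range(d)]
    X, y = [], []
    for _ in range(n):
        x = np.concatenate([[rng.random()], rng.integers(0, 2, d - 1)])
        p = 1.0 / (1.0 + np.exp(-(x @ w - 0.5)))
        X.append({nm: float(v) for nm, v in zip(names, x) if v})
        y.append(int(rng.random() < p))
    return X, y, w, names


class TestTrainScorer:
    def test_recovers_planted_weight_signs_and_cv_accuracy(self):
        rng = np.random.default_rng(11)
        X, y, w, names = synthetic_logistic_data(5000, rng)
        model = train_scorer(X, y, seed=0)
        assert model.cv_accuracy >= 0.85
        vec = model.pipeline.named_steps["vec"]
        clf = model.pipeline.named_steps["clf"]
        coef = dict(zip(vec.get_feature_names_out(), clf.coef_[0]))
        for nm, true_w in zip(names, w):
            assert np.sign(coef[nm]) == np.sign(true_w)

    def test_label_independent_features_near_majority_accuracy(self):
        rng = np.random.default_rng(4)
        X = [{"a": float(rng.integers(0, 2)), "b": float(rng.random())}
             for _ in range(800)]
        y = [int(rng.random() < 0.7) for _ in range(800)]
        model = train_scorer(X, y, seed=0)
        assert abs(model.cv_accuracy - 0.7) < 0.08

    def test_minimal_two_class_fit(self):
        X = [{"a": 1.0}] * 5 + [{"b": 1.0}] * 5
        y = [0] * 5 + [1] * 5
        assert train_scorer(X, y, seed=0).cv_accuracy > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_scorer([{"a": 1.0}] * 10, [1] * 10, seed=0)


class TestScoreAndFilter:
    @pytest.fixture()
    def scored_world(self, models):
        sentence = make_sentence("The human gene ABC1 regulates cell growth.")
        start = sentence.text.index("ABC1")
        sols = [TagSolution(label_for_span(sentence, start, start + 4), 0.0),
                TagSolution(label_for_span(sentence, start, start + 3), 0.0),
                TagSolution(("O",) * len(sentence.tokens), 0.0)]
        variants = extract_variants(sols, sentence)
        return sentence, variants

    def test_threshold_zero_retains_all(self, scored_world, models):
        sentence, variants = scored_world
        kept = score_and_filter(variants, sentence, models.scorer, 0.0)
        assert len(kept) == len(variants)
        assert all(v.score is not None for v in kept)

    def test_threshold_one_retains_none(self, scored_world, models):
        sentence, variants = scored_world
        assert score_and_filter(variants, sentence, models.scorer, 1.0) == []

    def test_retained_sets_nested_across_thresholds(self, scored_world,
                                                    models):
        sentence, variants = scored_world
        at_02 = {v.span for v in
                 score_and_filter(variants, sentence, models.scorer, 0.2)}
        at_05 = {v.span for v in
                 score_and_filter(variants, sentence, models.scorer, 0.5)}
        assert at_05 <= at_02


def brute_force_selection(variants):
    """Independent trace of the defined recursion: pick the global max
    (ties: longer, then leftmost), discard overlaps, recurse."""
    pool = list(variants)
    out = []
    while pool:
        best = max(pool, key=lambda v: (v.score, v.end - v.start, -v.start,
                                        -v.end))
        out.append(best)
        pool = [v for v in pool if v is not best
                and not variants_overlap(best, v)]
    return sorted(out, key=lambda v: (v.start, v.end))


class TestSelectNonoverlappingMax:
    def test_worked_example_higher_scored_longer_variant_wins(self):
        a = Variant("human Na,K-ATPase beta", 0, 22, 0.9, score=0.9957)
        b = Variant("human Na,K-ATPase", 0, 17, 0.9, score=0.9316)
        assert select_nonoverlapping_max([a, b]) == [a]

    def test_disjoint_variants_identity(self):
        a = Variant("ABC", 0, 3, 0.5, score=0.7)
        b = Variant("DEF", 10, 13, 0.5, score=0.3)
        assert select_nonoverlapping_max([a, b]) == [a, b]

    def test_chain_middle_max_suppresses_both_neighbours(self):
        # A overlaps B, B overlaps C, A and C disjoint, scores B > A > C
        a = Variant("aa", 0, 4, 0.5, score=0.6)
        b = Variant("bb", 3, 8, 0.5, score=0.9)
        c = Variant("cc", 7, 10, 0.5, score=0.3)
        assert select_nonoverlapping_max([a, b, c]) == [b]

    def test_unscored_variant_rejected(self):
        with pytest.raises(ValueError):
            select_nonoverlapping_max([Variant("x", 0, 1, 0.5)])

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = rng.integers(1, 7)
            variants = []
            scores = rng.permutation(n) + 1  # distinct scores
            for i in range(n):
                s = int(rng.integers(0, 6))
                e = s + int(rng.integers(1, 4))
                variants.append(Variant(f"v{i}", s, e, 0.5,
                                        score=float(scores[i])))
            got = select_nonoverlapping_max(variants)
            assert got == brute_force_selection(variants)
            # independent set
            for i, u in enumerate(got):
                for w in got[i + 1:]:
                    assert not variants_overlap(u, w)
            # every discarded variant was eliminated by a kept variant that
            # overlaps it and scores at least as high
            kept = set(got)
            for w in variants:
                if w not in kept:
                    assert any(variants_overlap(u, w) and u.score >= w.score
                               for u in got)
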