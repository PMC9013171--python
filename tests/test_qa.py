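"""Memory network: tuple encoding, intent rules, memory search, the
generalization rules, region-affinity attention, response generation, the
margin loss, training and evaluation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medkgqa import (EntityVectors, KnowledgeTuple, QaConfig, QaModel,
                     QaSystem, attend, attention_features, build_memory,
                     detect_intent, evaluate_qa, generalize,
                     label_qa_test_data, merge_triples, qa_margin_loss,
                     respond, train_qa)
from medkgqa.qa import MemoryStore, extract_question_entities, \
    process_question
from medkgqa.schema import RELATION_TYPES, RELATION_INDEX


@pytest.fixture(scope="module")
def toy_model():
    surfaces = [f"e{i}" for i in range(30)] + ["d1", "s1", "s2", "t1", "r1"]
    ev = EntityVectors.random(surfaces, dim=8, rng_seed=0)
    return QaModel(ev, QaConfig(encoder_dim=10), rng_seed=0)


# ---------------------------------------------------------------------------
# Tuples and encoding
# ---------------------------------------------------------------------------

def test_tuples_merge_and_sort_alphabetically():
    triples = [("d2", "hasSymptom", "s1"), ("d1", "hasSymptom", "s2"),
               ("d1", "hasSymptom", "s1"), ("d1", "needsTest", "t1")]
    merged = merge_triples(triples)
    assert [t.sort_key for t in merged] == sorted(t.sort_key for t in merged)
    d1_sym = [t for t in merged if t.subject == "d1" and
              t.relation == "hasSymptom"]
    assert len(d1_sym) == 1 and d1_sym[0].objects == ("s1", "s2")


def test_relation_one_hot_order_is_fixed():
    assert RELATION_TYPES[:2] == ("hasSymptom", "needsTest")
    assert [RELATION_INDEX[r] for r in RELATION_TYPES] == [0, 1, 2, 3, 4]


def test_encoding_deterministic_and_object_order_invariant(toy_model):
    a = toy_model.encode_tuple(KnowledgeTuple("d1", "hasSymptom", ("s1", "s2")))
    b = toy_model.encode_tuple(KnowledgeTuple("d1", "hasSymptom", ("s2", "s1")))
    assert np.array_equal(a, b)
    assert np.array_equal(a, toy_model.encode_tuple(
        KnowledgeTuple("d1", "hasSymptom", ("s1", "s2"))))


def test_unknown_entity_warns_and_uses_reserved_vector(toy_model):
    with pytest.warns(UserWarning):
        v = toy_model.entity_vecs("never seen before")
    assert np.array_equal(v, toy_model.entity_vecs.unknown)


# ---------------------------------------------------------------------------
# Intent detection
# ---------------------------------------------------------------------------

def test_what_disease_marker_maps_to_disease():
    intent, marker = detect_intent(["what", "disease", "with", "fever", "?"])
    assert intent == "Disease" and marker == ("what", "disease")


def test_first_matching_rule_wins_in_document_order():
    intent, _ = detect_intent(["what", "disease", "symptoms", "?"])
    assert intent == "Disease"


def test_no_marker_flags_unknown_intent():
    intent, marker = detect_intent(["tell", "me", "something"])
    assert intent is None and marker is None


def test_generator_intents_agree_with_rule_table(qa_pairs):
    for p in qa_pairs:
        intent, _ = detect_intent(p.question_tokens)
        assert intent == p.intent_type


# ---------------------------------------------------------------------------
# Memory search
# ---------------------------------------------------------------------------

def linear_scan(slots, entities):
    return sorted(i for i, s in enumerate(slots)
                  if set(s.tuple.entities()) & set(entities))


def test_absent_entity_gives_no_candidates(toy_model):
    mem = build_memory([KnowledgeTuple("d1", "hasSymptom", ("s1",))],
                       toy_model, {})
    assert mem.search(["zz"]) == []
    empty = build_memory([], toy_model, {})
    assert empty.search(["d1"]) == []


def test_object_entities_are_indexed_too(toy_model):
    mem = build_memory([KnowledgeTuple("d1", "hasSymptom", ("s1", "s2")),
                        KnowledgeTuple("d2", "needsTest", ("t1",))],
                       toy_model, {})
    assert mem.search(["s2"]) == [0]
    assert mem.search(["t1"]) == [1]
    assert mem.search(["d1", "t1"]) == [0, 1]


def test_search_matches_linear_scan_on_large_memory():
    rng = np.random.default_rng(0)
    names = [f"e{i}" for i in range(200)]
    ev = EntityVectors.random(names, dim=4, rng_seed=0)
    model = QaModel(ev, QaConfig(encoder_dim=4), rng_seed=0)
    triples = set()
    while len(triples) < 1000:
        s, o = rng.choice(200, size=2, replace=False)
        triples.add((names[s], RELATION_TYPES[int(rng.integers(5))], names[o]))
    mem = build_memory(merge_triples(triples), model, {})
    assert len(mem) <= 1000
    for _ in range(25):
        q = [names[i] for i in rng.choice(200, size=3, replace=False)]
        assert mem.search(q) == linear_scan(mem.slots, q)


# ---------------------------------------------------------------------------
# Generalization rules (memory management)
# ---------------------------------------------------------------------------

def test_question_input_above_floor_uses_memory_for_answer():
    d = generalize(0.76, 0.017, 3, "needsTreatment", "question", QaConfig(),
                   utilities=(0.0, 0.83))
    assert d.o_i == "use-for-answer" and d.v_i == 0.83


def test_knowledge_duplicate_with_higher_utility_replaces_old():
    d = generalize(0.76, 0.017, 3, "needsTreatment", "knowledge", QaConfig(),
                   utilities=(0.92, 0.83))
    assert d.o_i == "replace-old" and d.o_n == "store-new"
    d2 = generalize(0.76, 0.017, 3, "needsTreatment", "knowledge", QaConfig(),
                    utilities=(0.70, 0.83))
    assert d2.o_i == "no-op"  # old memory wins


def test_clean_command_forgets_unused_dissimilar_memory():
    d = generalize(0.0, 0.0, 2, "needsTest", "clean", QaConfig(),
                   utilities=(0.0, 0.03))
    assert d.o_i == "forget"
    d2 = generalize(0.0, 0.4, 2, "needsTest", "clean", QaConfig(),
                    utilities=(0.0, 0.5))
    assert d2.o_i == "no-op"  # frequently used memories survive cleaning


def test_rule_only_fallback_uses_similarity():
    d = generalize(0.76, 0.0, 3, "hasSymptom", "question", QaConfig())
    assert d.o_i == "use-for-answer"
    d2 = generalize(0.2, 0.0, 3, "hasSymptom", "question", QaConfig())
    assert d2.o_i == "no-op"


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

def test_identical_single_patches_give_unit_feature_triple():
    v = np.array([[1.0, 2.0, 3.0]])
    s, alpha, feats = attention_features(v, v)
    assert s.shape == (1, 1) and s[0, 0] == pytest.approx(1.0)
    assert alpha[0, 0] == pytest.approx(1.0)
    assert np.allclose(feats, [1.0, 1.0, 1.0])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(i=st.integers(1, 4), j=st.integers(1, 5), seed=st.integers(0, 10 ** 6))
def test_alpha_rows_are_probability_distributions(i, j, seed):
    rng = np.random.default_rng(seed)
    U, M = rng.normal(size=(i, 6)), rng.normal(size=(j, 6))
    _, alpha, _ = attention_features(U, M)
    assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-9)
    assert (alpha >= 0).all()


def test_fixed_W_ranking_equals_mean_cosine_oracle():
    rng = np.random.default_rng(4)
    U = rng.normal(size=(3, 6))
    mems = [rng.normal(size=(rng.integers(1, 5), 6)) for _ in range(8)]
    results, order = attend(U, mems, np.array([1.0, 0.0, 0.0]))

    def mean_cos(A, B):
        A = A / np.linalg.norm(A, axis=1, keepdims=True)
        B = B / np.linalg.norm(B, axis=1, keepdims=True)
        return (A @ B.T).mean()

    oracle = sorted(range(len(mems)),
                    key=lambda k: (-mean_cos(U, mems[k]), k))
    assert order == oracle


def test_zero_norm_patch_excluded_with_warning():
    U = np.array([[1.0, 0.0], [0.0, 0.0]])
    with pytest.warns(UserWarning):
        s, alpha, _ = attention_features(U, np.array([[1.0, 0.0]]))
    assert s.shape == (1, 1)


# ---------------------------------------------------------------------------
# Response
# ---------------------------------------------------------------------------

def test_single_candidate_memory_returns_it(toy_model):
    mem = build_memory([KnowledgeTuple("d1", "hasSymptom", ("s1",))],
                       toy_model, {"d1": "Disease", "s1": "Symptom"})
    q = process_question(["what", "disease", "with", "s1", "?"],
                         toy_model, mem)
    ans, sent, flagged = respond(q, mem.slots[0], toy_model, mem)
    assert ans == "d1" and not flagged
    assert sent.split().count("d1") == 1  # entity appears exactly once


def test_intentless_memory_falls_back_to_topk_pool(toy_model):
    types = {"d1": "Disease", "s1": "Symptom", "t1": "Test", "r1": "Result"}
    mem = build_memory([KnowledgeTuple("t1", "hasResult", ("r1",)),
                        KnowledgeTuple("d1", "hasSymptom", ("s1",))],
                       toy_model, types)
    q = process_question(["what", "disease", "with", "s1", "?"],
                         toy_model, mem)
    slot_without_disease = next(s for s in mem.slots if s.tuple.subject == "t1")
    ans, _, flagged = respond(q, slot_without_disease, toy_model, mem,
                              fallback_slots=mem.slots)
    assert flagged and ans == "d1"


def test_answer_selection_on_symptom_memory_returns_subject_disease(toy_model):
    """A "what disease" question matched to a symptom memory decodes the
    subject disease."""
    types = {"d1": "Disease", "s1": "Symptom", "s2": "Symptom"}
    mem = build_memory([KnowledgeTuple("d1", "hasSymptom", ("s1", "s2"))],
                       toy_model, types)
    sys = QaSystem(toy_model, mem)
    ans, sentence, diag = sys.answer(["what", "disease", "with", "s1", "and",
                                      "s2", "?"])
    assert ans == "d1"
    assert "d1" in sentence


# ---------------------------------------------------------------------------
# Margin loss
# ---------------------------------------------------------------------------

def test_satisfied_margin_first_term_zero():
    loss = qa_margin_loss(1.0, [-1.0, -1.0], 1.0, [], gamma=0.2)
    assert loss == 0.0


def test_equal_similarities_cost_gamma_each():
    n = 3
    loss = qa_margin_loss(0.5, [0.5] * n, 0.2, [0.2] * n, gamma=0.2)
    assert loss == pytest.approx(2 * 0.2 * n)


def test_loss_monotone_in_positive_similarity():
    negs = [0.1, 0.3]
    prev = None
    for s in np.linspace(-1, 1, 11):
        l = qa_margin_loss(s, negs, 1.0, [], gamma=0.2)
        if prev is not None:
            assert l <= prev + 1e-12
        prev = l


def test_no_negatives_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        assert qa_margin_loss(0.5, [], 0.5, [], gamma=0.2) == 0.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(-1, 1), st.lists(st.floats(-1, 1), max_size=4),
       st.floats(-1, 1), st.lists(st.floats(-1, 1), min_size=1, max_size=4),
       st.floats(0.01, 1))
def test_loss_nonnegative_and_zero_iff_margins_met(sp, sn, rp, rn, gamma):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loss = qa_margin_loss(sp, sn, rp, rn, gamma)
    assert loss >= 0.0
    met = all(sp - s >= gamma for s in sn) and all(rp - r >= gamma for r in rn)
    assert (loss == 0.0) == met


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------

def test_negative_sampler_avoids_question_and_answer_entities(toy_model):
    from medkgqa.qa import _sample_negatives

    triples = [(f"e{i}", "hasSymptom", f"e{i + 10}") for i in range(8)]
    mem = build_memory(merge_triples(triples), toy_model, {})
    rng = np.random.default_rng(0)
    forbidden = {"e0", "e10", "e1"}
    for _ in range(20):
        for ni in _sample_negatives(mem, forbidden, 3, rng):
            assert not (set(mem.slots[ni].tuple.entities()) & forbidden)


def test_disjoint_vocabularies_refuse_training(toy_model, qa_pairs):
    mem = build_memory([KnowledgeTuple("e1", "hasSymptom", ("e2",))],
                       toy_model, {})
    with pytest.raises(ValueError):
        train_qa(qa_pairs[:10], mem, toy_model)


def test_trained_qa_reaches_high_precision(small_kb, qa_pairs):
    ev = EntityVectors.random(small_kb.all_entities(), dim=16, rng_seed=1)
    cfg = QaConfig(encoder_dim=24, epochs=3)
    model = QaModel(ev, cfg, rng_seed=0)
    mem = build_memory(small_kb.tuples(), model, small_kb.entity_types())
    system, hist = train_qa(qa_pairs[:150], mem, model, cfg, rng_seed=0)
    types = small_kb.entity_types()

    def ent_ex(tokens):
        return [(e, types[e]) for e in
                extract_question_entities(tokens, set(types))]

    labeled = label_qa_test_data(qa_pairs[150:], ent_ex)
    res = evaluate_qa(system, labeled, n_resamples=5)
    assert res["p_at_1"] >= 0.9
    # ablating the memory strictly reduces precision
    ablated = QaSystem(model, build_memory([], model, {}), cfg)
    res0 = evaluate_qa(ablated, labeled, n_resamples=2)
    assert res0["p_at_1"] < res["p_at_1"]
    # phase-2 supervision incremented usage counts on supporting slots
    assert any(s.usage_count > 0 for s in mem.slots)
    assert mem.total_queries > 0


# ---------------------------------------------------------------------------
# Test-set labeling and metrics
# ---------------------------------------------------------------------------

def _const_extractor(mapping):
    def ex(tokens):
        return [(t, mapping[t]) for t in tokens if t in mapping]
    return ex


def test_majority_entity_wins():
    docs = [{"title": ["what", "disease", "?"],
             "body": ["d1", "x", "d1", "d1", "d2"]}]
    ex = _const_extractor({"d1": "Disease", "d2": "Disease"})
    labeled = label_qa_test_data(docs, ex)
    assert labeled[0]["answer"] == "d1"


def test_frequency_tie_drops_document():
    docs = [{"title": ["what", "disease", "?"], "body": ["d1", "d2"]}]
    ex = _const_extractor({"d1": "Disease", "d2": "Disease"})
    assert label_qa_test_data(docs, ex) == []


def test_multi_relation_documents_excluded():
    docs = [{"title": ["what", "disease", "?"], "body": ["d1", "d1"]}]
    ex = _const_extractor({"d1": "Disease"})
    two_rels = lambda body: {"hasSymptom", "needsTest"}
    assert label_qa_test_data(docs, ex, two_rels) == []
    one_rel = lambda body: {"hasSymptom"}
    assert len(label_qa_test_data(docs, ex, one_rel)) == 1


class FixedSystem:
    def __init__(self, answers):
        self.answers = answers
        self.i = -1

    def answer(self, tokens):
        self.i += 1
        return self.answers[self.i], None, {}


def test_metrics_all_correct_and_all_wrong():
    labeled = [{"title": ["q"], "answer": "a"}] * 5
    res = evaluate_qa(FixedSystem(["a"] * 5), labeled, n_resamples=3)
    assert res["p_at_1"] == 1.0 and res["f1"] == 1.0
    res = evaluate_qa(FixedSystem(["b"] * 5), labeled, n_resamples=3)
    assert res["p_at_1"] == 0.0 and res["f1"] == 0.0


def test_metrics_match_hand_confusion_on_ten_questions():
    labeled = [{"title": [str(i)], "answer": f"g{i}"} for i in range(10)]
    answers = [f"g{i}" for i in range(6)] + ["wrong"] * 2 + [None, None]
    res = evaluate_qa(FixedSystem(answers), labeled, n_resamples=2)
    # tp=6, fp=2, fn=4 -> precision .75, recall .6, F1 = 2*.45/1.35
    assert res["p_at_1"] == pytest.approx(0.6)
    assert res["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)
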