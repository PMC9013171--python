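"""Bootstrapping miner: context grids, the support/confidence/reliability
formulas against a brute-force counting oracle, validation channels, and
loop behaviour."""

import numpy as np
import pytest

from medkgqa import (BootstrapConfig, CandidatePattern, LedgerOracle,
                     SeedStore, StaticDictionaryOracle, UndefinedSupportError,
                     bidirectional_max_match, extract_entity_patterns,
                     extract_relation_patterns, match_pattern,
                     match_relation_pattern, run_bootstrap, score_pattern,
                     validate_candidates)
from medkgqa.bootstrap import CorpusIndex, document_frequencies
from medkgqa.pipeline import initial_seeds


def store_with(entities=None, relations=None):
    s = SeedStore()
    for etype, names in (entities or {}).items():
        for n in names:
            s.add_entity(n, etype, "manual")
    for tr in relations or []:
        s.add_relation(tr, "manual")
    return s


# ---------------------------------------------------------------------------
# Entity pattern extraction
# ---------------------------------------------------------------------------

def test_full_context_grid_gives_fifteen_candidates():
    corpus = [["w1", "w2", "w3", "seedx", "v1", "v2", "v3", "."]]
    seeds = store_with({"Disease": {"seedx"}})
    pats = extract_entity_patterns(corpus, seeds, "Disease")
    # 3x3 combinations + 3 left-only + 3 right-only
    assert len(pats) == 15
    assert all(p.left_context or p.right_context for p in pats)


def test_seed_at_sentence_start_has_no_left_contexts():
    corpus = [["seedx", "v1", "v2", "v3", "."]]
    seeds = store_with({"Disease": {"seedx"}})
    pats = extract_entity_patterns(corpus, seeds, "Disease")
    assert all(not p.left_context for p in pats)
    assert any(p.right_context for p in pats)


def test_worked_pattern_shape_is_extracted():
    corpus = [["treatment", "admission", "for", "diabetes", "and", "cure",
               "with", "cytosine", "."]]
    seeds = store_with({"Disease": {"diabetes"}, "Treatment": {"cytosine"}})
    pats = extract_entity_patterns(corpus, seeds, "Disease")
    keys = {(p.left_context, p.right_context) for p in pats}
    assert (("admission", "for"), ("and",)) in keys
    tre = extract_entity_patterns(corpus, seeds, "Treatment")
    keys = {(p.left_context, p.right_context) for p in tre}
    assert (("cure", "with"), ()) in keys  # right side open at sentence end


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def test_match_extracts_text_between_contexts():
    corpus = [["admitted", "admission", "for", "pneumonia", "and", "rest", "."]]
    pat = CandidatePattern("entity", "Disease",
                           left_context=("admission", "for"),
                           right_context=("and",))
    found = match_pattern(pat, corpus, BootstrapConfig())
    assert [f[0] for f in found] == ["pneumonia"]


def test_candidate_crossing_sentence_boundary_rejected():
    corpus = [["admission", "for", "flu", ".", "and", "rest", "."]]
    pat = CandidatePattern("entity", "Disease",
                           left_context=("admission", "for"),
                           right_context=("and",))
    assert match_pattern(pat, corpus, BootstrapConfig()) == []


def test_matched_strings_rewrap_into_the_corpus():
    rng = np.random.default_rng(0)
    vocab = [f"t{i}" for i in range(12)]
    corpus = [[vocab[i] for i in rng.integers(0, 12, size=40)] + ["."]
              for _ in range(10)]
    pat = CandidatePattern("entity", "Disease", left_context=("t1",),
                           right_context=("t2",))
    for s, di, a, b in match_pattern(pat, corpus, BootstrapConfig()):
        doc = " ".join(corpus[di])
        assert f"t1 {s} t2" in doc


# ---------------------------------------------------------------------------
# Scoring (support / confidence / reliability)
# ---------------------------------------------------------------------------

def brute_force_scores(pattern, corpus, seeds, w):
    """Independent counting oracle for the pattern statistics."""
    extracted = {m[0] for m in match_pattern(pattern, corpus, BootstrapConfig())}
    seed_all = {e for ss in seeds.entity_seeds.values() for e in ss}
    inter = extracted & seed_all
    support = len(inter) / len(extracted)
    confs = {}
    for c, members in seeds.entity_seeds.items():
        confs[c] = len(inter & members) / len(inter) if inter else 0.0
    return support, confs, w * support + (1 - w) * max(confs.values())


def test_scores_on_constructed_corpus():
    # pattern "l _ r" extracts {A, B, C}; seeds = {A, B}, both Disease
    corpus = [["l", "A", "r", ".", "l", "B", "r", ".", "l", "C", "r", "."]]
    seeds = store_with({"Disease": {"A", "B"}})
    pat = CandidatePattern("entity", "Disease", left_context=("l",),
                           right_context=("r",))
    scored = score_pattern(pat, corpus, seeds, BootstrapConfig(w=0.5))
    assert scored.support == pytest.approx(2 / 3)
    assert scored.confidence_by_type["Disease"] == pytest.approx(1.0)
    assert scored.score == pytest.approx(0.5 * 2 / 3 + 0.5 * 1.0)


def test_saturated_pattern_scores_one_for_any_weight():
    corpus = [["l", "A", "r", ".", "l", "B", "r", "."]]
    seeds = store_with({"Disease": {"A", "B"}})
    pat = CandidatePattern("entity", "Disease", left_context=("l",),
                           right_context=("r",))
    for w in (0.0, 0.3, 1.0):
        scored = score_pattern(pat, corpus, seeds, BootstrapConfig(w=w))
        assert scored.score == pytest.approx(1.0)
        assert scored.validated


@pytest.mark.parametrize("trial", range(5))
def test_scores_equal_brute_force_on_random_corpora(trial):
    rng = np.random.default_rng(trial)
    words = [f"e{i}" for i in range(8)]
    corpus = []
    for _ in range(6):
        doc = []
        for _ in range(25):
            doc += ["l", words[rng.integers(8)], "r"]
            if rng.random() < 0.5:
                doc.append(".")
        corpus.append(doc + ["."])
    assert sum(len(d) for d in corpus) <= 1000
    seeds = store_with({"Disease": set(words[:3]), "Symptom": set(words[3:5])})
    pat = CandidatePattern("entity", "Disease", left_context=("l",),
                           right_context=("r",))
    cfg = BootstrapConfig(w=0.4)
    scored = score_pattern(pat, corpus, seeds, cfg)
    support, confs, score = brute_force_scores(pat, corpus, seeds, 0.4)
    assert scored.support == pytest.approx(support)
    for c in confs:
        assert scored.confidence_by_type[c] == pytest.approx(confs[c])
    assert scored.score == pytest.approx(score)


def test_threshold_bracketing_point_seven():
    # support 0.5, confidence 1.0 under w -> score = w/2 + (1-w)
    corpus = [["l", "A", "r", ".", "l", "X", "r", "."]]
    seeds = store_with({"Disease": {"A"}})
    pat = CandidatePattern("entity", "Disease", left_context=("l",),
                           right_context=("r",))
    hi = score_pattern(pat, corpus, seeds, BootstrapConfig(w=0.58))
    assert hi.score == pytest.approx(0.71)
    assert hi.validated
    lo = score_pattern(pat, corpus, seeds, BootstrapConfig(w=0.62))
    assert lo.score == pytest.approx(0.69)
    assert not lo.validated


def test_pattern_extracting_nothing_raises():
    corpus = [["a", "b", "."]]
    seeds = store_with({"Disease": {"zz"}})
    pat = CandidatePattern("entity", "Disease", left_context=("q",),
                           right_context=("w",))
    with pytest.raises(UndefinedSupportError):
        score_pattern(pat, corpus, seeds, BootstrapConfig())


# ---------------------------------------------------------------------------
# Relation patterns
# ---------------------------------------------------------------------------

def test_relation_context_and_substrings():
    corpus = [["admission", "for", "diabetes", "cure", "with", "cytosine",
               "end", "."]]
    seeds = store_with({"Disease": {"diabetes"}, "Treatment": {"cytosine"}},
                       [("diabetes", "needsTreatment", "cytosine")])
    pats = extract_relation_patterns(corpus, seeds, BootstrapConfig())
    ctxs = {p.context_string for p in pats}
    # context words: for(pre) cure with end(post); 4 words -> 10 substrings
    assert ("cure", "with") in ctxs
    assert len([p for p in pats if not p.degenerate]) == 4 * 5 // 2


def test_adjacent_entities_give_degenerate_empty_pattern():
    corpus = [["diabetes", "cytosine", "."]]
    cfg = BootstrapConfig(stop_words=frozenset({".", "?"}))
    seeds = store_with({"Disease": {"diabetes"}, "Treatment": {"cytosine"}},
                       [("diabetes", "needsTreatment", "cytosine")])
    pats = extract_relation_patterns(corpus, seeds, cfg)
    assert len(pats) == 1
    assert pats[0].degenerate and pats[0].context_string == ()


def test_relation_pattern_matches_typed_pairs():
    corpus = [["admission", "for", "diabetes", "cure", "with", "cytosine", "."],
              ["admission", "for", "flu", "cure", "with", "aspirin", "."]]
    seeds = store_with({"Disease": {"diabetes", "flu"},
                        "Treatment": {"cytosine", "aspirin"}},
                       [("diabetes", "needsTreatment", "cytosine")])
    pat = CandidatePattern("relation", "needsTreatment",
                           context_string=("cure", "with"), subject_first=True)
    found = match_relation_pattern(pat, corpus, seeds, BootstrapConfig())
    pairs = {(s, o) for (s, _, o, _) in found}
    assert pairs == {("diabetes", "cytosine"), ("flu", "aspirin")}


def test_bidirectional_max_match_groups_dictionary_words():
    dictionary = {"a b", "b c d"}
    assert bidirectional_max_match(["a", "b", "c", "d"], dictionary) \
        == ["a", "b c d"]
    assert bidirectional_max_match(["x", "a", "b", "y"], dictionary) \
        == ["x", "a b", "y"]


# ---------------------------------------------------------------------------
# Validation channels
# ---------------------------------------------------------------------------

def test_dictionary_hit_short_circuits():
    oracle = StaticDictionaryOracle({"flu"})
    acc, q, rej, log = validate_candidates(["flu"], oracle, BootstrapConfig())
    assert acc == {"flu"} and not q and not rej
    assert log[0][2] == "dictionary"


def test_score_c_saturation_and_routing():
    cfg = BootstrapConfig(search_K=10)
    oracle = StaticDictionaryOracle(set(), searchable={"hit"})
    acc, q, rej, log = validate_candidates(["hit"], oracle, cfg,
                                           from_lowband=True)
    # |H| = K -> Score_c = 1.0 -> human channel (static oracle cannot judge)
    assert q == {"hit"}

    class ThreeOfTen(StaticDictionaryOracle):
        def topk_hits(self, c, k):
            return 3

    acc, q, rej, log = validate_candidates(["x"], ThreeOfTen(set()), cfg,
                                           from_lowband=True)
    assert q == {"x"}  # Score_c = 0.3 meets the low band -> queued
    assert "search:0.30" in log[0][2]

    class OneOfTen(StaticDictionaryOracle):
        def topk_hits(self, c, k):
            return 1

    acc, q, rej, _ = validate_candidates(["x"], OneOfTen(set()), cfg,
                                         from_lowband=True)
    assert rej == {"x"}


def test_no_oracle_queues_everything():
    acc, q, rej, _ = validate_candidates(["a", "b"], None, BootstrapConfig())
    assert not acc and q == {"a", "b"} and not rej


# ---------------------------------------------------------------------------
# The loop
# ---------------------------------------------------------------------------

def test_fixed_point_terminates_after_one_growth_check():
    corpus = [["l", "A", "r", ".", "l", "B", "r", "."]]
    seeds = store_with({"Disease": {"A", "B"}})
    oracle = StaticDictionaryOracle({"A", "B"})
    _, seeds, _, trace = run_bootstrap(corpus, seeds, BootstrapConfig(), oracle)
    assert len(trace["iterations"]) == 1
    assert not trace["truncated"]


def test_planted_expansion_chain_of_depth_three():
    # e1 seeds context c1; c1 extracts e2; e2's second context extracts e3 ...
    corpus = [
        ["a1", "b1", "e1", "c1", "d1", "."],
        ["a1", "b1", "e2", "c1", "d1", "."],   # e2 shares e1's context
        ["a2", "b2", "e2", "c2", "d2", "."],
        ["a2", "b2", "e3", "c2", "d2", "."],   # e3 shares e2's second context
        ["a3", "b3", "e3", "c3", "d3", "."],
        ["a3", "b3", "e4", "c3", "d3", "."],   # e4 reached at depth 3
    ]
    seeds = store_with({"Disease": {"e1"}})
    oracle = StaticDictionaryOracle({"e1", "e2", "e3", "e4"})
    _, seeds, _, trace = run_bootstrap(corpus, seeds, BootstrapConfig(), oracle)
    assert seeds.entity_seeds["Disease"] == {"e1", "e2", "e3", "e4"}
    growth = [it["new"] for it in trace["iterations"] if it["new"] > 0]
    assert len(growth) == 3


def test_seed_counts_monotone_nondecreasing(clean_run):
    trace = clean_run["bootstrap"]["trace"]
    last = None
    for it in trace["iterations"]:
        total = sum(v for k, v in it.items() if k not in ("iteration", "new"))
        if last is not None:
            assert total >= last
        last = total


def test_bootstrap_recovers_planted_instances(small_kb, small_corpus,
                                              ledger_oracle, seed_store):
    records, ledger = small_corpus
    import copy

    seeds = copy.deepcopy(seed_store)
    annotated, seeds, library, trace = run_bootstrap(
        records, seeds, BootstrapConfig(), ledger_oracle)
    occurring = {i["entity"] for i in ledger.insertions}
    mined = seeds.all_entities()
    assert len(mined & occurring) / len(occurring) >= 0.95
    assert mined <= small_kb.all_entities()  # precision 1.0 on noise-free text
    mined_rel = {t for b in seeds.relation_seeds.values() for t in b}
    occ_rel = {i["triple"] for i in ledger.insertions}
    assert len(mined_rel & occ_rel) / len(occ_rel) >= 0.95
    assert mined_rel <= small_kb.relations
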