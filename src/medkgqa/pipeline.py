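"""End-to-end pipeline harness: synth -> bootstrap -> taggers -> fusion -> QA.

One function runs the whole study at a configurable (small) scale and
returns every stage artifact plus the headline metrics.  Defaults are the
package's desk-scale study conditions: a balanced KB of 12 entities per
type and 6 relations per type, ~300 records averaging 3.3 statements,
250 QA pairs, and scaled-down network dimensions.
"""

from __future__ import annotations

import logging

import numpy as np

from .bootstrap import (BootstrapConfig, SeedStore, annotate_corpus,
                        run_bootstrap)
from .corpus import generate_kb, render_qa_pairs, render_records
from .fusion import CharNgramVectorizer, FusionConfig, collect_extractions, fuse
from .oracle import LedgerOracle
from .qa import (EntityVectors, QaConfig, QaModel, QaSystem, build_memory,
                 evaluate_qa, label_qa_test_data, train_qa)
from .relation import (RelationCnnConfig, build_relation_examples,
                       classify_pair, classify_relation, train_relation_cnn,
                       ENT_SLOT)
from .schema import NONE_RELATION, RELATION_SIGNATURE
from .tagger import TaggerConfig, extract_entities, span_f1, train_tagger

log = logging.getLogger("medkgqa")


def initial_seeds(kb, n_entities: int = 5, n_relations: int = 3) -> SeedStore:
    """Deterministic manual seed selection from the planted KB."""
    seeds = SeedStore()
    for t, es in kb.entities.items():
        for e in sorted(es)[:n_entities]:
            seeds.add_entity(e, t, "manual")
    by_rel = {}
    for tr in sorted(kb.relations):
        by_rel.setdefault(tr[1], []).append(tr)
    for r, ts in by_rel.items():
        for tr in ts[:n_relations]:
            seeds.add_relation(tr, "manual")
    return seeds


def small_tagger_config(**over) -> TaggerConfig:
    cfg = dict(embed_dim=24, hidden=24, crf_input_dim=24, epochs=30,
               patience=4, use_bridge=True)
    cfg.update(over)
    return TaggerConfig(**cfg)


def small_cnn_config(**over) -> RelationCnnConfig:
    cfg = dict(word_dim=24, window_len=12, kernel_h=3, n_kernels=8,
               fc_units=32, epochs=20, patience=4, pretrain_epochs=2)
    cfg.update(over)
    return RelationCnnConfig(**cfg)


def extract_with_models(records, tagger_model, cnn_model, pv_model,
                        enumerate_substrings: bool = False):
    """Model-based extraction over raw text, for fusion.

    Tags every record with the trained tagger, then classifies each
    within-sentence typed entity pair with the CNN.  Returns
    (mentions, triple_counts) in the shape fusion consumes.
    """
    from collections import Counter

    mention_counts = Counter()
    mention_types = {}
    triple_counts = Counter()
    for pid, rec in enumerate(records):
        toks = rec.tokens if hasattr(rec, "tokens") else list(rec)
        spans = extract_entities(toks, tagger_model)
        for (a, b, t, surf) in spans:
            mention_counts[surf] += 1
            mention_types[surf] = t
        # sentence-local pairs
        bounds, start = [], 0
        for i, t in enumerate(toks):
            if t == ".":
                bounds.append((start, i + 1))
                start = i + 1
        if start < len(toks):
            bounds.append((start, len(toks)))
        for (s, e) in bounds:
            local = [sp for sp in spans if s <= sp[0] and sp[1] <= e]
            for i in range(len(local)):
                for j in range(i + 1, len(local)):
                    sp1, sp2 = local[i], local[j]
                    pre = [toks[sp1[0] - 1]] if sp1[0] - 1 >= s else []
                    post = [toks[sp2[1]]] if sp2[1] < e else []
                    words = tuple(pre) + (ENT_SLOT,) + tuple(
                        toks[sp1[1]:sp2[0]]) + (ENT_SLOT,) + tuple(post)
                    pvec = np.zeros(cnn_model.config.word_dim)
                    label, conf = classify_pair(
                        words, (sp1[3], sp2[3]), pvec, cnn_model,
                        enumerate_substrings=enumerate_substrings)
                    if label == NONE_RELATION:
                        continue
                    sub_t, obj_t = RELATION_SIGNATURE[label]
                    if sp1[2] == sub_t and sp2[2] == obj_t:
                        triple_counts[(sp1[3], label, sp2[3])] += 1
                    elif sp2[2] == sub_t and sp1[2] == obj_t:
                        triple_counts[(sp2[3], label, sp1[3])] += 1
    mentions = {s: (mention_types[s], c) for s, c in mention_counts.items()}
    return mentions, dict(triple_counts)


def run_pipeline(seed: int = 0, n_entities: int = 12, n_relations: int = 6,
                 n_records: int = 300, n_qa: int = 250,
                 mean_statements: float = 3.3, noise_rate: float = 0.0,
                 use_model_extraction: bool = True,
                 heldout_records: int = 40) -> dict:
    """The full study at desk scale; returns artifacts and metrics."""
    rng = np.random.default_rng(seed)
    out = {"seed": seed, "noise_rate": noise_rate}

    # ---- synthesis ------------------------------------------------------
    kb = generate_kb(n_entities, n_relations, rng_seed=seed)
    records, ledger = render_records(kb, n_records + heldout_records,
                                     mean_statements, noise_rate,
                                     rng_seed=seed + 1)
    train_records, test_records = records[:n_records], records[n_records:]
    qa_pairs, _ = render_qa_pairs(kb, n_qa, rng_seed=seed + 2)
    n_qa_test = max(20, n_qa // 5)
    qa_train, qa_test = qa_pairs[:-n_qa_test], qa_pairs[-n_qa_test:]
    oracle = LedgerOracle(kb, ledger)
    out.update(kb=kb, ledger=ledger, records=records, qa_pairs=qa_pairs)

    # ---- bootstrapping --------------------------------------------------
    seeds = initial_seeds(kb)
    annotated, seeds, library, trace = run_bootstrap(
        train_records, seeds, BootstrapConfig(), oracle)
    occurring = {i["entity"] for i in ledger.insertions}
    mined = seeds.all_entities()
    canon_mined = {ledger.canonical_of(m) or m for m in mined}
    out["bootstrap"] = {
        "trace": trace,
        "entity_recall": len(canon_mined & occurring) / len(occurring),
        "entity_precision": (sum(1 for m in mined
                                 if ledger.canonical_of(m) is not None)
                             / len(mined)),
        "relation_recall": (len({t for b in seeds.relation_seeds.values()
                                 for t in b} & kb.relations)
                            / max(1, len({i["triple"] for i in ledger.insertions}))),
        "relation_precision": (1.0 if not ({t for b in seeds.relation_seeds.values()
                                            for t in b} - kb.relations) else 0.0),
    }
    log.info("bootstrap: %s", out["bootstrap"])

    # ---- sequence tagger ------------------------------------------------
    tagger_model, tagger_hist = train_tagger(
        annotated, small_tagger_config(), rng_seed=seed + 3,
        pattern_library=library)
    f1s = []
    for rec in test_records:
        gold = [(s.start, s.end, s.entity_type) for s in rec.gold_spans]
        pred = [(a, b, t) for a, b, t, _ in extract_entities(rec.tokens,
                                                             tagger_model)]
        f1s.append(span_f1(gold, pred))
    out["tagger"] = {"span_f1": float(np.mean(f1s)), "history": tagger_hist}
    log.info("tagger span F1 = %.4f", out["tagger"]["span_f1"])

    # ---- relation CNN ---------------------------------------------------
    examples, paragraphs = build_relation_examples(annotated, rng_seed=seed + 4)
    idx = rng.permutation(len(examples))
    n_te = max(1, len(examples) // 5)
    test_ex = [examples[i] for i in idx[:n_te]]
    train_ex = [examples[i] for i in idx[n_te:]]
    cnn_model, pv_model, cnn_hist = train_relation_cnn(
        train_ex, paragraphs, small_cnn_config(), rng_seed=seed + 5)
    from sklearn.metrics import f1_score

    y_true, y_pred = [], []
    for ex in test_ex:
        pvec = pv_model.D.data[ex.paragraph_id]
        lab, _ = classify_relation(ex, pvec, cnn_model)
        y_true.append(ex.label)
        y_pred.append(lab)
    rel_labels = sorted({l for l in y_true if l != NONE_RELATION})
    out["relation"] = {
        "macro_f1": float(f1_score(y_true, y_pred, labels=rel_labels,
                                   average="macro", zero_division=0)),
        "history": cnn_hist}
    log.info("relation macro F1 = %.4f", out["relation"]["macro_f1"])

    # ---- fusion ---------------------------------------------------------
    if use_model_extraction:
        mentions, triple_counts = extract_with_models(
            train_records, tagger_model, cnn_model, pv_model)
    else:
        mentions, triple_counts = collect_extractions(annotated)
    vec = CharNgramVectorizer(list(mentions) or ["x"])
    graph = fuse(mentions, triple_counts, vec, FusionConfig(), oracle,
                 groundings=kb.groundings)
    planted = {t for t in kb.relations if any(i["triple"] == t
                                              for i in ledger.insertions)}
    got = set(graph.triple_counts)
    out["fusion"] = {"report": graph.report,
                     "tuple_recall": len(got & planted) / max(1, len(planted)),
                     "tuple_precision": (len(got & planted) / len(got)) if got else 0.0,
                     "exact_match": got == planted}
    out["graph"] = graph
    log.info("fusion: %s", out["fusion"])

    # ---- memory + QA ----------------------------------------------------
    surfaces = set(graph.entities)
    entity_vecs = EntityVectors.from_tagger(tagger_model, surfaces)
    qa_config = QaConfig(encoder_dim=24, epochs=4)
    qa_model = QaModel(entity_vecs, qa_config, rng_seed=seed + 6)
    memory = build_memory(graph, qa_model)
    system, qa_hist = train_qa(qa_train, memory, qa_model, qa_config,
                               rng_seed=seed + 7)
    types = graph.entity_types()

    def entity_extractor(tokens):
        from .qa import extract_question_entities

        ents = extract_question_entities(tokens, set(types))
        return [(e, types[e]) for e in ents]

    labeled = label_qa_test_data(qa_test, entity_extractor)
    metrics = evaluate_qa(system, labeled, rng_seed=seed + 8)
    ablated = QaSystem(qa_model, build_memory([], qa_model, {}), qa_config)
    metrics_ablated = evaluate_qa(ablated, labeled, n_resamples=2,
                                  rng_seed=seed + 8)
    out["qa"] = {"metrics": metrics, "ablated_p_at_1": metrics_ablated["p_at_1"],
                 "n_labeled": len(labeled), "history": qa_hist}
    out["system"] = system
    log.info("qa: %s", out["qa"])
    return out
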