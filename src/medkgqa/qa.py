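"""Memory-network question answering over the fused knowledge graph.

Knowledge tuples become memory slots: each <subject, relation, {objects}>
is encoded patch-by-patch (entity vectors from the co-trained embedding,
the relation as a one-hot-derived embedding) and summarised by an LSTM
tuple encoder.  A question is processed the same way: rule-table intent
detection finds the target entity type, entity mentions become patches, a
placeholder patch stands for the question word.

Answering selects candidate slots sharing an entity with the question
(binary search in the sorted memory), ranks them by region-affinity
attention

    s_ij = < u_i / ||u_i||, m_j / ||m_j|| >,    alpha_ij = softmax_j(s_ij),
    Att  = W . [ mean(s), sum(alpha * s), max(alpha) ],

and decodes an answer entity of the intent type from the top memory with a
trained response head, rendered through a per-intent text frame.

Training is two-phase: first the attention weights, tuple encoder and
response head on a margin ranking loss with negative memories and answers
sampled disjoint from the question/answer entities; then the
generalization utility MLP, supervised by which memories supported correct
answers (usage counts increment there too).
"""

from __future__ import annotations

import bisect
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .corpus import INTENT_MARKERS
from .schema import (ENTITY_TYPES, KnowledgeTuple, RELATION_INDEX,
                     RELATION_TYPES, merge_triples, relation_one_hot)

ANSWER_TEMPLATES = {
    "Disease": ("it", "seems", "to", "be", "{}", "."),
    "Symptom": ("typical", "signs", "are", "{}", "."),
    "Treatment": ("the", "advised", "treatment", "is", "{}", "."),
    "Test": ("the", "indicated", "test", "is", "{}", "."),
    "Result": ("the", "expected", "finding", "is", "{}", "."),
}


@dataclass
class QaConfig:
    encoder_dim: int = 32
    gamma: float = 0.2            # margin of the ranking loss
    n_negatives: int = 5
    top_k: int = 1                # memories used for answering
    answer_floor: float = 0.5     # v_i floor for use-for-answer
    dup_floor: float = 0.7        # similarity floor for replace decisions
    usage_floor: float = 0.05     # used-times floor under which forget applies
    lr: float = 0.02
    epochs: int = 8
    utility_epochs: int = 60


# ---------------------------------------------------------------------------
# Entity vectors
# ---------------------------------------------------------------------------

class EntityVectors:
    """Fixed vector per entity surface; unknowns share a reserved vector."""

    def __init__(self, vectors: dict, dim: int):
        self.vectors = {k: np.asarray(v, dtype=float) for k, v in vectors.items()}
        self.dim = dim
        rng = np.random.default_rng(0)
        self.unknown = rng.normal(0, 0.1, size=dim)

    @classmethod
    def from_tagger(cls, tagger_model, surfaces):
        from .tagger import embed_entity

        vecs = {s: embed_entity(tagger_model, s) for s in surfaces}
        return cls(vecs, tagger_model.config.embed_dim)

    @classmethod
    def random(cls, surfaces, dim: int = 16, rng_seed: int = 0):
        rng = np.random.default_rng(rng_seed)
        return cls({s: rng.normal(0, 1, size=dim) for s in sorted(surfaces)}, dim)

    def __call__(self, surface: str) -> np.ndarray:
        v = self.vectors.get(surface)
        if v is None:
            warnings.warn(f"unknown entity {surface!r}; using reserved vector")
            return self.unknown
        return v


# ---------------------------------------------------------------------------
# Tuple encoding
# ---------------------------------------------------------------------------

class QaModel:
    """All trainable pieces of the QA network."""

    def __init__(self, entity_vecs: EntityVectors, config: QaConfig,
                 rng_seed: int = 0):
        self.entity_vecs = entity_vecs
        self.config = config
        rng = np.random.default_rng(rng_seed)
        de, dh = entity_vecs.dim, config.encoder_dim
        p = {}
        # relation embedding rows are seeded from the one-hot coding
        R = np.zeros((len(RELATION_TYPES), de))
        for i in range(len(RELATION_TYPES)):
            R[i, i % de] = 1.0
        p["R"] = nn.Param(R + rng.normal(0, 0.01, size=R.shape))
        p["placeholder"] = nn.Param(rng.normal(0, 0.1, size=de))
        nn.init_lstm(rng, p, "enc_", de, dh)
        p["W_att"] = nn.Param(np.array([1.0, 1.0, 1.0]) / 3.0)
        p["D1"] = nn.init_matrix(rng, 2 * dh, dh)
        p["D1b"] = nn.Param(np.zeros(dh))
        p["D2"] = nn.init_matrix(rng, dh, de)
        p["D2b"] = nn.Param(np.zeros(de))
        # generalization utility MLP over [sim, used, n_entities, rel one-hot]
        p["G1"] = nn.init_matrix(rng, 8, 16)
        p["G1b"] = nn.Param(np.zeros(16))
        p["G2"] = nn.init_matrix(rng, 16, 2)
        p["G2b"] = nn.Param(np.zeros(2))
        self.params = p

    # ---- encoding -------------------------------------------------------
    def tuple_patches(self, tup: KnowledgeTuple) -> np.ndarray:
        """Patch matrix: subject vector, relation embedding, sorted objects."""
        rows = [self.entity_vecs(tup.subject),
                self.params["R"].data[RELATION_INDEX[tup.relation]]]
        rows += [self.entity_vecs(o) for o in tup.objects]  # objects pre-sorted
        return np.stack(rows)

    def question_patches(self, entities, relation: str | None) -> np.ndarray:
        rows = [self.entity_vecs(e) for e in entities]  # may be empty
        if relation is not None:
            rows.append(self.params["R"].data[RELATION_INDEX[relation]])
        rows.append(self.params["placeholder"].data)
        return np.stack(rows)

    def encode_patches(self, patches: np.ndarray):
        """LSTM summary of a patch sequence -> (encoder_dim,) tensor."""
        dh = self.config.encoder_dim
        h = nn.Tensor(np.zeros((1, dh)))
        c = nn.Tensor(np.zeros((1, dh)))
        for i in range(patches.shape[0]):
            x = nn.Tensor(patches[i:i + 1])
            h, c = nn.lstm_step(self.params, "enc_", x, h, c)
        return h.reshape(-1)

    def encode_tuple(self, tup: KnowledgeTuple) -> np.ndarray:
        return self.encode_patches(self.tuple_patches(tup)).data.copy()

    def decode(self, u_enc, m_enc):
        """Response head: joint [u, m] -> predicted answer-entity vector."""
        z = nn.concat([u_enc, m_enc], axis=0)
        hid = (z @ self.params["D1"] + self.params["D1b"]).tanh()
        return hid @ self.params["D2"] + self.params["D2b"]

    def utility(self, features: np.ndarray):
        """(v_n, v_i) in (0,1) from the Table-style feature vector."""
        z = nn.Tensor(features)
        hid = (z @ self.params["G1"] + self.params["G1b"]).tanh()
        return (hid @ self.params["G2"] + self.params["G2b"]).sigmoid()


def encode_tuple(tup: KnowledgeTuple, model: QaModel) -> np.ndarray:
    """Deterministic tuple vector (objects in sorted order)."""
    return model.encode_tuple(tup)


# ---------------------------------------------------------------------------
# Memory
# ---------------------------------------------------------------------------

@dataclass
class MemorySlot:
    tuple: KnowledgeTuple
    vector: np.ndarray
    usage_count: int = 0

    @property
    def sort_key(self):
        return self.tuple.sort_key


class MemoryStore:
    """Sorted memory with entity indexes for O(log n) candidate lookup."""

    def __init__(self, tuples, model: QaModel, entity_types: dict | None = None):
        merged = sorted(tuples, key=lambda t: t.sort_key)
        self.slots = [MemorySlot(t, model.encode_tuple(t)) for t in merged]
        self.entity_types = dict(entity_types or {})
        self._subject_keys = [s.tuple.subject for s in self.slots]
        pairs = sorted((o, i) for i, s in enumerate(self.slots)
                       for o in s.tuple.objects)
        self._object_keys = [p[0] for p in pairs]
        self._object_slots = [p[1] for p in pairs]
        self.total_queries = 0

    def __len__(self):
        return len(self.slots)

    def all_entities(self) -> set:
        return {e for s in self.slots for e in s.tuple.entities()}

    def search(self, entities) -> list:
        """Slot indices sharing >=1 entity with the question (binary search)."""
        hits = set()
        for e in entities:
            lo = bisect.bisect_left(self._subject_keys, e)
            while lo < len(self._subject_keys) and self._subject_keys[lo] == e:
                hits.add(lo)
                lo += 1
            lo = bisect.bisect_left(self._object_keys, e)
            while lo < len(self._object_keys) and self._object_keys[lo] == e:
                hits.add(self._object_slots[lo])
                lo += 1
        return sorted(hits)

    def used_times_feature(self, slot: MemorySlot) -> float:
        return slot.usage_count / self.total_queries if self.total_queries else 0.0


def build_memory(graph_or_tuples, model: QaModel,
                 entity_types: dict | None = None) -> MemoryStore:
    """Memory slots from a fused KnowledgeGraph or an iterable of tuples."""
    if hasattr(graph_or_tuples, "tuples"):
        tuples = graph_or_tuples.tuples
        entity_types = entity_types or graph_or_tuples.entity_types()
    else:
        tuples = list(graph_or_tuples)
        if tuples and not isinstance(tuples[0], KnowledgeTuple):
            tuples = merge_triples(tuples)
    return MemoryStore(tuples, model, entity_types)


# ---------------------------------------------------------------------------
# Input processing
# ---------------------------------------------------------------------------

def detect_intent(question_tokens, rule_table=None):
    """(intent type, placeholder phrase) by first-matching marker rule."""
    rules = rule_table or INTENT_MARKERS
    toks = list(question_tokens)
    for marker, intent in rules:
        m = list(marker)
        for i in range(len(toks) - len(m) + 1):
            if toks[i:i + len(m)] == m:
                return intent, tuple(m)
    return None, None


_INTENT_RELATION = {
    "Symptom": "hasSymptom",
    "Treatment": "needsTreatment",
    "Test": "needsTest",
    "Result": "hasTestResult",
}


def extract_question_entities(question_tokens, known_surfaces) -> list:
    """Longest-match known entity surfaces in the question."""
    by_first = {}
    for s in known_surfaces:
        toks = tuple(s.split())
        by_first.setdefault(toks[0], []).append(toks)
    for v in by_first.values():
        v.sort(key=len, reverse=True)
    out, i = [], 0
    toks = list(question_tokens)
    while i < len(toks):
        hit = None
        for cand in by_first.get(toks[i], ()):
            if tuple(toks[i:i + len(cand)]) == cand:
                hit = cand
                break
        if hit:
            out.append(" ".join(hit))
            i += len(hit)
        else:
            i += 1
    return out


@dataclass
class QuestionRep:
    u: np.ndarray                  # encoded question vector
    patches: np.ndarray
    intent: str | None
    entities: list
    relation: str | None
    placeholder: tuple | None


def process_question(question_tokens, model: QaModel, memory: MemoryStore,
                     rule_table=None) -> QuestionRep:
    intent, marker = detect_intent(question_tokens, rule_table)
    entities = extract_question_entities(question_tokens, memory.all_entities())
    relation = _INTENT_RELATION.get(intent)
    patches = model.question_patches(entities, relation)
    u = model.encode_patches(patches).data.copy()
    return QuestionRep(u, patches, intent, entities, relation, marker)


# ---------------------------------------------------------------------------
# Attention response
# ---------------------------------------------------------------------------

@dataclass
class AttentionResult:
    similarities: np.ndarray   # s_ij
    alpha: np.ndarray          # row-softmax over memory patches
    features: np.ndarray       # [mean(s), sum(alpha*s), max(alpha)]
    score: float               # Att = W . features


def attention_features(u_patches: np.ndarray, m_patches: np.ndarray):
    """(s, alpha, features) for one question/memory patch pair."""
    def normed(M):
        out, keep = [], []
        for i, row in enumerate(np.atleast_2d(M)):
            n = np.linalg.norm(row)
            if n == 0:
                warnings.warn("zero-norm patch excluded from attention")
                continue
            out.append(row / n)
            keep.append(i)
        return np.stack(out) if out else np.zeros((0, np.atleast_2d(M).shape[1]))

    U, M = normed(u_patches), normed(m_patches)
    if U.shape[0] == 0 or M.shape[0] == 0:
        return np.zeros((0, 0)), np.zeros((0, 0)), np.zeros(3)
    s = U @ M.T
    e = np.exp(s - s.max(axis=1, keepdims=True))
    alpha = e / e.sum(axis=1, keepdims=True)
    feats = np.array([s.mean(), float((alpha * s).sum()), float(alpha.max())])
    return s, alpha, feats


def attend(u_patches: np.ndarray, memory_patches: list, W: np.ndarray):
    """AttentionResult per memory plus a ranking (descending Att score).

    Ties break by position in the sorted memory (the slot sort key order).
    """
    results = []
    for mp in memory_patches:
        s, alpha, feats = attention_features(u_patches, mp)
        results.append(AttentionResult(s, alpha, feats, float(W @ feats)))
    order = sorted(range(len(results)),
                   key=lambda i: (-results[i].score, i))
    return results, order


# ---------------------------------------------------------------------------
# Generalization (memory management)
# ---------------------------------------------------------------------------

@dataclass
class UtilityDecision:
    v_n: float
    v_i: float
    o_n: str   # operation on the new input
    o_i: str   # operation on the existing slot


def generalization_features(similarity: float, used_times: float,
                            n_entities: int, relation: str) -> np.ndarray:
    return np.concatenate([[similarity, used_times, float(n_entities)],
                           relation_one_hot(relation)])


def generalize(input_similarity: float, used_times: float, n_entities: int,
               relation: str, input_type: str, config: QaConfig,
               model: QaModel | None = None,
               utilities: tuple | None = None) -> UtilityDecision:
    """Utility values and memory operations for one (input, slot) pair.

    ``input_type`` is "question", "knowledge" or "clean".  Utilities come
    from the trained MLP when a model is given, from ``utilities`` when
    supplied explicitly, else from the rule-only fallback (v = similarity).
    """
    feats = generalization_features(input_similarity, used_times, n_entities,
                                    relation)
    if utilities is not None:
        v_n, v_i = float(utilities[0]), float(utilities[1])
    elif model is not None:
        v = model.utility(feats).data
        v_n, v_i = float(v[0]), float(v[1])
    else:
        v_n = v_i = float(input_similarity)
    o_n, o_i = "no-op", "no-op"
    if input_type == "question":
        if v_i >= config.answer_floor:
            o_i = "use-for-answer"
    elif input_type == "knowledge":
        if input_similarity >= config.dup_floor and v_n > v_i:
            o_n, o_i = "store-new", "replace-old"
        elif input_similarity < config.dup_floor:
            o_n = "store-new"
    elif input_type == "clean":
        if input_similarity <= 0.0 and used_times < config.usage_floor:
            o_i = "forget"
    else:
        raise ValueError(f"unknown input type {input_type!r}")
    return UtilityDecision(v_n, v_i, o_n, o_i)


# ---------------------------------------------------------------------------
# Response generation
# ---------------------------------------------------------------------------

def respond(q: QuestionRep, slot: MemorySlot, model: QaModel,
            memory: MemoryStore, fallback_slots=()):
    """(answer entity, rendered sentence, flagged) for the selected memory."""
    intent = q.intent
    types = memory.entity_types
    cands = [e for e in slot.tuple.entities() if types.get(e) == intent] \
        if intent else list(slot.tuple.entities())
    flagged = False
    if not cands:
        pool = Counter()
        for s in fallback_slots:
            for e in s.tuple.entities():
                if types.get(e) == intent:
                    pool[e] += 1
        if not pool:
            return None, None, True
        cands, flagged = [pool.most_common(1)[0][0]], True
    if len(cands) == 1:
        answer = cands[0]
    else:
        u_enc = nn.Tensor(q.u)
        m_enc = nn.Tensor(slot.vector)
        pred = model.decode(u_enc, m_enc).data
        pn = np.linalg.norm(pred) or 1.0
        scored = []
        for e in cands:
            v = model.entity_vecs(e)
            nv = np.linalg.norm(v) or 1.0
            scored.append((float(pred @ v / (pn * nv)), e))
        answer = max(scored, key=lambda x: (x[0], x[1]))[1]
    template = ANSWER_TEMPLATES.get(intent or "Disease")
    sentence = " ".join(w.format(answer) if w == "{}" else w for w in template)
    return answer, sentence, flagged


# ---------------------------------------------------------------------------
# Margin ranking loss
# ---------------------------------------------------------------------------

def _cos(a, b) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def qa_margin_loss(s_o_pos: float, s_o_negs, s_r_pos: float, s_r_negs,
                   gamma: float) -> float:
    """Hinge ranking loss over similarity values.

        sum_f max(0, gamma - s_o(u, m_o) + s_o(u, f))
      + sum_a max(0, gamma - s_R([u, m_o], a) + s_R([u, m_o], a_neg))

    Zero exactly when every negative trails the positive by the margin.
    Empty negative lists contribute zero (with a warning).
    """
    if not s_o_negs and not s_r_negs:
        warnings.warn("margin loss over no negatives is trivially zero")
    loss = sum(max(0.0, gamma - s_o_pos + s) for s in s_o_negs)
    loss += sum(max(0.0, gamma - s_r_pos + s) for s in s_r_negs)
    return float(loss)


# ---------------------------------------------------------------------------
# The QA system
# ---------------------------------------------------------------------------

class QaSystem:
    def __init__(self, model: QaModel, memory: MemoryStore,
                 config: QaConfig | None = None, rule_table=None):
        self.model = model
        self.memory = memory
        self.config = config or model.config
        self.rule_table = rule_table

    def answer(self, question_tokens, top_k: int | None = None):
        """(answer entity, sentence, diagnostics) for a token question."""
        q = process_question(question_tokens, self.model, self.memory,
                             self.rule_table)
        cand_idx = self.memory.search(q.entities)
        if not cand_idx:
            return None, None, {"question": q, "candidates": [], "ranked": []}
        patches = [self.model.tuple_patches(self.memory.slots[i].tuple)
                   for i in cand_idx]
        results, order = attend(q.patches, patches,
                                self.model.params["W_att"].data)
        ranked = [cand_idx[i] for i in order]
        k = top_k or self.config.top_k
        top = self.memory.slots[ranked[0]]
        fallback = [self.memory.slots[i] for i in ranked[:max(k, 3)]]
        ans, sent, flagged = respond(q, top, self.model, self.memory, fallback)
        return ans, sent, {"question": q, "candidates": cand_idx,
                           "ranked": ranked, "attention": results,
                           "flagged": flagged}


def _sample_negatives(memory: MemoryStore, forbidden: set, n: int, rng):
    """Slots sharing no entity with the question or answer."""
    pool = [i for i, s in enumerate(memory.slots)
            if not (set(s.tuple.entities()) & forbidden)]
    if not pool:
        return []
    idx = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
    return [pool[i] for i in np.atleast_1d(idx)]


def train_qa(qa_pairs, memory: MemoryStore, model: QaModel,
             config: QaConfig | None = None, rng_seed: int = 0):
    """Two-phase training; returns a QaSystem and a history dict.

    Phase 1 fits attention weights, the tuple encoder and the response head
    with the margin ranking loss.  Phase 2 fits the generalization MLP:
    a memory that supports a correct answer is labeled 1 (and its usage
    count increments); sampled negatives are labeled 0.
    """
    config = config or model.config
    rng = np.random.default_rng(rng_seed)
    kb_entities = memory.all_entities()
    pairs = [p for p in qa_pairs
             if set(p.supporting_tuple.entities()) & kb_entities]
    if not pairs:
        raise ValueError("QA and KB vocabularies are disjoint; cannot train")
    slot_of = {s.tuple.sort_key: i for i, s in enumerate(memory.slots)}
    history = {"phase1_loss": [], "phase2_loss": []}

    opt = nn.Adam({k: model.params[k] for k in
                   ("W_att", "enc_W", "enc_b", "D1", "D1b", "D2", "D2b",
                    "placeholder", "R")}, lr=config.lr)
    gamma = config.gamma
    for epoch in range(config.epochs):
        rng.shuffle(pairs)
        ep = []
        for p in pairs:
            key = p.supporting_tuple.sort_key
            if key not in slot_of:
                continue
            pos_i = slot_of[key]
            q = process_question(p.question_tokens, model, memory)
            forbidden = set(q.entities) | {p.answer_entity}
            negs = _sample_negatives(memory, forbidden, config.n_negatives, rng)
            if not negs:
                continue
            # output (attention) term — trainable through W_att
            _, _, f_pos = attention_features(
                q.patches, model.tuple_patches(memory.slots[pos_i].tuple))
            terms = []
            W = model.params["W_att"]
            att_pos = W @ nn.Tensor(f_pos)
            for ni in negs:
                _, _, f_neg = attention_features(
                    q.patches, model.tuple_patches(memory.slots[ni].tuple))
                terms.append((gamma - att_pos + W @ nn.Tensor(f_neg)).relu())
            # response term — trainable through encoder and decoder
            u_enc = model.encode_patches(q.patches)
            m_enc = model.encode_patches(
                model.tuple_patches(memory.slots[pos_i].tuple))
            pred = model.decode(u_enc, m_enc)
            a_vec = model.entity_vecs(p.answer_entity)

            def cos_t(pred, v):
                v = np.asarray(v, dtype=float)
                nv = np.linalg.norm(v) or 1.0
                num = (pred * (v / nv)).sum()
                den = ((pred * pred).sum() + 1e-12) ** 0.5
                return num / den

            s_r_pos = cos_t(pred, a_vec)
            neg_entities = sorted(kb_entities - forbidden)
            if neg_entities:
                pick = rng.choice(len(neg_entities),
                                  size=min(config.n_negatives, len(neg_entities)),
                                  replace=False)
                for j in np.atleast_1d(pick):
                    s_r_neg = cos_t(pred, model.entity_vecs(neg_entities[j]))
                    terms.append((gamma - s_r_pos + s_r_neg).relu())
            loss = terms[0]
            for t in terms[1:]:
                loss = loss + t
            loss = loss * (1.0 / len(terms))
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep.append(float(loss.data))
        history["phase1_loss"].append(float(np.mean(ep)) if ep else 0.0)
    # refresh stored slot vectors under the trained encoder
    for s in memory.slots:
        s.vector = model.encode_tuple(s.tuple)

    # ---- phase 2: generalization utility network -------------------------
    feats, labels = [], []
    for p in pairs:
        key = p.supporting_tuple.sort_key
        if key not in slot_of:
            continue
        pos_i = slot_of[key]
        q = process_question(p.question_tokens, model, memory)
        memory.total_queries += 1
        slot = memory.slots[pos_i]
        sys_tmp = QaSystem(model, memory, config)
        ans, _, _ = sys_tmp.answer(p.question_tokens)
        correct = ans == p.answer_entity
        if correct:
            slot.usage_count += 1
        sim = _cos(q.u, slot.vector)
        feats.append(generalization_features(
            sim, memory.used_times_feature(slot),
            len(slot.tuple.entities()), slot.tuple.relation))
        labels.append(1.0 if correct else 0.0)
        for ni in _sample_negatives(memory, set(q.entities) | {p.answer_entity},
                                    2, rng):
            ns = memory.slots[ni]
            feats.append(generalization_features(
                _cos(q.u, ns.vector), memory.used_times_feature(ns),
                len(ns.tuple.entities()), ns.tuple.relation))
            labels.append(0.0)
    if feats:
        F = np.stack(feats)
        y = np.array(labels)
        gopt = nn.Adam({k: model.params[k] for k in ("G1", "G1b", "G2", "G2b")},
                       lr=0.05)
        for _ in range(config.utility_epochs):
            z = nn.Tensor(F)
            hid = (z @ model.params["G1"] + model.params["G1b"]).tanh()
            v = (hid @ model.params["G2"] + model.params["G2b"]).sigmoid()
            v_i = v[:, 1]
            eps = 1e-9
            bce = -(nn.Tensor(y) * (v_i + eps).log()
                    + nn.Tensor(1 - y) * (1 - v_i + eps).log()).mean()
            gopt.zero_grad()
            bce.backward()
            gopt.step()
            history["phase2_loss"].append(float(bce.data))
    return QaSystem(model, memory, config), history


# ---------------------------------------------------------------------------
# Test-set labeling and evaluation
# ---------------------------------------------------------------------------

def label_qa_test_data(qa_docs, entity_extractor, relation_extractor=None,
                       rule_table=None):
    """Labeled evaluation set by the automatic rules.

    Per document: intent from the title marker rules; the answer is the
    most frequent intent-type entity of the body (frequency ties drop the
    document); documents whose body expresses more than one relation type
    are dropped.  ``entity_extractor(tokens) -> [(surface, type), ...]``;
    ``relation_extractor(tokens) -> set of relation types`` (optional).
    """
    labeled = []
    for doc in qa_docs:
        title = doc["title"] if isinstance(doc, dict) else doc.question_tokens
        body = doc["body"] if isinstance(doc, dict) else doc.body_tokens
        intent, _ = detect_intent(title, rule_table)
        if intent is None:
            continue
        if relation_extractor is not None:
            rels = relation_extractor(body)
            if len(rels) != 1:
                continue
        counts = Counter(s for s, t in entity_extractor(body) if t == intent)
        if not counts:
            continue
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            continue  # frequency tie: drop
        labeled.append({"title": list(title), "body": list(body),
                        "intent": intent, "answer": ranked[0][0]})
    return labeled


def evaluate_qa(system: QaSystem, labeled, n_resamples: int = 20,
                rng_seed: int = 0):
    """P@1 and answer F1 with bootstrap-resample standard deviations."""
    rng = np.random.default_rng(rng_seed)
    outcomes = []
    for item in labeled:
        ans, _, _ = system.answer(item["title"])
        outcomes.append((ans, item["answer"]))

    def metrics(sample):
        tp = sum(1 for a, g in sample if a is not None and a == g)
        fp = sum(1 for a, g in sample if a is not None and a != g)
        fn = sum(1 for a, g in sample if a is None or a != g)
        p_at_1 = tp / len(sample) if sample else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        return f1, p_at_1

    f1, p1 = metrics(outcomes)
    f1s, p1s = [], []
    for _ in range(n_resamples):
        idx = rng.integers(len(outcomes), size=len(outcomes))
        s = [outcomes[i] for i in idx]
        a, b = metrics(s)
        f1s.append(a)
        p1s.append(b)
    return {"f1": f1, "p_at_1": p1,
            "f1_std": float(np.std(f1s)), "p_at_1_std": float(np.std(p1s)),
            "n": len(outcomes)}
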