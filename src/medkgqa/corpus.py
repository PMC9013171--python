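"""Synthetic clinical-corpus generator.

Emulates the statistical structure of character-level clinical records:
entity mentions are pseudo-word token sequences embedded in short templated
statements (one relational statement per sentence, ~3.3 statements per
record on average), with optional typo-style surface noise, plus
question-answer pairs whose answer is a single target entity.  Every
insertion is logged in a ledger, which serves as the oracle for all
extraction-stage tests and as the stand-in for web-encyclopedia / human
validation channels.

Tokens are atomic symbols: a token is never segmented further, mirroring
character-level processing of unsegmented text.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np

from .schema import (ENTITY_TYPES, RELATION_SIGNATURE, RELATION_TYPES,
                     GroundTruthKB, KnowledgeTuple, merge_triples)


class CapacityError(ValueError):
    """Requested relation count exceeds the available pair space."""


# ---------------------------------------------------------------------------
# Surface inventory
# ---------------------------------------------------------------------------

_SYLLABLES = [c + v for c in "bcdfghjklmnprstvz" for v in "aeiou"]

DEPARTMENTS = ("InternalMed", "Surgery", "Gynecology", "Pediatrics",
               "Infectious", "ENT", "Laboratory", "Radiology")

# Statement templates per relation type; <S>/<O> are subject/object slots.
# Each statement is one sentence terminated by ".".
TEMPLATES = {
    "hasSymptom": [
        ["patient", "admitted", "for", "<S>", "with", "<O>", "noted", "."],
        ["<S>", "presents", "signs", "of", "<O>", "."],
        ["history", "of", "<S>", "showing", "<O>", "."],
    ],
    "needsTest": [
        ["suspected", "<S>", "requires", "<O>", "exam", "."],
        ["ordered", "<O>", "to", "confirm", "<S>", "."],
        ["<S>", "workup", "includes", "<O>", "."],
    ],
    "hasTestResult": [
        ["<S>", "indicated", "by", "<O>", "finding", "."],
        ["diagnosis", "of", "<S>", "supported", "by", "<O>", "."],
        ["<S>", "consistent", "with", "<O>", "."],
    ],
    "needsTreatment": [
        ["admission", "for", "<S>", "and", "cure", "with", "<O>", "."],
        ["<S>", "managed", "with", "<O>", "."],
        ["started", "<O>", "against", "<S>", "."],
    ],
    "hasResult": [
        ["<S>", "returned", "<O>", "reading", "."],
        ["result", "of", "<S>", "was", "<O>", "."],
        ["<S>", "showed", "<O>", "."],
    ],
}

# Question openers per intent type.  The marker phrases double as the rule
# table for intent detection ("what disease" -> Disease and so on).
INTENT_MARKERS = [
    (("what", "disease"), "Disease"),
    (("how", "to", "treat"), "Treatment"),
    (("symptoms",), "Symptom"),
    (("manifestations",), "Symptom"),
    (("what", "test"), "Test"),
    (("what", "finding"), "Result"),
]

# intent -> (relation, role of answer in the tuple)
_INTENT_PLANS = {
    "Disease": [("hasSymptom", "subject"), ("needsTest", "subject"),
                ("hasTestResult", "subject"), ("needsTreatment", "subject")],
    "Symptom": [("hasSymptom", "object")],
    "Treatment": [("needsTreatment", "object")],
    "Test": [("needsTest", "object"), ("hasResult", "subject")],
    "Result": [("hasTestResult", "object"), ("hasResult", "object")],
}


@dataclass
class GoldSpan:
    start: int
    end: int  # half-open token index
    entity_type: str
    entity: str      # canonical KB entity string
    surface: str     # surface form actually rendered (may be a typo variant)


@dataclass
class SynthRecord:
    record_id: str
    department: str
    tokens: list
    gold_spans: list          # list of GoldSpan
    gold_tuples: list         # list of (subject, relation, object) triples
    statement_count: int


@dataclass
class SynthQAPair:
    question_tokens: list
    answer_entity: str
    intent_type: str
    supporting_tuple: KnowledgeTuple
    body_tokens: list
    body_spans: list = field(default_factory=list)  # GoldSpan over body


@dataclass
class CorpusLedger:
    """Generation log: the oracle for every extraction-stage test."""

    entity_types: dict = field(default_factory=dict)   # canonical -> type
    aliases: list = field(default_factory=list)        # (canonical, variant)
    insertions: list = field(default_factory=list)     # per-mention dicts
    relation_mentions: list = field(default_factory=list)

    def variant_map(self) -> dict:
        return {v: c for c, v in self.aliases}

    def canonical_of(self, surface: str):
        if surface in self.entity_types:
            return surface
        return self.variant_map().get(surface)


# ---------------------------------------------------------------------------
# KB generation
# ---------------------------------------------------------------------------

def _make_entity(rng: np.random.Generator, used: set) -> str:
    """A unique entity string of 1-3 atomic glyph tokens."""
    for _ in range(1000):
        n_tok = rng.choice([1, 2, 3], p=[0.45, 0.40, 0.15])
        toks = []
        for _ in range(n_tok):
            a, b, c = rng.choice(len(_SYLLABLES), size=3)
            toks.append(_SYLLABLES[a] + _SYLLABLES[b] + _SYLLABLES[c])
        s = " ".join(toks)
        if s not in used and all(t not in used for t in toks):
            used.add(s)
            used.update(toks)
            return s
    raise RuntimeError("entity namespace exhausted")


def generate_kb(n_entities_per_type: int, n_relations_per_type: int,
                rng_seed: int) -> GroundTruthKB:
    """Sample a ground-truth KB honouring the relation type signatures.

    Deterministic for a fixed seed.  Raises :class:`CapacityError` when the
    requested relation count exceeds the subject x object pair space.
    """
    if n_entities_per_type < 1:
        raise ValueError("n_entities_per_type must be >= 1")
    if n_relations_per_type > n_entities_per_type ** 2:
        raise CapacityError(
            f"{n_relations_per_type} relations requested per type but only "
            f"{n_entities_per_type ** 2} subject-object pairs exist")
    rng = np.random.default_rng(rng_seed)
    used: set = set()
    kb = GroundTruthKB()
    for t in ENTITY_TYPES:
        kb.entities[t] = {_make_entity(rng, used) for _ in range(n_entities_per_type)}

    # Subjects are drawn least-used-first (across relation types) so no
    # entity dominates the subject role — supportability confidence of a
    # planted tuple then reflects a balanced mention budget.
    subject_usage: dict = {}
    # hasResult first so hasTestResult objects can be drawn from its pool.
    order = ["hasResult"] + [r for r in RELATION_TYPES if r != "hasResult"]
    has_result_objects: list = []
    for rel in order:
        sub_t, obj_t = RELATION_SIGNATURE[rel]
        subs = sorted(kb.entities[sub_t])
        objs = sorted(kb.entities[obj_t])
        if rel == "hasTestResult" and has_result_objects:
            objs = sorted(set(has_result_objects))
        taken = set()
        for _ in range(n_relations_per_type):
            ranked = sorted(subs, key=lambda s: (subject_usage.get(s, 0), rng.random()))
            placed = False
            for s in ranked:
                free = [o for o in objs if (s, o) not in taken]
                if rel == "hasTestResult":
                    free = free or [o for o in sorted(kb.entities[obj_t])
                                    if (s, o) not in taken]
                if free:
                    o = free[int(rng.integers(len(free)))]
                    taken.add((s, o))
                    kb.relations.add((s, rel, o))
                    subject_usage[s] = subject_usage.get(s, 0) + 1
                    if rel == "hasResult":
                        has_result_objects.append(o)
                    placed = True
                    break
            if not placed:  # pair space exhausted despite the capacity check
                raise CapacityError("relation pair space exhausted")
    for res in sorted(set(has_result_objects)):
        kb.groundings[res] = float(np.round(rng.uniform(1.0, 100.0), 1))
    return kb


# ---------------------------------------------------------------------------
# Record rendering
# ---------------------------------------------------------------------------

def _typo(rng: np.random.Generator, token: str) -> str:
    """Replace one character of the token (a typo variant)."""
    i = int(rng.integers(len(token)))
    letters = [c for c in string.ascii_lowercase if c != token[i]]
    return token[:i] + letters[int(rng.integers(len(letters)))] + token[i + 1:]


def render_records(kb: GroundTruthKB, n_records: int, mean_statements: float = 3.3,
                   noise_rate: float = 0.0, rng_seed: int = 0,
                   noise_kind: str = "typo"):
    """Render records and the generation ledger.

    Statement counts are drawn from a shifted Poisson with the requested
    mean.  Relations are sampled stratified (full shuffled cycles) so every
    KB relation is expressed at least once when enough statements are drawn.
    With ``noise_rate`` > 0 the given fraction of entity mentions is
    corrupted into a variant surface form — a one-character typo inside one
    token (``noise_kind='typo'``) or a whole-token substitution
    (``noise_kind='token'``) — and logged as a (canonical, variant) alias.

    Returns ``(records, ledger)``.
    """
    if not kb.relations:
        raise ValueError("KB has no relations to express")
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    ledger = CorpusLedger(entity_types=kb.entity_types())
    triples = sorted(kb.relations)
    cycle: list = []
    records = []
    for ridx in range(n_records):
        n_stmt = 1 + int(rng.poisson(max(mean_statements - 1.0, 0.0)))
        rec_id = f"rec{ridx:05d}"
        tokens: list = []
        spans: list = []
        rec_triples: list = []
        for sidx in range(n_stmt):
            if not cycle:
                cycle = list(triples)
                rng.shuffle(cycle)
            s, rel, o = cycle.pop()
            tmpl = TEMPLATES[rel][int(rng.integers(len(TEMPLATES[rel])))]
            stmt_spans = {}
            for w in tmpl:
                if w in ("<S>", "<O>"):
                    ent = s if w == "<S>" else o
                    etype = ledger.entity_types[ent]
                    mention = ent.split()
                    if noise_rate > 0 and rng.random() < noise_rate:
                        j = int(rng.integers(len(mention)))
                        if noise_kind == "typo":
                            mention = mention[:j] + [_typo(rng, mention[j])] + mention[j + 1:]
                        else:
                            a, b, c = rng.choice(len(_SYLLABLES), size=3)
                            mention = mention[:j] \
                                + [_SYLLABLES[a] + _SYLLABLES[b] + _SYLLABLES[c]] \
                                + mention[j + 1:]
                    surface = " ".join(mention)
                    if surface != ent and (ent, surface) not in ledger.aliases:
                        ledger.aliases.append((ent, surface))
                    start = len(tokens)
                    tokens.extend(mention)
                    sp = GoldSpan(start, len(tokens), etype, ent, surface)
                    spans.append(sp)
                    stmt_spans[w] = sp
                    ledger.insertions.append({
                        "record_id": rec_id, "start": sp.start, "end": sp.end,
                        "entity": ent, "entity_type": etype, "surface": surface,
                        "statement_idx": sidx, "triple": (s, rel, o)})
                else:
                    tokens.append(w)
            rec_triples.append((s, rel, o))
            ledger.relation_mentions.append({
                "record_id": rec_id, "triple": (s, rel, o),
                "subject_span": (stmt_spans["<S>"].start, stmt_spans["<S>"].end),
                "object_span": (stmt_spans["<O>"].start, stmt_spans["<O>"].end)})
        records.append(SynthRecord(
            record_id=rec_id,
            department=DEPARTMENTS[int(rng.integers(len(DEPARTMENTS)))],
            tokens=tokens, gold_spans=spans, gold_tuples=rec_triples,
            statement_count=n_stmt))
    return records, ledger


# ---------------------------------------------------------------------------
# QA pair rendering
# ---------------------------------------------------------------------------

def _question_tokens(intent: str, relation: str, role: str,
                     tup: KnowledgeTuple, rng) -> list:
    def mention(e):
        return e.split()

    if role == "subject":  # answer is the subject; question names the objects
        if intent == "Disease":
            opener = ["what", "disease", "with"]
        elif intent == "Test":
            opener = ["what", "test", "gives"]
        else:
            opener = ["what", "finding", "for"]
        toks = list(opener)
        for i, o in enumerate(tup.objects):
            if i:
                toks.append("and")
            toks.extend(mention(o))
    else:  # answer is the single object; question names the subject
        openers = {"Symptom": [["symptoms", "of"], ["manifestations", "of"]],
                   "Treatment": [["how", "to", "treat"]],
                   "Test": [["what", "test", "for"]],
                   "Result": [["what", "finding", "for"]]}
        opener = openers[intent][int(rng.integers(len(openers[intent])))]
        toks = list(opener) + mention(tup.subject)
    toks.append("?")
    return toks


def render_qa_pairs(kb: GroundTruthKB, n_pairs: int, rng_seed: int = 0,
                    intent_weights: dict | None = None):
    """Render QA pairs whose answer is recoverable by the test-labeling rule.

    Each pair's body expresses only the supporting tuple's relation type and
    mentions the answer entity more often than any other entity of the
    intent type.  Questions are only emitted when the mentioned entities
    determine the supporting tuple uniquely, so top-1 retrieval is
    well-posed.  Returns ``(pairs, ledger)`` where the ledger records body
    insertions.
    """
    tuples = merge_triples(kb.relations)
    if not tuples:
        raise ValueError("KB has no relations")
    rng = np.random.default_rng(rng_seed)
    etypes = kb.entity_types()
    by_rel: dict = {}
    for t in tuples:
        by_rel.setdefault(t.relation, []).append(t)

    weights = dict(intent_weights or {t: 1.0 for t in ENTITY_TYPES})

    def eligible(intent):
        out = []
        for rel, role in _INTENT_PLANS[intent]:
            for t in by_rel.get(rel, []):
                if role == "object":
                    if len(t.objects) == 1:
                        out.append((rel, role, t))
                else:
                    # unique subject for this object set under this relation
                    clash = [t2 for t2 in by_rel[rel] if t2 is not t
                             and set(t.objects) <= set(t2.objects)]
                    if not clash:
                        out.append((rel, role, t))
        return out

    pools = {i: eligible(i) for i in ENTITY_TYPES}
    avail = [i for i in ENTITY_TYPES if pools[i] and weights.get(i, 0) > 0]
    if not avail:
        raise ValueError("no intent type has an eligible supporting tuple")
    w = np.array([weights[i] for i in avail], dtype=float)
    w = w / w.sum()

    pairs = []
    ledger = CorpusLedger(entity_types=etypes)
    for _ in range(n_pairs):
        intent = avail[int(rng.choice(len(avail), p=w))]
        rel, role, tup = pools[intent][int(rng.integers(len(pools[intent])))]
        answer = tup.subject if role == "subject" else tup.objects[0]
        q = _question_tokens(intent, rel, role, tup, rng)
        # body: 2-3 statements of the supporting relation, answer in each
        body: list = []
        body_spans: list = []
        n_stmt = 2 + int(rng.integers(2))
        for _ in range(n_stmt):
            tmpl = TEMPLATES[rel][int(rng.integers(len(TEMPLATES[rel])))]
            obj = tup.objects[int(rng.integers(len(tup.objects)))]
            if role == "object":
                obj = answer
            for wtok in tmpl:
                if wtok in ("<S>", "<O>"):
                    ent = tup.subject if wtok == "<S>" else obj
                    start = len(body)
                    body.extend(ent.split())
                    body_spans.append(GoldSpan(start, len(body),
                                               etypes[ent], ent, ent))
                else:
                    body.append(wtok)
        pairs.append(SynthQAPair(question_tokens=q, answer_entity=answer,
                                 intent_type=intent, supporting_tuple=tup,
                                 body_tokens=body, body_spans=body_spans))
    return pairs, ledger
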