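"""Knowledge fusion: entity alignment and consistency analysis.

Alignment merges surface forms denoting one concept by cosine similarity of
their vectors with two-threshold triage: at or above 0.7 a pair auto-merges,
in [0.3, 0.7) a human (here: the validation oracle) decides, below 0.3 the
pair stays separate.  Merges close transitively; each alias cluster is named
by its most frequent surface form (ties: lexicographic).

Consistency analysis scores every relation triple by supportability,
confidence = tuple frequency / subject-entity mention frequency, with the
same two-threshold triage (e.g. a tuple seen 74 times under a subject seen
379 times has confidence 74/379 = 0.195 and is dropped; one at 0.71 is
retained).  Conflicting relations on one subject-object pair keep the
higher-confidence tuple.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .schema import KnowledgeTuple, RELATION_SIGNATURE, merge_triples


class ZeroVectorError(ValueError):
    """Cosine similarity is undefined for a zero vector."""


class DataIntegrityError(ValueError):
    """A tuple was extracted more often than its subject entity."""


def cosine_similarity(v1, v2) -> float:
    v1, v2 = np.asarray(v1, dtype=float), np.asarray(v2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ZeroVectorError("similarity undefined for zero vectors")
    return float(np.dot(v1, v2) / (n1 * n2))


@dataclass
class FusionConfig:
    merge_threshold: float = 0.7
    queue_threshold: float = 0.3
    retain_threshold: float = 0.7
    drop_threshold: float = 0.3


@dataclass
class AlignmentDecision:
    pair: tuple
    similarity: float
    action: str            # auto-merge | human-queue | keep-separate
    canonical: str | None = None


@dataclass
class RelationConfidence:
    triple: tuple
    tuple_freq: int
    entity_freq: int
    confidence: float
    decision: str          # retain | human-queue | drop


@dataclass
class KnowledgeGraph:
    entities: dict = field(default_factory=dict)  # canonical -> {"type","aliases","count"}
    tuples: list = field(default_factory=list)    # merged KnowledgeTuples
    triple_counts: dict = field(default_factory=dict)
    groundings: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    def entity_types(self) -> dict:
        return {e: info["type"] for e, info in self.entities.items()}


# ---------------------------------------------------------------------------
# Entity vectorizers
# ---------------------------------------------------------------------------

class EmbeddingVectorizer:
    """Vectorize an entity as the mean of its co-trained token embeddings."""

    def __init__(self, tagger_model):
        self.model = tagger_model

    def vector(self, surface: str) -> np.ndarray:
        from .tagger import embed_entity

        return embed_entity(self.model, surface)


class CharNgramVectorizer:
    """Character 2-3-gram count vectors of the surface form.

    Typo-style alias variants keep most n-grams of the canonical form, so
    surface similarity is high for aliases and near zero for unrelated
    entities — a robust alignment signal when embeddings are trained on
    little text.
    """

    def __init__(self, surfaces):
        from sklearn.feature_extraction.text import CountVectorizer

        self.vec = CountVectorizer(analyzer="char", ngram_range=(2, 3))
        self.vec.fit(list(surfaces))

    def vector(self, surface: str) -> np.ndarray:
        return self.vec.transform([surface]).toarray()[0].astype(float)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_entities(mentions: dict, vectorizer, config: FusionConfig | None = None,
                   oracle=None):
    """Cluster same-type surface forms into alias sets.

    ``mentions`` maps surface -> (entity_type, count).  Returns
    (clusters, decisions) where clusters is a list of dicts with canonical
    name, type, aliases and pooled count.  Auto-merges close transitively;
    processing order does not affect the result.
    """
    config = config or FusionConfig()
    surfaces = sorted(mentions)
    parent = {s: s for s in surfaces}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    vectors = {}
    for s in surfaces:
        try:
            vectors[s] = vectorizer.vector(s)
        except Exception:
            vectors[s] = None
    decisions = []
    for i, a in enumerate(surfaces):
        for b in surfaces[i + 1:]:
            if mentions[a][0] != mentions[b][0]:
                continue  # cross-type merges are rejected outright
            va, vb = vectors[a], vectors[b]
            if va is None or vb is None or not np.any(va) or not np.any(vb):
                continue
            sim = cosine_similarity(va, vb)
            if sim >= config.merge_threshold:
                union(a, b)
                decisions.append(AlignmentDecision((a, b), sim, "auto-merge"))
            elif sim >= config.queue_threshold:
                verdict = oracle.should_merge(a, b) if oracle is not None else None
                if verdict:
                    union(a, b)
                    decisions.append(AlignmentDecision((a, b), sim, "human-queue"))
                else:
                    decisions.append(AlignmentDecision((a, b), sim, "keep-separate"))
            else:
                decisions.append(AlignmentDecision((a, b), sim, "keep-separate"))
    clusters = defaultdict(list)
    for s in surfaces:
        clusters[find(s)].append(s)
    out = []
    for members in clusters.values():
        # canonical name: highest mention count, ties lexicographic
        canonical = min(members, key=lambda s: (-mentions[s][1], s))
        out.append({"canonical": canonical,
                    "type": mentions[canonical][0],
                    "aliases": sorted(members),
                    "count": sum(mentions[m][1] for m in members)})
        for d in decisions:
            if d.pair[0] in members and d.action != "keep-separate":
                d.canonical = canonical
    return sorted(out, key=lambda c: c["canonical"]), decisions


# ---------------------------------------------------------------------------
# Consistency analysis
# ---------------------------------------------------------------------------

def relation_consistency(triple_counts: dict, entity_counts: dict,
                         config: FusionConfig | None = None, oracle=None):
    """Retain / queue / drop triples by supportability confidence.

    confidence = tuple frequency / subject mention frequency.  Conflicts
    (same subject and object, different relation) keep the higher
    confidence; exact ties go to the oracle.
    """
    config = config or FusionConfig()
    log = []
    kept = {}
    for triple in sorted(triple_counts):
        tf = triple_counts[triple]
        ef = entity_counts.get(triple[0], 0)
        if ef == 0 and tf > 0:
            raise DataIntegrityError(
                f"subject {triple[0]!r} has zero mentions but {tf} tuple extractions")
        conf = tf / ef if ef else 0.0
        if conf >= config.retain_threshold:
            decision = "retain"
        elif conf >= config.drop_threshold:
            verdict = oracle.keep_relation(triple) if oracle is not None else None
            decision = "retain" if verdict else "human-queue" if verdict is None \
                else "drop"
        else:
            decision = "drop"
        log.append(RelationConfidence(triple, tf, ef, conf, decision))
        if decision == "retain":
            kept[triple] = conf
    # conflict resolution: one relation per subject-object pair
    by_pair = defaultdict(list)
    for (s, r, o), conf in kept.items():
        by_pair[(s, o)].append(((s, r, o), conf))
    retained = set()
    for pair, items in by_pair.items():
        if len(items) == 1:
            retained.add(items[0][0])
            continue
        items.sort(key=lambda x: (-x[1], x[0]))
        best = [t for t, c in items if c == items[0][1]]
        if len(best) == 1:
            retained.add(best[0])
        else:
            pick = None
            if oracle is not None:
                for t in best:
                    if oracle.keep_relation(t):
                        pick = t
                        break
            retained.add(pick or best[0])
    return retained, log


# ---------------------------------------------------------------------------
# Extraction collection and full fusion
# ---------------------------------------------------------------------------

def collect_extractions(annotated_records):
    """Mention and triple frequencies from annotated records."""
    mention_counts = Counter()
    mention_types = {}
    triple_counts = Counter()
    for rec in annotated_records:
        for (s, e, t, surf) in rec.spans:
            mention_counts[surf] += 1
            mention_types[surf] = t
        for triple in rec.tuples:
            triple_counts[tuple(triple)] += 1
    mentions = {s: (mention_types[s], c) for s, c in mention_counts.items()}
    return mentions, dict(triple_counts)


def fuse(mentions: dict, triple_counts: dict, vectorizer,
         config: FusionConfig | None = None, oracle=None,
         groundings: dict | None = None) -> KnowledgeGraph:
    """Alignment, count pooling, then consistency analysis.

    Returns a KnowledgeGraph whose report carries before/after entity and
    relation counts.  The retained tuple set never contains a triple absent
    from the input (modulo alias canonicalization).
    """
    config = config or FusionConfig()
    graph = KnowledgeGraph()
    before_entities = len(mentions)
    before_triples = len(triple_counts)
    if not mentions:
        graph.report = {"entities_before": 0, "entities_after": 0,
                        "relations_before": before_triples, "relations_after": 0}
        return graph
    clusters, decisions = align_entities(mentions, vectorizer, config, oracle)
    canon = {}
    for c in clusters:
        for m in c["aliases"]:
            canon[m] = c["canonical"]
        graph.entities[c["canonical"]] = {"type": c["type"],
                                          "aliases": c["aliases"],
                                          "count": c["count"]}
    pooled = Counter()
    for (s, r, o), n in triple_counts.items():
        cs, co = canon.get(s, s), canon.get(o, o)
        sig = RELATION_SIGNATURE[r]
        if graph.entities.get(cs, {}).get("type") != sig[0] or \
                graph.entities.get(co, {}).get("type") != sig[1]:
            continue  # type-violating extraction
        pooled[(cs, r, co)] += n
    entity_counts = {c: info["count"] for c, info in graph.entities.items()}
    retained, log = relation_consistency(dict(pooled), entity_counts, config, oracle)
    graph.triple_counts = {t: pooled[t] for t in retained}
    graph.tuples = merge_triples(retained)
    if groundings:
        graph.groundings = {k: v for k, v in groundings.items()
                            if canon.get(k, k) in graph.entities}
    graph.report = {"entities_before": before_entities,
                    "entities_after": len(graph.entities),
                    "relations_before": before_triples,
                    "relations_after": len(retained),
                    "alignment_decisions": len(decisions),
                    "consistency_log": len(log)}
    return graph
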