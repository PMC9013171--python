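"""Ontology of the medical knowledge graph.

Five coarse-grained entity classes (Disease, Symptom, Treatment, Test,
Result) and five relation types between them.  A knowledge tuple is
<subject entity, relation type, object entity set>; objects with the same
subject and relation are pooled into one tuple, and tuples sort
alphabetically by subject then objects, which is what the QA memory index
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field


ENTITY_TYPES = ("Disease", "Symptom", "Treatment", "Test", "Result")

# Short placeholder codes used in tag labels and pattern placeholders.
TYPE_CODES = {"Disease": "DIS", "Symptom": "SYM", "Treatment": "TRE",
              "Test": "TST", "Result": "RES"}
CODE_TYPES = {v: k for k, v in TYPE_CODES.items()}

# Relation order is fixed: the one-hot coding assigns 1 to hasSymptom and
# 2 to needsTest; the rest follow the ontology table's row order.
RELATION_TYPES = ("hasSymptom", "needsTest", "hasTestResult",
                  "needsTreatment", "hasResult")
RELATION_INDEX = {r: i for i, r in enumerate(RELATION_TYPES)}

# Subject/object entity-type constraints per relation.
RELATION_SIGNATURE = {
    "hasSymptom": ("Disease", "Symptom"),
    "needsTest": ("Disease", "Test"),
    "hasTestResult": ("Disease", "Result"),
    "needsTreatment": ("Disease", "Treatment"),
    "hasResult": ("Test", "Result"),
}

NONE_RELATION = "NONE"  # rejection class for unrelated entity pairs


def relation_one_hot(relation: str):
    import numpy as np

    v = np.zeros(len(RELATION_TYPES))
    v[RELATION_INDEX[relation]] = 1.0
    return v


@dataclass(frozen=True, order=True)
class KnowledgeTuple:
    """<subject, relation, {objects}> — the KB and memory unit."""

    subject: str
    relation: str
    objects: tuple  # sorted tuple of object entity strings

    def __post_init__(self):
        object.__setattr__(self, "objects", tuple(sorted(self.objects)))

    @property
    def sort_key(self):
        return (self.subject, self.relation, self.objects)

    def entities(self):
        return (self.subject,) + self.objects

    def type_check(self, entity_types: dict) -> bool:
        """True when subject/object types match the relation signature."""
        sub_t, obj_t = RELATION_SIGNATURE[self.relation]
        if entity_types.get(self.subject) != sub_t:
            return False
        return all(entity_types.get(o) == obj_t for o in self.objects)


def merge_triples(triples) -> list:
    """Pool (subject, relation, object) triples into KnowledgeTuples.

    Output is globally sorted by (subject, relation, objects).
    """
    pooled: dict = {}
    for s, r, o in triples:
        pooled.setdefault((s, r), set()).add(o)
    out = [KnowledgeTuple(s, r, tuple(sorted(objs))) for (s, r), objs in pooled.items()]
    return sorted(out, key=lambda t: t.sort_key)


@dataclass
class GroundTruthKB:
    """Planted knowledge base: entity sets per type plus relation triples."""

    entities: dict = field(default_factory=dict)   # type -> set of strings
    relations: set = field(default_factory=set)    # {(subject, relation, object)}
    groundings: dict = field(default_factory=dict)  # Result entity -> float standard

    def entity_types(self) -> dict:
        return {e: t for t, es in self.entities.items() for e in es}

    def tuples(self) -> list:
        return merge_triples(self.relations)

    def all_entities(self) -> set:
        return {e for es in self.entities.values() for e in es}
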