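"""Candidate-validation oracles.

Bootstrapping validates mined candidates against external knowledge: a
dictionary channel (a web-encyclopedia stand-in), a top-K retrieval channel
(search-engine stand-in, hit count |H| out of K), and a human-judgment
channel.  Live crawling is out of scope, so validation is a declared
interface with two shipped implementations: a static dictionary, and the
synthetic generator's ledger (which knows the planted truth and so plays
encyclopedia, search engine and human at once).
"""

from __future__ import annotations


class ValidationOracle:
    """Interface; every channel may answer None = "cannot decide"."""

    def dictionary_lookup(self, candidate: str) -> bool:
        raise NotImplementedError

    def topk_hits(self, candidate: str, k: int) -> int:
        raise NotImplementedError

    def human_accepts(self, candidate: str, entity_type: str | None = None):
        return None

    def entity_type_of(self, candidate: str):
        return None

    def relation_accepts(self, triple) -> bool | None:
        return None

    def should_merge(self, a: str, b: str) -> bool | None:
        return None

    def keep_relation(self, tup) -> bool | None:
        return None


class StaticDictionaryOracle(ValidationOracle):
    """Dictionary + retrieval backed by fixed string sets."""

    def __init__(self, dictionary: set, searchable: set | None = None,
                 relations: set | None = None):
        self.dictionary = set(dictionary)
        self.searchable = set(searchable) if searchable is not None else set(dictionary)
        self.relations = set(relations) if relations is not None else None

    def dictionary_lookup(self, candidate: str) -> bool:
        return candidate in self.dictionary

    def topk_hits(self, candidate: str, k: int) -> int:
        return k if candidate in self.searchable else 0

    def relation_accepts(self, triple):
        if self.relations is None:
            return None
        return tuple(triple) in self.relations


class LedgerOracle(ValidationOracle):
    """Generator-ledger oracle: answers every channel from the planted truth.

    The encyclopedia dictionary holds the canonical entity strings; the
    search channel also recognises logged typo variants; the human channel
    accepts exactly the planted surface forms.
    """

    def __init__(self, kb, ledger):
        self.kb = kb
        self.types = kb.entity_types()
        self.variants = ledger.variant_map()
        self.relations = set(kb.relations)

    def _canonical(self, s: str):
        if s in self.types:
            return s
        return self.variants.get(s)

    def dictionary_lookup(self, candidate: str) -> bool:
        return candidate in self.types

    def topk_hits(self, candidate: str, k: int) -> int:
        return k if self._canonical(candidate) is not None else 0

    def human_accepts(self, candidate: str, entity_type: str | None = None):
        c = self._canonical(candidate)
        if c is None:
            return False
        return entity_type is None or self.types[c] == entity_type

    def entity_type_of(self, candidate: str):
        c = self._canonical(candidate)
        return None if c is None else self.types[c]

    def relation_accepts(self, triple):
        s, r, o = triple
        cs, co = self._canonical(s), self._canonical(o)
        if cs is None or co is None:
            return False
        return (cs, r, co) in self.relations

    def should_merge(self, a: str, b: str):
        ca, cb = self._canonical(a), self._canonical(b)
        return ca is not None and ca == cb

    def keep_relation(self, triple):
        return self.relation_accepts(tuple(triple))
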