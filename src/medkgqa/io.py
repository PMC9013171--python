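"""Readers/writers, configuration, and the reproducibility manifest.

Corpora travel as JSON-lines (one record per line, UTF-8); the knowledge
graph exports to TSV (typed entity rows with aliases and counts, then
triple rows, sorted), Turtle (OWL classes, object properties and the
DataGrounding data property) or JSON.  Every pipeline stage can write a
RunManifest recording config hash, seed and input/output digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict

from .corpus import GoldSpan, SynthRecord
from .bootstrap import AnnotatedRecord
from .fusion import KnowledgeGraph
from .schema import ENTITY_TYPES, RELATION_TYPES, RELATION_SIGNATURE, merge_triples


class CorpusFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# JSON-lines corpora
# ---------------------------------------------------------------------------

def write_corpus(records, path):
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if isinstance(rec, SynthRecord):
                obj = {"record_id": rec.record_id, "department": rec.department,
                       "tokens": rec.tokens,
                       "gold_spans": [[s.start, s.end, s.entity_type, s.entity,
                                       s.surface] for s in rec.gold_spans],
                       "gold_tuples": [list(t) for t in rec.gold_tuples],
                       "statement_count": rec.statement_count}
            elif isinstance(rec, AnnotatedRecord):
                obj = {"record_id": rec.record_id, "tokens": rec.tokens,
                       "spans": [list(s) for s in rec.spans],
                       "tuples": [list(t) for t in rec.tuples]}
            else:
                obj = rec
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_corpus(path):
    """Records from a JSON-lines file; malformed lines raise with the
    offending line number."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise CorpusFormatError(f"line {ln}: malformed JSON ({e})") from e
            if "gold_spans" in obj:
                out.append(SynthRecord(
                    record_id=obj["record_id"], department=obj.get("department", ""),
                    tokens=obj["tokens"],
                    gold_spans=[GoldSpan(*s) for s in obj["gold_spans"]],
                    gold_tuples=[tuple(t) for t in obj["gold_tuples"]],
                    statement_count=obj.get("statement_count", 1)))
            elif "spans" in obj:
                out.append(AnnotatedRecord(
                    obj["record_id"], obj["tokens"],
                    [tuple(s) for s in obj["spans"]],
                    [tuple(t) for t in obj["tuples"]]))
            else:
                out.append(obj)
    return out


def write_qa_pairs(pairs, path):
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(json.dumps({
                "question": p.question_tokens, "answer": p.answer_entity,
                "intent": p.intent_type,
                "supporting": [p.supporting_tuple.subject,
                               p.supporting_tuple.relation,
                               list(p.supporting_tuple.objects)],
                "body": p.body_tokens}, ensure_ascii=False) + "\n")


def read_qa_pairs(path):
    from .corpus import SynthQAPair
    from .schema import KnowledgeTuple

    out = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise CorpusFormatError(f"line {ln}: malformed JSON ({e})") from e
            s, r, objs = obj["supporting"]
            out.append(SynthQAPair(obj["question"], obj["answer"], obj["intent"],
                                   KnowledgeTuple(s, r, tuple(objs)), obj["body"]))
    return out


# ---------------------------------------------------------------------------
# Knowledge-graph export
# ---------------------------------------------------------------------------

TSV_HEADER = "kind\tsubject\trelation\tobject\ttype\taliases\tcount"


def export_kb(graph: KnowledgeGraph, path, fmt: str = "tsv"):
    if fmt == "tsv":
        _export_tsv(graph, path)
    elif fmt == "turtle":
        _export_turtle(graph, path)
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"entities": graph.entities,
                       "triples": [[s, r, o] for (s, r, o) in
                                   sorted(graph.triple_counts)],
                       "counts": {f"{s}|{r}|{o}": c for (s, r, o), c in
                                  sorted(graph.triple_counts.items())},
                       "groundings": graph.groundings,
                       "report": graph.report}, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}; supported: tsv, turtle, json")


def _export_tsv(graph: KnowledgeGraph, path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(TSV_HEADER + "\n")
        for ent in sorted(graph.entities):
            info = graph.entities[ent]
            fh.write("entity\t%s\t\t\t%s\t%s\t%d\n" % (
                ent, info["type"], ",".join(info["aliases"]), info["count"]))
        for (s, r, o) in sorted(graph.triple_counts):
            fh.write("triple\t%s\t%s\t%s\t\t\t%d\n"
                     % (s, r, o, graph.triple_counts[(s, r, o)]))
        for ent, val in sorted(graph.groundings.items()):
            fh.write("grounding\t%s\tDataGrounding\t%s\t\t\t0\n" % (ent, val))


def import_kb_tsv(path) -> KnowledgeGraph:
    graph = KnowledgeGraph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != TSV_HEADER:
            raise CorpusFormatError("line 1: unexpected TSV header")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise CorpusFormatError(f"line {ln}: expected 7 columns")
            kind, s, r, o, typ, aliases, count = parts
            if kind == "entity":
                graph.entities[s] = {"type": typ,
                                     "aliases": aliases.split(",") if aliases else [],
                                     "count": int(count)}
            elif kind == "triple":
                graph.triple_counts[(s, r, o)] = int(count)
            elif kind == "grounding":
                graph.groundings[s] = float(o)
            else:
                raise CorpusFormatError(f"line {ln}: unknown row kind {kind!r}")
    graph.tuples = merge_triples(graph.triple_counts)
    return graph


_NS = "http://example.org/medkg#"


def _export_turtle(graph: KnowledgeGraph, path):
    from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef

    g = Graph()
    ns = Namespace(_NS)
    g.bind("med", ns)
    for t in ENTITY_TYPES:
        g.add((ns[t], RDF.type, OWL.Class))
    for r in RELATION_TYPES:
        sub_t, obj_t = RELATION_SIGNATURE[r]
        g.add((ns[r], RDF.type, OWL.ObjectProperty))
        g.add((ns[r], RDFS.domain, ns[sub_t]))
        g.add((ns[r], RDFS.range, ns[obj_t]))
    g.add((ns["DataGrounding"], RDF.type, OWL.DatatypeProperty))

    def uri(name):
        return ns[name.replace(" ", "_")]

    for ent, info in graph.entities.items():
        g.add((uri(ent), RDF.type, ns[info["type"]]))
        g.add((uri(ent), RDFS.label, Literal(ent)))
    for (s, r, o) in sorted(graph.triple_counts):
        g.add((uri(s), ns[r], uri(o)))
    for ent, val in graph.groundings.items():
        g.add((uri(ent), ns["DataGrounding"], Literal(float(val))))
    g.serialize(destination=str(path), format="turtle")


# ---------------------------------------------------------------------------
# Config and manifest
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "synth": {"n_entities_per_type": 12, "n_relations_per_type": 6,
              "n_records": 300, "mean_statements": 3.3, "noise_rate": 0.0,
              "n_qa_pairs": 250},
    "bootstrap": {"score_threshold_valid": 0.7, "score_threshold_lowband": 0.3,
                  "w": 0.5, "search_K": 10, "max_iterations": 25,
                  "max_candidate_len": 10, "same_sentence": True,
                  "n_seed_entities": 5, "n_seed_relations": 3},
    "tagger": {"embed_dim": 512, "hidden": 200, "crf_input_dim": 200,
               "batch_size": 16, "epochs": 40, "use_bridge": True},
    "relation": {"word_dim": 100, "window_len": 20, "kernel_h": 5,
                 "n_kernels": 16, "fc_units": 128, "epochs": 30},
    "fusion": {"merge_threshold": 0.7, "queue_threshold": 0.3,
               "retain_threshold": 0.7, "drop_threshold": 0.3},
    "qa": {"encoder_dim": 32, "gamma": 0.2, "n_negatives": 5, "top_k": 1,
           "epochs": 8},
    "logging": {"level": "INFO"},
}


class ConfigError(ValueError):
    pass


def load_config(path=None) -> dict:
    """Defaults overlaid with a YAML file; unknown keys are rejected."""
    import copy

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is None:
        return cfg
    import yaml

    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}

    def merge(base, over, trail=""):
        for k, v in over.items():
            if k not in base:
                raise ConfigError(f"unknown config key {trail + k!r}")
            if isinstance(base[k], dict) and isinstance(v, dict):
                merge(base[k], v, trail + k + ".")
            else:
                base[k] = v

    merge(cfg, user)
    return cfg


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    stage: str
    config_hash: str
    seed: int
    inputs: dict = field(default_factory=dict)   # path -> digest
    outputs: dict = field(default_factory=dict)
    deterministic: bool = True
    timestamp: str = ""
    version: str = "0.1.0"


def make_manifest(stage, config, seed, inputs=(), outputs=(),
                  deterministic=True) -> RunManifest:
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
    return RunManifest(
        stage=stage, config_hash=cfg_hash, seed=seed,
        inputs={str(p): file_digest(p) for p in inputs},
        outputs={str(p): file_digest(p) for p in outputs},
        deterministic=deterministic,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))


def write_manifest(manifest: RunManifest, path):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=1)
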