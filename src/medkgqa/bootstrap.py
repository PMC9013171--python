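"""Bootstrapping pattern miner for entities and relations.

Starting from seed entities and seed relation triples, the miner
alternately (a) extracts surface patterns around seed occurrences and
(b) extracts new instances with validated patterns, until a fixed point.

Pattern quality is scored with support / confidence / reliability:

    support(s)      = |Pt(s) ∩ seeds| / |Pt(s)|
    confidence(s,c) = |Pt(s) ∩ seeds ∩ Tp(c)| / |Pt(s) ∩ seeds|
    score(s)        = w * support(s) + (1 - w) * max_c confidence(s, c)

where Pt(s) is the set of instances pattern s extracts from the corpus and
Tp(c) the seed instances of type c.  Patterns scoring at or above the
validation threshold (default 0.7) extract candidate instances that are
checked against the dictionary channel; patterns in the low band (default
[0.3, 0.7)) route their candidates through the retrieval channel, where
Score_c = |H| / K decides whether a human judges them.

Entity patterns are 1-3 tokens of left and/or right context inside one
sentence.  Relation patterns are word subsequences of the segmented,
frequency-filtered context string between an entity pair (with at most one
boundary word on each side).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

from .schema import ENTITY_TYPES, RELATION_SIGNATURE
from .oracle import ValidationOracle


class UndefinedSupportError(ValueError):
    """Pattern extracts nothing: support is undefined."""


# ---------------------------------------------------------------------------
# Config and stores
# ---------------------------------------------------------------------------

DEFAULT_STOP_WORDS = frozenset({".", "?", ","})


@dataclass
class BootstrapConfig:
    score_threshold_valid: float = 0.7     # validated at or above
    score_threshold_lowband: float = 0.3   # retrieval channel at or above
    w: float = 0.5                         # reliability mixing weight
    search_K: int = 10                     # top-K for Score_c
    max_iterations: int = 25
    max_candidate_len: int = 10            # tokens per extracted instance
    same_sentence: bool = True
    cross_sentence_relations: bool = False
    max_context_words: int = 8             # relation context substring cap
    stop_words: frozenset = DEFAULT_STOP_WORDS
    df_floor: int = 1                      # min document frequency of a context word
    min_pattern_occurrences: int = 1

    def __post_init__(self):
        if not 0.0 <= self.score_threshold_lowband <= self.score_threshold_valid <= 1.0:
            raise ValueError("need 0 <= lowband <= valid <= 1")


@dataclass
class SeedStore:
    """Monotonically growing seed sets with provenance."""

    entity_seeds: dict = field(default_factory=lambda: {t: set() for t in ENTITY_TYPES})
    relation_seeds: dict = field(default_factory=dict)  # rel -> {(s, rel, o)}
    provenance: dict = field(default_factory=dict)      # instance -> source tag

    def type_of(self, s: str):
        for t, seeds in self.entity_seeds.items():
            if s in seeds:
                return t
        return None

    def all_entities(self) -> set:
        return {e for seeds in self.entity_seeds.values() for e in seeds}

    def add_entity(self, s: str, etype: str, source: str) -> bool:
        existing = self.type_of(s)
        if existing is not None:
            return False
        self.entity_seeds.setdefault(etype, set()).add(s)
        self.provenance[s] = source
        return True

    def add_relation(self, triple, source: str) -> bool:
        triple = tuple(triple)
        rel = triple[1]
        bucket = self.relation_seeds.setdefault(rel, set())
        if triple in bucket:
            return False
        bucket.add(triple)
        self.provenance[triple] = source
        return True

    def counts(self) -> dict:
        out = {t: len(s) for t, s in self.entity_seeds.items()}
        out.update({r: len(s) for r, s in self.relation_seeds.items()})
        return out


@dataclass
class CandidatePattern:
    kind: str                      # "entity" | "relation"
    placeholder_type: str          # entity type or relation type
    left_context: tuple = ()
    right_context: tuple = ()
    context_string: tuple = ()     # relation kind: word sequence between pair
    subject_first: bool = True     # relation kind: order of roles in text
    degenerate: bool = False
    support: float = 0.0
    confidence_by_type: dict = field(default_factory=dict)
    score: float = 0.0
    validated: bool = False

    def key(self):
        if self.kind == "entity":
            return ("entity", self.left_context, self.right_context)
        return ("relation", self.context_string, self.subject_first,
                self.placeholder_type)


# ---------------------------------------------------------------------------
# Corpus helpers
# ---------------------------------------------------------------------------

def tokens_of(record) -> list:
    return record.tokens if hasattr(record, "tokens") else list(record)


def sentence_spans(tokens: list) -> list:
    """Half-open (start, end) sentence spans; '.' closes its sentence."""
    spans, start = [], 0
    for i, t in enumerate(tokens):
        if t == ".":
            spans.append((start, i + 1))
            start = i + 1
    if start < len(tokens):
        spans.append((start, len(tokens)))
    return spans


class CorpusIndex:
    """Token position index over a list of records."""

    def __init__(self, corpus):
        self.docs = [tokens_of(r) for r in corpus]
        self.sents = [sentence_spans(d) for d in self.docs]
        self.pos = defaultdict(list)  # token -> [(doc, idx)]
        for di, d in enumerate(self.docs):
            for i, t in enumerate(d):
                self.pos[t].append((di, i))

    def find_seq(self, seq: tuple):
        """All (doc, start) where the token sequence occurs."""
        if not seq:
            return []
        out = []
        for di, i in self.pos.get(seq[0], ()):
            if tuple(self.docs[di][i:i + len(seq)]) == tuple(seq):
                out.append((di, i))
        return out

    def sentence_at(self, doc: int, i: int):
        for s, e in self.sents[doc]:
            if s <= i < e:
                return s, e
        return 0, len(self.docs[doc])


# ---------------------------------------------------------------------------
# Entity patterns
# ---------------------------------------------------------------------------

def extract_entity_patterns(corpus, seeds: SeedStore, entity_type: str,
                            index: CorpusIndex | None = None) -> list:
    """All candidate context patterns around seed occurrences.

    For every occurrence: each left context of 1-3 tokens, each right
    context of 1-3 tokens, every left x right combination, and each side
    alone.  Contexts never cross a sentence boundary.  Deduplicated by
    exact context identity.
    """
    index = index or CorpusIndex(corpus)
    seen, out = set(), []
    for seed in sorted(seeds.entity_seeds.get(entity_type, ())):
        mention = tuple(seed.split())
        for di, i in index.find_seq(mention):
            s, e = index.sentence_at(di, i)
            doc = index.docs[di]
            lefts = [tuple(doc[i - n:i]) for n in (1, 2, 3) if i - n >= s]
            rights = [tuple(doc[i + len(mention):i + len(mention) + n])
                      for n in (1, 2, 3) if i + len(mention) + n <= e]
            combos = ([(l, r) for l in lefts for r in rights]
                      + [(l, ()) for l in lefts] + [((), r) for r in rights])
            for l, r in combos:
                k = ("entity", l, r)
                if k not in seen:
                    seen.add(k)
                    out.append(CandidatePattern("entity", entity_type,
                                                left_context=l, right_context=r))
    return out


def match_pattern(pattern: CandidatePattern, corpus, config: BootstrapConfig,
                  index: CorpusIndex | None = None) -> list:
    """Instances a pattern extracts, as (string, doc, start, end) tuples.

    Two-sided patterns extract every gap of 1..max_candidate_len tokens
    between the contexts; one-sided patterns are bounded by the sentence
    edge on the open side.  Candidates never cross a sentence boundary.
    """
    index = index or CorpusIndex(corpus)
    L, R = pattern.left_context, pattern.right_context
    out = []
    if L:
        for di, i in index.find_seq(L):
            s, e = index.sentence_at(di, i)
            doc = index.docs[di]
            gap_start = i + len(L)
            if gap_start >= e:
                continue
            if R:
                for g in range(1, config.max_candidate_len + 1):
                    j = gap_start + g
                    if j + len(R) > e:
                        break
                    if tuple(doc[j:j + len(R)]) == R:
                        out.append((" ".join(doc[gap_start:j]), di, gap_start, j))
            else:
                end = e - 1 if doc[e - 1] == "." else e
                if 0 < end - gap_start <= config.max_candidate_len:
                    out.append((" ".join(doc[gap_start:end]), di, gap_start, end))
    elif R:
        for di, j in index.find_seq(R):
            s, e = index.sentence_at(di, j)
            doc = index.docs[di]
            if 0 < j - s <= config.max_candidate_len:
                out.append((" ".join(doc[s:j]), di, s, j))
    return out


def score_pattern(pattern: CandidatePattern, corpus, seeds: SeedStore,
                  config: BootstrapConfig,
                  index: CorpusIndex | None = None,
                  extractions: list | None = None) -> CandidatePattern:
    """Fill support / per-type confidence / reliability score.

    Entity kind counts extracted strings; relation kind counts extracted
    (subject, object) pairs.  Confidence with an empty seed intersection is
    defined as 0.  Raises UndefinedSupportError when the pattern extracts
    nothing.
    """
    if pattern.kind == "entity":
        if extractions is None:
            extractions = match_pattern(pattern, corpus, config, index)
        pt = {x[0] for x in extractions}
        seed_all = seeds.all_entities()
        tp = {c: seeds.entity_seeds.get(c, set()) for c in ENTITY_TYPES}
    else:
        if extractions is None:
            extractions = match_relation_pattern(pattern, corpus, seeds, config, index)
        pt = {(x[0], x[2]) for x in extractions}
        seed_all = {(s, o) for bucket in seeds.relation_seeds.values()
                    for (s, _, o) in bucket}
        tp = {r: {(s, o) for (s, _, o) in bucket}
              for r, bucket in seeds.relation_seeds.items()}
    if not pt:
        raise UndefinedSupportError(f"pattern {pattern.key()} extracts nothing")
    inter = pt & seed_all
    support = len(inter) / len(pt)
    conf = {}
    for c, members in tp.items():
        conf[c] = (len(inter & members) / len(inter)) if inter else 0.0
    best = max(conf.values()) if conf else 0.0
    score = config.w * support + (1.0 - config.w) * best
    return replace(pattern, support=support, confidence_by_type=conf, score=score,
                   validated=score >= config.score_threshold_valid)


# ---------------------------------------------------------------------------
# Relation patterns
# ---------------------------------------------------------------------------

def bidirectional_max_match(tokens: list, dictionary: set, max_word_len: int = 6) -> list:
    """Segment an atomic-token sequence into words with a dictionary.

    Runs forward and backward maximum matching; when they disagree, the
    segmentation with fewer words wins (ties: fewer out-of-dictionary
    single tokens, then the backward result).
    """
    def fmm(seq):
        out, i = [], 0
        while i < len(seq):
            for n in range(min(max_word_len, len(seq) - i), 0, -1):
                w = " ".join(seq[i:i + n])
                if n == 1 or w in dictionary:
                    out.append(w)
                    i += n
                    break
        return out

    def bmm(seq):
        out, j = [], len(seq)
        while j > 0:
            for n in range(min(max_word_len, j), 0, -1):
                w = " ".join(seq[j - n:j])
                if n == 1 or w in dictionary:
                    out.append(w)
                    j -= n
                    break
        return out[::-1]

    f, b = fmm(list(tokens)), bmm(list(tokens))
    if f == b:
        return f
    if len(f) != len(b):
        return min(f, b, key=len)
    oov = lambda seg: sum(1 for w in seg if " " not in w and w not in dictionary)
    return b if oov(b) <= oov(f) else f


def document_frequencies(corpus) -> dict:
    """Per-token document frequency, via sklearn's vectorizer."""
    from sklearn.feature_extraction.text import CountVectorizer

    docs = [tokens_of(r) for r in corpus]
    vec = CountVectorizer(analyzer=lambda d: d, lowercase=False, binary=True)
    X = vec.fit_transform(docs)
    df = X.sum(axis=0).A1
    return {w: int(df[i]) for w, i in vec.vocabulary_.items()}


def filter_context_words(words: list, config: BootstrapConfig, df: dict) -> list:
    """Drop stop-listed words and words under the document-frequency floor."""
    return [w for w in words
            if w not in config.stop_words and df.get(w, 0) >= config.df_floor]


def _pair_context(index: CorpusIndex, di: int, span1, span2):
    """Context words around an in-sentence entity pair: <=1 boundary word
    each side plus the tokens between the mentions."""
    doc = index.docs[di]
    s, e = index.sentence_at(di, span1[0])
    pre = [doc[span1[0] - 1]] if span1[0] - 1 >= s else []
    post = [doc[span2[1]]] if span2[1] < e else []
    between = doc[span1[1]:span2[0]]
    return pre, between, post


def extract_relation_patterns(corpus, seeds: SeedStore, config: BootstrapConfig,
                              index: CorpusIndex | None = None,
                              df: dict | None = None) -> list:
    """Candidate relation patterns from seed-triple co-occurrences.

    For every co-occurrence of a seed pair in one sentence the context
    string (boundary words + between-words) is segmented with the seed
    dictionary, frequency-filtered, and every contiguous substring of the
    word sequence becomes a candidate pattern.  Adjacent entities yield a
    single degenerate empty pattern.
    """
    index = index or CorpusIndex(corpus)
    df = df if df is not None else document_frequencies(corpus)
    dictionary = seeds.all_entities()
    seen, out = set(), []
    for rel, bucket in sorted(seeds.relation_seeds.items()):
        for (s, _, o) in sorted(bucket):
            s_occ = index.find_seq(tuple(s.split()))
            o_occ = index.find_seq(tuple(o.split()))
            by_doc = defaultdict(lambda: ([], []))
            for di, i in s_occ:
                by_doc[di][0].append(i)
            for di, i in o_occ:
                by_doc[di][1].append(i)
            for di, (sis, ois) in by_doc.items():
                for si in sis:
                    for oi in ois:
                        st, en = index.sentence_at(di, si)
                        if not (st <= oi < en) and not config.cross_sentence_relations:
                            continue
                        sp_s = (si, si + len(s.split()))
                        sp_o = (oi, oi + len(o.split()))
                        if sp_s[0] < sp_o[0]:
                            first, second, subj_first = sp_s, sp_o, True
                        elif sp_o[0] < sp_s[0]:
                            first, second, subj_first = sp_o, sp_s, False
                        else:
                            continue
                        if first[1] > second[0]:
                            continue  # overlapping mentions
                        pre, between, post = _pair_context(index, di, first, second)
                        words = bidirectional_max_match(pre + between + post, dictionary)
                        words = filter_context_words(words, config, df)
                        if not words:
                            key = ("relation", (), subj_first, rel)
                            if key not in seen:
                                seen.add(key)
                                out.append(CandidatePattern(
                                    "relation", rel, context_string=(),
                                    subject_first=subj_first, degenerate=True))
                            continue
                        k = min(len(words), config.max_context_words)
                        words = words[:k]
                        for a in range(len(words)):
                            for b in range(a + 1, len(words) + 1):
                                sub = tuple(words[a:b])
                                key = ("relation", sub, subj_first, rel)
                                if key not in seen:
                                    seen.add(key)
                                    out.append(CandidatePattern(
                                        "relation", rel, context_string=sub,
                                        subject_first=subj_first))
    return out


def _typed_spans(index: CorpusIndex, di: int, typed_surfaces: dict) -> list:
    """Longest-match typed entity spans in one document.

    ``typed_surfaces`` maps surface string -> entity type.
    """
    doc = index.docs[di]
    by_first = defaultdict(list)
    for surf, t in typed_surfaces.items():
        toks = tuple(surf.split())
        by_first[toks[0]].append((toks, t, surf))
    for lst in by_first.values():
        lst.sort(key=lambda x: -len(x[0]))
    spans, i = [], 0
    while i < len(doc):
        hit = None
        for toks, t, surf in by_first.get(doc[i], ()):
            if tuple(doc[i:i + len(toks)]) == toks:
                hit = (i, i + len(toks), t, surf)
                break
        if hit:
            spans.append(hit)
            i = hit[1]
        else:
            i += 1
    return spans


def match_relation_pattern(pattern: CandidatePattern, corpus, seeds: SeedStore,
                           config: BootstrapConfig,
                           index: CorpusIndex | None = None,
                           df: dict | None = None,
                           typed_surfaces: dict | None = None) -> list:
    """Entity pairs extracted by a relation pattern.

    Returns (subject, relation, object, doc) tuples for every correctly
    typed in-sentence pair whose filtered context word sequence contains
    the pattern's word sequence contiguously.
    """
    index = index or CorpusIndex(corpus)
    df = df if df is not None else document_frequencies(corpus)
    if typed_surfaces is None:
        typed_surfaces = {s: t for t, ss in seeds.entity_seeds.items() for s in ss}
    dictionary = set(typed_surfaces)
    sub_t, obj_t = RELATION_SIGNATURE[pattern.placeholder_type]
    want = tuple(pattern.context_string)
    out = []
    for di in range(len(index.docs)):
        spans = _typed_spans(index, di, typed_surfaces)
        for a in range(len(spans)):
            for b in range(a + 1, len(spans)):
                sp1, sp2 = spans[a], spans[b]
                st, en = index.sentence_at(di, sp1[0])
                if not (st <= sp2[0] < en) and not config.cross_sentence_relations:
                    continue
                if pattern.subject_first:
                    subj, obj = sp1, sp2
                else:
                    subj, obj = sp2, sp1
                if subj[2] != sub_t or obj[2] != obj_t:
                    continue
                pre, between, post = _pair_context(index, di, (sp1[0], sp1[1]),
                                                   (sp2[0], sp2[1]))
                words = filter_context_words(
                    bidirectional_max_match(pre + between + post, dictionary),
                    config, df)
                n, m = len(want), len(words)
                found = (n == 0 and m == 0) or any(
                    tuple(words[i:i + n]) == want for i in range(m - n + 1)) if n else \
                    (m == 0)
                if found:
                    out.append((subj[3], pattern.placeholder_type, obj[3], di))
    return out


# ---------------------------------------------------------------------------
# Candidate validation
# ---------------------------------------------------------------------------

def validate_candidates(candidates, oracle: ValidationOracle | None,
                        config: BootstrapConfig, from_lowband: bool = False,
                        entity_type: str | None = None):
    """Route candidates through the dictionary / retrieval / human channels.

    Returns (accepted, queued_for_human, rejected, log).  With no oracle
    every candidate is queued — never silently accepted.  Dictionary hits
    are accepted outright; low-band candidates receive Score_c = |H| / K
    and are queued when Score_c reaches the low-band threshold.
    """
    accepted, queued, rejected, log = set(), set(), set(), []
    for cand in sorted(set(candidates)):
        if oracle is None:
            queued.add(cand)
            log.append((cand, "queued", "no-oracle"))
            continue
        if not from_lowband:
            if oracle.dictionary_lookup(cand):
                accepted.add(cand)
                log.append((cand, "accepted", "dictionary"))
                continue
            verdict = oracle.human_accepts(cand, entity_type)
            if verdict is True:
                accepted.add(cand)
                log.append((cand, "accepted", "human"))
            elif verdict is False:
                rejected.add(cand)
                log.append((cand, "rejected", "human"))
            else:
                queued.add(cand)
                log.append((cand, "queued", "dictionary-miss"))
        else:
            score_c = oracle.topk_hits(cand, config.search_K) / config.search_K
            if score_c >= config.score_threshold_lowband:
                verdict = oracle.human_accepts(cand, entity_type)
                if verdict is True:
                    accepted.add(cand)
                    log.append((cand, "accepted", f"search:{score_c:.2f}+human"))
                elif verdict is False:
                    rejected.add(cand)
                    log.append((cand, "rejected", f"search:{score_c:.2f}+human"))
                else:
                    queued.add(cand)
                    log.append((cand, "queued", f"search:{score_c:.2f}"))
            else:
                rejected.add(cand)
                log.append((cand, "rejected", f"search:{score_c:.2f}"))
    return accepted, queued, rejected, log


# ---------------------------------------------------------------------------
# The bootstrap loop
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedRecord:
    record_id: str
    tokens: list
    spans: list    # (start, end, entity_type, surface)
    tuples: list   # (subject, relation, object)


def annotate_corpus(corpus, seeds: SeedStore, config: BootstrapConfig,
                    pattern_library: list | None = None,
                    index: CorpusIndex | None = None) -> list:
    """Label every seed occurrence and every pattern-matched relation."""
    index = index or CorpusIndex(corpus)
    typed = {s: t for t, ss in seeds.entity_seeds.items() for s in ss}
    rel_instances = {tuple(t) for b in seeds.relation_seeds.values() for t in b}
    out = []
    for di, rec in enumerate(corpus):
        spans = _typed_spans(index, di, typed)
        tuples = []
        span_by_surface = defaultdict(list)
        for (st, en, t, surf) in spans:
            span_by_surface[surf].append((st, en))
        for (s, r, o) in sorted(rel_instances):
            if s in span_by_surface and o in span_by_surface:
                for ss, se in span_by_surface[s]:
                    sent = index.sentence_at(di, ss)
                    for os_, oe in span_by_surface[o]:
                        if sent[0] <= os_ < sent[1] and (s, r, o) not in tuples:
                            tuples.append((s, r, o))
        rid = getattr(rec, "record_id", f"doc{di:05d}")
        out.append(AnnotatedRecord(rid, list(tokens_of(rec)),
                                   [(st, en, t, surf) for (st, en, t, surf) in spans],
                                   tuples))
    return out


def run_bootstrap(corpus, seeds: SeedStore, config: BootstrapConfig | None = None,
                  oracle: ValidationOracle | None = None):
    """Iterate pattern mining and instance extraction to a fixed point.

    Returns (annotated_corpus, seeds, pattern_library, trace).  The trace
    holds per-iteration seed counts; it ends with a truncation flag when
    max_iterations stopped a still-growing run.
    """
    config = config or BootstrapConfig()
    index = CorpusIndex(corpus)
    df = document_frequencies(corpus)
    pattern_library: dict = {}
    trace = {"iterations": [], "truncated": False}

    for it in range(config.max_iterations):
        new_count = 0
        # --- entities ---------------------------------------------------
        for etype in ENTITY_TYPES:
            if not seeds.entity_seeds.get(etype):
                continue
            cands_valid, cands_low = set(), set()
            for pat in extract_entity_patterns(corpus, seeds, etype, index):
                ext = match_pattern(pat, corpus, config, index)
                if len(ext) < config.min_pattern_occurrences or not ext:
                    continue
                scored = score_pattern(pat, corpus, seeds, config, index, ext)
                pattern_library[scored.key()] = scored
                known = seeds.all_entities()
                new = {x[0] for x in ext} - known
                if scored.validated:
                    cands_valid |= new
                elif scored.score >= config.score_threshold_lowband:
                    cands_low |= new
            acc_v, _, _, _ = validate_candidates(cands_valid, oracle, config,
                                                 from_lowband=False, entity_type=etype)
            acc_l, _, _, _ = validate_candidates(cands_low - cands_valid, oracle,
                                                 config, from_lowband=True,
                                                 entity_type=etype)
            for cand in sorted(acc_v | acc_l):
                final_type = etype
                if oracle is not None:
                    t = oracle.entity_type_of(cand)
                    if t is not None:
                        final_type = t
                if seeds.add_entity(cand, final_type,
                                    "pattern-mined" if cand in acc_v
                                    else "oracle-validated"):
                    new_count += 1
        # --- relations ---------------------------------------------------
        if seeds.relation_seeds:
            typed = {s: t for t, ss in seeds.entity_seeds.items() for s in ss}
            known_pairs = {(s, r, o) for b in seeds.relation_seeds.values()
                           for (s, r, o) in b}
            rel_cands = set()
            for pat in extract_relation_patterns(corpus, seeds, config, index, df):
                if pat.degenerate:
                    continue
                ext = match_relation_pattern(pat, corpus, seeds, config, index,
                                             df, typed)
                if not ext:
                    continue
                scored = score_pattern(pat, corpus, seeds, config, index,
                                       [(s, r, o) for (s, r, o, _) in ext])
                pattern_library[scored.key()] = scored
                if scored.validated or scored.score >= config.score_threshold_lowband:
                    rel_cands |= {(s, r, o) for (s, r, o, _) in ext} - known_pairs
            for triple in sorted(rel_cands):
                verdict = oracle.relation_accepts(triple) if oracle else None
                if verdict and seeds.add_relation(triple, "pattern-mined"):
                    new_count += 1
        trace["iterations"].append({"iteration": it, "new": new_count,
                                    **seeds.counts()})
        if new_count == 0:
            break
    else:
        trace["truncated"] = True

    library = sorted(pattern_library.values(), key=lambda p: (-p.score, p.key()))
    annotated = annotate_corpus(corpus, seeds, config, library, index)
    return annotated, seeds, library, trace
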