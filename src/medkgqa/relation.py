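"""Relation classification: sliding-window CNN over word vectors plus a
paragraph-context vector.

The classifier takes the context word sequence of an entity pair (entity
slots replaced by a placeholder), embeds each word (k-dimensional vectors,
pre-trained on the corpus and fine-tuned during supervised training),
convolves with a bank of kernels of window h,

    c_i = f(w . x_{i:i+h-1} + b),      c = [c_1, ..., c_{n-h+1}],

max-pools each kernel's feature map to a scalar, concatenates the pooled
features with the paragraph vector of the source record, and classifies
with a fully connected softmax layer.  A NONE class rejects unrelated
pairs.  Training maximises  sum_i log p(y_i | sp_i, theta).

Paragraph vectors follow the distributed-memory scheme: each paragraph
owns a vector trained jointly with the word vectors to predict words in the
paragraph; vectors for unseen paragraphs are inferred by gradient steps
with the word table frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .schema import NONE_RELATION, RELATION_SIGNATURE, RELATION_TYPES

PAD_WORD, UNK_WORD, ENT_SLOT = "<pad>", "<unk>", "<ent>"
LABELS = list(RELATION_TYPES) + [NONE_RELATION]
LABEL_INDEX = {l: i for i, l in enumerate(LABELS)}


@dataclass
class RelationExample:
    words: tuple            # context word sequence with <ent> placeholders
    pair: tuple             # (subject surface, object surface)
    paragraph_id: int
    label: str              # relation type or NONE


@dataclass
class RelationCnnConfig:
    word_dim: int = 100       # k
    window_len: int = 20      # fixed input length n, symmetric padding
    kernel_h: int = 5         # words per convolution window
    n_kernels: int = 16
    fc_units: int = 128
    kernel_geometry: str = "window"   # "window" (h=5 x full k) | "half" preset
    lr: float = 0.02
    epochs: int = 30
    batch_size: int = 32
    patience: int = 5
    val_fraction: float = 0.2
    none_threshold: float = 0.5
    pretrain_epochs: int = 3
    pv_context: int = 2
    clip_norm: float = 5.0


# ---------------------------------------------------------------------------
# Paragraph vectors
# ---------------------------------------------------------------------------

@dataclass
class ParagraphVector:
    paragraph_id: int
    vector: np.ndarray
    inferred: bool = False
    degenerate: bool = False


class ParagraphVectorModel:
    """Jointly trained word and paragraph vectors (distributed-memory)."""

    def __init__(self, vocab, dim, n_paragraphs, rng):
        self.vocab = [PAD_WORD, UNK_WORD, ENT_SLOT] + \
            [w for w in vocab if w not in (PAD_WORD, UNK_WORD, ENT_SLOT)]
        self.tok2id = {w: i for i, w in enumerate(self.vocab)}
        self.dim = dim
        self.W = nn.Param(rng.normal(0, 0.1, size=(len(self.vocab), dim)))
        self.W.data[0] = 0.0
        self.D = nn.Param(rng.normal(0, 0.1, size=(n_paragraphs, dim)))
        self.Out = nn.init_matrix(rng, dim, len(self.vocab))

    def ids(self, words):
        unk = self.tok2id[UNK_WORD]
        return [self.tok2id.get(w, unk) for w in words]


def train_paragraph_vectors(paragraphs, dim: int, rng_seed: int,
                            epochs: int = 3, context: int = 2,
                            lr: float = 0.05) -> ParagraphVectorModel:
    """Train word + paragraph vectors by predicting each word from the
    paragraph vector averaged with its context words."""
    rng = np.random.default_rng(rng_seed)
    vocab = sorted({w for p in paragraphs for w in p})
    model = ParagraphVectorModel(vocab, dim, len(paragraphs), rng)
    opt = nn.Adam({"W": model.W, "D": model.D, "Out": model.Out}, lr=lr)
    positions = [(pi, i) for pi, p in enumerate(paragraphs) for i in range(len(p))]
    for _ in range(epochs):
        rng.shuffle(positions)
        for b0 in range(0, len(positions), 64):
            batch = positions[b0:b0 + 64]
            if not batch:
                continue
            ctx_ids, para_ids, targets = [], [], []
            for pi, i in batch:
                p = paragraphs[pi]
                ctx = [p[j] for j in range(max(0, i - context),
                                           min(len(p), i + context + 1)) if j != i]
                ctx = ctx or [PAD_WORD]
                ctx_ids.append(model.ids(ctx) + [0] * (2 * context - len(ctx)))
                para_ids.append(pi)
                targets.append(model.ids([p[i]])[0])
            C = np.array(ctx_ids)
            h = model.W[C.reshape(-1)].reshape(len(batch), C.shape[1], dim).mean(axis=1)
            h = (h + model.D[np.array(para_ids)]) * 0.5
            logits = h @ model.Out
            lp = nn.log_softmax(logits, axis=1)
            loss = -lp[np.arange(len(batch)), np.array(targets)].mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


def infer_paragraph_vector(paragraph_tokens, model: ParagraphVectorModel,
                           rng_seed: int = 0, steps: int = 30,
                           context: int = 2, lr: float = 0.1) -> ParagraphVector:
    """Vector for an unseen paragraph; only the new vector is updated."""
    if not paragraph_tokens:
        return ParagraphVector(-1, np.zeros(model.dim), inferred=True,
                               degenerate=True)
    rng = np.random.default_rng(rng_seed)
    vec = nn.Param(rng.normal(0, 0.1, size=model.dim))
    opt = nn.Adam({"v": vec}, lr=lr)
    W_frozen = model.W.data  # plain array: word table stays fixed
    Out_frozen = model.Out.data
    p = list(paragraph_tokens)
    for _ in range(steps):
        ctx_rows, targets = [], []
        for i in range(len(p)):
            ctx = [p[j] for j in range(max(0, i - context),
                                       min(len(p), i + context + 1)) if j != i]
            ctx = ctx or [PAD_WORD]
            ids = model.ids(ctx)
            ctx_rows.append(W_frozen[ids].mean(axis=0))
            targets.append(model.ids([p[i]])[0])
        h = (nn.Tensor(np.array(ctx_rows)) + vec.reshape(1, -1)) * 0.5
        logits = h @ nn.Tensor(Out_frozen)
        lp = nn.log_softmax(logits, axis=1)
        loss = -lp[np.arange(len(p)), np.array(targets)].mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    return ParagraphVector(-1, vec.data.copy(), inferred=True)


# ---------------------------------------------------------------------------
# CNN
# ---------------------------------------------------------------------------

class CnnParams:
    def __init__(self, vocab, config: RelationCnnConfig, rng_seed: int,
                 pretrained_words: np.ndarray | None = None):
        self.config = config
        self.vocab = list(vocab)
        self.tok2id = {w: i for i, w in enumerate(self.vocab)}
        rng = np.random.default_rng(rng_seed)
        k, n = config.word_dim, config.window_len
        if config.kernel_geometry == "half":
            self.h = max(1, n // 2)
            self.k_eff = max(1, k // 2)
        else:
            self.h = config.kernel_h
            self.k_eff = k
        p = {}
        if pretrained_words is not None:
            p["W"] = nn.Param(pretrained_words.copy())
        else:
            p["W"] = nn.Param(rng.normal(0, 0.1, size=(len(self.vocab), k)))
        p["W"].data[self.tok2id[PAD_WORD]] = 0.0
        p["K"] = nn.init_matrix(rng, self.h * self.k_eff, config.n_kernels)
        p["Kb"] = nn.Param(np.zeros(config.n_kernels))
        p["F1"] = nn.init_matrix(rng, config.n_kernels + k, config.fc_units)
        p["F1b"] = nn.Param(np.zeros(config.fc_units))
        p["F2"] = nn.init_matrix(rng, config.fc_units, len(LABELS))
        p["F2b"] = nn.Param(np.zeros(len(LABELS)))
        self.params = p

    def ids(self, words):
        unk = self.tok2id[UNK_WORD]
        return [self.tok2id.get(w, unk) for w in words]

    def pad_window(self, words) -> list:
        """Fix length n by symmetric PAD or centre truncation."""
        n = self.config.window_len
        w = list(words)[:n]
        short = n - len(w)
        left = short // 2
        return [PAD_WORD] * left + w + [PAD_WORD] * (short - left)


def conv_features(emb, kernels, bias, h: int, k_eff: int):
    """Pooled convolution features for an embedded window.

    ``emb`` is an (n, k) tensor; windows shorter than h are PAD-completed
    upstream, so n >= h always holds here.  Returns a (n_kernels,) tensor:
    the max over positions of tanh(w . x_{i:i+h-1} + b).
    """
    n = emb.shape[0]
    rows = [emb[i:i + h, :k_eff].reshape(1, -1) for i in range(n - h + 1)]
    windows = nn.concat(rows, axis=0)          # (n-h+1, h*k_eff)
    c = (windows @ kernels + bias).tanh()      # (n-h+1, K)
    return c.max(axis=0)


def _forward(model: CnnParams, word_ids: np.ndarray, para_vec: np.ndarray):
    p = model.params
    emb = p["W"][word_ids]                       # (n, k)
    pooled = conv_features(emb, p["K"], p["Kb"], model.h, model.k_eff)
    feat = nn.concat([pooled, nn.Tensor(para_vec)], axis=0)
    hid = (feat @ p["F1"] + p["F1b"]).tanh()
    return hid @ p["F2"] + p["F2b"]


def classify_relation(example: RelationExample, para_vec: np.ndarray,
                      model: CnnParams):
    """(label, probability vector); argmax ties break to the lowest index."""
    ids = np.array(model.ids(model.pad_window(example.words)))
    logits = _forward(model, ids, para_vec)
    probs = nn.softmax(logits, axis=0).data
    return LABELS[int(np.argmax(probs))], probs


def train_relation_cnn(examples, paragraphs, config: RelationCnnConfig | None = None,
                       rng_seed: int = 0):
    """Pre-train word vectors on the paragraphs, then fine-tune with the CNN.

    Returns (CnnParams, ParagraphVectorModel, history).  Refuses a corpus
    with fewer than two label classes.
    """
    config = config or RelationCnnConfig()
    labels = {e.label for e in examples}
    if len(labels) < 2:
        raise ValueError("need at least two relation classes to train")
    rng = np.random.default_rng(rng_seed)
    pv = train_paragraph_vectors(paragraphs, config.word_dim, rng_seed,
                                 epochs=config.pretrain_epochs,
                                 context=config.pv_context)
    model = CnnParams(pv.vocab, config, rng_seed, pretrained_words=pv.W.data)

    order = rng.permutation(len(examples))
    n_val = max(1, int(len(examples) * config.val_fraction))
    val_idx, train_idx = order[:n_val], order[n_val:]
    para_vectors = pv.D.data

    def batch_loss(idx):
        losses = []
        for i in idx:
            ex = examples[i]
            ids = np.array(model.ids(model.pad_window(ex.words)))
            pvec = para_vectors[ex.paragraph_id] if 0 <= ex.paragraph_id < len(
                para_vectors) else np.zeros(config.word_dim)
            logits = _forward(model, ids, pvec)
            lp = nn.log_softmax(logits, axis=0)
            losses.append(-lp[LABEL_INDEX[ex.label]])
        total = losses[0]
        for l in losses[1:]:
            total = total + l
        return total * (1.0 / len(losses))

    opt = nn.Adam(model.params, lr=config.lr, clip_norm=config.clip_norm)
    history = {"train_loss": [], "val_loss": []}
    best, best_state, wait = np.inf, None, 0
    for epoch in range(config.epochs):
        rng.shuffle(train_idx)
        ep = []
        for b0 in range(0, len(train_idx), config.batch_size):
            idx = train_idx[b0:b0 + config.batch_size]
            if len(idx) == 0:
                continue
            loss = batch_loss(idx)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep.append(float(loss.data))
        vl = float(batch_loss(val_idx).data)
        history["train_loss"].append(float(np.mean(ep)))
        history["val_loss"].append(vl)
        if vl < best - 1e-4:
            best, wait = vl, 0
            best_state = {k: p.data.copy() for k, p in model.params.items()}
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best_state is not None:
        for k, p in model.params.items():
            p.data = best_state[k]
    return model, pv, history


def classify_pair(context_words, pair, para_vec, model: CnnParams,
                  enumerate_substrings: bool = True):
    """Relation label for an entity pair from its context word sequence.

    Enumerates substrings of the context (always including the full
    sequence) and aggregates by maximum class probability; pairs whose best
    non-NONE probability stays under the rejection threshold are NONE.
    """
    words = list(context_words)
    cands = [tuple(words)]
    if enumerate_substrings:
        core = [w for w in words if w != ENT_SLOT]
        for a in range(len(core)):
            for b in range(a + 1, len(core) + 1):
                sub = (ENT_SLOT,) + tuple(core[a:b]) + (ENT_SLOT,)
                if sub not in cands:
                    cands.append(sub)
    best_label, best_prob = NONE_RELATION, -1.0
    for sub in cands:
        lab, probs = classify_relation(
            RelationExample(sub, pair, -1, NONE_RELATION), para_vec, model)
        conf = float(np.max(probs))
        if lab != NONE_RELATION and conf > best_prob:
            best_label, best_prob = lab, conf
    if best_prob < model.config.none_threshold:
        return NONE_RELATION, best_prob
    return best_label, best_prob


# ---------------------------------------------------------------------------
# Example construction from annotated records
# ---------------------------------------------------------------------------

def build_relation_examples(annotated_records, max_none_per_record: int = 2,
                            rng_seed: int = 0):
    """Labeled training examples and source paragraphs.

    Within-sentence typed pairs take their annotated relation label (or
    NONE when the pair expresses none); pairs straddling sentence
    boundaries provide NONE examples.  Entity mentions are replaced by a
    placeholder word; context keeps at most one boundary word per side.
    """
    rng = np.random.default_rng(rng_seed)
    examples, paragraphs = [], []
    for pid, rec in enumerate(annotated_records):
        toks = rec.tokens
        paragraphs.append(list(toks))
        spans = sorted(rec.spans)
        tuples = set(map(tuple, rec.tuples))
        bounds, start = [], 0
        for i, t in enumerate(toks):
            if t == ".":
                bounds.append((start, i + 1))
                start = i + 1
        if start < len(toks):
            bounds.append((start, len(toks)))

        def sentence_of(i):
            for bi, (s, e) in enumerate(bounds):
                if s <= i < e:
                    return bi
            return -1

        none_quota = max_none_per_record
        for a in range(len(spans)):
            for b in range(a + 1, len(spans)):
                s1, s2 = spans[a], spans[b]
                same = sentence_of(s1[0]) == sentence_of(s2[0])
                t1, t2 = s1[2], s2[2]
                label = NONE_RELATION
                pair = (s1[3], s2[3])
                for rel, (st, ot) in RELATION_SIGNATURE.items():
                    if t1 == st and t2 == ot and (s1[3], rel, s2[3]) in tuples and same:
                        label, pair = rel, (s1[3], s2[3])
                        break
                    if t2 == st and t1 == ot and (s2[3], rel, s1[3]) in tuples and same:
                        label, pair = rel, (s2[3], s1[3])
                        break
                if label == NONE_RELATION:
                    if same or none_quota <= 0 or rng.random() > 0.5:
                        if not same:
                            continue
                    else:
                        none_quota -= 1
                s, e = bounds[sentence_of(s1[0])]
                pre = [toks[s1[0] - 1]] if s1[0] - 1 >= s else []
                post_end = bounds[sentence_of(s2[0])][1]
                post = [toks[s2[1]]] if s2[1] < post_end else []
                between = toks[s1[1]:s2[0]]
                words = tuple(pre) + (ENT_SLOT,) + tuple(between) + (ENT_SLOT,) \
                    + tuple(post)
                words = tuple(w for w in words if w != ".") if not same else words
                examples.append(RelationExample(words, pair, pid, label))
    return examples, paragraphs
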