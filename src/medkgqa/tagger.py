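"""Character-level entity recognition: embeddings -> BiLSTM -> linear-chain CRF.

The encoder is a single bidirectional LSTM whose cell carries an optional
*context bridge*: at positions whose surroundings match a validated
bootstrapping pattern, the 8-slot pattern vector pt (concatenated token
embeddings, leftmost/rightmost selection with padding) is projected to the
cell dimension and added to the cell state through a learned gate,

    c_t = c_t_orig + p_t * pt,   p_t = sigma(W_pi [H_{t-1}, x_t] + W_pc c_{t-1} + b_p).

Decoding maximises  score(x, y) = sum_t (A[y_{t-1}, y_t] + P[t, y_t])
subject to BIOES legality.  Embeddings are co-trained with the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .schema import ENTITY_TYPES, TYPE_CODES, CODE_TYPES

PAD, UNK = "<pad>", "<unk>"
BRIDGE_SLOTS = 8


# ---------------------------------------------------------------------------
# Tag scheme
# ---------------------------------------------------------------------------

class TagScheme:
    """BIOES x entity-type labels plus O; 21 labels total."""

    def __init__(self):
        self.labels = ["O"]
        for code in (TYPE_CODES[t] for t in ENTITY_TYPES):
            for p in "BIES":
                self.labels.append(f"{p}-{code}")
        self.index = {l: i for i, l in enumerate(self.labels)}

    def __len__(self):
        return len(self.labels)

    def encode_spans(self, n_tokens: int, spans) -> list:
        """BIOES labels for (start, end, entity_type, ...) spans."""
        y = ["O"] * n_tokens
        for sp in spans:
            start, end, etype = sp[0], sp[1], sp[2]
            code = TYPE_CODES[etype]
            if end - start == 1:
                y[start] = f"S-{code}"
            else:
                y[start] = f"B-{code}"
                for i in range(start + 1, end - 1):
                    y[i] = f"I-{code}"
                y[end - 1] = f"E-{code}"
        return [self.index[l] for l in y]

    def decode_labels(self, label_ids) -> list:
        """Spans (start, end, entity_type) from a BIOES label sequence."""
        spans, start, code = [], None, None
        for i, li in enumerate(label_ids):
            lab = self.labels[li]
            if lab == "O":
                start, code = None, None
                continue
            p, c = lab.split("-")
            if p == "S":
                spans.append((i, i + 1, CODE_TYPES[c]))
                start, code = None, None
            elif p == "B":
                start, code = i, c
            elif p == "I":
                if code != c:
                    start, code = None, None  # malformed; drop
            elif p == "E":
                if start is not None and code == c:
                    spans.append((start, i + 1, CODE_TYPES[c]))
                start, code = None, None
        return spans

    def legality_mask(self) -> np.ndarray:
        """mask[i, j] True when label j may follow label i."""
        L = len(self.labels)
        ok = np.zeros((L, L), dtype=bool)

        def kind(lab):
            return ("O", None) if lab == "O" else tuple(lab.split("-"))

        for i, a in enumerate(self.labels):
            pa, ca = kind(a)
            for j, b in enumerate(self.labels):
                pb, cb = kind(b)
                if pa in ("O", "E", "S"):
                    ok[i, j] = pb in ("O", "B", "S")
                else:  # B or I must continue the same entity
                    ok[i, j] = pb in ("I", "E") and cb == ca
        return ok

    def start_mask(self) -> np.ndarray:
        return np.array([l == "O" or l[0] in "BS" for l in self.labels])

    def end_mask(self) -> np.ndarray:
        return np.array([l == "O" or l[0] in "ES" for l in self.labels])


# ---------------------------------------------------------------------------
# CRF primitives
# ---------------------------------------------------------------------------

def crf_sequence_score(P: np.ndarray, A: np.ndarray, y,
                       start: np.ndarray | None = None,
                       stop: np.ndarray | None = None) -> float:
    """Exact path score: start transition + sum_t (A[y_{t-1}, y_t] + P[t, y_t])."""
    y = list(y)
    T, L = P.shape
    if len(y) != T:
        raise ValueError("label sequence length mismatch")
    if any(not 0 <= yi < L for yi in y):
        raise ValueError("illegal label index")
    s = float(start[y[0]]) if start is not None else 0.0
    s += float(P[0, y[0]])
    for t in range(1, T):
        s += float(A[y[t - 1], y[t]]) + float(P[t, y[t]])
    if stop is not None:
        s += float(stop[y[-1]])
    return s


def crf_log_partition(P: np.ndarray, A: np.ndarray,
                      start: np.ndarray | None = None,
                      stop: np.ndarray | None = None) -> float:
    """log sum over all paths of exp(score), by the forward algorithm."""
    from scipy.special import logsumexp

    T, L = P.shape
    alpha = P[0] + (start if start is not None else 0.0)
    for t in range(1, T):
        alpha = logsumexp(alpha[:, None] + A, axis=0) + P[t]
    if stop is not None:
        alpha = alpha + stop
    return float(logsumexp(alpha))


def viterbi_decode(P: np.ndarray, A: np.ndarray,
                   legality: np.ndarray | None = None,
                   start_mask: np.ndarray | None = None,
                   end_mask: np.ndarray | None = None) -> list:
    """Highest-scoring label path; ties break to the lowest label index."""
    NEG = -1e12
    T, L = P.shape
    A_eff = A.copy()
    if legality is not None:
        A_eff = np.where(legality, A_eff, NEG)
    delta = P[0].copy()
    if start_mask is not None:
        delta = np.where(start_mask, delta, NEG)
    back = np.zeros((T, L), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + A_eff
        back[t] = np.argmax(cand, axis=0)  # argmax takes lowest index on ties
        delta = cand[back[t], np.arange(L)] + P[t]
    if end_mask is not None:
        delta = np.where(end_mask, delta, NEG)
    path = [int(np.argmax(delta))]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return path[::-1]


# ---------------------------------------------------------------------------
# Bridge pattern lookup
# ---------------------------------------------------------------------------

@dataclass
class BridgePattern:
    tokens: tuple        # exactly BRIDGE_SLOTS entries (PAD-padded)
    score: float
    source_key: tuple

    def __post_init__(self):
        assert len(self.tokens) == BRIDGE_SLOTS


def make_bridge_tokens(left: tuple, right: tuple) -> tuple:
    """8 slots from a pattern's contexts: leftmost/rightmost selection or padding."""
    toks = list(left) + list(right)
    if len(toks) > BRIDGE_SLOTS:
        half = BRIDGE_SLOTS // 2
        toks = toks[:half] + toks[-half:]
    return tuple(toks) + (PAD,) * (BRIDGE_SLOTS - len(toks))


def lookup_bridge_patterns(position: int, sentence: list, pattern_library,
                           max_gap: int = 4):
    """Best validated pattern bracketing this position, or None.

    A pattern matches when its left context ends at a window start s <= t
    and its right context starts at a window end e > t with e - s <= max_gap.
    Ties: longest total context, then higher score, then lexicographic.
    """
    t = position
    best = None
    for pat in pattern_library:
        if getattr(pat, "kind", "entity") != "entity" or not pat.validated:
            continue
        L, R = tuple(pat.left_context), tuple(pat.right_context)
        matched = False
        for s in range(max(0, t - max_gap + 1), t + 1):
            if L and tuple(sentence[max(0, s - len(L)):s]) != L:
                continue
            if not L and s != 0:
                continue
            hi = min(len(sentence), s + max_gap)
            for e in range(t + 1, hi + 1):
                if R:
                    if tuple(sentence[e:e + len(R)]) == R:
                        matched = True
                        break
                else:
                    if e == len(sentence) or sentence[e] == ".":
                        matched = True
                        break
            if matched:
                break
        if not matched:
            continue
        rank = (len(L) + len(R), pat.score, tuple(reversed(L + R)))
        if best is None or rank > best[0]:
            best = (rank, pat)
    if best is None:
        return None
    pat = best[1]
    return BridgePattern(make_bridge_tokens(tuple(pat.left_context),
                                            tuple(pat.right_context)),
                         pat.score, pat.key())


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class TaggerConfig:
    embed_dim: int = 512        # co-trained character embedding size
    hidden: int = 200           # LSTM hidden units per direction
    crf_input_dim: int = 200
    batch_size: int = 16        # alternative preset: 50 sentences per batch
    lr: float = 0.02
    epochs: int = 40
    patience: int = 5
    val_fraction: float = 0.2
    use_bridge: bool = True
    bridge_max_gap: int = 4
    clip_norm: float = 5.0


class TaggerParams:
    """Vocabulary, tag scheme and all trainable tensors."""

    def __init__(self, vocab: list, config: TaggerConfig, rng_seed: int,
                 pattern_library=None):
        self.config = config
        self.scheme = TagScheme()
        self.vocab = list(vocab)
        if PAD not in self.vocab:
            self.vocab = [PAD, UNK] + [v for v in self.vocab if v not in (PAD, UNK)]
        self.tok2id = {t: i for i, t in enumerate(self.vocab)}
        self.pattern_library = list(pattern_library or [])
        rng = np.random.default_rng(rng_seed)
        d, H, L = config.embed_dim, config.hidden, len(self.scheme)
        p = {}
        p["E"] = nn.Param(rng.normal(0, 0.1, size=(len(self.vocab), d)))
        p["E"].data[0] = 0.0  # PAD embedding
        nn.init_lstm(rng, p, "fw_", d, H, with_bridge=config.use_bridge)
        nn.init_lstm(rng, p, "bw_", d, H, with_bridge=config.use_bridge)
        if config.use_bridge:
            p["bridge_proj"] = nn.init_matrix(rng, BRIDGE_SLOTS * d, H)
        p["proj"] = nn.init_matrix(rng, 2 * H, config.crf_input_dim)
        p["proj_b"] = nn.Param(np.zeros(config.crf_input_dim))
        p["out"] = nn.init_matrix(rng, config.crf_input_dim, L)
        p["out_b"] = nn.Param(np.zeros(L))
        p["A"] = nn.Param(rng.normal(0, 0.01, size=(L, L)))
        p["start"] = nn.Param(np.zeros(L))
        self.params = p

    def ids(self, tokens) -> list:
        unk = self.tok2id.get(UNK, 0)
        return [self.tok2id.get(t, unk) for t in tokens]

    def bridge_ids(self, tokens) -> tuple:
        """(T, 8) slot-token id matrix and (T,) active mask."""
        T = len(tokens)
        ids = np.zeros((T, BRIDGE_SLOTS), dtype=int)
        active = np.zeros(T, dtype=bool)
        if not (self.config.use_bridge and self.pattern_library):
            return ids, active
        for t in range(T):
            bp = lookup_bridge_patterns(t, tokens, self.pattern_library,
                                        self.config.bridge_max_gap)
            if bp is not None:
                ids[t] = self.ids(bp.tokens)
                active[t] = True
        return ids, active


def bridge_cell_update(c_orig, pt, H_prev, x_t, c_prev, W_pi, W_pc, b_p):
    """Reference bridge formula on plain tensors:
    c_t = c_orig + sigma(W_pi [H_prev, x_t] + W_pc c_prev + b_p) * pt."""
    z = nn.concat([H_prev, x_t], axis=-1)
    p_t = (z @ W_pi + c_prev @ W_pc + b_p).sigmoid()
    return c_orig + p_t * pt


def _encode_batch(params, config: TaggerConfig, X: np.ndarray, mask: np.ndarray,
                  bridge_vecs=None):
    """Emissions (B, T, L) for a padded id batch (B, T)."""
    p = params
    B, T = X.shape
    H = config.hidden
    emb = p["E"][X.reshape(-1)].reshape(B, T, config.embed_dim)
    outs_f, outs_b = [], []
    h = nn.Tensor(np.zeros((B, H)))
    c = nn.Tensor(np.zeros((B, H)))
    for t in range(T):
        br = bridge_vecs[:, t] if bridge_vecs is not None else None
        h_new, c_new = nn.lstm_step(p, "fw_", emb[:, t], h, c,
                                    bridge=br)
        m = mask[:, t:t + 1]
        h = h_new * m + h * (1 - m)
        c = c_new * m + c * (1 - m)
        outs_f.append(h)
    h = nn.Tensor(np.zeros((B, H)))
    c = nn.Tensor(np.zeros((B, H)))
    for t in range(T - 1, -1, -1):
        br = bridge_vecs[:, t] if bridge_vecs is not None else None
        h_new, c_new = nn.lstm_step(p, "bw_", emb[:, t], h, c,
                                    bridge=br)
        m = mask[:, t:t + 1]
        h = h_new * m + h * (1 - m)
        c = c_new * m + c * (1 - m)
        outs_b.append(h)
    outs_b = outs_b[::-1]
    feats = nn.stack([nn.concat([f, b], axis=1) for f, b in zip(outs_f, outs_b)],
                     axis=1)  # (B, T, 2H)
    z = feats.reshape(B * T, 2 * H) @ p["proj"] + p["proj_b"]
    z = z.tanh()
    em = (z @ p["out"] + p["out_b"]).reshape(B, T, -1)
    return em


def _bridge_vectors(params, config, Bids: np.ndarray, Bact: np.ndarray):
    """(B, T) -> per-step projected bridge tensors or None."""
    if not config.use_bridge or not Bact.any():
        return None
    B, T, S = Bids.shape
    emb = params["E"][Bids.reshape(-1)].reshape(B, T, S * config.embed_dim)
    proj = (emb.reshape(B * T, S * config.embed_dim) @ params["bridge_proj"]) \
        .reshape(B, T, config.hidden)
    act = nn.Tensor(Bact[:, :, None].astype(float))
    return proj * act


def _crf_nll(em, A, start, Y: np.ndarray, mask: np.ndarray):
    """Mean negative log-likelihood of gold paths for a padded batch."""
    B, T, L = em.shape
    lengths = mask.sum(axis=1).astype(int)
    # gold scores
    bidx = np.arange(B)
    gold = em[bidx, 0, Y[:, 0]] + start[Y[:, 0]]
    for t in range(1, T):
        step = em[bidx, t, Y[:, t]] + A[Y[:, t - 1], Y[:, t]]
        gold = gold + step * nn.Tensor(mask[:, t])
    # partition
    alpha = em[:, 0] + start.reshape(1, L)
    for t in range(1, T):
        nxt = (alpha.reshape(B, L, 1) + A.reshape(1, L, L)
               + em[:, t].reshape(B, 1, L)).logsumexp(axis=1)
        m = mask[:, t:t + 1]
        alpha = nxt * m + alpha * (1 - m)
    logZ = alpha.logsumexp(axis=1)
    return (logZ - gold).mean()


def _sentences_from_annotated(records, scheme: TagScheme):
    """(tokens, label_ids) training sentences from annotated records."""
    out = []
    for rec in records:
        toks = rec.tokens if hasattr(rec, "tokens") else rec["tokens"]
        if hasattr(rec, "gold_spans"):
            spans = [(s.start, s.end, s.entity_type) for s in rec.gold_spans]
        elif hasattr(rec, "spans"):
            spans = rec.spans
        else:
            spans = rec["spans"]
        bounds, start = [], 0
        for i, t in enumerate(toks):
            if t == ".":
                bounds.append((start, i + 1))
                start = i + 1
        if start < len(toks):
            bounds.append((start, len(toks)))
        for s, e in bounds:
            sub_spans = [(a - s, b - s, t) for (a, b, t, *_) in spans
                         if s <= a and b <= e]
            y = scheme.encode_spans(e - s, sub_spans)
            out.append((toks[s:e], y))
    return out


def train_tagger(annotated_records, config: TaggerConfig | None = None,
                 rng_seed: int = 0, pattern_library=None):
    """Train by CRF maximum likelihood with co-trained embeddings.

    Splits off a validation fraction for early stopping; reproducible for a
    fixed seed.  Refuses corpora with zero entity spans.  Returns
    (TaggerParams, history).
    """
    config = config or TaggerConfig()
    scheme = TagScheme()
    sents = _sentences_from_annotated(annotated_records, scheme)
    if not any(any(y != scheme.index["O"] for y in ys) for _, ys in sents):
        raise ValueError("corpus contains no entity spans; refusing to train")
    rng = np.random.default_rng(rng_seed)
    vocab = sorted({t for toks, _ in sents for t in toks})
    model = TaggerParams(vocab, config, rng_seed, pattern_library)

    order = rng.permutation(len(sents))
    n_val = max(1, int(len(sents) * config.val_fraction))
    val_idx, train_idx = order[:n_val], order[n_val:]

    def pad_batch(idx):
        batch = [sents[i] for i in idx]
        T = max(len(t) for t, _ in batch)
        X = np.zeros((len(batch), T), dtype=int)
        Y = np.zeros((len(batch), T), dtype=int)
        M = np.zeros((len(batch), T))
        Bids = np.zeros((len(batch), T, BRIDGE_SLOTS), dtype=int)
        Bact = np.zeros((len(batch), T), dtype=bool)
        for bi, (toks, ys) in enumerate(batch):
            X[bi, :len(toks)] = model.ids(toks)
            Y[bi, :len(ys)] = ys
            M[bi, :len(toks)] = 1.0
            ids, act = model.bridge_ids(toks)
            Bids[bi, :len(toks)] = ids
            Bact[bi, :len(toks)] = act
        return X, Y, M, Bids, Bact

    opt = nn.Adam(model.params, lr=config.lr, clip_norm=config.clip_norm)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, wait = np.inf, None, 0
    for epoch in range(config.epochs):
        rng.shuffle(train_idx)
        losses = []
        for b0 in range(0, len(train_idx), config.batch_size):
            idx = train_idx[b0:b0 + config.batch_size]
            X, Y, M, Bids, Bact = pad_batch(idx)
            bv = _bridge_vectors(model.params, config, Bids, Bact)
            em = _encode_batch(model.params, config, X, M, bv)
            loss = _crf_nll(em, model.params["A"], model.params["start"], Y, M)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        X, Y, M, Bids, Bact = pad_batch(val_idx)
        bv = _bridge_vectors(model.params, config, Bids, Bact)
        em = _encode_batch(model.params, config, X, M, bv)
        vl = float(_crf_nll(em, model.params["A"], model.params["start"], Y, M).data)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(vl)
        if vl < best_val - 1e-4:
            best_val, wait = vl, 0
            best_state = {k: p.data.copy() for k, p in model.params.items()}
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best_state is not None:
        for k, p in model.params.items():
            p.data = best_state[k]
    return model, history


def tag_sentence(model: TaggerParams, tokens: list) -> list:
    """Viterbi label ids for one sentence."""
    X = np.array([model.ids(tokens)])
    M = np.ones((1, len(tokens)))
    Bids = np.zeros((1, len(tokens), BRIDGE_SLOTS), dtype=int)
    Bact = np.zeros((1, len(tokens)), dtype=bool)
    ids, act = model.bridge_ids(tokens)
    Bids[0], Bact[0] = ids, act
    bv = _bridge_vectors(model.params, model.config, Bids, Bact)
    em = _encode_batch(model.params, model.config, X, M, bv)
    scheme = model.scheme
    return viterbi_decode(em.data[0], model.params["A"].data,
                          scheme.legality_mask(), scheme.start_mask(),
                          scheme.end_mask())


def extract_entities(tokens: list, model: TaggerParams) -> list:
    """(start, end, entity_type, surface) spans over a token sequence.

    Sentences are decoded independently; spans use 0-based half-open
    indices into the full sequence.
    """
    out = []
    bounds, start = [], 0
    for i, t in enumerate(tokens):
        if t == ".":
            bounds.append((start, i + 1))
            start = i + 1
    if start < len(tokens):
        bounds.append((start, len(tokens)))
    for s, e in bounds:
        labels = tag_sentence(model, tokens[s:e])
        for (a, b, t) in model.scheme.decode_labels(labels):
            out.append((a + s, b + s, t, " ".join(tokens[a + s:b + s])))
    return out


def embed_entity(model: TaggerParams, entity: str) -> np.ndarray:
    """Mean co-trained token embedding — the entity vectorizer fusion uses."""
    ids = model.ids(entity.split())
    return model.params["E"].data[ids].mean(axis=0)


def span_f1(gold_spans, pred_spans) -> float:
    """Exact span-level F1 over (start, end, type) triples."""
    g, p = set(gold_spans), set(pred_spans)
    if not g and not p:
        return 1.0
    tp = len(g & p)
    prec = tp / len(p) if p else 0.0
    rec = tp / len(g) if g else 0.0
    return 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
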