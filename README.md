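# medkgqa

Automatic construction of a medical knowledge graph from clinical-style
free text, and question answering over that graph with a memory network —
an end-to-end, desk-scale re-implementation of a bootstrapping + deep
learning pipeline for clinical corpora, complete with a synthetic corpus
generator so every stage is testable without access to real health
records.

The package is aimed at researchers in biomedical text mining who want a
transparent, fully seeded reference implementation of the following
pipeline:

1. **Bootstrapping annotation.** Starting from seed entities and seed
   relation triples, surface patterns (1–3 tokens of left/right context
   around an entity; segmented, frequency-filtered context strings between
   an entity pair) are mined and scored by

   ```
   support(s)      = |Pt(s) ∩ seeds| / |Pt(s)|
   confidence(s,c) = |Pt(s) ∩ seeds ∩ Tp(c)| / |Pt(s) ∩ seeds|
   score(s)        = w·support(s) + (1−w)·max_c confidence(s,c)
   ```

   Patterns scoring ≥ 0.7 are validated; instances from patterns in
   [0.3, 0.7) are triaged through a retrieval channel (`Score_c = |H|/K`)
   and a human-judgment channel. Both channels are pluggable oracles; the
   bundled generator ledger stands in for web encyclopedias and human
   validators.
2. **Neural extractors.** A character-level BiLSTM + CRF tagger (BIOES × 5
   entity types) whose LSTM cell carries a gated *context bridge*
   `c_t = c_t^orig + p_t ⊙ pt` injecting the embedding of the best-matching
   bootstrap pattern, and a sliding-window CNN relation classifier
   (`c_i = tanh(w·x_{i:i+h−1}+b)`, max-pooled, concatenated with a
   paragraph-context vector) over five relation types plus a NONE class.
3. **Knowledge fusion.** Entity alignment by cosine similarity with
   two-threshold triage (auto-merge ≥ 0.7, human queue in [0.3, 0.7)) and
   supportability-based consistency analysis
   (`confidence = tuple frequency / subject mentions`, e.g. 74/379 = 0.195
   → dropped, 0.71 → retained).
4. **Memory-network QA.** Fused tuples become sorted memory slots; a
   question is encoded patch-by-patch; candidate slots (shared-entity
   binary search) are ranked by region-affinity attention
   (`s_ij` patch cosines, row-softmax `α`, trained aggregation
   `Att = W·[mean s, Σ α⊙s, max α]`), and a trained response head decodes a
   typed answer entity, rendered through a text frame. Training is
   two-phase: a margin ranking loss with sampled negative memories and
   answers, then a generalization MLP that learns memory utility values.

## Worked example

```python
from medkgqa.pipeline import run_pipeline

out = run_pipeline(seed=1, n_records=250, n_qa=200, noise_rate=0.0)
print("bootstrap entity recall ", out["bootstrap"]["entity_recall"])
print("tagger span F1          ", out["tagger"]["span_f1"])
print("relation macro F1       ", round(out["relation"]["macro_f1"], 4))
print("fusion exact match      ", out["fusion"]["exact_match"])
print("QA P@1                  ", out["qa"]["metrics"]["p_at_1"])
print("QA P@1, no memory       ", out["qa"]["ablated_p_at_1"])
```

prints, on the default noise-free study (about two minutes on one CPU):

```
bootstrap entity recall  1.0
tagger span F1           1.0
relation macro F1        0.997
fusion exact match       True
QA P@1                   1.0
QA P@1, no memory        0.0
```

Reading: bootstrapping recovered every planted entity that occurs in the
corpus (with perfect precision, since every acceptance is traceable to the
dictionary or the validation channel); the trained extractors reproduce the
gold annotation on held-out records; fusion undid the injected alias noise
and discarded spurious low-support tuples, so the fused graph equals the
planted one; and the memory network answers all held-out questions, while
deleting its memory drops precision to zero.

The same pipeline is exposed as a CLI (`medkgqa synth | bootstrap |
train-ner | tag | train-re | classify-re | fuse | build-memory | train-qa |
answer | label-testset | evaluate | demo`), each stage writing its outputs
and a reproducibility manifest into a workspace directory.

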