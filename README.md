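# consortcheck

Sentence-level screening of randomized controlled trial (RCT) publications
against the CONSORT 2010 reporting checklist.

Complete reporting of RCTs — trial design, randomization, blinding, outcomes,
harms, funding — is what lets readers, reviewers and meta-analysts judge a
trial's credibility, yet adherence to the CONSORT checklist remains poor and
manual screening is slow. `consortcheck` is a toolkit for journal editorial
workflows and meta-research: it decides, sentence by sentence and article by
article, **which of the 37 fine-grained CONSORT checklist items a publication
reports**, and backs every "reported" verdict with supporting sentences.

## What it does

* **Multi-label sentence classification** over the 34 sentence-level items.
  Each sentence is represented as a context window — preceding, target and
  trailing sentence, each prepended with its nested section headers
  (`Methods Patients <sentence>`) — encoded to a pooled vector, optionally
  concatenated with a learned sentence-position embedding (absolute index or
  relative-position decile), and classified through a fully connected layer
  with sigmoid outputs: for sentence representation **h** and items
  *k* = 1…34, *P(item k)* = σ(**w**ₖᵀ**h** + bₖ), trained with binary
  cross-entropy (batch size 4, encoder learning rate 1e-5, head learning
  rate 1e-3, dropout 0.1, 20 epochs). A deterministic hashed bag-of-tokens
  reference encoder is shipped so everything runs on a CPU with no
  downloads; a pretrained biomedical transformer can be plugged in through
  the same encoder contract.
* **Rule-based article-level items**: 1a (title contains a `random*` stem)
  and 1b (abstract opens with a National Library of Medicine
  structured-abstract header).
* **Data augmentation for the 8 rare items** (3b, 6b, 7b, 9, 11b, 12b, 14b,
  21): easy-data-augmentation perturbations (synonym replacement, random
  insertion/swap/deletion) with pluggable synonym providers, plus
  deterministic LLM prompt builders (rephrasing and generative) and a
  response parser behind an offline completion-provider interface.
* **Evaluation** exactly as adherence-screening work reports it: grouped
  5-fold cross-validation (articles never straddle folds), micro/macro
  precision/recall/F1 and AUC at the sentence level, the article **(ANY)**
  and stricter article **(1+)** verification schemes, and McNemar
  matched-pairs tests on pooled (sentence, label) decisions.
* **Synthetic corpora**: a generator that reproduces the statistical shape
  of an annotated RCT corpus (IMRaD structure, skewed label frequencies,
  controllable cue strength and cue placement) so every pipeline stage is
  testable end to end.

## Worked example

```python
import consortcheck as cc
from consortcheck.evaluation import cross_validate, group_kfold

# a synthetic study corpus: 30 articles, every labeled sentence carries
# its item's cue token
arts = cc.generate_corpus(cc.GeneratorSpec(
    n_articles=30, sentences_per_article=(30, 50), cue_strength=1.0, seed=11))

cfg = cc.ModelConfig(seed=3)           # context + all headers, 20 epochs
plan = group_kfold(arts, 5, seed=3)
report = cross_validate(arts, cfg, plan)
s = report.summary()
print(f"sentence micro-F1 {s['sentence.micro_f1']['mean']:.3f} "
      f"(sd {s['sentence.micro_f1']['sd']:.3f})")
print(f"article (ANY) micro-F1 {s['article_any.micro_f1']['mean']:.3f}")
print(f"article (1+)  micro-F1 {s['article_one_plus.micro_f1']['mean']:.3f}")
```

prints

```
sentence micro-F1 0.925 (sd 0.104)
article (ANY) micro-F1 0.934
article (1+)  micro-F1 0.934
```

— held-out sentence-level micro-F1 of the classifier on a perfectly cued
corpus, and the two article-level verification scores (ANY credits an item
when the article is correctly flagged as reporting it anywhere; 1+
additionally requires at least one correctly identified supporting
sentence).

The same pipeline is available from the shell:

```bash
consortcheck simulate --out corpus.csv --seed 1
consortcheck train corpus.csv --model-dir model/
consortcheck predict corpus.csv --model-dir model/ --out preds.jsonl
consortcheck check corpus.csv --model-dir model/   # per-article report
consortcheck evaluate corpus.csv --folds 5
```

## Real corpora

`consortcheck ingest` converts JATS-style PMC XML into the documented
sentence-per-row CSV schema (`article_id, sentence_index, part,
section_path, text, labels`), and `read_corpus` accepts the same schema as
CSV or JSON-lines, so an annotated corpus such as CONSORT-TM can be dropped
in directly. Training a pretrained-transformer encoder on such a corpus is
a GPU workflow outside the scope of the built-in reference encoder.
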