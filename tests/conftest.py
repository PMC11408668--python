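import numpy as np
import pytest

import consortcheck as cc
from consortcheck.corpus_io import Article, SentenceRecord


@pytest.fixture(scope="session")
def checklist():
    return cc.load_checklist()


@pytest.fixture(scope="session")
def label_set():
    return tuple(it.code for it in cc.sentence_level_items())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_article(article_id, sentence_specs, title="A study"):
    """Build an Article from (section_path, text, labels) body specs."""
    art = Article(article_id=article_id, title=title)
    art.title_sentences.append(
        SentenceRecord(article_id, 0, [], title, part="title")
    )
    for i, (path, text, labels) in enumerate(sentence_specs, start=1):
        art.body_sentences.append(
            SentenceRecord(article_id, i, list(path), text, labels=set(labels))
        )
    return art


@pytest.fixture()
def tiny_corpus():
    """Two small hand-built articles with known labels."""
    a = make_article(
        "a1",
        [
            (["Methods", "Patients"], "Adults were eligible for inclusion", {"4a"}),
            (["Methods", "Patients"], "Recruitment happened at two sites", {"4b"}),
            (["Methods", "Statistical analysis"], "We used mixed models", {"12a"}),
            (["Results"], "Outcomes improved in the treatment arm", {"17a"}),
            (["Discussion"], "The trial had several limitations", {"20"}),
        ],
        title="A randomized trial of X",
    )
    b = make_article(
        "b2",
        [
            (["Introduction"], "We aimed to test the hypothesis", {"2b"}),
            (["Methods"], "The sample size was computed in advance", {"7a"}),
            (["Results"], "Participant flow is shown in the figure", {"13a"}),
            (["Results"], "No harms were observed", {"19"}),
        ],
        title="An observational study of Y",
    )
    return [a, b]


# ---------------------------------------------------------------------------
# Independent brute-force oracles (naive enumeration; no reuse of package
# metric code)
# ---------------------------------------------------------------------------

def oracle_sentence_metrics(gold_units, pred_units, labels):
    """gold_units/pred_units: dict (aid, idx) -> set of labels."""
    tp = fp = fn = 0
    per_label = {}
    for lab in labels:
        ltp = lfp = lfn = 0
        for key in gold_units:
            g = lab in gold_units[key]
            p = lab in pred_units[key]
            if g and p:
                ltp += 1
            elif p:
                lfp += 1
            elif g:
                lfn += 1
        per_label[lab] = (ltp, lfp, lfn)
        tp += ltp
        fp += lfp
        fn += lfn
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    f1s = []
    for lab in labels:
        ltp, lfp, lfn = per_label[lab]
        if ltp + lfp + lfn == 0:
            continue
        lp = ltp / (ltp + lfp) if ltp + lfp else 0.0
        lr = ltp / (ltp + lfn) if ltp + lfn else 0.0
        f1s.append(2 * lp * lr / (lp + lr) if lp + lr else 0.0)
    macro = sum(f1s) / len(f1s) if f1s else 0.0
    return prec, rec, f1, macro


def oracle_article_scheme(gold_units, pred_units, labels, require_overlap):
    articles = sorted({aid for aid, _ in gold_units})
    tp = fp = fn = 0
    for aid in articles:
        keys = [k for k in gold_units if k[0] == aid]
        for lab in labels:
            g_idx = {k[1] for k in keys if lab in gold_units[k]}
            p_idx = {k[1] for k in keys if lab in pred_units[k]}
            if g_idx and p_idx:
                if not require_overlap or (g_idx & p_idx):
                    tp += 1
                else:
                    fp += 1
                    fn += 1
            elif p_idx:
                fp += 1
            elif g_idx:
                fn += 1
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def random_case(rng, labels=("a", "b", "c", "d")):
    """A random small gold/prediction pair over <=5 articles, <=6 sentences."""
    n_articles = int(rng.integers(1, 6))
    gold, pred = {}, {}
    for a in range(n_articles):
        n_s = int(rng.integers(1, 7))
        for i in range(n_s):
            key = (f"art{a}", i)
            gold[key] = {l for l in labels if rng.random() < 0.3}
            pred[key] = {l for l in labels if rng.random() < 0.3}
    return gold, pred


def units_to_predictions(pred_units, labels):
    """Convert unit dict to SentencePrediction objects (probability 1/0)."""
    out = []
    for (aid, idx), labs in pred_units.items():
        probs = np.array([1.0 if l in labs else 0.0 for l in labels])
        out.append(
            cc.SentencePrediction(
                article_id=aid,
                sentence_index=idx,
                label_set=tuple(labels),
                probabilities=probs,
                predicted_labels=set(labs),
            )
        )
    return out


def units_to_records(gold_units):
    out = []
    for (aid, idx), labs in sorted(gold_units.items()):
        out.append(
            SentenceRecord(
                article_id=aid,
                sentence_index=idx,
                section_path=["Methods"],
                text=f"sentence {idx}",
                labels=set(labs),
            )
        )
    return out
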