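# Methods

## Task and model

The package treats CONSORT screening as multi-label sentence classification.
The CONSORT 2010 checklist is decomposed into 37 fine-grained items; two
(1a, randomized in the title; 1b, structured abstract) are properties of the
whole article and are handled by rules, one (2a, Background) is excluded
because essentially every article reports background material, and the
remaining 34 are sentence-level labels. A sentence may report several items
at once, and many items are reported over short runs of contiguous
sentences, so the classifier consumes a *context window*: the preceding,
target and trailing sentence of the same article (never crossing article
boundaries), each prepended with its nested section headers outermost-first
(`Methods Patients <sentence>`). Section headers are strong evidence — a
sentence under *Statistical analysis* is far more likely to report items
12a/12b — and the header modes `none | innermost | outermost | all` expose
exactly how much of that evidence the model sees.

The classification head receives the encoder's pooled representation,
standardized per coordinate against training-set statistics, optionally
concatenated with a learned position embedding, with dropout applied, and
produces an independent sigmoid output per item. The loss is mean binary
cross-entropy over the label dimension. Optimization is AdamW (decoupled
weight decay 0.01) with two parameter groups — 1e-5 for trainable encoder
parameters, 1e-3 for the head and position embedding — batch size 4, a
fixed 20 epochs, no scheduler, no early stopping, no validation
checkpointing. Predictions are thresholded at 0.5 (configurable); the
threshold is a plain sigmoid cut, not calibrated.

### Position features

Checklist items tend to appear in a predictable order (trial design near
the start of Methods, funding at the end), so the sentence's position is
available as a feature: `absolute` embeds the raw sentence index (clipped
at 512 — longer articles are rare), `relative` embeds the index divided by
*n* − 1 discretized into ten equal bins. The denominator *n* − 1 (rather
than *n*) guarantees the last sentence maps to relative position 1.0 and
the top bin is always populated; bins are half-open with the last bin
closed. Instances without a meaningful position (augmented sentences) embed
at index 0.

### The reference encoder

The encoder is a contract: an assembled input (1 or 3 header-prefixed
segments plus an optional position feature) in, a pooled fixed-width vector
out. The shipped reference encoder is a deterministic hashed bag of tokens:
every distinct (segment-role, token) pair lights up two coordinates of a
4096-wide presence vector, chosen by independent salted BLAKE2b hashes.
Three design points matter:

* **Role-aware hashing.** A token in the target sentence and the same token
  in a neighbor map to different coordinates, so the head can learn that
  evidence *about the target* differs from evidence *nearby* — this is what
  makes the context-window benefit measurable rather than assumed.
* **Two hashes, presence values, no signs.** With a single hash, one
  unlucky collision buries a feature under an unrelated frequent token; with
  signed counts, a same-slot collision of opposite sign can cancel a feature
  to exactly zero. Two salted copies (count-sketch style) of an unsigned
  presence value make any single collision recoverable by a linear head.
* **Standardization in the head.** Raw presence features are dominated by
  frequent coordinates; standardizing each coordinate to zero mean and unit
  variance on the training set amplifies rare but informative coordinates
  by ≈ 1/√(p(1−p)) and lets the bias absorb label prevalence. Without it,
  the fixed 20-epoch/1e-3 schedule cannot drive the scarce items' logits
  past threshold; with it, rare items train as readily as common ones. The
  statistics are part of the saved model. Positive-class-weighted losses
  were evaluated for the same purpose and rejected: they collapse precision
  by pulling the per-label operating point toward the noise floor.

The reference encoder has no trainable parameters, so the full pipeline is
exactly reproducible from a seed and runs in seconds on one CPU. Selecting
any other `encoder_id` resolves a pretrained transformer through an optional
backend and fails with a clear configuration error when that backend is not
installed; fine-tuning such an encoder is a GPU workflow and is not part of
the test surface.

### Section-specific models

`train_section_specific` restricts training sentences to one top-level
section (Methods, Results or Discussion, recognized from the outermost
header) and the label set to that section's items. No Introduction-specific
model exists: the section has a single relevant label (2b), so a dedicated
model is pointless.

## Article-level rules

Item 1a: case-insensitive *substring* search of the title for the stems
`random`, `randomis`, `randomiz`. Substring rather than word-boundary
matching is deliberate — the stems are stems, so *randomisation*,
*nonrandomized* and *randomised* all match; `random` being a prefix of the
other two makes them redundant, which is tolerated and documented. Item 1b:
the abstract's leading token sequence (up to the first colon or period),
uppercased and stripped of trailing punctuation, must equal a header from
the packaged National Library of Medicine structured-abstract label list;
only the first header position is checked because the rule tests whether
the abstract *starts* structured. The list is a curated snapshot of
canonical NLM labels, vendored as plain text and overridable.

## Augmentation

Eight items occur fewer than ~100 times in a realistic corpus; only
*single-label* sentences of these items are augmentation candidates (a
multi-label sentence would propagate its other labels into the synthetic
instance). EDA generates six variations per original, each applying one
randomly chosen operation — synonym replacement, random insertion, random
swap, random deletion — at rate α = 0.1 (the operation family's
conventional default; the deletion operation always leaves at least one
word). Stop-words are excluded from synonym replacement. Synonyms come from
a provider contract with two backends: a packaged general-English table and
a table-driven adapter usable with clinical-terminology exports (full UMLS
licensing cannot be assumed) or test fixtures; a word is never its own
synonym and lookups are deterministic.

LLM-based augmentation is exposed as deterministic prompt builders — a
rephrasing prompt (N = 6, matching the EDA count) around an existing
positively labeled sentence, and a generative prompt (N = 6 or 8, iterated
until 100 instances accumulate) around an *edited* item description: "with
reasons" becomes "with specifics", hedges ("when applicable", "if
relevant") and illustrative "such as …" spans are removed, the deletion
span running to the next comma or closing parenthesis. Responses are parsed
into (preceding, target, trailing) triples; rephrased instances inherit the
source sentence's label, generative instances the label of the description
in the prompt. Live API calls sit behind a minimal completion-provider
interface (temperature 1 for augmentation, 0 for inference); tests use
canned providers only. EDA instances reuse their source's real neighbors
and section header; generative instances get a canonical header for the
item's section group.

## Evaluation

The unit of sentence-level evaluation is the (sentence, label) binary
decision. Micro metrics pool confusion counts over all units; macro-F1
averages per-label F1, excluding labels absent from both gold and
predictions in a fold (their F1 is undefined, and rare items do vanish from
small folds — the exclusion is logged). AUC is computed from predicted
probabilities, micro-averaged over pooled scores. Article-level evaluation
summarizes practical screening utility per (article, item) unit: **ANY**
credits a true positive when gold and prediction agree the article reports
the item anywhere; **1+** additionally requires the predicted and gold
supporting-sentence sets to intersect, and counts a both-present unit with
empty intersection as one false positive *and* one false negative (this
convention is isolated in one function; under it, 1+ true positives can
never exceed ANY true positives). Article-level schemes consume thresholded
sentence predictions; probabilities are not re-aggregated.

Cross-validation is grouped by article — shuffle articles by seed, deal
round-robin into k = 5 folds — so no article contributes sentences to both
training and test. Augmentation instances enter training folds only, and
the leakage invariant is asserted at run time. Fold aggregation is the
unweighted mean ± sd over folds, not pooled counts.

Model comparisons use McNemar's matched-pairs test on the pooled
(sentence, label) decisions of two systems evaluated on identical units:
with n01/n10 the discordant counts, the continuity-corrected statistic
(|n01−n10|−1)²/(n01+n10) is referred to χ²(1) when n01+n10 ≥ 20; below
that the exact two-sided binomial tail is used; p = 1 with no discordant
pairs.

## Synthetic corpora

The generator emulates the statistical *shape* of a sentence-annotated RCT
corpus, not clinical prose: articles with title, abstract (structured or
not, randomized wording or not) and an IMRaD body with nested Methods and
Results subsections; per-sentence Bernoulli labeling restricted to each
item's own section group, with default frequencies an order of magnitude
lower for the eight rare items (≈ 0.01 vs 0.04–0.12 per eligible sentence)
so rare-item corpus counts stay well under 100; a multi-label retention
rate (default 0.15) governing how often co-drawn labels survive on one
sentence. Every item owns a reserved cue token (`cue3a`, …) inserted into
the labeled sentence with probability `cue_strength`; a placement knob
optionally puts the cue into a neighbor sentence instead, making the value
of context windows a testable property. Infeasible frequency maps (group
mass > 1) are rejected.

What passing tests on this corpus do and do not show: cue tokens are
perfectly clean lexical evidence, so separability results are a check of
the pipeline's mechanics (representation, optimization, evaluation), not a
forecast of performance on real clinical text, where evidence is
distributed, ambiguous and correlated with section position in ways no cue
token captures. The noise-floor condition (`cue_strength = 0`) bounds the
opposite extreme: with no signal, held-out micro-F1 must not beat a
label-frequency baseline.

## Problem sizes and numerical choices

Default study corpora are 30 articles; the test and acceptance runs use
30–50 sentences per article, which keeps five training runs of the
reference pipeline to roughly a minute while leaving ≈ 270 sentences per
held-out fold, and the generator's frequency calibration is checked on a
larger (~5,000-sentence) draw. The memorization check trains 100 epochs on
a ~50-sentence corpus: it is a capacity oracle, and 20 epochs of batch-4
updates provide too few optimizer steps at that corpus size to saturate
any model. Ties and degenerate inputs: empty neighbor segments are kept as
empty strings so the 3-segment layout is stable at article boundaries;
token-budget overflow trims the preceding segment first, then trailing,
then the target from the right, because the target carries the label;
probability serialization uses 12 significant digits (round-trip error
< 1e-9); fold assignment, training shuffling, dropout and the generator
all draw from explicit seeds.

## Known limitations

The reference encoder is lexical and order-free within a segment; it cannot
represent negation, syntax or long-range discourse. Real-corpus performance
therefore requires the pretrained-transformer path. The NLM header list is
a curated snapshot; abstracts structured with unconventional labels will be
missed. The 1a rule accepts any `random*` stem, including phrases like
"random-effects meta-analysis" in a title. Augmentation quality is not
filtered or deduplicated. Calibration of predicted probabilities is out of
scope, as are CONSORT extensions (cluster, non-inferiority), the flow
diagram, and any judgment of *adequacy* of what is reported.
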