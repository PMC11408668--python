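import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import consortcheck as cc
from consortcheck.augmentation import (
    DEFAULT_N_AUG,
    EDA_OPS,
    TableSynonymProvider,
    accumulate_generative,
    eda_augment,
    eda_transform,
    edit_item_description,
    general_synonym_provider,
    label_counts,
    parse_augmentation_response,
    select_candidates,
)
from consortcheck.corpus_io import SentenceRecord
from consortcheck.schema import item_by_code
from conftest import make_article


@pytest.fixture()
def fixture_synonyms():
    return TableSynonymProvider({"big": ["large"], "trial": ["study", "experiment"]})


class TestCandidateSelection:
    def test_single_label_rare_sentences_selected(self):
        art = make_article(
            "a",
            [
                (["Methods"], "outcome change happened", {"6b"}),       # rare, single
                (["Methods"], "primary outcomes were defined", {"6a"}),  # common
                (["Methods"], "mixed", {"6b", "11a"}),                   # multi-label
                (["Discussion"], "generalizability remarks", {"21"}),    # rare, single
            ],
        )
        selected = select_candidates([art])
        texts = {r.text for r in selected}
        assert texts == {"outcome change happened", "generalizability remarks"}

    def test_label_counts(self, tiny_corpus):
        counts = label_counts(tiny_corpus)
        assert counts["4a"] == 1
        assert sum(counts.values()) == 9


class TestEdaTransforms:
    @pytest.mark.parametrize("op", EDA_OPS)
    def test_rate_zero_is_identity(self, op, rng, fixture_synonyms):
        s = "the big trial enrolled many adults"
        assert eda_transform(s, op, 0.0, rng, fixture_synonyms) == s

    @given(words=st.lists(st.sampled_from("alpha beta gamma delta".split()),
                          min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=100)
    def test_rate_zero_identity_property(self, words):
        s = " ".join(words)
        rng = np.random.default_rng(0)
        syn = TableSynonymProvider({"alpha": ["omega"]})
        for op in EDA_OPS:
            assert eda_transform(s, op, 0.0, rng, syn) == s

    def test_deletion_never_empties_sentence(self, fixture_synonyms):
        rng = np.random.default_rng(4)
        for _ in range(50):
            out = eda_transform("a b c", "random_deletion", 1.0, rng, fixture_synonyms)
            assert len(out.split()) >= 1

    def test_synonym_replacement_uses_lexicon(self, fixture_synonyms):
        rng = np.random.default_rng(0)
        out = eda_transform("big trial", "synonym_replacement", 1.0, rng, fixture_synonyms)
        words = out.split()
        assert words[0] in {"large"}
        assert words[1] in {"study", "experiment"}

    def test_swap_preserves_multiset(self, fixture_synonyms):
        rng = np.random.default_rng(1)
        s = "one two three four five"
        out = eda_transform(s, "random_swap", 0.5, rng, fixture_synonyms)
        assert sorted(out.split()) == sorted(s.split())

    def test_insertion_adds_words(self, fixture_synonyms):
        rng = np.random.default_rng(2)
        out = eda_transform("big trial", "random_insertion", 1.0, rng, fixture_synonyms)
        assert len(out.split()) > 2

    def test_empty_sentence_unchanged(self, rng, fixture_synonyms):
        assert eda_transform("", "random_swap", 0.5, rng, fixture_synonyms) == ""

    def test_word_never_its_own_synonym(self):
        provider = TableSynonymProvider({"trial": ["trial", "study"]})
        assert provider.synonyms("trial") == ["study"]
        packaged = general_synonym_provider()
        for word in ("study", "outcome", "random"):
            assert word not in [s.lower() for s in packaged.synonyms(word)]


class TestEdaAugment:
    def rec(self):
        return SentenceRecord("a1", 3, ["Methods"], "the big trial changed outcomes",
                              labels={"6b"})

    def test_exactly_six_instances_by_default(self, fixture_synonyms):
        rng = np.random.default_rng(0)
        out = eda_augment(self.rec(), rng, fixture_synonyms)
        assert len(out) == DEFAULT_N_AUG == 6

    def test_label_and_context_preserved(self, fixture_synonyms):
        rng = np.random.default_rng(0)
        out = eda_augment(self.rec(), rng, fixture_synonyms,
                          preceding="before", trailing="after")
        for inst in out:
            assert inst.labels == frozenset({"6b"})
            assert (inst.preceding, inst.trailing) == ("before", "after")
            assert inst.section_path == ("Methods",)
            assert inst.method == "eda"

    def test_deterministic_under_seed(self, fixture_synonyms):
        out1 = eda_augment(self.rec(), np.random.default_rng(9), fixture_synonyms)
        out2 = eda_augment(self.rec(), np.random.default_rng(9), fixture_synonyms)
        assert out1 == out2

    def test_multi_label_record_rejected(self, fixture_synonyms):
        rec = SentenceRecord("a", 0, [], "text here", labels={"6b", "7b"})
        with pytest.raises(ValueError):
            eda_augment(rec, np.random.default_rng(0), fixture_synonyms)


class TestPromptTemplates:
    def test_rephrase_prompt_exact(self):
        prompt = cc.build_rephrase_prompt("The dose was reduced", 6)
        assert prompt == (
            "You are a scientific researcher writing a research paper for "
            "randomized clinical trials. Please rephrase the following "
            "sentence 6 times: The dose was reduced. For the 6 rephrased "
            "sentences, also provide an example preceding sentence and an "
            "example trailing sentence. Vary the sentence structure and "
            "sentence complexity for each sentence. Also, vary the use of "
            "introductory prepositional phrases in all sentences"
        )

    def test_generative_prompt_exact(self, checklist):
        item = item_by_code("3b", checklist)
        prompt = cc.build_generative_prompt(item, 8)
        assert prompt == (
            "You are a scientific researcher writing a research paper for "
            "randomized clinical trials. From your research paper, please "
            "provide 8 different 1 sentence examples of the following: "
            "Important changes to methods after trial commencement, with "
            "specifics. For each example, also provide an example preceding "
            "sentence and an example trailing sentence. Vary the sentence "
            "structure and sentence complexity for each example. Also, vary "
            "the use of introductory prepositional phrases in all examples"
        )

    def test_prompts_deterministic(self, checklist):
        item = item_by_code("9", checklist)
        assert cc.build_rephrase_prompt("s", 6) == cc.build_rephrase_prompt("s", 6)
        assert cc.build_generative_prompt(item, 6) == cc.build_generative_prompt(item, 6)

    def test_empty_sentence_rejected(self):
        with pytest.raises(ValueError):
            cc.build_rephrase_prompt("   ", 6)


class TestDescriptionEditing:
    def test_example_spans_and_reasons(self):
        out = edit_item_description(
            "Important changes to methods after trial commencement "
            "(such as eligibility criteria), with reasons"
        )
        assert out == "Important changes to methods after trial commencement, with specifics"

    def test_hedges_removed(self):
        out = edit_item_description("Important changes, when applicable, with reasons")
        assert out == "Important changes, with specifics"
        out = edit_item_description(
            "When applicable, explanation of any interim analyses and stopping guidelines"
        )
        assert out == "explanation of any interim analyses and stopping guidelines"

    def test_untouched_description_unchanged(self):
        s = "Eligibility criteria for participants"
        assert edit_item_description(s) == s


RESPONSE = """Here are the examples:
1.
Preceding: The trial began enrollment in March.
Sentence: Midway through the study, the eligibility threshold was lowered.
Trailing: Recruitment accelerated after the change.
2.
Preceding: The protocol was registered in advance.
Sentence: The steering committee amended the follow-up schedule.
Trailing: All sites adopted the revision.
3.
Preceding: Only the preceding line is present here.
"""


class TestResponseParsing:
    def test_well_formed_triples_parsed(self):
        out = parse_augmentation_response(RESPONSE, "3b", "llm_generative",
                                          section_group="Methods")
        assert len(out) == 2
        assert out[0].target.startswith("Midway through")
        assert out[0].preceding.startswith("The trial began")
        assert out[0].trailing.startswith("Recruitment")
        assert out[0].section_path == ("Methods",)

    def test_label_assignment_rule(self):
        out = parse_augmentation_response(RESPONSE, "9", "llm_generative")
        assert all(inst.labels == frozenset({"9"}) for inst in out)

    def test_empty_text_gives_empty_list(self):
        assert parse_augmentation_response("", "9", "llm_rephrase") == []


class _CountingProvider:
    def __init__(self, per_call):
        self.per_call = per_call
        self.calls = 0

    def complete(self, prompt, temperature=1.0):
        self.calls += 1
        blocks = []
        for i in range(self.per_call):
            blocks.append(
                f"Preceding: before {self.calls}-{i}.\n"
                f"Sentence: generated example {self.calls}-{i}.\n"
                f"Trailing: after {self.calls}-{i}.\n"
            )
        return "\n".join(blocks)


class TestAccumulation:
    def test_reaches_target_in_expected_calls(self, checklist):
        provider = _CountingProvider(8)
        item = item_by_code("6b", checklist)
        out = accumulate_generative(provider, item, batch_n=8, target_total=100)
        assert len(out) >= 100
        assert provider.calls == 13

    def test_degenerate_provider_stops_at_cap(self, checklist):
        provider = _CountingProvider(0)
        item = item_by_code("6b", checklist)
        out = accumulate_generative(provider, item, batch_n=8, target_total=100,
                                    max_iterations=5)
        assert out == []
        assert provider.calls == 5
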