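"""Semantic schema, report rendering, text augmentation, prompt banks,
harmonization thresholds and the toy tokenizer."""

import itertools

import numpy as np
import pytest

from noduleclip.semantics import (MISSING, NEGATIVE_PROMPT, SemanticRecord,
                                  TextAugPolicy, WhitespaceHashTokenizer,
                                  augment_text, build_prompts, default_schema,
                                  harmonize_lidc, read_semantics_csv,
                                  render_report, schema_from_dict,
                                  schema_to_dict, select_training_text,
                                  write_semantics_csv)

SCHEMA = default_schema()


def make_record(values, pid="P1", nid="N1"):
    return SemanticRecord(pid, nid, values)


# ------------------------------------------------------------ harmonization
def test_lidc_spiculation_thresholds_enumerated():
    for median in range(1, 6):
        rec = harmonize_lidc({"spiculation": median})
        margin = rec.get("margin")
        if median >= 4:
            assert "spiculated" in margin
        else:
            assert margin is MISSING or "spiculated" not in margin


def test_lidc_texture_endpoints_and_midpoint():
    assert harmonize_lidc({"texture": 1}).get("consistency") == "pure ground glass"
    assert harmonize_lidc({"texture": 3}).get("consistency") == "part-solid"
    assert harmonize_lidc({"texture": 5}).get("consistency") == "solid"


def test_lidc_sphericity_maps_to_shape():
    assert harmonize_lidc({"sphericity": 5}).get("shape") == "round"
    assert harmonize_lidc({"sphericity": 3}).get("shape") == "ovoid"
    assert harmonize_lidc({"sphericity": 1}).get("shape") == "irregular"


def test_lidc_margin_ordinal_rules():
    assert harmonize_lidc({"margin": 1}).get("margin") == ("ill-defined",)
    assert harmonize_lidc({"margin": 5}).get("margin") == ("smooth",)
    rec = harmonize_lidc({"margin": 5, "spiculation": 5})
    assert rec.get("margin") == ("spiculated",)


def test_lidc_all_absent_gives_all_missing():
    rec = harmonize_lidc({})
    assert all(rec.is_missing(f.name) for f in SCHEMA)


def test_lidc_out_of_range_rejected():
    with pytest.raises(ValueError):
        harmonize_lidc({"texture": 6})
    with pytest.raises(ValueError):
        harmonize_lidc({"nonsense": 3})


# ----------------------------------------------------------------- reports
def test_report_two_feature_example():
    rec = make_record({"margin": ("spiculated",), "consistency": "solid"})
    rep = render_report(rec, SCHEMA)
    assert len(rep.findings) == 2
    assert "spiculated solid nodule" in " ".join(rep.impression)


def test_report_all_missing_degenerates_to_no_findings():
    rep = render_report(make_record({}), SCHEMA)
    assert rep.findings == [NEGATIVE_PROMPT]
    assert rep.impression == [NEGATIVE_PROMPT]


def test_binary_absence_only_in_findings():
    rec = make_record({"pleural_attachment": False})
    rep = render_report(rec, SCHEMA)
    assert any("No pleural attachment" in s for s in rep.findings)
    assert not any("pleural attachment" in s for s in rep.impression)


def test_binary_presence_reaches_impression():
    rec = make_record({"pleural_attachment": True})
    rep = render_report(rec, SCHEMA)
    assert any("pleural attachment" in s for s in rep.impression)


def test_report_is_pure_function():
    rec = make_record({"margin": ("smooth", "lobulated"), "consistency": "solid",
                       "necrosis": False})
    a, b = render_report(rec, SCHEMA), render_report(rec, SCHEMA)
    assert a.findings == b.findings and a.impression == b.impression


def test_findings_count_equals_non_missing_features():
    rng = np.random.default_rng(0)
    for _ in range(25):
        values = {}
        for f in SCHEMA:
            if rng.random() < 0.5:
                continue
            if f.kind == "binary":
                values[f.name] = bool(rng.random() < 0.5)
            elif f.kind == "multilabel":
                values[f.name] = ("smooth",)
            else:
                values[f.name] = f.classes[int(rng.integers(len(f.classes)))]
        rep = render_report(make_record(values), SCHEMA)
        if values:
            assert len(rep.findings) == len(values)
        assert len(rep.impression) >= 1


def test_text_provider_hook_overrides_templater():
    from noduleclip.semantics import ReportText

    rep = render_report(make_record({}), SCHEMA,
                        text_provider=lambda rec, s: ReportText(["x."], ["y."]))
    assert rep.findings == ["x."]


# ------------------------------------------------------------ augmentation
def test_zero_probability_augmentation_is_identity():
    sents = ["This nodule margin is smooth.", "No findings."]
    policy = TextAugPolicy(synonym_prob=0.0, sentence_crop_prob=0.0)
    assert augment_text(sents, policy, np.random.default_rng(0)) == sents


def test_augmentation_deterministic_under_seed():
    sents = ["The nodule is seen and shows a smooth margin."]
    policy = TextAugPolicy(synonym_prob=1.0, sentence_crop_prob=0.5)
    a = augment_text(sents, policy, np.random.default_rng(3))
    b = augment_text(sents, policy, np.random.default_rng(3))
    assert a == b


def test_sentence_crop_yields_contiguous_subsequence():
    sents = ["A.", "B.", "C.", "D."]
    valid = {tuple(sents[i:j + 1]) for i in range(4) for j in range(i, 4)}
    policy = TextAugPolicy(synonym_prob=0.0, sentence_crop_prob=1.0)
    rng = np.random.default_rng(4)
    for _ in range(50):
        out = augment_text(sents, policy, rng)
        assert 1 <= len(out) <= 4
        assert tuple(out) in valid


def test_class_vocabulary_never_substituted():
    protected = SCHEMA.class_vocabulary()
    policy = TextAugPolicy(synonym_prob=1.0, sentence_crop_prob=0.0)
    sents = ["This nodule consistency is solid."]
    out = augment_text(sents, policy, np.random.default_rng(5), protected)
    assert "solid." in out[0]
    assert "consistency" in out[0]


def test_select_training_text_balanced_coin():
    from noduleclip.semantics import ReportText

    rep = ReportText(["f."], ["i."])
    rng = np.random.default_rng(6)
    hits = sum(select_training_text(rep, rng) == ["f."] for _ in range(10_000))
    assert abs(hits / 10_000 - 0.5) < 0.02


def test_select_training_text_invariant_for_identical_sections():
    from noduleclip.semantics import ReportText

    rep = ReportText(["same."], ["same."])
    rng = np.random.default_rng(7)
    assert all(select_training_text(rep, rng) == ["same."] for _ in range(10))


# ----------------------------------------------------------------- prompts
def test_margin_prompt_bank():
    bank = build_prompts(SCHEMA)
    prompts = dict(bank.categorical["margin"])
    assert len(prompts) == 4
    assert prompts["spiculated"] == "This nodule margin is spiculated."


def test_binary_prompt_pair():
    bank = build_prompts(SCHEMA)
    pos, neg = bank.binary["pleural_attachment"]
    assert pos == "There is pleural attachment."
    assert neg == NEGATIVE_PROMPT


def test_prompt_counts_match_schema():
    bank = build_prompts(SCHEMA)
    for f in SCHEMA:
        if f.kind == "binary":
            assert len(bank.binary[f.name]) == 2
        else:
            assert len(bank.categorical[f.name]) == len(f.classes)


def test_schema_without_binaries_has_no_negatives():
    from noduleclip.semantics import Feature, SemanticSchema

    schema = SemanticSchema([Feature("shape", "categorical", ("round", "ovoid"))])
    bank = build_prompts(schema)
    assert bank.binary == {}


def test_every_class_appears_in_exactly_one_prompt():
    bank = build_prompts(SCHEMA)
    seen = list(itertools.chain.from_iterable(
        [cls for cls, _ in prompts] for prompts in bank.categorical.values()))
    assert len(seen) == len(set(seen))
    all_classes = [c for f in SCHEMA for c in f.classes]
    assert sorted(seen) == sorted(all_classes)


# --------------------------------------------------------------- tokenizer
def test_tokenizer_deterministic_and_framed():
    tok = WhitespaceHashTokenizer(vocab_size=512, context_length=16)
    ids, eot = tok.encode("This nodule margin is smooth.")
    ids2, eot2 = tok.encode("This nodule margin is smooth.")
    assert np.array_equal(ids, ids2) and eot == eot2
    assert ids[0] == tok.SOT and ids[eot] == tok.EOT
    assert len(ids) == 16


def test_tokenizer_truncates_long_text():
    tok = WhitespaceHashTokenizer(vocab_size=512, context_length=8)
    ids, eot = tok.encode("word " * 50)
    assert len(ids) == 8 and eot == 7 and ids[eot] == tok.EOT


def test_tokenizer_case_and_punctuation_normalized():
    tok = WhitespaceHashTokenizer()
    a, _ = tok.encode("Solid.")
    b, _ = tok.encode("solid")
    assert np.array_equal(a, b)


# ---------------------------------------------------------------- CSV / IO
def test_semantics_csv_roundtrip(tmp_path):
    records = [
        make_record({"margin": ("smooth", "lobulated"), "consistency": "solid",
                     "necrosis": False, "pleural_attachment": True}, "P1", "N1"),
        make_record({}, "P2", "N1"),
    ]
    path = tmp_path / "sem.csv"
    write_semantics_csv(records, path, SCHEMA)
    back = read_semantics_csv(path, SCHEMA)
    assert back[0].get("margin") == ("smooth", "lobulated")
    assert back[0].get("necrosis") is False
    assert back[0].get("pleural_attachment") is True
    assert all(back[1].is_missing(f.name) for f in SCHEMA)


def test_schema_json_roundtrip():
    d = schema_to_dict(SCHEMA)
    back = schema_from_dict(d)
    assert back.names == SCHEMA.names
    assert back["margin"].classes == SCHEMA["margin"].classes


def test_record_validation_rejects_unknown_class():
    rec = make_record({"consistency": "granite"})
    with pytest.raises(ValueError):
        rec.validate(SCHEMA)
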