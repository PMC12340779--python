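"""Harmonized semantic-feature schema, report-like text rendering, text
augmentation, zero-shot prompt banks, and tokenization.

Radiologist-assigned nodule descriptors (margin, consistency, shape, internal
and external findings) are the text-side supervision of the dual encoder.
Records are rendered into a two-section report (findings + impression) by a
deterministic templater; an alternative generator (e.g. an LLM) can be plugged
in through the ``text_provider`` hook of :func:`render_report`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING", "Feature", "SemanticSchema", "SemanticRecord", "ReportText",
    "TextAugPolicy", "PromptBank", "default_schema", "render_report",
    "augment_text", "select_training_text", "build_prompts", "harmonize_lidc",
    "WhitespaceHashTokenizer", "read_semantics_csv", "write_semantics_csv",
    "DEFAULT_LEXICON", "NEGATIVE_PROMPT",
]

MISSING = None
NEGATIVE_PROMPT = "No findings."


@dataclass(frozen=True)
class Feature:
    name: str                       # snake_case key (CSV column)
    kind: str                       # "categorical" | "binary" | "multilabel"
    classes: tuple = ()             # vocabulary for (multi-)categorical features
    group: str = "general"          # "general" | "internal" | "external"

    @property
    def display(self) -> str:
        return self.name.replace("_", " ")


@dataclass
class SemanticSchema:
    features: list[Feature]

    def __post_init__(self):
        for f in self.features:
            if f.kind in ("categorical", "multilabel") and len(set(f.classes)) != len(f.classes):
                raise ValueError(f"duplicate class names in feature {f.name}")

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def class_vocabulary(self) -> set[str]:
        words: set[str] = set()
        for f in self.features:
            for c in f.classes:
                words.update(c.split())
            words.update(f.display.split())
        return {w.lower() for w in words}


def default_schema() -> SemanticSchema:
    """The harmonized feature set: general nodule descriptors plus binary
    internal and external findings."""
    return SemanticSchema([
        Feature("margin", "multilabel",
                ("smooth", "lobulated", "spiculated", "ill-defined"), "general"),
        Feature("consistency", "categorical",
                ("solid", "pure ground glass", "part-solid", "semiconsolidation",
                 "peri-cystic"), "general"),
        Feature("shape", "categorical",
                ("irregular", "ovoid", "polygonal", "round"), "general"),
        Feature("margin_conspicuity", "categorical",
                ("well marginated", "poorly marginated"), "general"),
        Feature("reticulation", "binary", (), "internal"),
        Feature("cyst-like_spaces", "binary", (), "internal"),
        Feature("necrosis", "binary", (), "internal"),
        Feature("eccentric_calcification", "binary", (), "internal"),
        Feature("cavitation", "binary", (), "internal"),
        Feature("intra-nodular_bronchiectasis", "binary", (), "internal"),
        Feature("airway_cutoff", "binary", (), "internal"),
        Feature("vascular_convergence", "binary", (), "external"),
        Feature("pleural_retraction", "binary", (), "external"),
        Feature("pleural_attachment", "binary", (), "external"),
        Feature("paracicatricial_emphysema", "binary", (), "external"),
        Feature("septal_stretching", "binary", (), "external"),
    ])


@dataclass
class SemanticRecord:
    """Per-nodule feature values; a value of ``MISSING`` (None) means the
    feature was not assessed — distinct from a binary feature being absent
    (False)."""

    patient_id: str
    nodule_id: str
    values: dict = field(default_factory=dict)

    def get(self, name: str):
        return self.values.get(name, MISSING)

    def is_missing(self, name: str) -> bool:
        return self.get(name) is MISSING

    def validate(self, schema: SemanticSchema) -> None:
        for f in schema:
            v = self.get(f.name)
            if v is MISSING:
                continue
            if f.kind == "binary":
                if not isinstance(v, (bool, np.bool_)):
                    raise ValueError(f"{f.name}: binary feature must be bool, got {v!r}")
            elif f.kind == "categorical":
                if v not in f.classes:
                    raise ValueError(f"{f.name}: unknown class {v!r}")
            else:  # multilabel
                labels = tuple(v)
                if not labels or any(c not in f.classes for c in labels):
                    raise ValueError(f"{f.name}: unknown classes {labels!r}")


@dataclass
class ReportText:
    findings: list[str]
    impression: list[str]

    def all_sentences(self) -> list[str]:
        return list(self.findings) + list(self.impression)


# -------------------------------------------------------------- report text
def _join_words(words: list[str]) -> str:
    if len(words) == 1:
        return words[0]
    return ", ".join(words[:-1]) + " and " + words[-1]


def render_report(rec: SemanticRecord, schema: SemanticSchema | None = None,
                  text_provider=None) -> ReportText:
    """Deterministic report templater.

    Findings list every non-missing feature exactly once (binary absences as a
    negative sentence); the impression summarizes the salient general
    descriptors plus any present internal/external finding, never absences.
    ``text_provider(record, schema) -> ReportText`` overrides the templater.
    """
    schema = schema or default_schema()
    rec.validate(schema)
    if text_provider is not None:
        return text_provider(rec, schema)

    findings: list[str] = []
    descriptor: list[str] = []
    present: list[str] = []
    for f in schema:
        v = rec.get(f.name)
        if v is MISSING:
            continue
        if f.kind == "multilabel":
            labels = [c for c in f.classes if c in tuple(v)]
            findings.append(f"This nodule {f.display} is {_join_words(labels)}.")
            descriptor.extend(labels)
        elif f.kind == "categorical":
            findings.append(f"This nodule {f.display} is {v}.")
            if f.name in ("consistency", "shape"):
                descriptor.append(v)
            elif f.name == "margin_conspicuity" and v == "poorly marginated":
                descriptor.append(v)
        else:
            if v:
                findings.append(f"There is {f.display}.")
                present.append(f.display)
            else:
                findings.append(f"No {f.display}.")

    if not findings:
        return ReportText([NEGATIVE_PROMPT], [NEGATIVE_PROMPT])

    impression: list[str] = []
    if descriptor:
        impression.append(f"A {' '.join(descriptor)} nodule.")
    for p in present:
        impression.append(f"There is {p}.")
    if not impression:
        impression.append("A nodule without salient findings.")
    return ReportText(findings, impression)


# ------------------------------------------------------------- augmentation
DEFAULT_LEXICON: dict[str, list[str]] = {
    # non-clinical filler words only; class vocabulary must never appear here
    "shows": ["demonstrates", "reveals"], "demonstrates": ["shows"],
    "seen": ["noted", "observed"], "noted": ["seen", "observed"],
    "observed": ["seen", "noted"], "is": ["appears"], "appears": ["is"],
    "are": ["appear"], "the": ["this"], "this": ["the"],
    "a": ["one"], "an": ["one"], "there": ["here"],
    "without": ["lacking"], "with": ["showing"], "no": ["without"],
    "present": ["evident", "apparent"], "evident": ["present"],
    "apparent": ["present"], "findings": ["abnormalities"],
    "abnormalities": ["findings"], "salient": ["notable", "prominent"],
    "notable": ["salient"], "prominent": ["salient"],
    "likely": ["probably", "presumably"], "probably": ["likely"],
    "presumably": ["likely"], "suggests": ["indicates", "implies"],
    "indicates": ["suggests"], "implies": ["suggests"],
    "consistent": ["compatible"], "compatible": ["consistent"],
    "adjacent": ["neighboring", "nearby"], "neighboring": ["adjacent"],
    "nearby": ["adjacent"], "small": ["tiny"], "tiny": ["small"],
    "large": ["sizable"], "sizable": ["large"], "unchanged": ["stable"],
    "stable": ["unchanged"], "new": ["recent"], "recent": ["new"],
    "multiple": ["several", "numerous"], "several": ["multiple"],
    "numerous": ["multiple"], "mild": ["slight"], "slight": ["mild"],
    "moderate": ["intermediate"], "intermediate": ["moderate"],
    "marked": ["pronounced"], "pronounced": ["marked"],
}


@dataclass
class TextAugPolicy:
    synonym_prob: float = 0.2
    sentence_crop_prob: float = 0.3
    lexicon: dict = field(default_factory=lambda: dict(DEFAULT_LEXICON))
    seed: int | None = None

    def __post_init__(self):
        if not (0 <= self.synonym_prob <= 1 and 0 <= self.sentence_crop_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


def augment_text(sentences: list[str], policy: TextAugPolicy,
                 rng: np.random.Generator, protected: set[str] | None = None) -> list[str]:
    """Synonym substitution of filler words plus random contiguous sentence
    cropping.  Words in ``protected`` (e.g. the schema class vocabulary) are
    never substituted; the output is never empty."""
    if not sentences:
        raise ValueError("augment_text requires a non-empty sentence list")
    protected = protected or set()
    out: list[str] = []
    for sent in sentences:
        words = sent.split(" ")
        new_words = []
        for w in words:
            core = w.strip(".,;:").lower()
            if (core in policy.lexicon and core not in protected
                    and policy.synonym_prob > 0
                    and rng.random() < policy.synonym_prob):
                repl = str(rng.choice(policy.lexicon[core]))
                if w[:1].isupper():
                    repl = repl.capitalize()
                trailing = w[len(w.rstrip(".,;:")):]
                new_words.append(repl + trailing)
            else:
                new_words.append(w)
        out.append(" ".join(new_words))
    if policy.sentence_crop_prob > 0 and rng.random() < policy.sentence_crop_prob:
        i = int(rng.integers(0, len(out)))
        j = int(rng.integers(i, len(out)))
        out = out[i:j + 1]
    return out


def select_training_text(report: ReportText, rng: np.random.Generator) -> list[str]:
    """Pick the findings or the impression section with probability 1/2 each."""
    return list(report.findings) if rng.random() < 0.5 else list(report.impression)


# ------------------------------------------------------------- prompt banks
@dataclass
class PromptBank:
    """Zero-shot prompts: one sentence per class for (multi-)categorical
    features; a presence sentence plus the shared negative for binaries."""

    categorical: dict  # feature name -> list[(class, sentence)]
    binary: dict       # feature name -> (positive sentence, negative sentence)

    def __post_init__(self):
        seen: set[str] = set()
        for prompts in self.categorical.values():
            for cls, _ in prompts:
                if cls in seen:
                    raise ValueError(f"class {cls!r} appears in more than one prompt")
                seen.add(cls)


def build_prompts(schema: SemanticSchema) -> PromptBank:
    categorical = {}
    binary = {}
    for f in schema:
        if f.kind in ("categorical", "multilabel"):
            categorical[f.name] = [(c, f"This nodule {f.display} is {c}.")
                                   for c in f.classes]
        else:
            binary[f.name] = (f"There is {f.display}.", NEGATIVE_PROMPT)
    return PromptBank(categorical, binary)


# ------------------------------------------------- LIDC ordinal harmonization
_LIDC_FIELDS = {"sphericity", "lobulation", "texture", "consistency",
                "internal_structure", "margin", "spiculation"}

DEFAULT_LIDC_THRESHOLDS = {
    "spiculated_min": 4,     # spiculation median >= 4 -> margin includes spiculated
    "lobulated_min": 4,      # lobulation median >= 4 -> margin includes lobulated
    "ill_defined_max": 2,    # margin median <= 2 -> ill-defined
    "part_solid_texture": 3,  # texture 1-2 ground glass, 3 part-solid, 4-5 solid
    "round_min": 4,          # sphericity >= 4 round, == 3 ovoid, <= 2 irregular
}


def harmonize_lidc(raw: dict, schema: SemanticSchema | None = None,
                   thresholds: dict | None = None,
                   patient_id: str = "", nodule_id: str = "") -> SemanticRecord:
    """Map LIDC 1-5 ordinal medians onto the harmonized schema.

    Features present in the harmonized schema but not annotated in LIDC are
    left MISSING.  The ``internal_structure`` field is accepted but has no
    harmonized counterpart and is ignored.
    """
    schema = schema or default_schema()
    th = dict(DEFAULT_LIDC_THRESHOLDS, **(thresholds or {}))
    unknown = set(raw) - _LIDC_FIELDS
    if unknown:
        raise ValueError(f"unknown LIDC fields: {sorted(unknown)}")
    for k, v in raw.items():
        if v is not None and not (1 <= float(v) <= 5):
            raise ValueError(f"LIDC ordinal {k}={v} outside [1, 5]")

    values: dict = {}
    spic = raw.get("spiculation")
    lob = raw.get("lobulation")
    marg = raw.get("margin")
    labels = []
    if spic is not None and float(spic) >= th["spiculated_min"]:
        labels.append("spiculated")
    if lob is not None and float(lob) >= th["lobulated_min"]:
        labels.append("lobulated")
    if marg is not None and float(marg) <= th["ill_defined_max"]:
        labels.append("ill-defined")
    if not labels and marg is not None:
        labels.append("smooth")
    if labels:
        values["margin"] = tuple(labels)

    texture = raw.get("texture", raw.get("consistency"))
    if texture is not None:
        t = float(texture)
        if t < th["part_solid_texture"]:
            values["consistency"] = "pure ground glass"
        elif t == th["part_solid_texture"]:
            values["consistency"] = "part-solid"
        else:
            values["consistency"] = "solid"

    sph = raw.get("sphericity")
    if sph is not None:
        s = float(sph)
        if s >= th["round_min"]:
            values["shape"] = "round"
        elif s >= 3:
            values["shape"] = "ovoid"
        else:
            values["shape"] = "irregular"

    rec = SemanticRecord(patient_id, nodule_id, values)
    rec.validate(schema)
    return rec


# ---------------------------------------------------------------- tokenizer
class WhitespaceHashTokenizer:
    """Deterministic toy tokenizer: lowercased, punctuation-stripped words are
    hashed (CRC-32) into a fixed vocabulary, framed by start/end tokens and
    padded to the context length.  A BPE tokenizer with the same
    ``encode_batch`` signature can be plugged in when pretrained weights are
    used."""

    PAD, SOT, EOT = 0, 1, 2

    def __init__(self, vocab_size: int = 512, context_length: int = 77):
        if vocab_size < 8:
            raise ValueError("vocab too small")
        self.vocab_size = vocab_size
        self.context_length = context_length

    def _word_id(self, word: str) -> int:
        return 3 + zlib.crc32(word.encode("utf-8")) % (self.vocab_size - 3)

    def encode(self, text: str) -> tuple[np.ndarray, int]:
        words = [w.strip(".,;:!?()").lower() for w in text.split()]
        words = [w for w in words if w]
        ids = [self.SOT] + [self._word_id(w) for w in words]
        ids = ids[: self.context_length - 1] + [self.EOT]  # truncate, keep EOT
        eot = len(ids) - 1
        ids = ids + [self.PAD] * (self.context_length - len(ids))
        return np.asarray(ids, dtype=np.int64), eot

    def encode_batch(self, texts: list[str]) -> tuple[np.ndarray, np.ndarray]:
        pairs = [self.encode(t) for t in texts]
        tokens = np.stack([p[0] for p in pairs])
        eots = np.asarray([p[1] for p in pairs], dtype=np.int64)
        return tokens, eots


# ---------------------------------------------------------- schema JSON IO
def schema_to_dict(schema: SemanticSchema) -> dict:
    return {"features": [{"name": f.name, "kind": f.kind,
                          "classes": list(f.classes), "group": f.group}
                         for f in schema]}


def schema_from_dict(d: dict) -> SemanticSchema:
    return SemanticSchema([Feature(f["name"], f["kind"], tuple(f.get("classes", ())),
                                   f.get("group", "general"))
                           for f in d["features"]])


# ------------------------------------------------------------------- CSV IO
def _format_value(feature: Feature, v) -> str:
    if v is MISSING:
        return ""
    if feature.kind == "binary":
        return "present" if v else "absent"
    if feature.kind == "multilabel":
        return "|".join(v)
    return str(v)


def _parse_value(feature: Feature, cell):
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell) == "":
        return MISSING
    s = str(cell).strip()
    if feature.kind == "binary":
        if s.lower() in ("present", "true", "1", "yes"):
            return True
        if s.lower() in ("absent", "false", "0", "no"):
            return False
        raise ValueError(f"{feature.name}: cannot parse binary cell {cell!r}")
    if feature.kind == "multilabel":
        return tuple(part.strip() for part in s.split("|") if part.strip())
    return s


def write_semantics_csv(records: list[SemanticRecord], path,
                        schema: SemanticSchema | None = None) -> pd.DataFrame:
    schema = schema or default_schema()
    rows = []
    for rec in records:
        row = {"patient_id": rec.patient_id, "nodule_id": rec.nodule_id}
        for f in schema:
            row[f.name] = _format_value(f, rec.get(f.name))
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_semantics_csv(path, schema: SemanticSchema | None = None) -> list[SemanticRecord]:
    schema = schema or default_schema()
    df = pd.read_csv(path, dtype={"patient_id": str, "nodule_id": str})
    records = []
    for _, row in df.iterrows():
        values = {}
        for f in schema:
            if f.name in row:
                v = _parse_value(f, row[f.name])
                if v is not MISSING:
                    values[f.name] = v
        rec = SemanticRecord(str(row["patient_id"]), str(row["nodule_id"]), values)
        rec.validate(schema)
        records.append(rec)
    return records
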