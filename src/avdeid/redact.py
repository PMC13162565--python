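"""Rule-based PHI detection and placeholder replacement on flattened transcripts.

The engine works on whole word rows: a detected span is a (start, end)
range of global word indices, never a sub-word character range, so the
mapping from redacted text back to audio timestamps is the identity on
word indices.

Rules come in three layers with fixed precedence:

1. ``safe_lexicon`` — never redact; overrides everything else.
2. ``patterns`` — an ordered list of regexes, each tagged with a PHI
   category (DATE, ID, CONTACT, AGE, ...). Order is evaluation order.
3. ``name_lexicon`` / ``location_lexicon`` — token or multi-token phrase
   lexicons for NAME and LOCATION.

Matching is case-insensitive after Unicode case-folding; punctuation
attached to a word is stripped for matching and untouched by replacement
of neighbouring words. Overlaps are resolved longest-match-first, ties by
rule priority (patterns before lexicons, earlier pattern first), then by
position.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "PhiCategory",
    "PhiSpan",
    "RedactionRuleSet",
    "RuleConfigError",
    "detect_phi",
    "apply_redaction",
    "load_ruleset",
]


class PhiCategory(str, Enum):
    NAME = "NAME"
    DATE = "DATE"
    LOCATION = "LOCATION"
    ID = "ID"
    CONTACT = "CONTACT"
    AGE = "AGE"


class RuleConfigError(ValueError):
    """A redaction rule set failed to load or compile."""


def normalize_token(token: str) -> str:
    """Case-fold and strip leading/trailing punctuation for matching."""
    stripped = token.strip()
    while stripped and unicodedata.category(stripped[0]).startswith("P"):
        stripped = stripped[1:]
    while stripped and unicodedata.category(stripped[-1]).startswith("P"):
        stripped = stripped[:-1]
    return stripped.casefold()


@dataclass(frozen=True)
class PatternRule:
    regex: re.Pattern
    category: PhiCategory
    rule_id: str


@dataclass(frozen=True)
class PhiSpan:
    """A detected PHI occurrence over an inclusive range of word indices."""

    word_start_index: int
    word_end_index: int
    category: PhiCategory
    matched_text: str
    rule_id: str

    def __post_init__(self):
        if self.word_end_index < self.word_start_index:
            raise ValueError("span end precedes start")

    def indices(self) -> range:
        return range(self.word_start_index, self.word_end_index + 1)


@dataclass
class RedactionRuleSet:
    """Lexicons + ordered patterns + placeholder rendering template."""

    name_lexicon: set[str] = field(default_factory=set)
    location_lexicon: set[str] = field(default_factory=set)
    safe_lexicon: set[str] = field(default_factory=set)
    patterns: list[PatternRule] = field(default_factory=list)
    placeholder_style: str = "[{CATEGORY}]"

    def __post_init__(self):
        self.name_lexicon = {normalize_token(p) for p in self.name_lexicon} - {""}
        self.location_lexicon = {
            normalize_token(p) for p in self.location_lexicon
        } - {""}
        self.safe_lexicon = {normalize_token(p) for p in self.safe_lexicon} - {""}

    def render_placeholder(self, category: PhiCategory) -> str:
        return self.placeholder_style.format(CATEGORY=category.value)

    def max_phrase_len(self) -> int:
        n = 1
        for lex in (self.name_lexicon, self.location_lexicon, self.safe_lexicon):
            for phrase in lex:
                n = max(n, phrase.count(" ") + 1)
        return n


def load_ruleset(source: str | Path | dict) -> RedactionRuleSet:
    """Load a rule set from YAML/JSON (path or mapping).

    Keys: ``name_lexicon``, ``location_lexicon``, ``safe_lexicon`` (inline
    lists or paths to newline-delimited token files), ``patterns`` (list of
    ``{regex, category, id}``), ``placeholder_style``. Invalid regexes or
    unknown categories fail here, at load time, never during detection.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        doc = yaml.safe_load(text)
        base = Path(source).parent
    else:
        doc, base = source, Path(".")
    if not isinstance(doc, dict):
        raise RuleConfigError("rule set document must be a mapping")

    def _lexicon(key: str) -> set[str]:
        val = doc.get(key, [])
        if isinstance(val, str):  # path to a newline-delimited lexicon file
            lines = (base / val).read_text(encoding="utf-8").splitlines()
            return {ln.strip() for ln in lines if ln.strip()}
        return set(val)

    patterns: list[PatternRule] = []
    for i, p in enumerate(doc.get("patterns", [])):
        try:
            regex = re.compile(p["regex"], re.IGNORECASE)
        except re.error as exc:
            raise RuleConfigError(
                f"pattern {p.get('id', i)}: invalid regex {p.get('regex')!r}: {exc}"
            ) from exc
        try:
            category = PhiCategory(p["category"])
        except ValueError as exc:
            raise RuleConfigError(
                f"pattern {p.get('id', i)}: unknown category {p.get('category')!r}"
            ) from exc
        patterns.append(PatternRule(regex, category, str(p.get("id", f"pattern_{i}"))))

    return RedactionRuleSet(
        name_lexicon=_lexicon("name_lexicon"),
        location_lexicon=_lexicon("location_lexicon"),
        safe_lexicon=_lexicon("safe_lexicon"),
        patterns=patterns,
        placeholder_style=str(doc.get("placeholder_style", "[{CATEGORY}]")),
    )


# Candidate priority: lower sorts earlier. Patterns (by list order) beat
# lexicons; NAME lexicon beats LOCATION lexicon only by listing order here.
_LEXICON_PRIORITY_BASE = 10_000


def _candidates(tokens: list[str], rules: RedactionRuleSet):
    """All (start, end, category, priority, rule_id) rule matches."""
    out = []
    n = len(tokens)
    for prio, rule in enumerate(rules.patterns):
        for i, tok in enumerate(tokens):
            if tok and rule.regex.fullmatch(tok):
                out.append((i, i, rule.category, prio, rule.rule_id))
    max_len = rules.max_phrase_len()
    for lex, category, rule_id, prio in (
        (rules.name_lexicon, PhiCategory.NAME, "name_lexicon",
         _LEXICON_PRIORITY_BASE),
        (rules.location_lexicon, PhiCategory.LOCATION, "location_lexicon",
         _LEXICON_PRIORITY_BASE + 1),
    ):
        for i in range(n):
            for ln in range(1, min(max_len, n - i) + 1):
                phrase = " ".join(tokens[i : i + ln])
                if phrase and phrase in lex:
                    out.append((i, i + ln - 1, category, prio, rule_id))
    return out


def _safe_indices(tokens: list[str], rules: RedactionRuleSet) -> set[int]:
    blocked: set[int] = set()
    max_len = rules.max_phrase_len()
    n = len(tokens)
    for i in range(n):
        for ln in range(1, min(max_len, n - i) + 1):
            phrase = " ".join(tokens[i : i + ln])
            if phrase and phrase in rules.safe_lexicon:
                blocked.update(range(i, i + ln))
    return blocked


def detect_phi(rows: pd.DataFrame, rules: RedactionRuleSet) -> list[PhiSpan]:
    """Scan flattened transcript rows for PHI.

    Returns spans sorted by ``word_start_index``, pairwise non-overlapping
    after longest-match-wins resolution, with safe-lexicon words excluded.
    Span indices are the ``index`` column values (global word indices).
    """
    texts = [str(t) for t in rows["text"].tolist()]
    indices = [int(i) for i in rows["index"].tolist()]
    tokens = [normalize_token(t) for t in texts]

    blocked = _safe_indices(tokens, rules)
    cands = [
        c for c in _candidates(tokens, rules)
        if not any(p in blocked for p in range(c[0], c[1] + 1))
    ]
    # longest first, then rule priority, then position
    cands.sort(key=lambda c: (-(c[1] - c[0]), c[3], c[0]))
    taken: set[int] = set()
    chosen = []
    for start, end, category, _prio, rule_id in cands:
        positions = range(start, end + 1)
        if any(p in taken for p in positions):
            continue
        taken.update(positions)
        chosen.append(
            PhiSpan(
                word_start_index=indices[start],
                word_end_index=indices[end],
                category=category,
                matched_text=" ".join(texts[start : end + 1]),
                rule_id=rule_id,
            )
        )
    chosen.sort(key=lambda s: s.word_start_index)
    return chosen


def apply_redaction(
    rows: pd.DataFrame, spans: list[PhiSpan], rules: RedactionRuleSet
) -> tuple[pd.DataFrame, list[dict]]:
    """Replace span words by rendered placeholders.

    Timestamps, indices, speakers and row count are untouched; only the
    ``text`` column changes. Returns the redacted table plus a redaction
    map (one record per span: indices, category, placeholder, original
    text) for the audit trail.
    """
    redacted = rows.copy(deep=True)
    pos_of = {int(idx): pos for pos, idx in enumerate(rows["index"].tolist())}
    redaction_map = []
    for span in spans:
        placeholder = rules.render_placeholder(span.category)
        for widx in span.indices():
            if widx not in pos_of:
                raise IndexError(f"span references unknown word index {widx}")
            redacted.iat[pos_of[widx], redacted.columns.get_loc("text")] = placeholder
        redaction_map.append(
            {
                "word_start_index": span.word_start_index,
                "word_end_index": span.word_end_index,
                "category": span.category.value,
                "placeholder": placeholder,
                "matched_text": span.matched_text,
                "rule_id": span.rule_id,
            }
        )
    return redacted, redaction_map


def redaction_map_json(redaction_map: list[dict]) -> str:
    return json.dumps(redaction_map, indent=2, sort_keys=True)
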