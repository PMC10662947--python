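"""Dictionary-based symptom tagging of clinical free text.

The pipeline mirrors a classic clinical NER-by-dictionary workflow:

1. build a surface-form -> ICD-10 level-3 dictionary and expand every base
   term with inflectional suffixes;
2. tokenize dictionary and corpus, and harvest corpus tokens that sit at
   Levenshtein distance exactly 1 from a dictionary token (length >= 5) as
   spelling variants;
3. tag notes with a case-insensitive, longest-match-wins n-gram scan;
4. discard mentions whose sentence contains a negation word or a word
   denoting another person (family history);
5. evaluate against gold annotations with a token-level confusion matrix,
   reporting sensitivity TP/(TP+FN) and specificity TN/(TN+FP).

Matching is whole-token and language-agnostic: only the lexicons encode
language.  Levenshtein distance uses unit costs with no transposition, so
distance 1 means exactly one substitution, deletion or insertion.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import edlib
import pandas as pd

from .lexicons import NEGATION_LEXICON, OTHER_PERSON_LEXICON

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[A-Za-z]+")
_SENTENCE_SPLIT_RE = re.compile(r"[.!?;](?:\s|$)|\n")

#: provenance tags for dictionary entries
PROVENANCE_TAGS = ("chapter18", "literature", "review", "suffix_variant", "spelling_variant")


class Token(NamedTuple):
    text: str
    start: int
    end: int


@dataclass
class SymptomMention:
    """One tagged dictionary hit in a note.

    Offsets are 0-based half-open; ``matched_text`` is the original slice.
    A mention contributes downstream only when both flags are False.
    """

    note_id: str
    code: str
    matched_text: str
    char_start: int
    char_end: int
    negated: bool = False
    other_person: bool = False


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise ZeroDivisionError("sensitivity undefined: no gold symptoms")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise ZeroDivisionError("specificity undefined: no negative tokens")
        return self.tn / (self.tn + self.fp)


def tokenize(text: str) -> list[Token]:
    """Lowercased alphabetic-run tokens with character offsets."""
    return [
        Token(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)
    ]


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Half-open character spans of sentences.

    Sentences end at ``.!?;`` followed by whitespace or end of text, and at
    newlines — clinical notes are newline-heavy, so a line break always
    closes the sentence scope.
    """
    spans, start = [], 0
    for m in _SENTENCE_SPLIT_RE.finditer(text):
        spans.append((start, m.end()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


class SymptomDictionary:
    """Surface-form -> code map with suffix and spelling-variant expansion.

    Surface forms are lowercase token strings (multiword entries joined by
    single spaces).  Each entry carries a provenance tag so that the
    expansion history stays auditable.
    """

    def __init__(
        self,
        entries: Mapping[str, str] | None = None,
        provenance: Mapping[str, str] | None = None,
        suffixes: Sequence[str] = (),
    ):
        self.entries: dict[str, str] = {}
        self.provenance: dict[str, str] = {}
        self.suffixes: list[str] = list(suffixes)
        for form, code in (entries or {}).items():
            tag = (provenance or {}).get(form, "literature")
            self.add(form, code, tag)

    def add(self, surface_form: str, code: str, provenance: str) -> bool:
        """Add an entry; earlier entries win on collision (returns False)."""
        form = " ".join(t.text for t in tokenize(surface_form))
        if not form or not code:
            raise ValueError("surface form and code must be non-empty")
        if form in self.entries:
            if self.entries[form] != code:
                logger.warning(
                    "dictionary collision: %r already -> %s, ignoring -> %s",
                    form, self.entries[form], code,
                )
            return False
        self.entries[form] = code
        self.provenance[form] = provenance
        return True

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, form: str) -> bool:
        return form in self.entries

    def codes(self) -> set[str]:
        return set(self.entries.values())

    def tokens(self) -> set[str]:
        """All unique tokens over all surface forms."""
        out: set[str] = set()
        for form in self.entries:
            out.update(form.split())
        return out

    def base_forms(self, code: str | None = None) -> list[str]:
        """Non-variant surface forms (optionally for one code), sorted."""
        out = [
            f
            for f, tag in self.provenance.items()
            if tag not in ("suffix_variant", "spelling_variant")
            and (code is None or self.entries[f] == code)
        ]
        return sorted(out)

    @property
    def max_ngram(self) -> int:
        return max((len(f.split()) for f in self.entries), default=0)

    def add_spelling_variants(self, variants: Mapping[str, str]) -> None:
        """Merge harvested ``variant token -> canonical token`` pairs.

        Every dictionary surface form containing the canonical token spawns
        a variant form with the token replaced, mapped to the same code.
        """
        for variant, canonical in variants.items():
            for form in list(self.entries):
                parts = form.split()
                if canonical in parts:
                    new_form = " ".join(variant if p == canonical else p for p in parts)
                    self.add(new_form, self.entries[form], "spelling_variant")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "surface_form": list(self.entries),
                "code": [self.entries[f] for f in self.entries],
                "provenance": [self.provenance[f] for f in self.entries],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, suffixes: Sequence[str] = ()) -> "SymptomDictionary":
        df = pd.read_csv(path, sep="\t", dtype=str)
        d = cls(suffixes=suffixes)
        for rec in df.itertuples():
            d.add(rec.surface_form, rec.code, rec.provenance)
        return d


def expand_suffixes(
    base_terms: Mapping[str, str],
    suffixes: Sequence[str],
    provenance: Mapping[str, str] | None = None,
) -> SymptomDictionary:
    """Base terms plus every term+suffix, all mapped to the base term's code.

    Collisions (two expansions producing the same surface form) resolve in
    favour of the earlier entry, with a logged warning.
    """
    d = SymptomDictionary(suffixes=suffixes)
    for term, code in base_terms.items():
        d.add(term, code, (provenance or {}).get(term, "literature"))
    for term, code in base_terms.items():
        for suffix in suffixes:
            d.add(term + suffix, code, "suffix_variant")
    return d


def harvest_spelling_variants(
    dict_tokens: Iterable[str],
    corpus_tokens: Iterable[str],
    max_distance: int = 1,
    min_length: int = 5,
) -> dict[str, str]:
    """Corpus tokens one edit away from a dictionary token.

    Returns ``variant -> canonical`` for corpus tokens of length >=
    ``min_length`` at Levenshtein distance in [1, max_distance] from some
    dictionary token, excluding tokens already in the dictionary.  Each
    variant maps to its nearest dictionary token; ties break to the
    lexicographically smallest canonical.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    dict_set = set(dict_tokens)
    by_len: dict[int, list[str]] = defaultdict(list)
    for t in dict_set:
        by_len[len(t)].append(t)
    for lst in by_len.values():
        lst.sort()

    out: dict[str, str] = {}
    for tok in sorted(set(corpus_tokens)):
        if len(tok) < min_length or tok in dict_set:
            continue
        best_d, best_canon = None, None
        for L in range(len(tok) - max_distance, len(tok) + max_distance + 1):
            for cand in by_len.get(L, ()):
                d = edlib.align(tok, cand, task="distance", k=max_distance)["editDistance"]
                if d < 1:  # -1 means above k; 0 cannot happen (tok not in dict)
                    continue
                if best_d is None or d < best_d or (d == best_d and cand < best_canon):
                    best_d, best_canon = d, cand
        if best_canon is not None:
            out[tok] = best_canon
    return out


def tag_note(
    text: str, dictionary: SymptomDictionary, note_id: str = ""
) -> list[SymptomMention]:
    """Case-insensitive longest-match-wins scan over token n-grams.

    Multiword entries match contiguous token sequences; mentions never
    overlap; flags default to False.
    """
    tokens = tokenize(text)
    max_n = dictionary.max_ngram
    mentions: list[SymptomMention] = []
    i = 0
    while i < len(tokens):
        matched = False
        for n in range(min(max_n, len(tokens) - i), 0, -1):
            phrase = " ".join(t.text for t in tokens[i : i + n])
            if phrase in dictionary.entries:
                start, end = tokens[i].start, tokens[i + n - 1].end
                mentions.append(
                    SymptomMention(
                        note_id=note_id,
                        code=dictionary.entries[phrase],
                        matched_text=text[start:end],
                        char_start=start,
                        char_end=end,
                    )
                )
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def _flag_by_lexicon(
    mentions: list[SymptomMention],
    note_text: str,
    lexicon: Iterable[str],
    attr: str,
) -> list[SymptomMention]:
    lex = set(lexicon)
    if not lex or not mentions:
        return mentions
    spans = sentence_spans(note_text)
    sent_tokens = [
        {t.text for t in tokenize(note_text[lo:hi])} for lo, hi in spans
    ]
    for m in mentions:
        for (lo, hi), toks in zip(spans, sent_tokens):
            if lo <= m.char_start < hi:
                if toks & lex:
                    setattr(m, attr, True)  # flags only ever go False -> True
                break
    return mentions


def flag_negations(
    mentions: list[SymptomMention],
    note_text: str,
    negation_lexicon: Iterable[str] = NEGATION_LEXICON,
) -> list[SymptomMention]:
    """Flag mentions whose sentence contains a negation word."""
    return _flag_by_lexicon(mentions, note_text, negation_lexicon, "negated")


def flag_other_person(
    mentions: list[SymptomMention],
    note_text: str,
    relation_lexicon: Iterable[str] = OTHER_PERSON_LEXICON,
) -> list[SymptomMention]:
    """Flag mentions whose sentence mentions a person other than the patient."""
    return _flag_by_lexicon(mentions, note_text, relation_lexicon, "other_person")


def confusion_counts(
    gold: Sequence[tuple[int, int, str]],
    predicted: Sequence[SymptomMention],
    n_tokens: int,
) -> ConfusionCounts:
    """Raw confusion counts of predictions against gold spans (no ratios)."""
    active = [m for m in predicted if not m.negated and not m.other_person]
    used = [False] * len(active)
    tp = 0
    for g_start, g_end, g_code in gold:
        hit = False
        for j, m in enumerate(active):
            if used[j] or m.code != g_code:
                continue
            if m.char_start < g_end and g_start < m.char_end:
                used[j] = True
                hit = True
                break
        tp += hit
    fn = len(gold) - tp
    fp = used.count(False)
    tn = n_tokens - (tp + fp + fn)
    return ConfusionCounts(tp=tp, fp=fp, tn=max(tn, 0), fn=fn)


def evaluate_tagging(
    gold: Sequence[tuple[int, int, str]],
    predicted: Sequence[SymptomMention],
    n_tokens: int,
) -> tuple[ConfusionCounts, float, float]:
    """Token-level confusion matrix of predictions against gold spans.

    A gold span ``(start, end, code)`` counts as TP when some active
    prediction (both flags False) has the same code and an overlapping
    span; span boundaries need not coincide because suffix variants shift
    them by design.  TN is the remaining token mass:
    ``n_tokens - (TP + FP + FN)``.  Raises ``ZeroDivisionError`` when a
    ratio's denominator is empty (no gold symptoms / no negative tokens).
    """
    counts = confusion_counts(gold, predicted, n_tokens)
    return counts, counts.sensitivity, counts.specificity
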