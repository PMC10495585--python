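"""Rule-based recognition of scale-name mentions in titles and abstracts.

Instrument names in the literature follow a strong surface pattern: runs of
capitalized tokens ("Hospital Anxiety and Depression Scale"), usually
containing a trigger noun (Scale, Questionnaire, Inventory, ...) or followed
by a parenthesized acronym ("(HADS)").  The extractor finds maximal token
spans obeying that pattern; the recognizer then normalizes each candidate
against the lexicon, keeping matches as :class:`ScaleOccurrence` objects and
routing non-matching candidates to an unknown-candidate report for manual
curation (never silently dropped).  Bare lexicon-known acronyms ("PHQ-9")
are matched even without a trigger noun.

Matching runs over raw field text — sentence boundaries are not modelled —
after normalizing unicode dashes to ASCII hyphens (a length-preserving
substitution, so character offsets always refer to the original text).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .lexicon import Lexicon, normalize_dashes
from .medline import ArticleRecord
from .mesh import DEFAULT_CATEGORIES, MeshTree, categorize_headings

__all__ = [
    "Mention",
    "ScaleOccurrence",
    "AnnotatedArticle",
    "NerRules",
    "DEFAULT_TRIGGERS",
    "DEFAULT_CONNECTORS",
    "extract_candidates",
    "recognize",
    "annotate_corpus",
]

DEFAULT_TRIGGERS = frozenset(
    {
        "scale",
        "scales",
        "questionnaire",
        "inventory",
        "index",
        "checklist",
        "instrument",
        "tool",
        "test",
        "survey",
        "measure",
        "schedule",
    }
)

DEFAULT_CONNECTORS = frozenset({"of", "for", "and", "the", "in", "to"})


@dataclass(frozen=True)
class NerRules:
    """Configurable trigger-noun and connector sets (compared lowercase)."""

    triggers: frozenset[str] = DEFAULT_TRIGGERS
    connectors: frozenset[str] = DEFAULT_CONNECTORS


@dataclass(frozen=True)
class Mention:
    """A located surface form: ``surface == source_field[start:end]``."""

    surface: str
    start: int
    end: int
    field: str  # "title" | "abstract"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad mention offsets [{self.start}, {self.end})")
        if self.field not in ("title", "abstract"):
            raise ValueError(f"bad field {self.field!r}")


@dataclass(frozen=True)
class ScaleOccurrence:
    """All mentions of one canonical scale within one article."""

    pmid: str
    canonical_name: str
    mentions: tuple[Mention, ...]

    def __post_init__(self) -> None:
        if not self.mentions:
            raise ValueError("ScaleOccurrence requires at least one mention")


@dataclass
class AnnotatedArticle:
    """A record coupled with its scale occurrences and categorized MeSH sets."""

    record: ArticleRecord
    occurrences: list[ScaleOccurrence]
    unknown_candidates: list[Mention]
    mesh_by_category: dict[str, set[str]]
    unmapped_mesh: list[str] = field(default_factory=list)

    @property
    def pmid(self) -> str:
        return self.record.pmid

    def scale_names(self) -> set[str]:
        return {o.canonical_name for o in self.occurrences}


_WORD_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9\-']*")
_ACRONYM_RE = re.compile(r"[A-Z0-9][A-Z0-9\-]+")


def _words(text: str):
    """(word, start, end) triples over dash-normalized text."""
    return [(m.group(), m.start(), m.end()) for m in _WORD_RE.finditer(text)]


def _is_cap(word: str) -> bool:
    return word[0].isupper()


def _is_digit_initial(word: str) -> bool:
    return word[0].isdigit()


def _is_trigger(word: str, rules: NerRules) -> bool:
    """Trigger nouns match case-insensitively, also in numbered variants
    ("Scale-21", "Questionnaire-9")."""
    wl = word.lower()
    return wl in rules.triggers or wl.split("-")[0] in rules.triggers


def _gap_ok(gap: str, next_word: str, rules: NerRules) -> bool:
    """May a candidate span continue across this inter-word gap?

    Plain whitespace always connects.  A single comma connects only when the
    next token is capitalized and not a connector, so "Depression, Anxiety
    and Stress Scale" stays one span while "in China, the ..." breaks.
    """
    if gap.strip() == "":
        return True
    if gap.strip() == "," and _is_cap(next_word) and next_word.lower() not in rules.connectors:
        return True
    return False


def _acronym_after(text: str, pos: int) -> tuple[str, int] | None:
    """Parenthesized all-caps/digit acronym at ``pos``; returns (acronym, end)."""
    m = re.match(r"\s*\(\s*([A-Z0-9][A-Z0-9\-]*[A-Z0-9])\s*\)", text[pos:])
    if m and any(c.isalpha() for c in m.group(1)):
        return m.group(1), pos + m.end()
    return None


def extract_candidates(text: str, rules: NerRules = NerRules(), field: str = "abstract") -> list[Mention]:
    """Maximal candidate spans matching the instrument-name pattern.

    A span starts at a capitalized non-connector token and extends over
    capitalized tokens, digit-initial tokens, connectors, and (lowercase)
    trigger nouns; it must not end on a connector.  It is kept as a
    candidate iff it contains a trigger noun or is immediately followed by
    a parenthesized acronym (which is then absorbed into the span, so
    "Long Name (ACR)" is one candidate).  Candidates are non-overlapping,
    chosen left-to-right, longest-match-first.
    """
    norm = normalize_dashes(text)
    words = _words(norm)
    candidates: list[Mention] = []
    n = len(words)
    i = 0
    while i < n:
        w, ws, _ = words[i]
        if not _is_cap(w) or w.lower() in rules.connectors:
            i += 1
            continue
        # extend maximal span
        j = i
        while j + 1 < n:
            nxt, ns, _ = words[j + 1]
            gap = norm[words[j][2] : ns]
            if not _gap_ok(gap, nxt, rules):
                break
            lower = nxt.lower()
            if _is_cap(nxt) or _is_digit_initial(nxt) or lower in rules.connectors or _is_trigger(nxt, rules):
                j += 1
            else:
                break
        # spans never end on a connector
        while j > i and words[j][0].lower() in rules.connectors:
            j -= 1
        span_start, span_end = words[i][1], words[j][2]
        has_trigger = any(_is_trigger(words[k][0], rules) for k in range(i, j + 1))
        acr = _acronym_after(norm, span_end)
        if acr is not None:
            span_end = acr[1]
        if has_trigger or acr is not None:
            candidates.append(Mention(text[span_start:span_end], span_start, span_end, field))
        i = j + 1
        while i < n and words[i][1] < span_end:  # skip tokens of an absorbed acronym
            i += 1
    return candidates


def _match_candidate(
    cand: Mention, lexicon: Lexicon, rules: NerRules
) -> list[tuple[str, Mention]]:
    """Normalize a candidate against the lexicon.

    The full span is tried first (including its name/acronym parts for the
    "Long Name (ACR)" shape).  If that fails, the candidate is scanned for
    lexicon-known sub-spans, left-to-right and longest-match-first, so that
    connector-glued spans ("Imaginary Wellness Scale and the GAD-7", or a
    capitalized word stuck on the front) still yield their embedded
    instruments.  Returns [] when nothing matches."""
    surface = cand.surface
    hit = lexicon.normalize(surface)
    if hit:
        return [(hit, cand)]
    norm_surface = normalize_dashes(surface)
    m = re.search(r"\s*\(\s*([A-Z0-9][A-Z0-9\-]*)\s*\)\s*$", norm_surface)
    if m:
        hit = lexicon.normalize(surface[: m.start()]) or lexicon.normalize(m.group(1))
        if hit:
            return [(hit, cand)]
    words = list(_WORD_RE.finditer(norm_surface))
    found: list[tuple[str, Mention]] = []
    i = 0
    while i < len(words):
        if words[i].group().lower() in rules.connectors:
            i += 1
            continue
        for j in range(len(words) - 1, i - 1, -1):
            sub = surface[words[i].start() : words[j].end()]
            hit = lexicon.normalize(sub)
            if hit:
                found.append(
                    (hit, Mention(sub, cand.start + words[i].start(), cand.start + words[j].end(), cand.field))
                )
                i = j
                break
        i += 1
    return found


def _bare_acronyms(text: str, field: str, lexicon: Lexicon, blocked: list[tuple[int, int]]):
    """Lexicon-known acronym tokens outside candidate spans."""
    from .lexicon import surface_key

    acro = lexicon.acronym_keys()
    out = []
    for w, ws, we in _words(normalize_dashes(text)):
        if any(s <= ws < e for s, e in blocked):
            continue
        if not _ACRONYM_RE.fullmatch(w):
            continue
        canonical = acro.get(surface_key(w))
        if canonical:
            out.append((canonical, Mention(text[ws:we], ws, we, field)))
    return out


def recognize(
    article: ArticleRecord,
    lexicon: Lexicon,
    rules: NerRules = NerRules(),
) -> tuple[list[ScaleOccurrence], list[Mention]]:
    """Recognize and normalize scale mentions in one article.

    Returns ``(occurrences, unknown_candidates)``: one
    :class:`ScaleOccurrence` per canonical scale found in the title or
    abstract, and the candidates that matched the surface pattern but no
    lexicon entry (kept for curation).  Recognized and unknown spans are
    disjoint.
    """
    matched: dict[str, list[Mention]] = {}
    unknown: list[Mention] = []
    for fieldname, text in (("title", article.title), ("abstract", article.abstract)):
        if not text:
            continue
        cands = extract_candidates(text, rules, fieldname)
        spans = [(c.start, c.end) for c in cands]
        for cand in cands:
            hits = _match_candidate(cand, lexicon, rules)
            if hits:
                for canonical, mention in hits:
                    matched.setdefault(canonical, []).append(mention)
            else:
                unknown.append(cand)
        for canonical, mention in _bare_acronyms(text, fieldname, lexicon, spans):
            matched.setdefault(canonical, []).append(mention)
    occurrences = [
        ScaleOccurrence(article.pmid, name, tuple(sorted(ms, key=lambda m: (m.field, m.start))))
        for name, ms in sorted(matched.items())
    ]
    return occurrences, unknown


def annotate_corpus(
    records: list[ArticleRecord],
    tree: MeshTree,
    lexicon: Lexicon,
    categories=DEFAULT_CATEGORIES,
    rules: NerRules = NerRules(),
) -> list[AnnotatedArticle]:
    """Run NER + MeSH categorization over a corpus (deterministic)."""
    out = []
    for rec in records:
        occurrences, unknown = recognize(rec, lexicon, rules)
        by_cat, unmapped = categorize_headings(rec, tree, categories)
        out.append(AnnotatedArticle(rec, occurrences, unknown, by_cat, unmapped))
    return out
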