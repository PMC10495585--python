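"""Canonical mental-health scale names and surface-form normalization.

Published articles refer to the same instrument in many ways — "DASS",
"Depression, Anxiety and Stress Scale-21", "DASS-21" — so recognized mentions
are mapped onto one canonical name per instrument ("Depression, Anxiety and
Stress Scale (DASS-21)") through a lexicon of canonical names, acronyms and
alias surface forms.  Matching is keyed on :func:`surface_key`, a
deterministic normalization that is insensitive to case, hyphens, commas,
extra whitespace, a leading article and a trailing parenthesized acronym.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "ScaleEntry",
    "Lexicon",
    "LexiconError",
    "surface_key",
    "load_lexicon",
    "save_lexicon",
    "default_lexicon",
]


class LexiconError(ValueError):
    """Raised on duplicate canonical names or colliding alias keys."""


_DASH_RE = re.compile(r"[‐‑‒–—−]")
_TRAILING_ACRONYM_RE = re.compile(r"\s*\(([^()]*)\)\s*$")
_ACRONYM_BODY_RE = re.compile(r"^[A-Z0-9][A-Z0-9\- ]*$")


def normalize_dashes(text: str) -> str:
    """Replace unicode hyphens/dashes with ASCII '-' (length-preserving)."""
    return _DASH_RE.sub("-", text)


def surface_key(text: str) -> str:
    """Reduce a surface form to its matching key.

    Lowercases; collapses hyphens, commas and whitespace runs to single
    spaces; strips a trailing parenthesized acronym ("... Scale (HADS)" and
    "... Scale" share a key) and a leading article "the".  Idempotent.
    """
    s = normalize_dashes(text)
    m = _TRAILING_ACRONYM_RE.search(s)
    if m and _ACRONYM_BODY_RE.match(normalize_dashes(m.group(1)).strip()):
        s = s[: m.start()]
    s = s.lower()
    s = re.sub(r"[-,]", " ", s)
    s = " ".join(s.split())
    if s.startswith("the "):
        s = s[4:]
    return s


@dataclass(frozen=True)
class ScaleEntry:
    """One instrument: canonical name, acronym, alias surface forms."""

    canonical_name: str
    acronym: str = ""
    aliases: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise ValueError("canonical_name must be non-empty")
        if self.acronym and self.acronym not in self.canonical_name:
            raise ValueError(
                f"{self.canonical_name!r}: acronym {self.acronym!r} does not "
                "appear in the canonical name"
            )
        if self.canonical_name in self.aliases:
            raise ValueError(f"{self.canonical_name!r} listed as its own alias")

    def keys(self) -> set[str]:
        ks = {surface_key(self.canonical_name)}
        if self.acronym:
            ks.add(surface_key(self.acronym))
        ks.update(surface_key(a) for a in self.aliases)
        ks.discard("")
        return ks


class Lexicon:
    """An alias index over scale entries.

    The index maps each normalized surface key to exactly one canonical
    name; a key claimed by two entries is a construction-time
    :class:`LexiconError` (curated standardization implies unique standard
    names).  Construction is order-independent: permuting
    the entries yields an identical index.
    """

    def __init__(self, entries: list[ScaleEntry]):
        self.entries: list[ScaleEntry] = list(entries)
        names = [e.canonical_name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise LexiconError(f"duplicate canonical names: {sorted(dupes)}")
        self.alias_index: dict[str, str] = {}
        owners: dict[str, set[str]] = {}
        for entry in sorted(self.entries, key=lambda e: e.canonical_name):
            for key in entry.keys():
                owners.setdefault(key, set()).add(entry.canonical_name)
        collisions = {k: sorted(v) for k, v in owners.items() if len(v) > 1}
        if collisions:
            raise LexiconError(f"alias key collisions: {collisions}")
        self.alias_index = {k: next(iter(v)) for k, v in owners.items()}

    def normalize(self, mention: str) -> str | None:
        """Canonical name for a mention, or None if it matches no entry."""
        return self.alias_index.get(surface_key(mention))

    def canonical_names(self) -> list[str]:
        return [e.canonical_name for e in self.entries]

    def acronym_keys(self) -> dict[str, str]:
        """Keys derived from acronyms/short aliases, for bare-acronym matching."""
        out = {}
        for entry in self.entries:
            if entry.acronym:
                out[surface_key(entry.acronym)] = entry.canonical_name
            for a in entry.aliases:
                if _ACRONYM_BODY_RE.match(normalize_dashes(a)):
                    out[surface_key(a)] = entry.canonical_name
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return sorted(self.entries, key=lambda e: e.canonical_name) == sorted(
            other.entries, key=lambda e: e.canonical_name
        )


def load_lexicon(stream) -> Lexicon:
    """Load a lexicon from TSV: canonical_name, acronym, pipe-separated aliases.

    Lines starting with ``#`` are comments; the alias column may be empty.
    Raises :class:`LexiconError` listing offenders on duplicate canonical
    names or alias-key collisions.
    """
    text = stream if isinstance(stream, str) else stream.read()
    entries = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 1 or not parts[0].strip():
            raise LexiconError(f"row {lineno}: missing canonical name")
        canonical = parts[0].strip()
        acronym = parts[1].strip() if len(parts) > 1 else ""
        aliases = frozenset(
            a.strip() for a in (parts[2].split("|") if len(parts) > 2 and parts[2].strip() else []) if a.strip()
        )
        entries.append(ScaleEntry(canonical, acronym, aliases))
    return Lexicon(entries)


def save_lexicon(lexicon: Lexicon) -> str:
    """Serialize to the three-column TSV format (round-trips with load)."""
    lines = []
    for e in lexicon.entries:
        lines.append(f"{e.canonical_name}\t{e.acronym}\t{'|'.join(sorted(e.aliases))}")
    return "\n".join(lines) + ("\n" if lines else "")


def default_lexicon() -> Lexicon:
    """The packaged default lexicon of pandemic-era mental-health scales."""
    text = resources.files("scalemine.data").joinpath("default_scales.tsv").read_text("utf-8")
    return load_lexicon(text)
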