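"""MeSH descriptors, tree numbers, and semantic-category classification.

MeSH places every descriptor at one or more positions in a 16-branch tree via
dot-separated tree numbers (e.g. ``N06.850.520``); prefix relations between
tree numbers encode subordination.  The pipeline classifies descriptors into
five semantic categories by tree-number prefix:

================== =========================== ======================
label              meaning                     default prefixes
================== =========================== ======================
research_objects   study population            M
research_methods   study design / method       N05, N06.850.520
countries_regions  geographic location         Z
research_topics    mental-health topic         F
factors            phenomenological process    G
================== =========================== ======================

Prefix sets are configuration: users may restrict a category to sub-branches
(say F01-F04) by passing their own :class:`SemanticCategory` list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "MeshDescriptor",
    "SemanticCategory",
    "MeshTree",
    "DEFAULT_CATEGORIES",
    "CATEGORY_LABELS",
    "matches_prefix",
    "classify",
    "categorize_headings",
    "load_mesh_tree",
    "save_mesh_tree",
    "mini_tree",
]

_TREE_NUMBER_RE = re.compile(r"^[A-Z]\d+(?:\.\d+)*$")


def _check_tree_number(tn: str) -> None:
    if not _TREE_NUMBER_RE.match(tn):
        raise ValueError(f"invalid tree number syntax: {tn!r}")


@dataclass(frozen=True)
class MeshDescriptor:
    """A descriptor name with its tree numbers."""

    name: str
    tree_numbers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("descriptor name must be non-empty")
        if not self.tree_numbers:
            raise ValueError(f"{self.name}: at least one tree number required")
        for tn in self.tree_numbers:
            _check_tree_number(tn)


@dataclass(frozen=True)
class SemanticCategory:
    """A category label plus the tree-number prefixes that define it."""

    label: str
    prefixes: tuple[str, ...]


CATEGORY_LABELS = (
    "research_objects",
    "research_methods",
    "countries_regions",
    "research_topics",
    "factors",
)

DEFAULT_CATEGORIES: tuple[SemanticCategory, ...] = (
    SemanticCategory("research_objects", ("M",)),
    SemanticCategory("research_methods", ("N05", "N06.850.520")),
    SemanticCategory("countries_regions", ("Z",)),
    SemanticCategory("research_topics", ("F",)),
    SemanticCategory("factors", ("G",)),
)


def _norm_name(name: str) -> str:
    return " ".join(name.split()).lower()


@dataclass
class MeshTree:
    """Mapping from descriptor name to :class:`MeshDescriptor`.

    Lookup is case-insensitive after whitespace normalization.
    """

    descriptors: dict[str, MeshDescriptor] = field(default_factory=dict)
    _index: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {_norm_name(n): n for n in self.descriptors}

    def add(self, name: str, tree_numbers) -> None:
        key = _norm_name(name)
        if key in self._index:
            existing = self.descriptors[self._index[key]]
            merged = tuple(dict.fromkeys(existing.tree_numbers + tuple(tree_numbers)))
            self.descriptors[existing.name] = MeshDescriptor(existing.name, merged)
        else:
            self.descriptors[name] = MeshDescriptor(name, tuple(tree_numbers))
            self._index[key] = name

    def get(self, name: str) -> MeshDescriptor | None:
        canonical = self._index.get(_norm_name(name))
        return self.descriptors[canonical] if canonical else None

    def __len__(self) -> int:
        return len(self.descriptors)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeshTree):
            return NotImplemented
        return self.descriptors == other.descriptors


def matches_prefix(tree_number: str, prefix: str) -> bool:
    """True iff ``tree_number`` sits at or below ``prefix`` in the tree.

    Comparison is on whole dot-groups: ``N06.850.520.445`` matches prefix
    ``N06.850.520`` but ``N055.100`` does not match ``N05``.  A bare-letter
    prefix denotes an entire top-level branch (``M01.526`` matches ``M``,
    since the letter is the branch and ``M01`` its first subdivision).
    """
    if len(prefix) == 1:
        return tree_number[0] == prefix
    if tree_number == prefix:
        return True
    return tree_number.startswith(prefix + ".")


def classify(
    descriptor: MeshDescriptor,
    categories: tuple[SemanticCategory, ...] = DEFAULT_CATEGORIES,
) -> set[str]:
    """Category labels whose prefixes match any tree number of ``descriptor``.

    A descriptor matching nothing yields the empty set (such descriptors are
    simply filtered out downstream, not errors).
    """
    labels = set()
    for cat in categories:
        for tn in descriptor.tree_numbers:
            if any(matches_prefix(tn, p) for p in cat.prefixes):
                labels.add(cat.label)
                break
    return labels


def categorize_headings(
    article,
    tree: MeshTree,
    categories: tuple[SemanticCategory, ...] = DEFAULT_CATEGORIES,
) -> tuple[dict[str, set[str]], list[str]]:
    """Classify an article's MeSH headings into per-category descriptor sets.

    Returns ``(by_category, unmapped)`` where ``by_category`` maps each
    category label (all labels always present) to the set of descriptor
    names from the article landing in that category, and ``unmapped`` lists
    headings whose descriptor is absent from the tree — collected for a
    report, never an error.
    """
    by_category: dict[str, set[str]] = {c.label: set() for c in categories}
    unmapped: list[str] = []
    for heading in article.headings:
        desc = tree.get(heading.descriptor)
        if desc is None:
            unmapped.append(heading.descriptor)
            continue
        for label in classify(desc, categories):
            by_category[label].add(desc.name)
    return by_category, unmapped


def load_mesh_tree(stream) -> MeshTree:
    """Load a tree from two-column TSV text: descriptor name, tree number.

    One row per (name, tree number) pair; rows sharing a name merge into one
    descriptor.  Lines starting with ``#`` are comments.  Raises
    ``ValueError`` naming the row on a missing column or bad tree-number
    syntax.
    """
    text = stream if isinstance(stream, str) else stream.read()
    tree = MeshTree()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            raise ValueError(f"row {lineno}: expected 'name<TAB>tree_number', got {line!r}")
        name, tn = parts[0].strip(), parts[1].strip()
        try:
            _check_tree_number(tn)
        except ValueError as exc:
            raise ValueError(f"row {lineno}: {exc}") from None
        tree.add(name, (tn,))
    return tree


def save_mesh_tree(tree: MeshTree) -> str:
    """Serialize to the two-column TSV format (round-trips with load)."""
    lines = []
    for name in tree.descriptors:
        for tn in tree.descriptors[name].tree_numbers:
            lines.append(f"{name}\t{tn}")
    return "\n".join(lines) + ("\n" if lines else "")


def mini_tree() -> MeshTree:
    """The packaged miniature MeSH tree (synthetic fixture, ~60 descriptors).

    Descriptor names are real MeSH headings relevant to pandemic mental-health
    literature; tree numbers are plausible but not authoritative.  Spans all
    five semantic categories.
    """
    text = resources.files("scalemine.data").joinpath("mesh_mini.tsv").read_text("utf-8")
    return load_mesh_tree(text)
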