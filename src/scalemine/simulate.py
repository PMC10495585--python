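"""Synthetic MEDLINE corpora with planted ground truth.

The generator emulates the structure of a pandemic-era PubMed download:
titles and abstracts built from sentence templates that embed scale mentions
(canonical names, acronyms, or alias variants), MH fields drawn from the
five semantic-category branches of a MeSH tree, optional distractor text to
exercise NER precision, and an exact ground-truth sidecar (per-article
plants plus corpus-level frequency and edge-weight tables) against which
pipeline output can be compared.

Identical seed + config produce byte-identical corpora.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from importlib import resources

import numpy as np

from .lexicon import Lexicon, ScaleEntry
from .medline import ArticleRecord, MeshHeading
from .mesh import DEFAULT_CATEGORIES, MeshTree, classify
from .ner import DEFAULT_TRIGGERS, _ACRONYM_RE

__all__ = ["SimConfig", "GroundTruth", "simulate", "distractor_text", "plantable_surfaces"]


def _templates() -> dict:
    text = resources.files("scalemine.data").joinpath("templates.json").read_text("utf-8")
    return json.loads(text)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic corpus.

    ``scale_freq`` plants exact document frequencies (each scale appears in
    that many distinct articles); when None, one scale per scale-bearing
    article is drawn from a Zipf-like law with exponent ``zipf_exponent``
    over ``scales`` (default: the 20 most frequent instruments of the
    default lexicon).  ``alias_prob`` is the chance a planted mention uses
    an acronym/alias surface form instead of the canonical name.
    ``mesh_per_article`` is the inclusive range of terms drawn per semantic
    category.  ``cooccur_bias`` multiplies the draw weight of one
    designated partner term per (scale, category), creating the hub
    structure co-occurrence analysis is meant to expose.
    """

    n_articles: int = 500
    scales: tuple[str, ...] | None = None
    scale_freq: dict[str, int] | None = None
    zipf_exponent: float = 1.1
    alias_prob: float = 0.0
    mesh_per_article: tuple[int, int] = (0, 1)
    cooccur_bias: float = 0.0
    p_no_scale: float = 0.1
    distractor_prob: float = 0.3
    title_mention_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 0:
            raise ValueError("n_articles must be >= 0")
        for p in (self.alias_prob, self.p_no_scale, self.distractor_prob, self.title_mention_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.cooccur_bias < 0:
            raise ValueError("cooccur_bias must be >= 0")
        lo, hi = self.mesh_per_article
        if not (0 <= lo <= hi):
            raise ValueError("mesh_per_article must be a non-decreasing pair")
        if self.scale_freq is not None:
            for name, f in self.scale_freq.items():
                if f > self.n_articles:
                    raise ValueError(f"requested frequency {f} for {name!r} exceeds n_articles")


@dataclass
class GroundTruth:
    """Exact record of what was planted.

    ``articles`` maps pmid to ``{"scales": set, "mentions": list of
    (canonical, field, start, end, surface), "mesh": {label: set}}``.
    The corpus-level ``frequency`` and ``edge_weights`` tables are computed
    by aggregation of the per-article rows, so they are consistent by
    construction.
    """

    articles: dict[str, dict] = dc_field(default_factory=dict)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(pmid, s) for pmid, a in self.articles.items() for s in a["scales"]}

    @property
    def frequency(self) -> dict[str, int]:
        freq: dict[str, int] = {}
        for a in self.articles.values():
            for s in a["scales"]:
                freq[s] = freq.get(s, 0) + 1
        return freq

    def edge_weights(self, category: str) -> dict[tuple[str, str], int]:
        w: dict[tuple[str, str], int] = {}
        for a in self.articles.values():
            for s in a["scales"]:
                for t in a["mesh"].get(category, ()):
                    w[(s, t)] = w.get((s, t), 0) + 1
        return w

    def to_tsvs(self) -> dict[str, str]:
        """Serialize the sidecar as plain TSV tables."""
        mention_lines = ["pmid\tcanonical_name\tfield\tstart\tend\tsurface"]
        mesh_lines = ["pmid\tcategory\tterm"]
        for pmid in sorted(self.articles, key=int):
            a = self.articles[pmid]
            for canonical, fieldname, start, end, surface in a["mentions"]:
                mention_lines.append(f"{pmid}\t{canonical}\t{fieldname}\t{start}\t{end}\t{surface}")
            for label in sorted(a["mesh"]):
                for t in sorted(a["mesh"][label]):
                    mesh_lines.append(f"{pmid}\t{label}\t{t}")
        freq_lines = ["canonical_name\tcount"]
        for name, c in sorted(self.frequency.items(), key=lambda kv: (-kv[1], kv[0])):
            freq_lines.append(f"{name}\t{c}")
        return {
            "truth_mentions.tsv": "\n".join(mention_lines) + "\n",
            "truth_mesh.tsv": "\n".join(mesh_lines) + "\n",
            "truth_frequency.tsv": "\n".join(freq_lines) + "\n",
        }


def plantable_surfaces(entry: ScaleEntry) -> list[str]:
    """Alias surface forms the rule set can spot standalone.

    The canonical name always qualifies; acronyms and aliases qualify when
    they are all-caps tokens (matched by the bare-acronym rule) or contain a
    trigger noun (matched by the span rules).  Other aliases stay in the
    lexicon for normalization but are not planted.
    """

    def visible(s: str) -> bool:
        if _ACRONYM_RE.fullmatch(s):
            return True
        return any(
            w.lower() in DEFAULT_TRIGGERS or w.lower().split("-")[0] in DEFAULT_TRIGGERS
            for w in s.replace(",", " ").split()
        )

    forms = []
    if entry.acronym and visible(entry.acronym):
        forms.append(entry.acronym)
    forms.extend(sorted(a for a in entry.aliases if visible(a)))
    return forms


def distractor_text(config: SimConfig | None = None) -> list[str]:
    """Text fragments that exercise NER precision.

    Capitalized non-scale phrases (organization names, software packages,
    survey frameworks) and lowercase scale-like phrases ("a sliding scale
    of doses"); none collide with default-lexicon keys.
    """
    return list(_templates()["distractor"])


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def simulate(
    config: SimConfig,
    lexicon: Lexicon,
    tree: MeshTree,
    categories=DEFAULT_CATEGORIES,
) -> tuple[list[ArticleRecord], GroundTruth]:
    """Generate a corpus and its exact ground-truth sidecar."""
    if config.n_articles == 0:
        return [], GroundTruth()
    if len(lexicon) == 0 or len(tree) == 0:
        raise ValueError("simulate requires a non-empty lexicon and tree")

    rng = np.random.default_rng(config.seed)
    tpl = _templates()
    entries = {e.canonical_name: e for e in lexicon.entries}

    scale_names = list(config.scales) if config.scales else lexicon.canonical_names()[:20]
    for name in scale_names:
        if name not in entries:
            raise ValueError(f"unknown scale {name!r}")

    # term pools per category, from tree-number classification
    pools: dict[str, list[str]] = {c.label: [] for c in categories}
    for name in sorted(tree.descriptors):
        for label in classify(tree.descriptors[name], categories):
            pools[label].append(name)

    # which scales go in which articles
    n = config.n_articles
    article_scales: list[list[str]] = [[] for _ in range(n)]
    if config.scale_freq is not None:
        for name in sorted(config.scale_freq):
            for idx in rng.choice(n, size=config.scale_freq[name], replace=False):
                article_scales[idx].append(name)
    else:
        weights = _zipf_weights(len(scale_names), config.zipf_exponent)
        for i in range(n):
            if rng.random() >= config.p_no_scale:
                article_scales[i].append(scale_names[rng.choice(len(scale_names), p=weights)])

    records: list[ArticleRecord] = []
    truth = GroundTruth()
    for i in range(n):
        pmid = str(100001 + i)
        scales = article_scales[i]
        population = tpl["populations"][rng.integers(len(tpl["populations"]))]

        # choose surface form per planted scale
        surfaces: list[tuple[str, str]] = []  # (canonical, surface)
        for name in scales:
            alt = plantable_surfaces(entries[name])
            if alt and rng.random() < config.alias_prob:
                surfaces.append((name, alt[rng.integers(len(alt))]))
            else:
                surfaces.append((name, name))

        mentions: list[tuple[str, str, int, int, str]] = []
        in_title = bool(surfaces) and rng.random() < config.title_mention_prob
        if in_title:
            canonical, surface = surfaces[0]
            t = tpl["title_mention"][rng.integers(len(tpl["title_mention"]))]
            prefix = t.split("{scale}")[0].format(population=population)
            title = t.format(scale=surface, population=population)
            mentions.append((canonical, "title", len(prefix), len(prefix) + len(surface), surface))
            body_surfaces = surfaces[1:]
        else:
            t = tpl["title"][rng.integers(len(tpl["title"]))]
            title = t.format(population=population)
            body_surfaces = surfaces

        sentences: list[str] = [tpl["filler"][rng.integers(len(tpl["filler"]))]]
        if rng.random() < config.distractor_prob:
            sentences.append(tpl["distractor"][rng.integers(len(tpl["distractor"]))])
        mention_slots: list[tuple[str, str, str, str]] = []  # canonical, prefix, surface, sentence
        for canonical, surface in body_surfaces:
            t = tpl["mention"][rng.integers(len(tpl["mention"]))]
            prefix = t.split("{scale}")[0]
            mention_slots.append((canonical, prefix, surface, t.format(scale=surface)))
        sentences_tail = [tpl["filler"][rng.integers(len(tpl["filler"]))]]

        abstract_parts: list[str] = []
        offset = 0
        for s in sentences:
            abstract_parts.append(s)
            offset += len(s) + 1
        for canonical, prefix, surface, sent in mention_slots:
            start = offset + len(prefix)
            mentions.append((canonical, "abstract", start, start + len(surface), surface))
            abstract_parts.append(sent)
            offset += len(sent) + 1
        abstract_parts.extend(sentences_tail)
        abstract = " ".join(abstract_parts)

        # MeSH assignments
        mesh: dict[str, set[str]] = {}
        lo, hi = config.mesh_per_article
        for cat in categories:
            pool = pools[cat.label]
            if not pool:
                mesh[cat.label] = set()
                continue
            k = int(rng.integers(lo, hi + 1))
            k = min(k, len(pool))
            if k == 0:
                mesh[cat.label] = set()
                continue
            w = np.ones(len(pool))
            if config.cooccur_bias > 0 and scales:
                partner = scale_names.index(scales[0]) % len(pool) if scales[0] in scale_names else 0
                w[partner] += config.cooccur_bias
            w /= w.sum()
            chosen = rng.choice(len(pool), size=k, replace=False, p=w)
            mesh[cat.label] = {pool[j] for j in sorted(chosen)}

        headings = []
        for label in sorted(mesh):
            for term in sorted(mesh[label]):
                headings.append(
                    MeshHeading(
                        descriptor=term,
                        qualifiers=("psychology",) if rng.random() < 0.2 else (),
                        major_topic=bool(rng.random() < 0.3),
                    )
                )

        records.append(ArticleRecord(pmid=pmid, title=title, abstract=abstract, headings=headings))
        truth.articles[pmid] = {"scales": set(scales), "mentions": mentions, "mesh": mesh}

    return records, truth


def demo_config(seed: int = 0, **overrides) -> SimConfig:
    """The default demonstration condition: 500 articles, Zipf 1.1 over the
    20 highest-frequency instruments, up to one term per category."""
    return replace(SimConfig(n_articles=500, zipf_exponent=1.1, seed=seed), **overrides)
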