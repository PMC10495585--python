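"""End-to-end pipeline: parse -> annotate -> classify -> network -> rank -> export.

`run_pipeline` reads a MEDLINE corpus, a scale lexicon and a MeSH tree,
annotates every record, builds one co-occurrence network per semantic
category, and writes all tabular artifacts plus a run manifest to an output
directory.  Re-running with identical inputs reproduces byte-identical
tabular outputs (the manifest carries a timestamp).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .lexicon import default_lexicon, load_lexicon
from .medline import read_medline_file
from .mesh import CATEGORY_LABELS, DEFAULT_CATEGORIES, SemanticCategory, load_mesh_tree, mini_tree
from .ner import DEFAULT_CONNECTORS, DEFAULT_TRIGGERS, NerRules, annotate_corpus
from .network import betweenness, build_network, export_network, frequency_table

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "ConfigError"]

logger = logging.getLogger("scalemine")


class ConfigError(ValueError):
    """Invalid pipeline configuration (bad paths or parameter values)."""


@dataclass
class PipelineConfig:
    corpus: str = ""
    lexicon: str = ""  # empty -> packaged default lexicon
    tree: str = ""  # empty -> packaged miniature tree
    outdir: str = "scalemine_out"
    category_prefixes: dict[str, list[str]] = field(default_factory=dict)
    triggers: list[str] = field(default_factory=list)
    connectors: list[str] = field(default_factory=list)
    counting_mode: str = "document"  # document | mention
    top_k: int = 20
    normalized_betweenness: bool = False
    network_format: str = "graphml"
    seed: int = 0

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.corpus:
            raise ConfigError("corpus path is required")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if self.counting_mode not in ("document", "mention"):
            raise ConfigError(f"counting_mode must be 'document' or 'mention', got {self.counting_mode!r}")
        bad = set(self.category_prefixes) - set(CATEGORY_LABELS)
        if bad:
            raise ConfigError(f"unknown category labels in prefix overrides: {sorted(bad)}")
        for label, path in (("corpus", self.corpus), ("lexicon", self.lexicon), ("tree", self.tree)):
            if path and not Path(path).exists():
                raise ConfigError(f"{label} file not found: {path}")

    def categories(self) -> tuple[SemanticCategory, ...]:
        if not self.category_prefixes:
            return DEFAULT_CATEGORIES
        return tuple(
            SemanticCategory(c.label, tuple(self.category_prefixes.get(c.label, c.prefixes)))
            for c in DEFAULT_CATEGORIES
        )

    def ner_rules(self) -> NerRules:
        return NerRules(
            triggers=frozenset(t.lower() for t in self.triggers) or DEFAULT_TRIGGERS,
            connectors=frozenset(c.lower() for c in self.connectors) or DEFAULT_CONNECTORS,
        )


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    n_records: int
    n_occurrences: int
    n_unknown: int
    edge_counts: dict[str, int]
    version: str
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _annotations_tsv(annotations) -> tuple[str, str, int, int]:
    lines = ["pmid\tcanonical_name\tfield\tstart\tend\tsurface"]
    unknown_lines = ["pmid\tfield\tstart\tend\tsurface"]
    n_occ = 0
    for ann in annotations:
        for occ in ann.occurrences:
            n_occ += 1
            for m in occ.mentions:
                lines.append(f"{occ.pmid}\t{occ.canonical_name}\t{m.field}\t{m.start}\t{m.end}\t{m.surface}")
        for m in ann.unknown_candidates:
            unknown_lines.append(f"{ann.pmid}\t{m.field}\t{m.start}\t{m.end}\t{m.surface}")
    n_unknown = len(unknown_lines) - 1
    return "\n".join(lines) + "\n", "\n".join(unknown_lines) + "\n", n_occ, n_unknown


def _mention_counts(annotations) -> dict[str, int]:
    counts: dict[str, int] = {}
    for ann in annotations:
        for occ in ann.occurrences:
            counts[occ.canonical_name] = counts.get(occ.canonical_name, 0) + len(occ.mentions)
    return counts


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = read_medline_file(config.corpus)
    logger.info("parsed %d records from %s", len(records), config.corpus)
    lexicon = load_lexicon(Path(config.lexicon).read_text("utf-8")) if config.lexicon else default_lexicon()
    tree = load_mesh_tree(Path(config.tree).read_text("utf-8")) if config.tree else mini_tree()
    categories = config.categories()

    annotations = annotate_corpus(records, tree, lexicon, categories, config.ner_rules())
    ann_tsv, unknown_tsv, n_occ, n_unknown = _annotations_tsv(annotations)
    (outdir / "annotations.tsv").write_text(ann_tsv, encoding="utf-8")
    (outdir / "annotations.unknown.tsv").write_text(unknown_tsv, encoding="utf-8")
    logger.info("recognized %d scale occurrences (%d unknown candidates)", n_occ, n_unknown)

    counts = _mention_counts(annotations) if config.counting_mode == "mention" else None
    rows = frequency_table(annotations, top_k=config.top_k, counts=counts)
    freq_lines = ["rank\tcanonical_name\tcount\tpercentage"]
    for r in rows:
        freq_lines.append(f"{r.rank}\t{r.canonical_name}\t{r.count}\t{r.percentage:.2f}")
    (outdir / "frequency_table.tsv").write_text("\n".join(freq_lines) + "\n", encoding="utf-8")

    edge_counts: dict[str, int] = {}
    ext = {"graphml": "graphml", "gexf": "gexf", "csv": "csv"}[config.network_format]
    for cat in categories:
        net = build_network(annotations, {cat.label})
        bc = betweenness(net, normalized=config.normalized_betweenness)
        edge_counts[cat.label] = net.graph.number_of_edges()
        out = export_network(net, bc, format=config.network_format)
        if isinstance(out, dict):
            for name, text in out.items():
                (outdir / f"network_{cat.label}.{name}").write_text(text, encoding="utf-8")
        else:
            (outdir / f"network_{cat.label}.{ext}").write_text(out, encoding="utf-8")
        rank_lines = ["rank\tnode\tkind\tbetweenness"]
        ordered = sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))
        for i, (node, b) in enumerate(ordered, start=1):
            rank_lines.append(f"{i}\t{node}\t{net.graph.nodes[node]['kind']}\t{b:.6f}")
        (outdir / f"betweenness_{cat.label}.tsv").write_text("\n".join(rank_lines) + "\n", encoding="utf-8")
        logger.info("network %s: %d nodes, %d edges", cat.label, net.graph.number_of_nodes(), edge_counts[cat.label])

    if not records:
        logger.warning("empty corpus: artifacts are empty")

    manifest = RunManifest(
        config={k: getattr(config, k) for k in config.__dataclass_fields__},
        input_digests={p: _sha256(p) for p in (config.corpus, config.lexicon, config.tree) if p},
        n_records=len(records),
        n_occurrences=n_occ,
        n_unknown=n_unknown,
        edge_counts=edge_counts,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    (outdir / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest
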