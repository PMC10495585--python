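# Methods

## Problem and approach

`scalemine` characterizes how standardized mental-health instruments are
used across a body of literature. Each article contributes (a) instrument
mentions in its title/abstract and (b) curated MeSH indexing. Coupling the
two yields, per article, a set of (scale, MeSH term) pairs; aggregating
over a corpus gives document-frequency rankings and bipartite co-occurrence
networks whose structure (hubs, brokers) reflects which instruments
dominate which populations, topics, methods, regions and factors.

The recognizer is deliberately rule-based rather than statistical:
instrument names are a closed, conventionalized vocabulary with strong
surface regularities, a hand-curated lexicon is the de-facto standard for
normalizing them, and a rule system is auditable — every non-match is
routed to an unknown-candidate report instead of being silently dropped,
so the lexicon can be grown by curation.

## MEDLINE I/O

Records are exchanged in the PubMed field-tagged text format. Field
content parsing (tag collection, 6-space continuation joining) is
delegated to `Bio.Medline`; around it the module enforces the contracts
the pipeline needs: every physical line must be a field start, a
continuation or blank (violations are reported with their line number),
PMIDs must be unique, TI is mandatory, and MH values are split on `/` into
descriptor + qualifiers with the major-topic asterisk recorded (including
which segment carried it, so raw values re-serialize). The writer emits
one physical line per field — the format's wrapped lines are accepted on
input but never produced — which makes `parse(write(records))` an exact
identity; this is property-tested on generated corpora. Records without
abstracts are kept: titles alone can carry instrument mentions. Unknown
tags (AU, DP, ...) are preserved opaquely on read and omitted on write.

## NER rules

Candidate spans are maximal token runs that start at a capitalized
non-connector token and continue over capitalized tokens, digit-initial
tokens ("3-Item"), connectors (*of, for, and, the, in, to*) and trigger
nouns; a span never ends on a connector. A span is kept when it contains a
trigger noun (*Scale(s), Questionnaire, Inventory, Index, Checklist,
Instrument, Tool, Test, Survey, Measure, Schedule* — configurable, matched
case-insensitively and in numbered variants like "Scale-21") or is
immediately followed by a parenthesized all-caps/digit acronym, which is
absorbed so "Hospital Anxiety and Depression Scale (HADS)" is one
candidate. Two deliberate refinements:

- **Commas** continue a span only when the next token is capitalized and
  not a connector. This keeps "Depression, Anxiety and Stress Scale"
  intact while "… in China, the …" breaks.
- **Sub-span matching.** When a full candidate matches no lexicon entry,
  it is scanned for lexicon-known sub-spans, left-to-right and
  longest-first. Connector glue otherwise swallows neighbours
  ("… Wellness Scale and the GAD-7" is one maximal span containing two
  entities); the sub-scan recovers each, and preserves monotonicity:
  adding a lexicon entry never removes recognized occurrences.

Bare acronym tokens ("PHQ", "GAD-7") known to the lexicon are matched even
without a trigger, outside candidate spans. Acronym-only mentions are
counted like any other mention; this is a documented divergence risk when
comparing against corpora curated by hand. Unicode dashes are normalized
to ASCII hyphens before matching (length-preserving, so offsets always
index the original text; every mention's surface is asserted to equal its
source slice). Sentence boundaries are ignored; matching runs on raw field
text.

Frequency counting is **document-level** by default (an article counts
once per scale regardless of mention count); mention-level counting is
available via the pipeline's `counting_mode` flag.

## Lexicon and normalization

Surface forms are reduced to a matching key: lowercase; hyphens, commas
and whitespace runs collapsed to single spaces; a trailing parenthesized
acronym stripped; a leading article "the" stripped. The last rule is this
package's own addition so that "The PTSD Checklist for DSM-5 (PCL-5)" and
the in-text "PTSD Checklist for DSM-5" share a key. Keys index canonical
names, acronyms and aliases; a key claimed by two entries is a load-time
error listing the offenders, which forces explicit alias ownership —
ambiguous acronyms must be resolved by the curator, mirroring manual
standardization practice. Consequently numeric variants that share a bare
name can only be merged, not split: the default lexicon keeps one General
Health Questionnaire entry (GHQ-28 canonical, GHQ/GHQ-12 as aliases) and
one GAD entry (GAD-7/GAD-2 as aliases). The packaged default lexicon holds
33 instruments: the published top-20 ranking plus instruments named in the
surrounding pandemic literature (MBI, ISI, HAMA/HAMD, PCL-C, CPDI, CDAS,
CSS, FCV-19S, ...).

## MeSH classification

Descriptors map to semantic categories by tree-number prefix:
research_objects = M, research_methods = {N05, N06.850.520},
countries_regions = Z, research_topics = F, factors = G. Prefix matching
is on whole dot-groups ("N055.100" never matches "N05"); a bare-letter
prefix denotes its entire top-level branch ("M01.526" matches "M", since
the letter is the branch and "M01" its first subdivision). Prefix sets are
configuration — users who consider whole-letter F or G too coarse can
restrict categories to sub-branches. Qualifiers and major-topic flags are
ignored for classification; descriptors absent from the tree go to an
"unmapped" report rather than erroring. The packaged miniature tree
(~60 descriptors) is a synthetic fixture: real descriptor names with
plausible, non-authoritative tree numbers spanning all five branches
(including a dual-branch method descriptor to exercise label dedup); a
full NLM ASCII export loads through the same two-column TSV interface.

## Networks and metrics

Edge weight w(s, t) = number of articles containing both scale *s* and
filtered term *t*; each article contributes at most 1 per edge. Node
frequency = supporting-article count, so w ≤ min of endpoint frequencies
(checked as an invariant on every build). Betweenness uses Brandes'
algorithm on the **unweighted** topology — co-occurrence weights are
similarities, not distances, and the conventional treatment of such graphs
ranks brokerage by topological shortest paths. Unnormalized pair counts
are the default (3-path middle node = 1, 3-star hub = 3); the
normalization flag divides by (N−1)(N−2)/2. Rankings break ties
alphabetically for determinism. Correctness is dual-routed in tests:
Brandes vs an independently written all-pairs BFS geodesic enumerator,
exact to 1e−9 on 100 random graphs of ≤ 8 nodes.

Percentages in frequency tables are 100·count/total **truncated** to two
decimals via integer arithmetic (`10000*count // total / 100`), the
convention uniquely consistent with the published ranking this package
re-derives: a brute-force scan over candidate totals in [1000, 1300] finds
exactly one denominator (1110) reproducing all 20 printed cells, which
rounding does not. The denominator is the whole-corpus occurrence total,
not the sum of displayed rows.

Exports: GEXF 1.2 and GraphML with node attributes kind/category/
frequency/betweenness and edge weight, or nodes/edges CSV; GraphML
re-imports to an equal network (round-trip tested).

## Synthetic corpora

The generator emulates a pandemic-era PubMed download. Per article it
plants: a title (25% of scale-bearing articles carry the mention in the
title), an abstract assembled from filler, mention and optional distractor
sentences, and MH fields drawn per category from the tree. Conditions are
set by `SimConfig`; the demonstration default is 500 articles with one
scale drawn per article (10% of articles carry none) from a Zipf law with
exponent 1.1 over the 20 highest-frequency instruments, up to one term per
category (so 0–5 MeSH terms per article), and distractors in 30% of
abstracts. Explicit per-scale document frequencies can be planted instead
(sampled without replacement, so the sidecar frequency table is exact by
construction). `alias_prob` controls how often a mention uses an
acronym/alias surface instead of the canonical name; planted alias
surfaces are restricted to forms the rule set can spot standalone
(all-caps acronyms or trigger-bearing aliases), since a form like
"EuroQol-5D" alone matches no rule — such aliases stay in the lexicon for
normalization but are not planted. `cooccur_bias` multiplies the draw
weight of one designated partner term per (scale, category), creating the
hub structure the network analysis is meant to expose. Identical
seed + config yield byte-identical corpora (single `numpy` generator,
fixed iteration order).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: free-form scientific prose (sentences come
from a fixed template set), OCR/encoding noise, novel instruments absent
from the lexicon, ambiguous acronyms shared with non-instrument senses
(SAS software vs SAS scale), hyphenated line breaks, and MeSH indexing
error. Perfect planted recovery demonstrates internal consistency of
rules + lexicon + generator, not field performance of the NER.

## Pipeline and reproducibility

`run_pipeline` validates configuration before touching outputs (exit
code 2 from the CLI; parse failures exit 3), logs per-stage record counts,
and writes a manifest with SHA-256 input digests, stage counts and the
package version. Tabular outputs are byte-identical across re-runs on
identical inputs; the manifest's timestamp is the only non-reproducible
field. Problem sizes throughout tests and the acceptance script (500-article
corpora, 100-instance round-trip batches, ≤ 8-node oracle graphs) keep the
full suite in seconds while exercising every code path; they are sizes at
which the brute-force oracles are exact.

## Known limitations

- Rule-based NER cannot find instruments whose names violate the surface
  pattern (all-lowercase names, non-Latin scripts) and counts acronym-only
  mentions, which may differ from manually curated counts.
- Bare-name keys force merge-level granularity for numeric variants
  (GHQ-12 vs GHQ-28) unless the curator splits aliases explicitly.
- Letter-level category prefixes (F, G, M, Z) are coarse; sub-branch
  restriction is supported but the defaults follow the conventional
  five-category scheme.
- Co-occurrence is article-level: a scale and a term in the same article
  need not be semantically linked in its text.
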