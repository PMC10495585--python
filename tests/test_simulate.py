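"""Synthetic corpus generator: determinism, planted ground truth, distractors."""

import pytest

from scalemine.medline import write_medline
from scalemine.mesh import CATEGORY_LABELS
from scalemine.ner import annotate_corpus, recognize
from scalemine.network import build_network, frequency_table, scale_document_frequencies
from scalemine.simulate import GroundTruth, SimConfig, distractor_text, plantable_surfaces, simulate


def test_empty_corpus():
    recs, truth = simulate(SimConfig(n_articles=0), None, None)
    assert recs == [] and truth.articles == {}


def test_same_seed_byte_identical(lexicon, tree):
    cfg = SimConfig(n_articles=60, alias_prob=0.4, seed=11)
    a = write_medline(simulate(cfg, lexicon, tree)[0])
    b = write_medline(simulate(cfg, lexicon, tree)[0])
    assert a == b


def test_different_seed_differs(lexicon, tree):
    a = write_medline(simulate(SimConfig(n_articles=40, seed=1), lexicon, tree)[0])
    b = write_medline(simulate(SimConfig(n_articles=40, seed=2), lexicon, tree)[0])
    assert a != b


def test_requested_frequency_exceeding_corpus_rejected():
    with pytest.raises(ValueError, match="exceeds n_articles"):
        SimConfig(n_articles=5, scale_freq={"Coronavirus Anxiety Scale (CAS)": 6})


def test_explicit_frequencies_planted_exactly(lexicon, tree):
    freqs = {
        "Patient Health Questionnaire (PHQ)": 10,
        "Coronavirus Anxiety Scale (CAS)": 3,
    }
    cfg = SimConfig(n_articles=30, scale_freq=freqs, seed=5)
    _, truth = simulate(cfg, lexicon, tree)
    assert truth.frequency == freqs


def test_planted_spans_match_text(lexicon, tree):
    recs, truth = simulate(SimConfig(n_articles=40, alias_prob=0.5, seed=3), lexicon, tree)
    by_pmid = {r.pmid: r for r in recs}
    for pmid, art in truth.articles.items():
        rec = by_pmid[pmid]
        for _, fieldname, start, end, surface in art["mentions"]:
            text = rec.title if fieldname == "title" else rec.abstract
            assert text[start:end] == surface


def test_ground_truth_tables_aggregate_articles(lexicon, tree):
    _, truth = simulate(SimConfig(n_articles=50, seed=9, mesh_per_article=(1, 2)), lexicon, tree)
    assert sum(truth.frequency.values()) == sum(len(a["scales"]) for a in truth.articles.values())
    for label in CATEGORY_LABELS:
        total = sum(truth.edge_weights(label).values())
        manual = sum(
            len(a["scales"]) * len(a["mesh"][label]) for a in truth.articles.values()
        )
        assert total == manual


@pytest.mark.parametrize("alias_prob", [0.0, 0.5, 1.0])
def test_end_to_end_recovery(alias_prob, lexicon, tree):
    """Recognized (pmid, scale) pairs equal the planted pairs exactly."""
    recs, truth = simulate(SimConfig(n_articles=120, alias_prob=alias_prob, seed=21), lexicon, tree)
    anns = annotate_corpus(recs, tree, lexicon)
    got = {(a.pmid, s) for a in anns for s in a.scale_names()}
    assert got == truth.pairs
    assert scale_document_frequencies(anns) == truth.frequency


def test_distractors_only_give_zero_occurrences(lexicon):
    from scalemine.medline import ArticleRecord

    art = ArticleRecord(pmid="1", title="Plain title", abstract=" ".join(distractor_text()))
    occ, unknown = recognize(art, lexicon)
    assert occ == []
    assert any("Survey" in m.surface for m in unknown)  # trigger-noun distractor routed to report


def test_distractor_invariance(lexicon, tree):
    """Adding distractor sentences does not change the recovered pairs."""
    base = SimConfig(n_articles=80, seed=17, distractor_prob=0.0)
    noisy = SimConfig(n_articles=80, seed=17, distractor_prob=1.0)
    pairs = []
    for cfg in (base, noisy):
        recs, truth = simulate(cfg, lexicon, tree)
        anns = annotate_corpus(recs, tree, lexicon)
        got = {(a.pmid, s) for a in anns for s in a.scale_names()}
        assert got == truth.pairs
        pairs.append({(p, s) for p, s in truth.pairs})
    assert pairs[0] == pairs[1]


def test_plantable_surfaces_are_recognizable(lexicon):
    from scalemine.medline import ArticleRecord

    for entry in lexicon.entries[:20]:
        for surface in plantable_surfaces(entry):
            art = ArticleRecord(pmid="1", title="t", abstract=f"Participants completed the {surface} at baseline.")
            occ, _ = recognize(art, lexicon)
            assert {o.canonical_name for o in occ} == {entry.canonical_name}, surface


def test_scaling_leaves_percentages_unchanged(lexicon, tree):
    """Doubling planted frequencies at a fixed ratio keeps the percentage column."""
    base = {"Patient Health Questionnaire (PHQ)": 6, "Coronavirus Anxiety Scale (CAS)": 2}
    doubled = {k: 2 * v for k, v in base.items()}
    tables = []
    for freqs, n in ((base, 40), (doubled, 80)):
        recs, _ = simulate(SimConfig(n_articles=n, scale_freq=freqs, seed=2), lexicon, tree)
        anns = annotate_corpus(recs, tree, lexicon)
        tables.append([(r.canonical_name, r.percentage) for r in frequency_table(anns)])
    assert tables[0] == tables[1]


def test_cooccur_bias_inflates_partner_edges(lexicon, tree):
    cfg = SimConfig(
        n_articles=300,
        scales=("Patient Health Questionnaire (PHQ)",),
        cooccur_bias=50.0,
        mesh_per_article=(1, 1),
        p_no_scale=0.0,
        seed=4,
    )
    recs, truth = simulate(cfg, lexicon, tree)
    weights = truth.edge_weights("countries_regions")
    top_pair = max(weights, key=weights.get)
    assert weights[top_pair] > 0.5 * sum(weights.values())
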