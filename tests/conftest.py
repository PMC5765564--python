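import pytest

from esmine.annotator import AnnotationResources
from esmine.corpus_io import parse_pubmed_citations
from esmine.es_detector import (
    apply_plausibility_filter,
    default_lexicon,
    detect_es_mentions,
)
from esmine.synthetic_corpus import SimConfig, generate_corpus, gold_records_from_frame


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def resources():
    return AnnotationResources.load()


@pytest.fixture(scope="session")
def validation_corpus(lexicon):
    """A seeded 2160-abstract corpus at the default style/trap mixture,
    with detector predictions and rehydrated gold records."""
    cfg = SimConfig(months=(0, 24), abstracts_per_month=90, seed=20)
    result = generate_corpus(cfg)
    citations = list(parse_pubmed_citations(result.xml))
    predictions = []
    for cit in citations:
        if cit.abstract_text:
            found = detect_es_mentions(cit.abstract_text, lexicon, source_id=cit.pmid)
            predictions.extend(apply_plausibility_filter(found))
    gold = gold_records_from_frame(result.gold)
    universe = [c.pmid for c in citations]
    return {
        "config": cfg,
        "result": result,
        "citations": citations,
        "predictions": predictions,
        "gold": gold,
        "universe": universe,
    }
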