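"""Detector grammar, polysemy guard, plausibility filter, and scoring."""

import pytest

from esmine.es_detector import (
    ESMention,
    PerformanceReport,
    apply_plausibility_filter,
    compile_lexicon,
    detect_es_mentions,
    evaluate_detection,
    parse_ci_fragment,
)
from esmine.synthetic_corpus import GoldRecord


class TestCompileLexicon:
    def test_adjusted_acronym_maps_to_type_with_flag(self, lexicon):
        assert lexicon.es_terms["aOR"] == ("OR", True)
        assert lexicon.es_terms["aHR"] == ("HR", True)

    def test_wording_variants_recognized(self, lexicon):
        for text in ("the hazard-ratio was 2.0 (95% CI 1.5-2.7)",
                     "hazard ratios were 2.0 (95% CI 1.5-2.7)"):
            ms = detect_es_mentions(text, lexicon)
            assert [m.es_type for m in ms] == ["HR"]

    def test_duplicate_surface_form_rejected(self):
        config = {"terms": {
            "OR": {"acronym": "OR", "wordings": ["odds ratio"]},
            "RR": {"acronym": "OR", "wordings": ["risk ratio"]},
        }}
        with pytest.raises(ValueError, match="two types"):
            compile_lexicon(config)


class TestDetect:
    def test_adjusted_wording_with_apposition(self, lexicon):
        ms = detect_es_mentions(
            "The adjusted odds ratio (aOR) was 2.5 (95% CI, 1.5–4.2).", lexicon)
        assert len(ms) == 1
        m = ms[0]
        assert (m.es_type, m.adjusted, m.value) == ("OR", True, 2.5)
        assert (m.ci_level, m.ci_lower, m.ci_upper) == (95, 1.5, 4.2)

    def test_trap_phrase_suppresses_bare_acronym(self, lexicon):
        ms = detect_es_mentions(
            "Heart rate (HR) was 72 (95% CI, 68–76) at rest.", lexicon)
        assert ms == []

    def test_two_statements_with_default_ci_level(self, lexicon):
        ms = detect_es_mentions(
            "RR = 0.80 (95% CI 0.70 to 0.91); OR = 1.9 (1.1-3.3)", lexicon)
        assert len(ms) == 2
        rr, orr = ms
        assert (rr.es_type, rr.value, rr.ci_level, rr.ci_lower, rr.ci_upper) == \
            ("RR", 0.80, 95, 0.70, 0.91)
        assert (orr.es_type, orr.value, orr.ci_level, orr.ci_lower, orr.ci_upper) == \
            ("OR", 1.9, 95, 1.1, 3.3)
        assert "ci_level_imputed" in orr.flags

    def test_restrictive_mode_is_per_acronym(self, lexicon):
        text = ("Heart rate (HR) was monitored. HR = 0.85 (95% CI 0.75-0.96). "
                "OR = 1.9 (95% CI 1.1-3.3).")
        ms = detect_es_mentions(text, lexicon)
        assert [m.es_type for m in ms] == ["OR"]

    def test_restrictive_mode_keeps_full_wording(self, lexicon):
        text = ("Heart rate was monitored throughout. "
                "The hazard ratio was 0.85 (95% CI 0.75-0.96).")
        (m,) = detect_es_mentions(text, lexicon)
        assert m.es_type == "HR"
        assert "restrictive_mode" in m.flags

    def test_determinism(self, lexicon):
        text = "OR = 1.9 (95% CI 1.1-3.3) and RR: 0.8; 95% CI: 0.7 to 0.9."
        a = detect_es_mentions(text, lexicon)
        b = detect_es_mentions(text, lexicon)
        assert a == b

    def test_mentions_ordered_and_nonoverlapping(self, lexicon):
        text = ("aHR 0.85 [95% CI 0.75–0.96] for death. "
                "OR = 1.9 (1.1-3.3). RR 1.44, 95% CI 1.12 to 1.85,")
        ms = detect_es_mentions(text, lexicon)
        assert len(ms) == 3
        for prev, nxt in zip(ms, ms[1:]):
            assert prev.span[1] <= nxt.span[0]

    def test_span_substring_reparses_to_same_numbers(self, lexicon):
        text = ("Smoking was associated with stroke (OR, 2.5; 95% CI, 1.5-4.2). "
                "the relative risk was 1.44, 95% CI 1.12 to 1.85, overall.")
        for m in detect_es_mentions(text, lexicon):
            sub = text[m.span[0]: m.span[1]]
            (again,) = detect_es_mentions(sub, lexicon)
            assert (again.es_type, again.value, again.ci_lower, again.ci_upper) == \
                (m.es_type, m.value, m.ci_lower, m.ci_upper)

    def test_value_beyond_window_not_paired(self, lexicon):
        padding = "for the primary endpoint, after adjustment for age, sex, " \
                  "body mass index, smoking status, and study center,"
        text = f"The odds ratio {padding} was 1.9 (95% CI 1.1-3.3)."
        assert detect_es_mentions(text, lexicon) == []

    def test_no_ci_mention_flagged(self, lexicon):
        (m,) = detect_es_mentions("The odds ratio was 1.9 overall.", lexicon)
        assert m.ci_lower is None
        assert "no_ci" in m.flags


class TestParseCiFragment:
    @pytest.mark.parametrize("fragment,expected", [
        ("(95% CI, 1.23–4.96)", (95, 1.23, 4.96)),
        ("[99% confidence interval: 0.42 to 0.91]", (99, 0.42, 0.91)),
        ("(95 % CI 1.1-3.3)", (95, 1.1, 3.3)),
        ("; 90% CI: 0.70 to 0.91", (90, 0.70, 0.91)),
        ("(CI 95%, 1.08–1.61)", (95, 1.08, 1.61)),
        ("(1.1, 3.3)", (95, 1.1, 3.3)),      # comma range inside brackets
        ("(1,23–4,96)", (95, 1.23, 4.96)),   # decimal commas, both bounds
    ])
    def test_dialects(self, fragment, expected):
        ci = parse_ci_fragment(fragment)
        assert ci is not None
        assert (ci.level, ci.lower, ci.upper) == expected

    @pytest.mark.parametrize("fragment", [
        "(CI 1.10; 0.95)",        # reversed bounds
        " 1.1, 3.3 overall",      # comma range outside brackets
        "no interval here",
        "(4.2)",                  # single number
    ])
    def test_rejections(self, fragment):
        assert parse_ci_fragment(fragment) is None


class TestPlausibilityFilter:
    def _m(self, value, lo=None, hi=None):
        return ESMention(source_id="1", es_type="OR", adjusted=False,
                         value=value, ci_lower=lo, ci_upper=hi)

    def test_consistent_mention_retained(self):
        assert len(apply_plausibility_filter([self._m(2.5, 1.5, 4.2)])) == 1

    def test_value_outside_ci_dropped(self):
        assert apply_plausibility_filter([self._m(5.0, 1.2, 3.0)]) == []

    def test_rounding_tolerance(self):
        # value 1.0 against CI (1.02, 1.5): off by 2% of value — within 5%
        assert len(apply_plausibility_filter([self._m(1.0, 1.02, 1.5)])) == 1

    def test_ceiling(self):
        assert apply_plausibility_filter([self._m(20000.0)]) == []

    def test_numeric_only_no_polysemy_judgement(self):
        # a trap statement that leaked past the guard is numerically plausible
        assert len(apply_plausibility_filter([self._m(72.0, 68.0, 76.0)])) == 1


class TestEvaluateDetection:
    def _gold(self, sid, value=2.0, lo=1.5, hi=2.7, planted=True, es_type="OR"):
        return GoldRecord(source_id=sid, planted=planted, es_type=es_type,
                          value=value if planted else None,
                          ci_lower=lo if planted else None,
                          ci_upper=hi if planted else None,
                          trap_phrase="" if planted else "heart rate")

    def _pred(self, sid, value=2.0, lo=1.5, hi=2.7, es_type="OR"):
        return ESMention(source_id=sid, es_type=es_type, adjusted=False,
                         value=value, ci_lower=lo, ci_upper=hi)

    def test_perfect_agreement(self):
        gold = [self._gold(str(i)) for i in range(6)]
        preds = [self._pred(str(i)) for i in range(6)]
        universe = [str(i) for i in range(10)]
        r = evaluate_detection(gold, preds, unit="abstract", universe=universe)
        assert (r.sensitivity, r.specificity, r.kappa) == (1.0, 1.0, 1.0)

    def test_one_missed_positive(self):
        gold = [self._gold(str(i)) for i in range(6)]
        preds = [self._pred(str(i)) for i in range(5)]
        r = evaluate_detection(gold, preds, unit="abstract",
                               universe=[str(i) for i in range(10)])
        assert r.sensitivity == pytest.approx(5 / 6)
        assert r.specificity == 1.0

    def test_kappa_closed_form(self):
        # independent hand computation: po = 0.8, pe = 0.52, kappa = 0.28/0.48
        r = PerformanceReport(tp=5, fn=1, tn=3, fp=1)
        assert r.kappa == pytest.approx(0.28 / 0.48)
        assert r.kappa == pytest.approx(0.58333, abs=1e-5)

    def test_mention_unit_requires_exact_numbers(self):
        gold = [self._gold("1", value=2.0, lo=1.5, hi=2.7)]
        close = [self._pred("1", value=2.0, lo=1.5, hi=2.8)]
        r = evaluate_detection(gold, close, unit="mention")
        assert (r.tp, r.fn, r.fp) == (0, 1, 1)

    def test_unknown_identifier_rejected(self):
        with pytest.raises(ValueError, match="unknown corpus identifiers"):
            evaluate_detection([self._gold("99")], [], unit="mention", universe=["1"])


class TestTrapOnlyCorpus:
    def test_trap_only_specificity_one(self, lexicon):
        from esmine.corpus_io import parse_pubmed_citations
        from esmine.synthetic_corpus import SimConfig, generate_corpus

        cfg = SimConfig(months=(0, 3), abstracts_per_month=40,
                        p_has_es=0.0, trap_rate=1.0, seed=5)
        result = generate_corpus(cfg)
        assert (result.gold["planted"] == False).all()  # noqa: E712
        preds = []
        for cit in parse_pubmed_citations(result.xml):
            preds.extend(detect_es_mentions(cit.abstract_text, lexicon, source_id=cit.pmid))
        assert preds == []
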