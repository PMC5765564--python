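"""Synthetic PubMed-style corpora with planted effect sizes and ground truth.

The generator emulates the statistical structure the pipeline is built to
measure: abstracts carrying 0-k ratio-ES statements rendered in
heterogeneous textual styles; |ln ES| drawn from a half-normal whose scale
drifts linearly across the month range (so standardized values are
log-half-normal and monthly medians trend monotonically); geometric CIs
``(v e^-w, v e^+w)`` whose log-half-width has its own drift; a monthly
schedule for the probability that a CI excludes 1; trap sentences that reuse
the acronyms RR/OR/HR for non-ES quantities; and citation metadata (dates,
MeSH descriptors, journals, affiliations, publication types) drawn from the
shipped annotation resources.

Ground truth is recorded per mention *as rendered*: values and CI limits are
stored after decimal rounding, with the lower limit floored and the upper
ceiled at the style's precision, so the printed statement always brackets
its printed value and gold equals what a reader of the abstract would
record.  Trap sentences yield gold rows with ``planted = False``.

Generation is deterministic: one global seed drives an explicit per-abstract
substream (seeded by ``(seed, month, slot)``), so the same config yields
byte-identical XML and gold tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from lxml import etree

from esmine.es_transforms import classify_es

_MONTH_NAMES = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]

_WORDINGS = {"OR": "odds ratio", "RR": "relative risk", "HR": "hazard ratio"}

#: Journals sampled for citations beyond the shipped OA/CCJ lists.
_PLAIN_JOURNALS = [
    ("0895-4356", "Journal of Clinical Epidemiology"),
    ("1044-3983", "Epidemiology"),
    ("0300-5771", "International Journal of Epidemiology"),
    ("0000-0000", "Acta Epidemiologica Synthetica"),   # synthetic journal
    ("0042-9686", "Bulletin of the World Health Organization"),
]

_EXPOSURES = [
    "Smoking", "Obesity", "Hypertension", "Physical inactivity",
    "Alcohol consumption", "The polymorphism", "Statin use",
    "Low socioeconomic status", "Vitamin D deficiency", "The intervention",
]
_OUTCOMES = [
    "all-cause mortality", "incident diabetes", "stroke", "hip fracture",
    "disease progression", "treatment failure", "hospital readmission",
    "cardiovascular events", "preterm birth", "cognitive decline",
]
_FILLERS = [
    "We conducted a population-based cohort study.",
    "A total of {n} participants were included in the analysis.",
    "The mean age at baseline was {age} years.",
    "Median follow-up lasted {fu} months.",
    "Data were analyzed with standard statistical software.",
    "Outcomes were ascertained through registry linkage.",
    "Baseline characteristics were balanced between groups.",
]


# ---------------------------------------------------------------------------
# Gold records

@dataclass
class GoldRecord:
    """Ground truth for one planted ES statement or one trap sentence."""

    source_id: str
    planted: bool
    es_type: str
    adjusted: bool = False
    value: Optional[float] = None
    ci_level: Optional[int] = None
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    significant: Optional[bool] = None
    style: str = ""
    detectable: bool = True
    trap_phrase: str = ""
    month_index: int = -1
    review: bool = False
    precision: int = 2          # decimals used when the statement was printed


# ---------------------------------------------------------------------------
# Rendering styles

def _fmt(x: float, prec: int) -> str:
    return f"{x:.{prec}f}"


def _render_detectable(style: str, es_type: str, adjusted: bool,
                       v: str, level: int, lo: str, hi: str,
                       level_shown: bool) -> str:
    w = _WORDINGS[es_type]
    a = "a" + es_type
    lvl = f"{level}% CI"
    if style == "acr_eq":
        ci = f"({lvl} {lo}–{hi})" if level_shown else f"({lo}-{hi})"
        return f"{es_type} = {v} {ci}"
    if style == "acr_comma":
        return f"({es_type}, {v}; {lvl}, {lo}-{hi})"
    if style == "acr_colon":
        return f"{es_type}: {v}; {lvl}: {lo} to {hi}"
    if style == "wording_was":
        return f"the {w} was {v} ({level}% confidence interval: {lo} to {hi})"
    if style == "wording_acr_adj":
        return f"The adjusted {w} ({a}) was {v} ({lvl}, {lo}–{hi})"
    if style == "adj_acr_bracket":
        return f"{a} {v} [{lvl} {lo}–{hi}]"
    if style == "ci_first":
        return f"{es_type} {v} (CI {level}%, {lo}–{hi})"
    if style == "wording_to":
        return f"the {w} was {v}, {lvl} {lo} to {hi},"
    if style == "undetectable":
        padding = ("for the primary endpoint, after adjustment for age, sex, "
                   "body mass index, smoking status, and study center,")
        return f"The {w} {padding} was {v} ({lvl} {lo}-{hi})"
    raise ValueError(f"unknown style {style!r}")


#: Styles the detector is expected to recover exactly.
DETECTABLE_STYLES = [
    "acr_eq", "acr_comma", "acr_colon", "wording_was",
    "wording_acr_adj", "adj_acr_bracket", "ci_first", "wording_to",
]
ALL_STYLES = DETECTABLE_STYLES + ["undetectable"]

#: Styles whose statement carries the adjusted flag.
_ADJUSTED_STYLES = {"wording_acr_adj", "adj_acr_bracket"}
#: Styles rendered without an explicit CI level (value imputed downstream);
#: only used when the true level is 95 so imputation is correct.
_NO_LEVEL_CAPABLE = {"acr_eq"}

_TRAP_TEMPLATES = {
    "HR": [
        ("heart rate", "The mean heart rate (HR) was {n} beats per minute."),
        ("heart rate", "Resting heart rate (HR) was {n} ({lvl}% CI, {lo}–{hi}) at rest."),
    ],
    "RR": [
        ("respiratory rate", "The respiratory rate (RR) was {n} breaths/min on admission."),
        ("response rate", "The overall response rate (RR) was {pct}% in the treated arm."),
    ],
    "OR": [
        ("operating room", "All procedures were performed in the operating room (OR) within {n} minutes."),
        ("ovulation rate", "The ovulation rate (OR) was {pct}% per stimulated cycle."),
    ],
}


def render_mention(truth: GoldRecord, style: str, rng: np.random.Generator) -> str:
    """Render one gold record as a sentence in the requested style.

    For planted records the numbers are printed exactly as stored in the
    gold record; a context clause is sampled from a fixed phrase bank.  For
    trap records the registered trap template for the acronym is filled with
    non-ES numerics.
    """
    if not truth.planted:
        phrase_templates = [t for t in _TRAP_TEMPLATES[truth.es_type]
                            if t[0] == truth.trap_phrase] or _TRAP_TEMPLATES[truth.es_type]
        _phrase, template = phrase_templates[int(rng.integers(len(phrase_templates)))]
        n = int(rng.integers(55, 110))
        return template.format(
            n=n, pct=int(rng.integers(20, 80)), lvl=95, lo=n - 4, hi=n + 4,
        )
    if style not in ALL_STYLES:
        raise ValueError(f"unknown style {style!r}")
    prec = truth.precision
    v = _fmt(truth.value, prec)
    lo = _fmt(truth.ci_lower, prec)
    hi = _fmt(truth.ci_upper, prec)
    level_shown = not (style in _NO_LEVEL_CAPABLE and truth.ci_level == 95
                       and rng.random() < 0.5)
    statement = _render_detectable(
        style, truth.es_type, truth.adjusted, v, truth.ci_level, lo, hi, level_shown
    )
    exposure = _EXPOSURES[int(rng.integers(len(_EXPOSURES)))]
    outcome = _OUTCOMES[int(rng.integers(len(_OUTCOMES)))]
    if style in ("acr_comma",):
        return f"{exposure} was associated with {outcome} {statement}."
    if statement[0].isupper():
        return f"{statement} for {outcome}."
    return f"For {exposure.lower()} and {outcome}, {statement}."


def _precision_for(value: float, lower: float, style: str, rng: np.random.Generator) -> int:
    prec = int(rng.integers(2, 4))        # 2 or 3 decimals
    if style == "acr_eq" and rng.random() < 0.3 and value >= 1.5 and lower >= 1.2:
        prec = 1                           # occasional coarse rendering
    # the floored lower limit must stay strictly positive when printed
    while math.floor(lower * 10**prec) <= 0 and prec < 6:
        prec += 1
    return prec


# ---------------------------------------------------------------------------
# Simulation config

@dataclass
class SimConfig:
    """Study conditions for one synthetic corpus.

    Defaults mirror the real-corpus magnitudes the pipeline targets: monthly
    medians of standardized ESs drifting from ~2.5 down to ~2.1 over
    1990-2015 (half-normal scale on |ln ES| interpolating 1.36 -> 1.11),
    CI log-half-widths drifting 0.70 -> 0.54, and the share of significant
    ESs scheduled from 0.74 to 0.85.
    """

    months: tuple[int, int] = (0, 312)        # [start, stop) month indices
    abstracts_per_month: int = 30
    p_has_es: float = 0.3
    es_count_probs: tuple[float, ...] = (0.35, 0.25, 0.18, 0.12, 0.10)  # 1..5
    log_es_scale_start: float = 1.36
    log_es_scale_end: float = 1.11
    ci_halfwidth_start: float = 0.70
    ci_halfwidth_end: float = 0.54
    p_significant_start: Optional[float] = 0.74
    p_significant_end: Optional[float] = 0.85
    ci_level_mix: tuple[tuple[int, float], ...] = ((90, 0.05), (95, 0.90), (99, 0.05))
    trap_rate: float = 0.1
    style_mix: Optional[dict[str, float]] = None   # default: uniform detectable
    review_prob: float = 0.1
    p_cross_continental: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for p in (self.p_has_es, self.trap_rate, self.review_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not (0 <= self.months[0] < self.months[1] <= 312):
            raise ValueError("month range must lie within 0..311")
        if self.log_es_scale_start <= 0 or self.log_es_scale_end <= 0:
            raise ValueError("half-normal scales must be positive")
        if self.ci_halfwidth_start <= 0 or self.ci_halfwidth_end <= 0:
            raise ValueError("CI half-widths must be positive")
        if abs(sum(p for _, p in self.ci_level_mix) - 1) > 1e-9:
            raise ValueError("ci_level_mix must sum to 1")
        if self.style_mix:
            unknown = set(self.style_mix) - set(ALL_STYLES)
            if unknown:
                raise ValueError(f"unknown styles in style_mix: {sorted(unknown)}")


@dataclass
class CorpusResult:
    xml: bytes
    gold: pd.DataFrame
    paths: dict = field(default_factory=dict)


def _interp(start: float, end: float, frac: float) -> float:
    return start + (end - start) * frac


def _round_ci(value: float, lower: float, upper: float, prec: int):
    scale = 10.0**prec
    v = round(value, prec)
    lo = math.floor(lower * scale) / scale
    hi = math.ceil(upper * scale) / scale
    return v, lo, hi


def _draw_mention(rng: np.random.Generator, cfg: SimConfig, frac: float,
                  style: str, source_id: str, month: int, review: bool) -> GoldRecord:
    scale = _interp(cfg.log_es_scale_start, cfg.log_es_scale_end, frac)
    a = abs(rng.normal(0.0, scale))           # |ln ES|, half-normal
    a = min(a, math.log(50.0))                # keep printed values in range
    sign = 1.0 if rng.random() < 0.5 else -1.0
    log_v = sign * a

    w_sched = _interp(cfg.ci_halfwidth_start, cfg.ci_halfwidth_end, frac)
    w = w_sched * math.exp(rng.normal(0.0, 0.3))

    if cfg.p_significant_start is not None:
        p_sig = _interp(cfg.p_significant_start, cfg.p_significant_end, frac)
        want_sig = rng.random() < p_sig
        margin = max(0.1 * a, 0.01)
        if want_sig and a > 2 * margin:
            w = min(w, a - margin)            # CI excludes 1
        else:
            w = max(w, 1.05 * a + 0.02)       # CI encompasses 1
    w = max(w, 1e-3)

    value = math.exp(log_v)
    lower, upper = value * math.exp(-w), value * math.exp(w)

    levels, probs = zip(*cfg.ci_level_mix)
    level = int(rng.choice(levels, p=probs))

    prec = _precision_for(value, lower, style, rng)
    v_r, lo_r, hi_r = _round_ci(value, lower, upper, prec)
    if v_r <= 0:
        v_r = 10.0**-prec
    significant = classify_es(v_r, lo_r, hi_r).significant
    return GoldRecord(
        source_id=source_id,
        planted=True,
        es_type=["OR", "RR", "HR"][int(rng.integers(3))],
        adjusted=style in _ADJUSTED_STYLES,
        value=v_r,
        ci_level=level,
        ci_lower=lo_r,
        ci_upper=hi_r,
        significant=significant,
        style=style,
        detectable=style != "undetectable",
        month_index=month,
        review=review,
        precision=prec,
    )


def _build_citation_xml(source_id: str, month: int, abstract_sentences: list[str],
                        rng: np.random.Generator, cfg: SimConfig,
                        journal: tuple[str, str], review: bool,
                        mesh: list[str], countries: list[str]) -> etree._Element:
    year, mo = 1990 + month // 12, month % 12 + 1
    art = etree.Element("PubmedArticle")
    mc = etree.SubElement(art, "MedlineCitation")
    etree.SubElement(mc, "PMID").text = source_id
    article = etree.SubElement(mc, "Article")
    j = etree.SubElement(article, "Journal")
    etree.SubElement(j, "ISSN").text = journal[0]
    ji = etree.SubElement(j, "JournalIssue")
    pub_date = etree.SubElement(ji, "PubDate")
    style_roll = rng.random()
    if style_roll < 0.85:
        etree.SubElement(pub_date, "Year").text = str(year)
        etree.SubElement(pub_date, "Month").text = _MONTH_NAMES[mo - 1]
    elif style_roll < 0.95:
        etree.SubElement(pub_date, "Year").text = str(year)
        etree.SubElement(pub_date, "Month").text = str(mo)
    else:
        nxt = _MONTH_NAMES[mo % 12]
        nxt_year = year + (1 if mo == 12 else 0)
        etree.SubElement(pub_date, "MedlineDate").text = (
            f"{year} {_MONTH_NAMES[mo - 1]}-{nxt_year} {nxt}"
        )
    etree.SubElement(j, "Title").text = journal[1]
    etree.SubElement(article, "ArticleTitle").text = (
        f"A synthetic study of {_OUTCOMES[int(rng.integers(len(_OUTCOMES)))]}."
    )
    if abstract_sentences:
        abstract = etree.SubElement(article, "Abstract")
        if rng.random() < 0.25 and len(abstract_sentences) >= 3:
            cut1 = len(abstract_sentences) // 3
            cut2 = 2 * len(abstract_sentences) // 3
            chunks = [("BACKGROUND", abstract_sentences[:cut1]),
                      ("METHODS", abstract_sentences[cut1:cut2]),
                      ("RESULTS", abstract_sentences[cut2:])]
            for label, sents in chunks:
                if sents:
                    at = etree.SubElement(abstract, "AbstractText")
                    at.set("Label", label)
                    at.text = " ".join(sents)
        else:
            etree.SubElement(abstract, "AbstractText").text = " ".join(abstract_sentences)
    author_list = etree.SubElement(article, "AuthorList")
    for country in countries:
        author = etree.SubElement(author_list, "Author")
        etree.SubElement(author, "LastName").text = "Author"
        ai = etree.SubElement(author, "AffiliationInfo")
        etree.SubElement(ai, "Affiliation").text = (
            f"Department of Epidemiology, University Hospital, {country}."
        )
    ptl = etree.SubElement(article, "PublicationTypeList")
    etree.SubElement(ptl, "PublicationType").text = "Journal Article"
    if review:
        etree.SubElement(ptl, "PublicationType").text = "Review"
    mh_list = etree.SubElement(mc, "MeshHeadingList")
    for d in mesh:
        mh = etree.SubElement(mh_list, "MeshHeading")
        etree.SubElement(mh, "DescriptorName").text = d
    pubmed_data = etree.SubElement(art, "PubmedData")
    etree.SubElement(etree.SubElement(pubmed_data, "ArticleIdList"), "ArticleId",
                     IdType="pubmed").text = source_id
    return art


def generate_corpus(config: SimConfig, out_dir: Optional[str | Path] = None) -> CorpusResult:
    """Generate a PubmedArticleSet XML corpus plus its gold table.

    Fully deterministic given ``config.seed``.  When ``out_dir`` is given,
    writes ``corpus.xml``, ``gold.tsv`` and a ``config.json`` echo there and
    records the paths in the result.
    """
    config.validate()
    from esmine.annotator import AnnotationResources   # journals/countries/MeSH pools

    res = AnnotationResources.load()
    mesh_pool = sorted(res.mesh_tree)
    country_rows = sorted(res.gazetteer.continent)
    journal_pool = (
        [(issn, title) for issn, title in _read_journal_list("ccj_journals.tsv")]
        + [(issn, title) for issn, title in _read_journal_list("oa_journals.tsv")]
        + _PLAIN_JOURNALS
    )

    style_mix = config.style_mix or {s: 1.0 for s in DETECTABLE_STYLES}
    style_names = sorted(style_mix)
    style_probs = np.array([style_mix[s] for s in style_names], dtype=float)
    style_probs = style_probs / style_probs.sum()

    root = etree.Element("PubmedArticleSet")
    gold_rows: list[GoldRecord] = []
    counter = 0
    m_start, m_stop = config.months
    span = max(m_stop - 1 - m_start, 1)
    for month in range(m_start, m_stop):
        frac = (month - m_start) / span
        for slot in range(config.abstracts_per_month):
            counter += 1
            rng = np.random.default_rng((config.seed, month, slot))
            source_id = str(10_000_000 + counter)
            review = rng.random() < config.review_prob

            sentences = []
            n_fill = int(rng.integers(2, 5))
            for _ in range(n_fill):
                t = _FILLERS[int(rng.integers(len(_FILLERS)))]
                sentences.append(t.format(
                    n=int(rng.integers(100, 20000)),
                    age=int(rng.integers(35, 75)),
                    fu=int(rng.integers(6, 120)),
                ))

            if rng.random() < config.p_has_es:
                k = 1 + int(rng.choice(len(config.es_count_probs),
                                       p=np.asarray(config.es_count_probs)
                                       / sum(config.es_count_probs)))
                for _ in range(k):
                    style = style_names[int(rng.choice(len(style_names), p=style_probs))]
                    g = _draw_mention(rng, config, frac, style, source_id, month, review)
                    gold_rows.append(g)
                    sentences.append(render_mention(g, style, rng))

            if rng.random() < config.trap_rate:
                es_type = ["OR", "RR", "HR"][int(rng.integers(3))]
                phrase, _t = _TRAP_TEMPLATES[es_type][int(rng.integers(len(_TRAP_TEMPLATES[es_type])))]
                g = GoldRecord(
                    source_id=source_id, planted=False, es_type=es_type,
                    trap_phrase=phrase, month_index=month, review=review,
                )
                gold_rows.append(g)
                sentences.append(render_mention(g, "", rng))

            journal = journal_pool[int(rng.integers(len(journal_pool)))]
            mesh = list(rng.choice(mesh_pool, size=int(rng.integers(1, 5)), replace=False))
            n_countries = 2 if rng.random() < config.p_cross_continental else 1
            countries = [country_rows[int(rng.integers(len(country_rows)))]
                         for _ in range(n_countries)]
            root.append(_build_citation_xml(
                source_id, month, sentences, rng, config, journal, review, mesh, countries,
            ))

    xml_bytes = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    gold = pd.DataFrame([asdict(g) for g in gold_rows])

    paths: dict = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "corpus.xml").write_bytes(xml_bytes)
        gold.to_csv(out_dir / "gold.tsv", sep="\t", index=False)
        (out_dir / "config.json").write_text(json.dumps(asdict(config), indent=2, default=str))
        paths = {
            "xml": str(out_dir / "corpus.xml"),
            "gold": str(out_dir / "gold.tsv"),
            "config": str(out_dir / "config.json"),
        }
    return CorpusResult(xml=xml_bytes, gold=gold, paths=paths)


def _read_journal_list(name: str):
    import csv
    from importlib import resources as importlib_resources

    text = importlib_resources.files("esmine.resources").joinpath(name).read_text()
    return [(row["issn"], row["title"]) for row in csv.DictReader(text.splitlines(), delimiter="\t")]


def gold_records_from_frame(gold: pd.DataFrame) -> list[GoldRecord]:
    """Rehydrate `GoldRecord`s from a gold table read back from TSV."""
    records = []
    for row in gold.itertuples(index=False):
        d = row._asdict()
        for key in ("value", "ci_lower", "ci_upper"):
            if pd.isna(d.get(key)):
                d[key] = None
        for key in ("ci_level",):
            d[key] = None if pd.isna(d.get(key)) else int(d[key])
        if pd.isna(d.get("significant")):
            d["significant"] = None
        d["source_id"] = str(d["source_id"])
        d["trap_phrase"] = "" if pd.isna(d.get("trap_phrase")) else d["trap_phrase"]
        d["style"] = "" if pd.isna(d.get("style")) else d["style"]
        records.append(GoldRecord(**d))
    return records
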