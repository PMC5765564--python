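"""Detection of ratio effect-size statements (OR/RR/HR) in free text.

The detector pairs an effect-size term (acronym, adjusted acronym, or full
wording) with the nearest following numeric value inside a bounded statement
window, then parses a confidence interval from the trailing context.  Two
guards keep precision high:

* **Acronym polysemy.**  Many medical abbreviations collide with ES acronyms
  ("heart rate" for HR, "respiratory rate" for RR, "ovulation rate" for OR).
  If a trap wording occurs anywhere in the text, detection of that acronym
  switches to a restrictive procedure: bare-acronym mentions are suppressed
  and only unambiguous statements (full wording, or adjusted acronym backed
  by a confidence interval) are kept, flagged ``restrictive_mode``.
* **Numeric plausibility.**  Values outside (0, ceiling] or inconsistent with
  their own confidence interval (beyond a relative rounding tolerance) are
  dropped, with the removal reason logged.

Windows are deliberately local: a candidate value must appear within
``VALUE_WINDOW`` characters after the term with no second ES term in
between, and the CI is searched in the ``CI_WINDOW`` characters after the
value.  Statements whose value drifts beyond these windows are accepted
false negatives.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

ES_TYPES = ("OR", "RR", "HR")

VALUE_WINDOW = 80   # chars after the term in which the value must occur
CI_WINDOW = 120     # chars after the value in which the CI must start

# Unicode minus and exotic spaces normalized 1:1 so spans keep their offsets.
_CHAR_MAP = {0x2212: "-", 0x00A0: " ", 0x2009: " ", 0x200A: " ", 0x202F: " "}


# ---------------------------------------------------------------------------
# Lexicon

@dataclass
class DetectorLexicon:
    """Compiled surface forms for ES terms plus the trap-phrase registry."""

    es_terms: dict[str, tuple[str, bool]]            # surface -> (type, adjusted)
    trap_phrases: dict[str, set[str]]                # acronym/type -> wordings
    term_pattern: re.Pattern = field(repr=False, default=None)
    group_info: dict[str, tuple[str, bool, str]] = field(repr=False, default_factory=dict)
    trap_patterns: dict[str, re.Pattern] = field(repr=False, default_factory=dict)


def _wording_regex(wording: str, optional_adjusted: bool = True) -> str:
    """Regex for a full wording tolerating plural, hyphen, or extra spaces."""
    words = wording.split()
    body = r"[\s\-]+".join(re.escape(w) for w in words[:-1] + [])
    last = re.escape(words[-1]) + r"s?"
    joined = (body + r"[\s\-]+" + last) if len(words) > 1 else last
    if optional_adjusted:
        return r"(?:[Aa]djusted[\s\-]+)?" + joined
    return joined


def compile_lexicon(term_config: Mapping) -> DetectorLexicon:
    """Compile a term/trap config mapping into a `DetectorLexicon`.

    ``term_config`` has two keys: ``terms`` (per canonical type: ``acronym``,
    ``adjusted_acronyms``, ``wordings``) and ``traps`` (per acronym: list of
    non-ES full wordings).  Acronyms match case-sensitively at word
    boundaries; wordings match case-insensitively with optional plural,
    hyphens, or an ``adjusted`` prefix.  A surface form mapped to two
    canonical types is a configuration error.
    """
    es_terms: dict[str, tuple[str, bool]] = {}
    alternates = []  # (regex fragment, group name)
    group_info: dict[str, tuple[str, bool, str]] = {}  # group -> (type, adjusted, kind)
    gi = 0

    def add(fragment: str, es_type: str, adjusted: bool, kind: str) -> None:
        nonlocal gi
        name = f"t{gi}"
        gi += 1
        alternates.append(f"(?P<{name}>{fragment})")
        group_info[name] = (es_type, adjusted, kind)

    for es_type, spec in term_config.get("terms", {}).items():
        if es_type not in ES_TYPES:
            raise ValueError(f"unknown canonical ES type {es_type!r}")
        # wordings first so longer matches win over embedded acronyms
        for wording in spec.get("wordings", []):
            key = wording.lower()
            if key in es_terms and es_terms[key][0] != es_type:
                raise ValueError(f"surface form {wording!r} mapped to two types")
            es_terms[key] = (es_type, False)
            add(r"(?i:" + _wording_regex(wording) + r")", es_type, False, "wording")
        for acr in spec.get("adjusted_acronyms", []):
            if acr in es_terms and es_terms[acr][0] != es_type:
                raise ValueError(f"surface form {acr!r} mapped to two types")
            es_terms[acr] = (es_type, True)
            add(r"\b" + re.escape(acr) + r"s?\b", es_type, True, "adj_acronym")
        acronym = spec.get("acronym")
        if acronym:
            if acronym in es_terms and es_terms[acronym][0] != es_type:
                raise ValueError(f"surface form {acronym!r} mapped to two types")
            es_terms[acronym] = (es_type, False)
            add(r"\b" + re.escape(acronym) + r"s?\b", es_type, False, "acronym")

    term_pattern = re.compile("|".join(alternates))

    trap_phrases: dict[str, set[str]] = {}
    trap_patterns: dict[str, re.Pattern] = {}
    for es_type, phrases in term_config.get("traps", {}).items():
        trap_phrases[es_type] = set(phrases)
        frags = [_wording_regex(p, optional_adjusted=False) for p in phrases]
        trap_patterns[es_type] = re.compile("|".join(frags), re.I)

    return DetectorLexicon(
        es_terms=es_terms,
        trap_phrases=trap_phrases,
        term_pattern=term_pattern,
        group_info=group_info,
        trap_patterns=trap_patterns,
    )


def default_lexicon() -> DetectorLexicon:
    """The lexicon shipped with the package (see ``resources/lexicon.yaml``)."""
    text = importlib_resources.files("esmine.resources").joinpath("lexicon.yaml").read_text()
    return compile_lexicon(yaml.safe_load(text))


def load_lexicon(path: str | Path) -> DetectorLexicon:
    with open(path) as fh:
        return compile_lexicon(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Mention and CI types

@dataclass
class CIParse:
    """A parsed confidence interval with canonical lower <= upper."""

    lower: float
    upper: float
    level: int | None = None


@dataclass
class ESMention:
    """One detected effect-size statement."""

    source_id: str
    es_type: str
    adjusted: bool
    value: float
    ci_level: int | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    span: tuple[int, int] = (0, 0)
    flags: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# CI grammar

_NUM = r"\d+(?:[.,]\d+)?"
# range separators; the plain comma is handled separately (brackets only)
_SEP = r"(?:\s*(?:-|–|—|to|;)\s*)"
_LEVEL = r"(?:90|95|99)"

_CI_RE = re.compile(
    rf"""
    (?P<lead>[\s,;:=]{{0,3}}(?:(?:with|and|at)\s+an?\s+|with\s+|and\s+|at\s+)?)
    (?P<open>[\(\[])?\s*
    (?:
        (?P<lvl1>{_LEVEL})\s*%\s*(?:C\.?I\.?s?|confidence\s+intervals?)
      | C\.?I\.?s?\s*(?P<lvl2>{_LEVEL})\s*%
      | (?P<bare>confidence\s+intervals?|C\.?I\.?s?)
    )?
    \s*[:,=]?\s*(?:of\s+|was\s+|were\s+)?
    (?P<lo>{_NUM})
    (?P<sep>{_SEP}|\s*,\s*)
    (?P<hi>{_NUM})
    """,
    re.I | re.X,
)


def _decimal(tok: str) -> float | None:
    """Parse a bound, converting a decimal comma only in the d+,d{1,2} form."""
    if "," in tok:
        if re.fullmatch(r"\d+,\d{1,2}", tok):
            tok = tok.replace(",", ".")
        else:
            return None
    return float(tok)


def _parse_ci(fragment: str) -> tuple[CIParse | None, set[str]]:
    """Parse the post-value context; returns (ci_or_none, flags)."""
    m = _CI_RE.match(fragment)
    if not m:
        return None, set()
    has_intro = bool(m.group("lvl1") or m.group("lvl2") or m.group("bare"))
    bracketed = bool(m.group("open")) and fragment[m.end():].lstrip()[:1] in (")", "]")
    comma_sep = m.group("sep").strip() == ","
    if not has_intro and not bracketed:
        return None, set()          # a bare number pair must be bracketed
    if comma_sep and not bracketed:
        return None, set()          # comma range accepted only inside brackets
    lo_tok, hi_tok = m.group("lo"), m.group("hi")
    if comma_sep and ("," in lo_tok or "," in hi_tok):
        return None, set()
    lower = _decimal(lo_tok)
    upper = _decimal(hi_tok)
    if lower is None or upper is None or lower <= 0 or upper <= 0:
        return None, set()
    if lower > upper:
        return None, {"bounds_swapped_discarded"}
    level_tok = m.group("lvl1") or m.group("lvl2")
    flags: set[str] = set()
    if level_tok:
        level = int(level_tok)
    else:
        level = 95
        flags.add("ci_level_imputed")
    return CIParse(lower=lower, upper=upper, level=level), flags


def parse_ci_fragment(fragment: str) -> CIParse | None:
    """Parse a CI from the context window following a candidate value.

    Recognized dialects: level-first ("95% CI", "95 % CI", "95% confidence
    interval"), level-last ("CI 95%"), level-less ("CI", "confidence
    interval", or a bare bracketed range); brackets ``()``, ``[]`` or none;
    range separators ``-`` ``–`` ``—`` ``to`` ``;`` and, inside brackets
    only, ``,``.  A level-less CI is canonicalized to level 95.  Reversed
    bounds make the parse fail (the caller records why).
    """
    fragment = fragment.translate(_CHAR_MAP)
    ci, _flags = _parse_ci(fragment)
    return ci


# ---------------------------------------------------------------------------
# Detection

# candidate value: a standalone number not attached to '%' (percentages are
# never ratio ESs) and not glued to another number or letter
_VALUE_RE = re.compile(rf"(?<![\d.\w])({_NUM})(?!\s*%)(?!\.?\d)")

_APPOSITION = re.compile(r"\s*\(\s*(a|adj)?(OR|RR|HR)s?\s*\)")


def _find_terms(text: str, lexicon: DetectorLexicon):
    """All ES-term occurrences: (start, end, type, adjusted, kind), merged
    with an immediately following parenthesized acronym apposition."""
    out = []
    info = lexicon.group_info
    for m in lexicon.term_pattern.finditer(text):
        es_type, adjusted, kind = info[m.lastgroup]
        start, end = m.span()
        if kind == "wording":
            if re.match(r"[Aa]djusted[\s\-]", m.group()):
                adjusted = True
            ap = _APPOSITION.match(text, end)
            if ap and ap.group(2) == es_type:
                end = ap.end()
                adjusted = adjusted or ap.group(1) is not None
        out.append((start, end, es_type, adjusted, kind))
    # drop overlaps (an acronym inside an already-matched wording span)
    out.sort(key=lambda t: (t[0], -(t[1] - t[0])))
    merged = []
    last_end = -1
    for t in out:
        if t[0] < last_end:
            continue
        merged.append(t)
        last_end = t[1]
    return merged


def detect_es_mentions(
    text: str,
    lexicon: DetectorLexicon | None = None,
    source_id: str = "",
) -> list[ESMention]:
    """Detect effect-size statements in one extraction channel.

    Deterministic; returns non-overlapping mentions ordered by span.  Trap
    wordings anywhere in the text put their acronym into restrictive mode
    for the whole text (see module docstring).  Undetectable statements are
    silently absent rather than errors.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    text = text.translate(_CHAR_MAP)

    restrictive = {
        es_type for es_type, pat in lexicon.trap_patterns.items() if pat.search(text)
    }

    terms = _find_terms(text, lexicon)
    mentions: list[ESMention] = []
    consumed_until = -1
    for i, (t_start, t_end, es_type, adjusted, kind) in enumerate(terms):
        if t_start < consumed_until:
            continue
        window_end = min(t_end + VALUE_WINDOW, len(text))
        if i + 1 < len(terms):
            window_end = min(window_end, terms[i + 1][0])
        vm = _VALUE_RE.search(text, t_end, window_end)
        if not vm:
            continue
        value = _decimal(vm.group(1))
        if value is None or value <= 0:
            continue
        ci_fragment = text[vm.end(): vm.end() + CI_WINDOW]
        ci, flags = _parse_ci(ci_fragment)
        span_end = vm.end()
        if ci is not None:
            m2 = _CI_RE.match(ci_fragment)
            span_end = vm.end() + m2.end()
            close = text[span_end: span_end + 2].lstrip()[:1]
            if close in (")", "]"):
                span_end = text.index(close, span_end) + 1
        mention = ESMention(
            source_id=source_id,
            es_type=es_type,
            adjusted=adjusted,
            value=value,
            ci_level=ci.level if ci else None,
            ci_lower=ci.lower if ci else None,
            ci_upper=ci.upper if ci else None,
            span=(t_start, span_end),
            flags=flags,
        )
        if ci is None:
            mention.flags.add("no_ci")
        if es_type in restrictive:
            # bare acronym suppressed; adjusted acronym needs a CI to count
            if kind == "acronym":
                continue
            if kind == "adj_acronym" and ci is None:
                continue
            mention.flags.add("restrictive_mode")
        mentions.append(mention)
        consumed_until = span_end
    return mentions


def apply_plausibility_filter(
    mentions: Iterable[ESMention],
    ceiling: float = 10_000.0,
    rel_tol: float = 0.05,
) -> list[ESMention]:
    """Drop mentions whose numbers cannot plausibly be ratio effect sizes.

    A mention is removed when its value is outside (0, ``ceiling``], or when
    a CI is present and the value lies outside [lower, upper] by more than
    ``rel_tol``  ×  value (rounding slack).  CI-less mentions are retained and
    keep their ``no_ci`` flag; values are never modified.  All removals are
    logged with their reason.  Polysemy is the detector's job: a trap
    statement that leaked past the guard is not re-filtered here.
    """
    kept: list[ESMention] = []
    for m in mentions:
        if m.value <= 0 or m.value > ceiling:
            logger.info("mention dropped (value %.4g outside (0, %g])", m.value, ceiling)
            continue
        if m.ci_lower is not None and m.ci_upper is not None:
            slack = rel_tol * m.value
            if m.value < m.ci_lower - slack or m.value > m.ci_upper + slack:
                logger.info(
                    "mention dropped (value %.4g outside CI [%.4g, %.4g])",
                    m.value, m.ci_lower, m.ci_upper,
                )
                m.flags.add("value_outside_ci")
                continue
        kept.append(m)
    return kept


# ---------------------------------------------------------------------------
# Diagnostic performance

@dataclass
class PerformanceReport:
    """Confusion counts with sensitivity, specificity and Cohen's kappa."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def kappa(self) -> float:
        n = self.tp + self.fp + self.tn + self.fn
        if n == 0:
            return float("nan")
        po = (self.tp + self.tn) / n
        pe = (
            (self.tp + self.fn) * (self.tp + self.fp)
            + (self.tn + self.fp) * (self.tn + self.fn)
        ) / (n * n)
        if pe == 1.0:
            return 1.0 if po == 1.0 else 0.0
        return (po - pe) / (1 - pe)


def _mention_key(es_type: str, value: float, lower, upper) -> tuple:
    def r(x):
        return None if x is None or (isinstance(x, float) and x != x) else round(float(x), 6)
    return (es_type, r(value), r(lower), r(upper))


def evaluate_detection(
    gold: Sequence,
    predicted: Sequence[ESMention],
    unit: str = "mention",
    universe: Iterable[str] | None = None,
) -> PerformanceReport:
    """Score detector output against a gold standard.

    ``unit="abstract"`` counts each abstract once: positive when it carries at
    least one detectable planted statement, predicted-positive when the
    detector reports any mention; ``universe`` must list every abstract id in
    the corpus (pure negatives carry no gold rows).  ``unit="mention"``
    requires type, value, and both CI limits to match exactly after
    canonicalization; trap records are the negative units, and a trap counts
    as a true negative when no unmatched prediction of its type exists in its
    abstract.  Gold records flagged undetectable (value rendered beyond the
    statement window) are excluded from scoring.

    Raises ``ValueError`` when gold or predictions refer to abstracts outside
    ``universe``.
    """
    gold = [g for g in gold if getattr(g, "detectable", True) or not g.planted]
    if universe is not None:
        ids = set(universe)
        stray = {g.source_id for g in gold} - ids
        stray |= {p.source_id for p in predicted} - ids
        if stray:
            raise ValueError(f"records refer to unknown corpus identifiers: {sorted(stray)[:5]}")

    if unit == "abstract":
        if universe is None:
            raise ValueError("abstract-level evaluation requires the corpus universe")
        pos = {g.source_id for g in gold if g.planted}
        pred_pos = {p.source_id for p in predicted}
        tp = fp = tn = fn = 0
        for sid in ids:
            if sid in pos:
                if sid in pred_pos:
                    tp += 1
                else:
                    fn += 1
            else:
                if sid in pred_pos:
                    fp += 1
                else:
                    tn += 1
        return PerformanceReport(tp=tp, fp=fp, tn=tn, fn=fn)

    if unit != "mention":
        raise ValueError(f"unknown evaluation unit {unit!r}")

    pred_pool: dict[str, list[ESMention]] = {}
    for p in predicted:
        pred_pool.setdefault(p.source_id, []).append(p)

    tp = fn = 0
    for g in gold:
        if not g.planted:
            continue
        key = _mention_key(g.es_type, g.value, g.ci_lower, g.ci_upper)
        pool = pred_pool.get(g.source_id, [])
        hit = next(
            (p for p in pool if _mention_key(p.es_type, p.value, p.ci_lower, p.ci_upper) == key),
            None,
        )
        if hit is not None:
            tp += 1
            pool.remove(hit)
        else:
            fn += 1

    leftovers = [p for pool in pred_pool.values() for p in pool]
    fp = len(leftovers)
    leftover_types = {}
    for p in leftovers:
        leftover_types.setdefault(p.source_id, []).append(p.es_type)
    tn = 0
    for g in gold:
        if g.planted:
            continue
        types = leftover_types.get(g.source_id, [])
        if g.es_type in types:
            types.remove(g.es_type)   # this trap attracted a false positive
        else:
            tn += 1
    return PerformanceReport(tp=tp, fp=fp, tn=tn, fn=fn)


def mentions_to_rows(mentions: Iterable[ESMention]) -> list[dict]:
    """Flatten mentions into the ES-table row schema (see corpus_io)."""
    rows = []
    for m in mentions:
        rows.append({
            "source_id": m.source_id,
            "es_type": m.es_type,
            "adjusted": m.adjusted,
            "value": m.value,
            "ci_level": m.ci_level,
            "ci_lower": m.ci_lower,
            "ci_upper": m.ci_upper,
            "span_start": m.span[0],
            "span_end": m.span[1],
            "flags": ",".join(sorted(m.flags)),
        })
    return rows
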