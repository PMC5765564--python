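"""Scale transformations, classification, and per-abstract condensation.

Ratio effect sizes live on a log scale: protective values in (0, 1), risk
values in (1, inf).  Four transformation modes are supported:

* ``T4`` — raw value (no transformation);
* ``T2`` — ``ln(value)`` (normalized: symmetric around 0);
* ``T1`` — standardized on the original scale: protective values are
  inverted (``1/value``), risk values kept, so every ES sits in [1, inf);
* ``T3`` — normalized then standardized, reported back on the linear scale:
  ``exp(|ln value|)``.

T1 and T3 coincide pointwise (both equal ``max(v, 1/v)``); they differ in
how an abstract's multiple ESs are aggregated — T3 averages on the log scale
(geometric mean of standardized values), which is what
:func:`condense_abstract` uses for the mean outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from esmine.es_detector import ESMention

#: Classification thresholds for the magnitude of an ES (inclusive bounds).
LARGE_LOW, LARGE_HIGH = 0.2, 5.0
TINY_LOW, TINY_HIGH = 0.95, 1.05


@dataclass
class ESClass:
    """Direction, magnitude class, and significance of a single ES."""

    direction: str                    # "risk" | "protective" | "neutral"
    magnitude: str                    # "large" | "tiny" | "other"
    significant: Optional[bool]       # None when no CI is available


@dataclass
class AbstractSummary:
    """Per-abstract condensed outcomes, keyed by month since 1990-01."""

    source_id: str
    month_index: Optional[int]
    n_es: int
    es_min: float
    es_max: float
    es_mean: float
    cimag_min: Optional[float]
    cimag_max: Optional[float]
    cimag_mean: Optional[float]
    any_significant: bool
    prop_significant: float
    strata: dict = field(default_factory=dict)


def transform_es(value: float, mode: str = "T3") -> float:
    """Apply one of the four transformation modes to a positive ratio ES."""
    if value <= 0:
        raise ValueError(f"effect size must be positive, got {value}")
    if mode == "T4":
        return value
    if mode == "T2":
        return math.log(value)
    if mode in ("T1", "T3"):
        return value if value >= 1 else 1.0 / value
    raise ValueError(f"unknown transformation mode {mode!r}")


def classify_es(
    value: float,
    ci_lower: Optional[float] = None,
    ci_upper: Optional[float] = None,
) -> ESClass:
    """Classify one ES by direction, magnitude, and statistical significance.

    Direction: risk (>1), protective (<1), neutral (=1).  Magnitude: large
    when value <= 0.2 or >= 5; tiny when 0.95 <= value <= 1.05 — a value of
    exactly 1 is neutral, its own class, and is excluded from the tiny count.
    Significant iff the CI excludes 1; a limit exactly at 1 encompasses it
    (not significant).  With no CI, significance is undetermined (None).
    """
    if value <= 0:
        raise ValueError(f"effect size must be positive, got {value}")
    if value > 1:
        direction = "risk"
    elif value < 1:
        direction = "protective"
    else:
        direction = "neutral"

    if value <= LARGE_LOW or value >= LARGE_HIGH:
        magnitude = "large"
    elif TINY_LOW <= value <= TINY_HIGH and value != 1:
        magnitude = "tiny"
    else:
        magnitude = "other"

    if ci_lower is None or ci_upper is None:
        significant = None
    else:
        significant = ci_upper < 1 or ci_lower > 1
    return ESClass(direction=direction, magnitude=magnitude, significant=significant)


def ci_magnitude(ci_lower: float, ci_upper: float) -> float:
    """CI width on the log scale, mapped back to the linear scale: upper/lower.

    Invariant under the protective<->risk inversion (L, U) -> (1/U, 1/L), so
    the magnitude of a protective interval equals that of its mirrored risk
    interval.
    """
    if ci_lower <= 0 or ci_upper <= 0:
        raise ValueError("CI limits must be positive")
    if ci_lower > ci_upper:
        raise ValueError("CI lower limit exceeds upper limit")
    return ci_upper / ci_lower


def month_index(pub_year: int, pub_month: Optional[int]) -> Optional[int]:
    """Months since 1990-01 (index 0); None when the month is unknown."""
    if pub_month is None:
        return None
    return (pub_year - 1990) * 12 + (pub_month - 1)


def condense_abstract(
    mentions: Iterable[ESMention],
    source_id: str = "",
    month: Optional[int] = None,
    strata: Optional[dict] = None,
) -> Optional[AbstractSummary]:
    """Condense an abstract's mentions to per-abstract outcomes.

    * ``es_min`` / ``es_max``: the standardized values (T3) nearest to and
      farthest from 1, with distance measured in |ln| so protective and risk
      values are comparable;
    * ``es_mean``: geometric mean of standardized values,
      ``exp(mean |ln v|)``;
    * ``cimag_*``: same min/max/geometric-mean reduction of the upper/lower
      ratios (None when no mention carries a CI);
    * ``any_significant`` / ``prop_significant`` from :func:`classify_es`
      (the proportion is over all mentions; CI-less mentions count as not
      significant).

    Returns None for an empty mention list — the caller excludes the
    citation and counts it.
    """
    mentions = list(mentions)
    if not mentions:
        return None
    abs_logs = [abs(math.log(m.value)) for m in mentions]
    std = [math.exp(a) for a in abs_logs]
    es_mean = math.exp(sum(abs_logs) / len(abs_logs))

    cimags = [
        ci_magnitude(m.ci_lower, m.ci_upper)
        for m in mentions
        if m.ci_lower is not None and m.ci_upper is not None
    ]
    if cimags:
        cimag_min = min(cimags)
        cimag_max = max(cimags)
        cimag_mean = math.exp(sum(math.log(c) for c in cimags) / len(cimags))
    else:
        cimag_min = cimag_max = cimag_mean = None

    sigs = [classify_es(m.value, m.ci_lower, m.ci_upper).significant for m in mentions]
    n_sig = sum(1 for s in sigs if s)
    return AbstractSummary(
        source_id=source_id or mentions[0].source_id,
        month_index=month,
        n_es=len(mentions),
        es_min=min(std),
        es_max=max(std),
        es_mean=es_mean,
        cimag_min=cimag_min,
        cimag_max=cimag_max,
        cimag_mean=cimag_mean,
        any_significant=n_sig > 0,
        prop_significant=n_sig / len(mentions),
        strata=dict(strata or {}),
    )


def select_mentions(
    mentions: Iterable[ESMention],
    ci_levels: Optional[set[int]] = frozenset({95}),
    require_ci: bool = True,
) -> list[ESMention]:
    """Primary-analysis filter over one abstract's mentions.

    The default keeps mentions carrying a 95% CI, matching the primary
    analysis restriction; subgroup profiles (90/99% CIs, CI-less) pass a
    different ``ci_levels``/``require_ci`` — condensation itself never
    changes.
    """
    kept = []
    for m in mentions:
        has_ci = m.ci_lower is not None and m.ci_upper is not None
        if require_ci and not has_ci:
            continue
        if ci_levels is not None and has_ci and m.ci_level not in ci_levels:
            continue
        kept.append(m)
    return kept
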