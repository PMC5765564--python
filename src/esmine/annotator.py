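"""Citation-level characteristics used to stratify the trend analyses.

Derives, from a citation and its detected mentions: evidence of a
multivariate analysis, review status, Open Access (OA) and Core Clinical
Journal (CCJ) membership, continents of the author affiliations, and MeSH
research fields (second-level branches of the C "diseases" and G "phenomena
and processes" trees).

All lookups are driven by editable TSV config files; the package ships
defaults (a gazetteer with aliases, a MeSH descriptor->tree-number fixture,
an OA fixture list, and a subset of the NLM Abridged Index Medicus list for
CCJ).  OA status in particular is a data problem, not an algorithm problem:
the shipped list is a small synthetic-scale fixture meant to be replaced by
the user's own list.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from esmine.corpus_io import CitationRecord
from esmine.es_detector import ESMention

logger = logging.getLogger(__name__)

CONTINENTS = ("Africa", "Asia", "Europe", "North America", "Oceania", "South America")

_MULTIVARIATE_RE = re.compile(r"adjust|multivariat|multivariabl", re.I)


@dataclass
class AnnotatedCitation:
    citation: CitationRecord
    multivariate: bool
    review: bool
    open_access: bool
    core_clinical: bool
    continents: set[str] = field(default_factory=set)
    fields: set[str] = field(default_factory=set)


def _read_tsv(path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def _resource_path(name: str):
    return importlib_resources.files("esmine.resources").joinpath(name)


def _normalize_title(title: str) -> str:
    t = re.sub(r"[^a-z0-9 ]", " ", title.lower())
    t = re.sub(r"\s+", " ", t).strip()
    return re.sub(r"^the ", "", t)


class Gazetteer:
    """Country -> continent lookup with alias support and longest-match search."""

    def __init__(self, rows: Iterable[dict]):
        self.continent: dict[str, str] = {}
        names = []
        for row in rows:
            continent = row["continent"].strip()
            surfaces = [row["country"].strip()]
            aliases = (row.get("aliases") or "").strip()
            if aliases:
                surfaces += [a.strip() for a in aliases.split("|") if a.strip()]
            for s in surfaces:
                self.continent[s.lower()] = continent
                names.append(s)
        # longest alternatives first so "South Korea" beats "Korea"
        names.sort(key=len, reverse=True)
        self._pattern = re.compile(
            r"\b(" + "|".join(re.escape(n) for n in names) + r")\b", re.I
        )

    def continents_of(self, affiliation: str) -> set[str]:
        return {self.continent[m.group(1).lower()] for m in self._pattern.finditer(affiliation)}


@dataclass
class AnnotationResources:
    gazetteer: Gazetteer
    mesh_tree: dict[str, list[str]]
    oa_issns: set[str]
    oa_titles: set[str]
    ccj_issns: set[str]
    ccj_titles: set[str]

    @classmethod
    def load(
        cls,
        gazetteer_path=None,
        mesh_tree_path=None,
        oa_path=None,
        ccj_path=None,
    ) -> "AnnotationResources":
        """Load resources from TSV files; package defaults fill any omission."""
        gaz = Gazetteer(_read_tsv(gazetteer_path or _resource_path("gazetteer.tsv")))
        mesh: dict[str, list[str]] = {}
        for row in _read_tsv(mesh_tree_path or _resource_path("mesh_tree.tsv")):
            mesh[row["descriptor"]] = [t.strip() for t in row["tree_numbers"].split("|")]
        oa = _read_tsv(oa_path or _resource_path("oa_journals.tsv"))
        ccj = _read_tsv(ccj_path or _resource_path("ccj_journals.tsv"))
        return cls(
            gazetteer=gaz,
            mesh_tree=mesh,
            oa_issns={r["issn"] for r in oa if r.get("issn")},
            oa_titles={_normalize_title(r["title"]) for r in oa},
            ccj_issns={r["issn"] for r in ccj if r.get("issn")},
            ccj_titles={_normalize_title(r["title"]) for r in ccj},
        )


def detect_multivariate(text: str, mentions: Sequence[ESMention]) -> bool:
    """True when any mention is adjusted or the abstract names an adjustment.

    The phrase check matches the stems "adjust", "multivariat" and
    "multivariabl" anywhere in the text.
    """
    if any(m.adjusted for m in mentions):
        return True
    return bool(_MULTIVARIATE_RE.search(text))


def map_affiliation_continents(
    affiliations: Sequence[str], gazetteer: Gazetteer
) -> set[str]:
    """Union of continents found by longest-match country search.

    Cross-continental author lists map to several continents; an affiliation
    with no recognizable country contributes nothing (logged).
    """
    out: set[str] = set()
    for aff in affiliations:
        found = gazetteer.continents_of(aff)
        if not found:
            logger.info("no country recognized in affiliation: %r", aff[:80])
        out |= found
    return out


def map_mesh_fields(
    descriptors: Iterable[str], mesh_tree: dict[str, list[str]]
) -> set[str]:
    """Second-level C/G branch codes (research fields) for a descriptor set.

    A citation belongs to field ``C04`` when any of its descriptors has a
    tree number starting ``C04``; one abstract can belong to several fields.
    Descriptors missing from the mapping are ignored.
    """
    fields: set[str] = set()
    for d in descriptors:
        numbers = mesh_tree.get(d)
        if numbers is None:
            logger.debug("descriptor %r absent from MeSH mapping", d)
            continue
        for tn in numbers:
            top = tn.split(".")[0]
            if top and top[0] in ("C", "G"):
                fields.add(top[:3])
    return fields


def annotate_citation(
    citation: CitationRecord,
    mentions: Sequence[ESMention],
    resources: AnnotationResources,
) -> AnnotatedCitation:
    """Compose all citation-level annotations (a pure function of its inputs).

    Journal-list membership tests the ISSN first and falls back to the
    normalized journal title.
    """
    issn = citation.journal_issn or ""
    title = _normalize_title(citation.journal_title)
    oa = issn in resources.oa_issns or (title != "" and title in resources.oa_titles)
    ccj = issn in resources.ccj_issns or (title != "" and title in resources.ccj_titles)
    return AnnotatedCitation(
        citation=citation,
        multivariate=detect_multivariate(citation.abstract_text, mentions),
        review="Review" in citation.pub_types,
        open_access=oa,
        core_clinical=ccj,
        continents=map_affiliation_continents(citation.affiliations, resources.gazetteer),
        fields=map_mesh_fields(citation.mesh_descriptors, resources.mesh_tree),
    )


def prune_fields(field_counts: dict[str, int], min_abstracts: int = 1000) -> set[str]:
    """Fields retained for field-level trend outputs.

    Branches with fewer than ``min_abstracts`` abstracts are dropped from
    trend reporting — never from per-citation annotation.
    """
    return {f for f, n in field_counts.items() if n >= min_abstracts}
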