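"""End-to-end orchestration: extract -> annotate -> condense -> trends.

Every stage consumes and produces the TSV interchange tables defined in
`corpus_io`, so stages are independently runnable and testable; the
`run_pipeline` entry point chains them with structured per-stage counts
(citations read, abstracts with ESs, mentions kept/dropped) and embeds the
configuration hash in every output's sidecar manifest.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from esmine import __version__
from esmine.annotator import AnnotationResources, annotate_citation
from esmine.corpus_io import CitationRecord, parse_pubmed_citations, write_es_table, read_es_table
from esmine.es_detector import (
    DetectorLexicon,
    ESMention,
    apply_plausibility_filter,
    default_lexicon,
    detect_es_mentions,
    load_lexicon,
    mentions_to_rows,
)
from esmine.es_transforms import condense_abstract, month_index, select_mentions
from esmine.trend_stats import trend_report

logger = logging.getLogger(__name__)

#: Column order of the per-abstract summary table.
SUMMARY_COLUMNS = [
    "source_id", "month_index", "n_es",
    "es_min", "es_max", "es_mean",
    "cimag_min", "cimag_max", "cimag_mean",
    "any_significant", "prop_significant",
    "multivariate", "review", "open_access", "core_clinical",
    "continents", "fields",
]

#: Outcome -> monthly aggregation statistic for the default trend battery.
DEFAULT_OUTCOMES = {
    "es_min": "median",
    "es_max": "median",
    "es_mean": "median",
    "cimag_mean": "median",
    "any_significant": "proportion",
    "prop_significant": "mean",
}


@dataclass
class RunConfig:
    citation_glob: str
    out_dir: str
    lexicon_path: Optional[str] = None
    gazetteer_path: Optional[str] = None
    mesh_tree_path: Optional[str] = None
    oa_path: Optional[str] = None
    ccj_path: Optional[str] = None
    include_reviews: bool = False
    reviews_only: bool = False
    ci_levels: tuple[int, ...] = (95,)
    year_range: tuple[int, int] = (1990, 2015)
    tau_variant: str = "b"
    min_months: int = 8
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def iter_citations(citation_glob: str) -> Iterable[CitationRecord]:
    paths = sorted(glob.glob(citation_glob))
    if not paths:
        raise FileNotFoundError(f"no citation XML matches {citation_glob!r}")
    for path in paths:
        yield from parse_pubmed_citations(path)


def extract_mentions(
    citations: Iterable[CitationRecord],
    lexicon: Optional[DetectorLexicon] = None,
) -> tuple[list[ESMention], dict]:
    """Detect and plausibility-filter mentions across a citation stream."""
    lexicon = lexicon or default_lexicon()
    mentions: list[ESMention] = []
    counts = {"citations": 0, "with_abstract": 0, "abstracts_with_es": 0, "mentions": 0}
    for cit in citations:
        counts["citations"] += 1
        if not cit.abstract_text:
            continue
        counts["with_abstract"] += 1
        found = detect_es_mentions(cit.abstract_text, lexicon, source_id=cit.pmid)
        found = apply_plausibility_filter(found)
        if found:
            counts["abstracts_with_es"] += 1
            counts["mentions"] += len(found)
            mentions.extend(found)
    return mentions, counts


def _mentions_by_source(mention_df: pd.DataFrame) -> dict[str, list[ESMention]]:
    out: dict[str, list[ESMention]] = {}
    for row in mention_df.itertuples(index=False):
        m = ESMention(
            source_id=str(row.source_id),
            es_type=row.es_type,
            adjusted=bool(row.adjusted),
            value=float(row.value),
            ci_level=None if pd.isna(row.ci_level) else int(row.ci_level),
            ci_lower=None if pd.isna(row.ci_lower) else float(row.ci_lower),
            ci_upper=None if pd.isna(row.ci_upper) else float(row.ci_upper),
            span=(int(row.span_start), int(row.span_end)),
            flags=set(str(row.flags).split(",")) - {"", "nan"},
        )
        out.setdefault(m.source_id, []).append(m)
    return out


def condense_corpus(
    citations: Iterable[CitationRecord],
    mention_df: pd.DataFrame,
    resources: AnnotationResources,
    include_reviews: bool = False,
    reviews_only: bool = False,
    ci_levels: tuple[int, ...] = (95,),
    year_range: tuple[int, int] = (1990, 2015),
) -> pd.DataFrame:
    """Annotate citations and condense their mentions to summary rows.

    The default filter reproduces the primary analysis: non-review abstracts,
    mentions with a 95% CI, publication years within ``year_range``.
    Subgroup profiles toggle the filters; the condensation formulas never
    change.
    """
    by_source = _mentions_by_source(mention_df)
    rows = []
    for cit in citations:
        mentions = by_source.get(cit.pmid)
        if not mentions:
            continue
        if not (year_range[0] <= cit.pub_year <= year_range[1]):
            continue
        ann = annotate_citation(cit, mentions, resources)
        if ann.review and not (include_reviews or reviews_only):
            continue
        if reviews_only and not ann.review:
            continue
        selected = select_mentions(mentions, ci_levels=set(ci_levels))
        summary = condense_abstract(
            selected,
            source_id=cit.pmid,
            month=month_index(cit.pub_year, cit.pub_month),
        )
        if summary is None:
            continue
        rows.append({
            "source_id": summary.source_id,
            "month_index": summary.month_index,
            "n_es": summary.n_es,
            "es_min": summary.es_min,
            "es_max": summary.es_max,
            "es_mean": summary.es_mean,
            "cimag_min": summary.cimag_min,
            "cimag_max": summary.cimag_max,
            "cimag_mean": summary.cimag_mean,
            "any_significant": summary.any_significant,
            "prop_significant": summary.prop_significant,
            "multivariate": ann.multivariate,
            "review": ann.review,
            "open_access": ann.open_access,
            "core_clinical": ann.core_clinical,
            "continents": "|".join(sorted(ann.continents)),
            "fields": "|".join(sorted(ann.fields)),
        })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def summaries_from_frame(df: pd.DataFrame):
    """AbstractSummary views over a summary table (for trend_stats)."""
    from esmine.es_transforms import AbstractSummary

    out = []
    for row in df.itertuples(index=False):
        out.append(AbstractSummary(
            source_id=str(row.source_id),
            month_index=None if pd.isna(row.month_index) else int(row.month_index),
            n_es=int(row.n_es),
            es_min=float(row.es_min),
            es_max=float(row.es_max),
            es_mean=float(row.es_mean),
            cimag_min=None if pd.isna(row.cimag_min) else float(row.cimag_min),
            cimag_max=None if pd.isna(row.cimag_max) else float(row.cimag_max),
            cimag_mean=None if pd.isna(row.cimag_mean) else float(row.cimag_mean),
            any_significant=bool(row.any_significant),
            prop_significant=float(row.prop_significant),
            strata={
                "multivariate": bool(getattr(row, "multivariate", False)),
                "review": bool(getattr(row, "review", False)),
                "open_access": bool(getattr(row, "open_access", False)),
                "core_clinical": bool(getattr(row, "core_clinical", False)),
            },
        ))
    return out


def field_trend_report(
    summaries: pd.DataFrame,
    outcome: str = "es_mean",
    statistic: str = "median",
    min_abstracts: int = 1000,
    tau_variant: str = "b",
    min_n: int = 8,
) -> pd.DataFrame:
    """Per-research-field Mann-Kendall trends with branch pruning.

    Fields (second-level MeSH C/G branches, from the summary table's
    ``fields`` column) with fewer than ``min_abstracts`` abstracts are
    dropped from the report — pruning affects reporting only, never the
    per-citation annotation.  One abstract can contribute to several fields.
    """
    from esmine.annotator import prune_fields
    from esmine.trend_stats import mann_kendall, monthly_series

    exploded = summaries.assign(
        field=summaries["fields"].fillna("").str.split("|")
    ).explode("field")
    exploded = exploded[exploded["field"] != ""]
    counts = exploded.groupby("field")["source_id"].nunique().to_dict()
    kept = prune_fields(counts, min_abstracts=min_abstracts)
    rows = []
    for field_code in sorted(kept):
        sub = exploded[exploded["field"] == field_code]
        series = monthly_series(summaries_from_frame(sub), outcome, statistic)
        if len(series) < min_n:
            continue
        r = mann_kendall(series, tau_variant=tau_variant, min_n=min_n)
        rows.append({"field": field_code, "n_abstracts": counts[field_code],
                     "S": r.S, "varS": r.varS, "z": r.z,
                     "tau": r.tau, "p": r.p, "n_months": r.n})
    return pd.DataFrame(
        rows, columns=["field", "n_abstracts", "S", "varS", "z", "tau", "p", "n_months"]
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute extract -> annotate -> condense -> trends; return the manifest.

    Identical config and inputs give identical outputs (timestamps live only
    in the log).  Any stage failure propagates with the stage name attached.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "tables": {},
        "counts": {},
    }

    stage = "extract"
    try:
        lexicon = load_lexicon(config.lexicon_path) if config.lexicon_path else default_lexicon()
        mentions, counts = extract_mentions(iter_citations(config.citation_glob), lexicon)
        mention_path = out_dir / "mentions.tsv"
        write_es_table(mentions_to_rows(mentions), mention_path)
        manifest["counts"][stage] = counts
        manifest["tables"]["mentions"] = str(mention_path)

        stage = "condense"
        resources = AnnotationResources.load(
            config.gazetteer_path, config.mesh_tree_path, config.oa_path, config.ccj_path,
        )
        mention_df = read_es_table(mention_path)
        summaries = condense_corpus(
            iter_citations(config.citation_glob), mention_df, resources,
            include_reviews=config.include_reviews,
            reviews_only=config.reviews_only,
            ci_levels=config.ci_levels,
            year_range=config.year_range,
        )
        summary_path = out_dir / "summaries.tsv"
        summaries.to_csv(summary_path, sep="\t", index=False)
        manifest["counts"][stage] = {"abstracts": len(summaries)}
        manifest["tables"]["summaries"] = str(summary_path)
        if summaries.empty:
            logger.warning("condense stage produced an empty summary table")

        stage = "trends"
        trend_path = out_dir / "trends.tsv"
        if len(summaries) and summaries["month_index"].nunique() >= config.min_months:
            report = trend_report(
                summaries_from_frame(summaries), DEFAULT_OUTCOMES,
                tau_variant=config.tau_variant, min_n=config.min_months,
            )
        else:
            report = pd.DataFrame(
                columns=["outcome", "statistic", "S", "varS", "z", "tau", "p", "n"]
            )
            logger.warning("too few months for a trend test; empty trend report written")
        report.to_csv(trend_path, sep="\t", index=False)
        manifest["tables"]["trends"] = str(trend_path)

        stage = "report"
        monthly_path = out_dir / "monthly_medians.csv"
        if len(summaries):
            med = (
                summaries.dropna(subset=["month_index"])
                .groupby("month_index")
                .agg(
                    es_mean_median=("es_mean", "median"),
                    cimag_mean_median=("cimag_mean", "median"),
                    prop_significant_mean=("prop_significant", "mean"),
                    any_significant_prop=("any_significant", "mean"),
                    n=("source_id", "size"),
                )
            )
            med.to_csv(monthly_path)
        else:
            pd.DataFrame().to_csv(monthly_path)
        manifest["tables"]["monthly_medians"] = str(monthly_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
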