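# esmine

Mining ratio effect sizes (odds, risk, and hazard ratios) from the
biomedical literature, and testing how their magnitude and statistical
significance evolve over time.

## The problem

Most associations in clinical and epidemiological abstracts are reported as
a ratio effect size (ES) — an odds ratio (OR), risk/rate ratio (RR), or
hazard ratio (HR) — together with a confidence interval (CI).  Meta-research
questions such as *are reported effects shrinking while becoming more often
statistically significant?* require extracting those statements at corpus
scale from free text, which is harder than it sounds: terminology is
unstandardized ("aOR 2.1", "adjusted odds ratio (aOR) was 2.1", "OR = 2.1
(1.4–3.2)"), and the acronyms collide with unrelated quantities ("heart
rate (HR) was 72").

`esmine` implements the full pipeline for this kind of study:

1. **corpus I/O** — streaming readers for MEDLINE/PubMed citation XML
   (`PubmedArticleSet`, gzip-transparent) and JATS full-text XML
   (abstract / Results paragraphs / table cells as separate channels);
2. **detection** — a windowed pattern grammar that pairs each ES term with
   the nearest following value and its CI, with a per-acronym *restrictive
   mode* triggered by trap wordings ("heart rate", "respiratory rate",
   "ovulation rate", …) and a numeric plausibility filter;
3. **annotation** — citation characteristics used for stratification:
   multivariate analysis, review status, Open Access and Core Clinical
   Journal membership, affiliation continents, MeSH research fields
   (second-level C/G tree branches);
4. **transformation & condensation** — ES values standardized on the log
   scale and condensed to per-abstract outcomes;
5. **trend statistics** — Mann-Kendall monotonic trend tests on monthly
   series, Mann-Whitney and Kruskal-Wallis/Dunn group comparisons;
6. **synthetic corpus** — a generator producing PubMed-style XML with
   planted statements, configurable temporal drifts, trap sentences, and an
   exact gold table, so every stage is testable without downloading PubMed.

## The statistics in brief

A ratio ES is standardized by inverting protective values,
`T3(v) = exp(|ln v|) = max(v, 1/v)`, so risk and protective effects are
comparable on one side of 1; an abstract's ESs are condensed to

- `es_min`, `es_max` — the standardized values nearest to / farthest from 1
  (distance in `|ln|`),
- `es_mean = exp(mean |ln v|)` — the geometric mean of standardized values,
- CI magnitude `U/L` (the log-scale width mapped back to a ratio), reduced
  the same way,
- significance: a CI excluding 1 (a limit exactly at 1 counts as
  encompassing it).

Monthly medians (or proportions) of these outcomes are tested for monotone
trend with the Mann-Kendall statistic `S = Σ_{i<j} sign(v_j − v_i)`,
tie-corrected variance, continuity-corrected normal `z`, and Kendall's
`τ_b` as effect size.

## Worked example

Simulate ten years of monthly literature with the default drifts (ES
magnitude shrinking, CIs narrowing, significance share rising), run the
pipeline, and test the trends:

```sh
esmine simulate --out demo/sim --seed 5 --months 0:120 --abstracts-per-month 30
esmine run --xml demo/sim/corpus.xml --out demo/out
esmine trends --summaries demo/out/summaries.tsv --out demo/out/trends.tsv
```

which prints (abridged):

```
         outcome  statistic     S       tau            p   n
         es_mean     median -1222 -0.171148 5.613867e-03 120
      cimag_mean     median -2940 -0.411765 2.622275e-11 120
prop_significant       mean  1610  0.226252 2.619915e-04 120
```

Monthly medians of the per-abstract mean ES trend downward (τ = −0.17),
CI magnitudes shrink steeply (τ = −0.41, P < 0.001), and the mean
proportion of significant ESs per abstract rises (τ = +0.23, P < 0.001) —
the generator's planted drifts, recovered end to end from rendered text.
Because the corpus ships a gold table, the detector itself can be scored:

```sh
esmine evaluate --gold demo/sim/gold.tsv --mentions demo/out/mentions.tsv \
    --xml demo/sim/corpus.xml --unit mention
```

```
{"tp": 2499, "fp": 0, "tn": 374, "fn": 46, ...
 "sensitivity": 0.98, "specificity": 1.0, "kappa": 0.93}
```

The ~2% misses are restrictive-mode suppressions: bare-acronym statements
in abstracts that also use the acronym for a non-ES quantity are dropped by
design to protect specificity.

## Layout

```
src/esmine/
  corpus_io.py         PubMed/JATS readers, ES-table TSV round trip
  es_detector.py       term lexicon, detection grammar, CI parser,
                       plausibility filter, sensitivity/specificity/kappa
  annotator.py         multivariate/review/OA/CCJ flags, continents, MeSH fields
  es_transforms.py     T1-T4 transformations, classification, condensation
  trend_stats.py       Mann-Kendall, Mann-Whitney, Kruskal-Wallis + Dunn
  synthetic_corpus.py  corpus generator with gold annotations
  pipeline.py, cli.py  orchestration and the `esmine` command
  resources/           lexicon, gazetteer, MeSH map, OA/CCJ journal lists
docs/methods.md        model, parameters, and design notes
```
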