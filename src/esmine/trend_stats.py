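"""Monthly aggregation and nonparametric trend/comparison statistics.

The temporal analysis reduces per-abstract summaries to one value per
calendar month (median, mean, or proportion) and asks whether that monthly
series trends monotonically.  The Mann-Kendall test answers this from the
pairwise sign statistic

    S = sum_{i<j} sign(v_j - v_i),

with the tie-corrected variance

    Var(S) = [ n(n-1)(2n+5) - sum_t t(t-1)(2t+5) ] / 18,

a +/-1 continuity-corrected normal z, and Kendall's tau as the effect size.
Monthly medians tie frequently, so tau-b (tie-adjusted denominator) is the
default; tau-a is available for sensitivity analyses.

Group comparisons use Mann-Whitney (two groups) or Kruskal-Wallis with
Dunn's z-based pairwise post hoc (three or more), multiplicity-adjusted and
summarized as a compact letter display.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from esmine.es_transforms import AbstractSummary


@dataclass
class MonthlySeries:
    """One value per observed month; empty months are absent, never zero."""

    months: np.ndarray
    values: np.ndarray
    n_per_month: np.ndarray

    def __len__(self) -> int:
        return len(self.months)


@dataclass
class TrendResult:
    S: int
    varS: float
    z: float
    tau: float
    p: float
    n: int


@dataclass
class TestResult:
    statistic: float
    p: float
    groups: list[str]
    pairwise: Optional[pd.DataFrame] = None
    letters: Optional[dict[str, str]] = None


_STATS = {"median", "mean", "proportion"}


def monthly_series(
    summaries: Iterable[AbstractSummary],
    outcome: str,
    statistic: str = "median",
) -> MonthlySeries:
    """Aggregate per-abstract summaries into one value per month.

    ``outcome`` names an `AbstractSummary` field (es_mean, cimag_mean,
    any_significant, prop_significant, ...).  ``proportion`` mode computes
    the share of summaries whose boolean outcome is true.  Summaries without
    a month index are excluded.
    """
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    rows = []
    for s in summaries:
        if s.month_index is None:
            continue
        if not hasattr(s, outcome):
            raise ValueError(f"unknown outcome {outcome!r}")
        v = getattr(s, outcome)
        if v is None:
            continue
        rows.append((s.month_index, float(v)))
    if not rows:
        return MonthlySeries(np.array([], int), np.array([]), np.array([], int))
    df = pd.DataFrame(rows, columns=["month", "value"])
    agg = {"median": "median", "mean": "mean", "proportion": "mean"}[statistic]
    g = df.groupby("month")["value"].agg([agg, "size"]).sort_index()
    return MonthlySeries(
        months=g.index.to_numpy(dtype=int),
        values=g[agg].to_numpy(dtype=float),
        n_per_month=g["size"].to_numpy(dtype=int),
    )


def mann_kendall(
    series: MonthlySeries | Sequence[float],
    tau_variant: str = "b",
    min_n: int = 8,
) -> TrendResult:
    """Mann-Kendall test for a monotonic trend in an ordered series.

    Uses the normal approximation with continuity correction; requires at
    least ``min_n`` points (below that, an exact test would be needed and an
    error is raised).  ``tau_variant`` selects tau-b (tie-adjusted, default)
    or tau-a (S over n(n-1)/2).
    """
    values = np.asarray(series.values if isinstance(series, MonthlySeries) else series, dtype=float)
    n = len(values)
    if n < min_n:
        raise ValueError(
            f"series of length {n} is below the minimum {min_n} for the normal "
            "approximation; use an exact test at this size"
        )
    diff_signs = np.sign(values[None, :] - values[:, None])
    S = int(np.triu(diff_signs, k=1).sum())

    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    varS = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0

    if varS > 0:
        if S > 0:
            z = (S - 1) / math.sqrt(varS)
        elif S < 0:
            z = (S + 1) / math.sqrt(varS)
        else:
            z = 0.0
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))

    n0 = n * (n - 1) / 2.0
    if tau_variant == "a":
        tau = S / n0
    elif tau_variant == "b":
        n1 = float(np.sum(counts * (counts - 1) / 2.0))
        denom = math.sqrt((n0 - n1) * n0)   # time axis has no ties
        tau = S / denom if denom > 0 else 0.0
    else:
        raise ValueError(f"unknown tau variant {tau_variant!r}")
    return TrendResult(S=S, varS=varS, z=z, tau=tau, p=p, n=n)


# ---------------------------------------------------------------------------
# Rank-based group comparisons

def _compact_letters(groups: list[str], significant: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different at the chosen
    alpha; every significantly different pair shares no letter.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in significant:
        new_sets = []
        for ls in letter_sets:
            if a in ls and b in ls:
                new_sets.append(ls - {a})
                new_sets.append(ls - {b})
            else:
                new_sets.append(ls)
        # absorb subsets
        new_sets.sort(key=len, reverse=True)
        kept: list[set[str]] = []
        for ls in new_sets:
            if ls and not any(ls <= k for k in kept):
                kept.append(ls)
        letter_sets = kept
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, ls in zip(alphabet, letter_sets):
        for g in groups:
            if g in ls:
                out[g] += letter
    return out


def rank_tests(
    groups: Mapping[str, Sequence[float]],
    mode: str = "mann_whitney",
    adjust: str = "bonferroni",
    alpha: float = 0.001,
) -> TestResult:
    """Nonparametric comparison of independent groups.

    ``mann_whitney`` (exactly 2 groups): U statistic with normal
    approximation and tie correction.  ``kruskal_dunn`` (>= 3 groups):
    Kruskal-Wallis omnibus H plus Dunn's pairwise z tests on mean ranks,
    p-values adjusted by ``adjust`` ('bonferroni' or 'holm'), with a compact
    letter display at ``alpha``.
    """
    labels = list(groups)
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")

    if mode == "mann_whitney":
        if len(labels) != 2:
            raise ValueError("mann_whitney requires exactly 2 groups")
        a, b = (samples[k] for k in labels)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return TestResult(statistic=float(res.statistic), p=float(res.pvalue), groups=labels)

    if mode != "kruskal_dunn":
        raise ValueError(f"unknown mode {mode!r}")
    if len(labels) < 3:
        raise ValueError("kruskal_dunn requires at least 3 groups")

    H, p_omnibus = stats.kruskal(*(samples[k] for k in labels))

    pooled = np.concatenate([samples[k] for k in labels])
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    mean_ranks = {}
    i = 0
    for k in labels:
        n_k = len(samples[k])
        mean_ranks[k] = ranks[i: i + n_k].mean()
        i += n_k
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))

    pairs = list(itertools.combinations(labels, 2))
    raw = []
    for a, b in pairs:
        se = math.sqrt(
            (N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1)))
            * (1.0 / len(samples[a]) + 1.0 / len(samples[b]))
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw.append(2.0 * stats.norm.sf(abs(z)))

    m = len(pairs)
    if adjust == "bonferroni":
        adj = [min(1.0, p * m) for p in raw]
    elif adjust == "holm":
        order = np.argsort(raw)
        adj = [0.0] * m
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, min(1.0, raw[idx] * (m - rank_i)))
            adj[idx] = running
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    mat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    significant = set()
    for (a, b), p_adj in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = p_adj
        if p_adj < alpha:
            significant.add((a, b))

    ordered = sorted(labels, key=lambda k: mean_ranks[k])
    letters = _compact_letters(ordered, significant)
    return TestResult(
        statistic=float(H), p=float(p_omnibus), groups=labels, pairwise=mat, letters=letters,
    )


def trend_report(
    summaries: Iterable[AbstractSummary],
    outcomes: Mapping[str, str],
    tau_variant: str = "b",
    min_n: int = 8,
) -> pd.DataFrame:
    """Mann-Kendall results for several outcomes, one row per outcome.

    ``outcomes`` maps an outcome field name to its aggregation statistic,
    e.g. ``{"es_mean": "median", "any_significant": "proportion"}``.
    """
    summaries = list(summaries)
    rows = []
    for outcome, statistic in outcomes.items():
        series = monthly_series(summaries, outcome, statistic)
        res = mann_kendall(series, tau_variant=tau_variant, min_n=min_n)
        rows.append({
            "outcome": outcome, "statistic": statistic,
            "S": res.S, "varS": res.varS, "z": res.z,
            "tau": res.tau, "p": res.p, "n": res.n,
        })
    return pd.DataFrame(rows)
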