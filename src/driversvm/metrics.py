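"""Rank-based evaluation statistics for per-patient driver lists.

All metrics operate on within-sample ranked gene lists with genes labelled
by annotation category (canonical / candidate / false_positive / rest):

- ``sample_auc`` — Mann–Whitney AUC of one category over another from their
  within-sample ranks;
- ``composition_score`` — position-weighted quality of a top-k list, driven
  negative by highly ranked false positives;
- ``oe_ratio`` — observed/expected count of a category in the top k;
- ``rbo`` — rank-biased overlap between two ranked lists, truncated at the
  evaluation depth with geometric positional weights;
- ``cohort_summary`` — medians/IQRs across samples, undefined values
  excluded rather than zero-filled.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

#: Category values for the composition score: canonical drivers reward the
#: list, candidates half as much, the rest is neutral and false positives
#: penalise twice as hard as a canonical rewards.
COMPOSITION_VALUES = {"canonical": 2.0, "candidate": 1.0, "rest": 0.0, "false_positive": -2.0}


def sample_auc(categories: Sequence[str], positive: str, negative: str) -> float:
    """AUC of `positive`-category genes over `negative`-category genes.

    `categories` is the category of each gene in rank order (best first).
    Equals the Mann–Whitney statistic: the fraction of (positive, negative)
    pairs in which the positive is ranked better, ties impossible since the
    ranking is strict.  Returns NaN when either group is absent; such samples
    are excluded from cohort medians.
    """
    pos = np.flatnonzero(np.asarray(categories, dtype=object) == positive)
    neg = np.flatnonzero(np.asarray(categories, dtype=object) == negative)
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    # number of (pos, neg) pairs where pos sits above neg
    wins = np.searchsorted(np.sort(pos), np.sort(neg)).sum()
    return float(wins / (len(pos) * len(neg)))


def composition_score(categories: Sequence[str], k: int = 5) -> float:
    """Position-weighted category score of the top-k list.

    Position i (1-based) gets weight (k + 1 - i) / (1 + ... + k), so the
    weights decay linearly and sum to one; each position contributes its
    weight times the category value (+2 canonical, +1 candidate, 0 rest,
    -2 false positive).  A list of all-canonical genes scores +2; a false
    positive in the top position drives the score negative.  Positions past
    the end of a short list contribute nothing.
    """
    if k < 1:
        raise InputError("k must be at least 1")
    if len(categories) < 1:
        raise InputError("empty ranked list")
    denom = k * (k + 1) / 2
    score = 0.0
    for i, cat in enumerate(categories[:k], start=1):
        if cat not in COMPOSITION_VALUES:
            raise InputError(f"unknown category {cat!r}")
        score += (k + 1 - i) / denom * COMPOSITION_VALUES[cat]
    return score


def oe_ratio(categories: Sequence[str], category: str, k: int = 5) -> float:
    """Observed/expected count of `category` in the top k of a ranked list.

    Expected is k times the category's frequency in the sample's full ranked
    pool.  Returns NaN when the category is absent from the pool (expected
    zero) or the pool holds fewer than k genes.
    """
    n = len(categories)
    if n < k:
        return float("nan")
    cats = np.asarray(categories, dtype=object)
    total = int((cats == category).sum())
    if total == 0:
        return float("nan")
    observed = int((cats[:k] == category).sum())
    expected = k * total / n
    return observed / expected


def rbo(list_a: Sequence[str], list_b: Sequence[str], p: float = 0.9, depth: int = 5) -> float:
    """Truncated rank-biased overlap of two ranked lists.

    At each depth d <= `depth` the overlap A_d is the size of the
    intersection of the two d-prefixes divided by d; depths are weighted
    geometrically, weight proportional to p**(d-1), normalised to sum to one
    over the evaluated depths.  Identical lists (to `depth`) score 1,
    disjoint lists 0; higher-ranked positions dominate.
    """
    if not 0 < p < 1:
        raise InputError("p must be in (0, 1)")
    if depth < 1:
        raise InputError("depth must be at least 1")
    if len(set(list_a)) != len(list_a) or len(set(list_b)) != len(list_b):
        raise InputError("ranked lists must be duplicate-free")
    weights = np.array([p ** (d - 1) for d in range(1, depth + 1)])
    weights /= weights.sum()
    score = 0.0
    seen_a: set = set()
    seen_b: set = set()
    overlap = 0
    for d in range(1, depth + 1):
        a = list_a[d - 1] if d <= len(list_a) else None
        b = list_b[d - 1] if d <= len(list_b) else None
        if a is not None and b is not None and a == b:
            overlap += 1
        else:
            if a is not None and a in seen_b:
                overlap += 1
            if b is not None and b in seen_a:
                overlap += 1
        if a is not None:
            seen_a.add(a)
        if b is not None:
            seen_b.add(b)
        score += weights[d - 1] * overlap / d
    # guard against floating-point overshoot just past the [0, 1] bounds
    return float(min(1.0, max(0.0, score)))


def ranked_categories(predictions: pd.DataFrame, annotation) -> dict[str, list[str]]:
    """Per-sample category sequences in rank order from a prediction table."""
    out: dict[str, list[str]] = {}
    for sample, grp in predictions.sort_values(["sample", "rank"]).groupby("sample"):
        out[sample] = [annotation.category(g) for g in grp["gene"]]
    return out


def cohort_summary(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Median, IQR and defined-sample count per metric column.

    `per_sample` has one row per sample and one column per metric; NaN marks
    an undefined value and is excluded (never zero-filled).  Metrics with no
    defined value are reported with NaN summaries and n_defined = 0.
    """
    if per_sample.empty:
        raise InputError("no per-sample metric values")
    rows = []
    for col in per_sample.columns:
        vals = per_sample[col].dropna().astype(float)
        if len(vals):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
        else:
            q1 = med = q3 = float("nan")
        rows.append({"metric": col, "median": med, "q1": q1, "q3": q3, "n_defined": len(vals)})
    return pd.DataFrame(rows)


def prediction_overlap(genes_a: set[str], genes_b: set[str], universe_size: int) -> tuple[int, float]:
    """Overlap count between two prediction sets plus a hypergeometric
    enrichment p-value against random draws from a universe of
    `universe_size` genes."""
    if universe_size < max(len(genes_a), len(genes_b)):
        raise InputError("universe smaller than a prediction set")
    k = len(genes_a & genes_b)
    if k == 0:
        return 0, 1.0
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(genes_a), len(genes_b)))
    return k, p


def pairwise_rbo(
    predictions_a: pd.DataFrame,
    predictions_b: pd.DataFrame,
    p: float = 0.9,
    depth: int = 5,
) -> pd.Series:
    """Per-sample rank-biased overlap of two models' top-`depth` lists.

    Samples present in only one table are skipped.  Used to assess the
    stability of gene rankings across models trained on different cohorts.
    """
    tops = []
    for preds in (predictions_a, predictions_b):
        srt = preds.sort_values(["sample", "rank"])
        tops.append({s: list(g["gene"][:depth]) for s, g in srt.groupby("sample")})
    shared = sorted(set(tops[0]) & set(tops[1]))
    return pd.Series({s: rbo(tops[0][s], tops[1][s], p=p, depth=depth) for s in shared}, dtype=float)


def evaluate_predictions(
    predictions: pd.DataFrame,
    annotation,
    k: int = 5,
) -> pd.DataFrame:
    """Per-sample evaluation of a ranked prediction table.

    Returns one row per sample with: AUC of canonical drivers over the rest,
    AUC of canonical drivers over false positives, composition score of the
    top k, and O/E ratios of canonical drivers and false positives in the
    top k.  Undefined values are NaN.
    """
    by_sample = ranked_categories(predictions, annotation)
    rows = []
    for sample, cats in by_sample.items():
        rows.append(
            {
                "sample": sample,
                "auc_canonical_vs_rest": sample_auc(cats, "canonical", "rest"),
                "auc_canonical_vs_false_positive": sample_auc(cats, "canonical", "false_positive"),
                "composition_score": composition_score(cats, k=k) if len(cats) else math.nan,
                "oe_canonical": oe_ratio(cats, "canonical", k=k),
                "oe_false_positive": oe_ratio(cats, "false_positive", k=k),
            }
        )
    return pd.DataFrame(rows)
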