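"""Downstream statistics on word IA scores.

Covers the analyses run on the scored word-image pairs: the IA-by-condition
one-way ANOVA, Pearson correlations of IA with Zipf word frequency and with
mean confidence (with default Bayes factors), and the existing/nonexisting
word-category proportions with their confidence-by-category ANOVA.

The unit of analysis throughout is the word-image pair: each scorable pair
contributes one IA value, one Zipf frequency, one mean confidence.

Bayes factors
-------------
The correlation BF10 integrates the exact sampling density of the observed
Pearson r over a uniform prior on the population correlation rho in (-1, 1)
(the stretched-beta prior with kappa = 1), evaluated by Gauss-Legendre
quadrature in log space.  The ANOVA BF10 is the BIC approximation
exp((BIC_null - BIC_full) / 2) comparing the group-means model against the
grand-mean model; it is reported as ``bf10_approx`` to make the
approximation explicit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .io_model import CategoryLabelSet, FrequencyTable, ValidationError
from .ia import ResponseMatrix, build_response_matrices

__all__ = [
    "CorrelationResult",
    "AnovaResult",
    "CategoryProportions",
    "attach_zipf",
    "pearson_with_bf",
    "pearson_bf10",
    "confidence_per_word_image",
    "category_proportions",
    "anova_oneway",
]

logger = logging.getLogger(__name__)


class AnalysisError(ValueError):
    """An analysis cannot be performed on the given inputs."""


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_two_sided: float
    bf10: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValidationError(f"|r| must be <= 1, got {self.r}")
        if self.bf10 <= 0:
            raise ValidationError("bf10 must be positive")


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    bf10_approx: float
    group_means: dict[str, float]
    posthoc: pd.DataFrame | None = None


@dataclass
class CategoryProportions:
    """Per-image category proportions among words holding an IA score."""

    per_image: pd.DataFrame  # image_id, n_scored, then one proportion column per category
    summary: pd.Series  # mean of per-image proportions

    def validate(self) -> None:
        cats = [c for c in self.per_image.columns if c not in ("image_id", "n_scored")]
        sums = self.per_image[cats].sum(axis=1)
        ok = (self.per_image["n_scored"] == 0) | ((sums - 1.0).abs() < 1e-12)
        if not ok.all():
            raise ValidationError("per-image proportions must sum to 1")


# ---------------------------------------------------------------------------


def attach_zipf(scores: pd.DataFrame, ft: FrequencyTable) -> pd.DataFrame:
    """Join each scored pair with its word's Zipf frequency.

    Words absent from the frequency table are excluded (count logged);
    an empty join is an error since no correlation could follow.
    """
    if scores.empty or len(ft) == 0:
        raise AnalysisError("scores and frequency table must be nonempty")
    present = scores["word"].map(lambda w: w in ft)
    n_missing = int((~present).sum())
    if n_missing:
        logger.info("attach_zipf: excluded %d rows with out-of-vocabulary words", n_missing)
    kept = scores[present].copy()
    if kept.empty:
        raise AnalysisError("no scored word found in the frequency table")
    kept["zipf"] = kept["word"].map(ft.zipf)
    return kept


def _log_r_density_kernel(rho: np.ndarray, r: float, n: int) -> np.ndarray:
    """Log of the rho-dependent part of the sampling density of Pearson r."""
    rho = np.asarray(rho, dtype=float)
    hyp = special.hyp2f1(0.5, 0.5, (2 * n - 1) / 2, (rho * r + 1) / 2)
    return (
        (n - 1) / 2 * np.log1p(-rho ** 2)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(hyp)
    )


def pearson_bf10(r: float, n: int, n_nodes: int = 400) -> float:
    """Default Bayes factor for a Pearson correlation.

    BF10 = integral over rho in (-1, 1) of p(r | rho, n) under a uniform
    prior, divided by p(r | rho = 0, n).  Evaluated by Gauss-Legendre
    quadrature on the log kernel for numerical stability at large n.
    """
    if n < 4:
        raise AnalysisError("need n >= 4 for a correlation Bayes factor")
    nodes, wts = np.polynomial.legendre.leggauss(n_nodes)
    logk = _log_r_density_kernel(nodes, r, n)
    log0 = _log_r_density_kernel(np.array([0.0]), r, n)[0]
    m = logk.max()
    integral = float(np.sum(wts * np.exp(logk - m))) / 2.0  # prior density 1/2
    log_bf = m - log0 + math.log(integral)
    try:
        return math.exp(log_bf)
    except OverflowError:
        return math.inf


def pearson_with_bf(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with two-sided p, 95% CI, and default BF10."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise AnalysisError("x and y must have equal length")
    if len(x) < 4:
        raise AnalysisError("need n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    return CorrelationResult(
        r=float(res.statistic),
        n=len(x),
        p_two_sided=float(res.pvalue),
        bf10=pearson_bf10(float(res.statistic), len(x)),
        ci95=(float(ci.low), float(ci.high)),
    )


def confidence_per_word_image(
    processed: pd.DataFrame | Mapping[str, ResponseMatrix], scores: pd.DataFrame
) -> pd.DataFrame:
    """Mean confidence of each scorable word within its image's matrix.

    For each scored (word, image) pair, averages the confidence ratings
    attached to the word in the rows that reported it.
    """
    matrices = (
        dict(processed)
        if isinstance(processed, Mapping)
        else build_response_matrices(processed)
    )
    rows = []
    for rec in scores.itertuples(index=False):
        m = matrices[rec.image_id]
        confs = [
            m.confidence_of(rec.word, row) for row in sorted(m.rows_with(rec.word))
        ]
        confs = [c for c in confs if c is not None]
        rows.append((rec.word, rec.image_id, float(np.mean(confs))))
    return pd.DataFrame(rows, columns=["word", "image_id", "mean_confidence"])


def category_proportions(
    scores: pd.DataFrame, labels: CategoryLabelSet
) -> CategoryProportions:
    """Category composition of the scored words, image by image.

    The denominator for an image is the number of its words holding an IA
    score; every scored pair must be labeled.  The experiment-level summary
    is the unweighted mean of per-image proportions.
    """
    from .io_model import CATEGORIES

    missing = [
        (r.word, r.image_id)
        for r in scores.itertuples(index=False)
        if labels.get(r.word, r.image_id) is None
    ]
    if missing:
        shown = ", ".join(map(str, missing[:10]))
        raise ValidationError(
            f"{len(missing)} scored pair(s) lack category labels: {shown}"
            + ("..." if len(missing) > 10 else "")
        )
    rows = []
    for image_id, group in scores.groupby("image_id", sort=False):
        n = len(group)
        counts = {c: 0 for c in CATEGORIES}
        for r in group.itertuples(index=False):
            counts[labels.get(r.word, r.image_id)] += 1
        rows.append([image_id, n] + [counts[c] / n for c in CATEGORIES])
    per_image = pd.DataFrame(rows, columns=["image_id", "n_scored", *CATEGORIES])
    out = CategoryProportions(
        per_image=per_image, summary=per_image[list(CATEGORIES)].mean()
    )
    out.validate()
    return out


def anova_oneway(
    values: Sequence[float], groups: Sequence[str], posthoc: bool = True
) -> AnovaResult:
    """Classical one-way ANOVA with a BIC-approximated Bayes factor.

    Post-hoc pairwise comparisons use the pooled within-group error term
    with Bonferroni-corrected p-values.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise AnalysisError("values and groups must align")
    labels = list(dict.fromkeys(groups.tolist()))
    samples = {g: values[groups == g] for g in labels}
    if len(labels) < 2:
        raise AnalysisError("need at least 2 groups")
    for g, s in samples.items():
        if len(s) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 values")

    f, p = sps.f_oneway(*samples.values())
    n = len(values)
    grand = values.mean()
    rss_null = float(((values - grand) ** 2).sum())
    rss_full = float(sum(((s - s.mean()) ** 2).sum() for s in samples.values()))
    g = len(labels)
    # gaussian BIC with k = number of mean parameters + variance
    bic_null = n * math.log(rss_null / n) + 2 * math.log(n)
    bic_full = n * math.log(rss_full / n) + (g + 1) * math.log(n)
    bf10 = math.exp((bic_null - bic_full) / 2)

    df_between, df_within = g - 1, n - g
    result = AnovaResult(
        f=float(f),
        df_between=df_between,
        df_within=df_within,
        p=float(p),
        bf10_approx=bf10,
        group_means={g_: float(s.mean()) for g_, s in samples.items()},
    )
    if posthoc:
        mse = rss_full / df_within
        ncomp = g * (g - 1) // 2
        rows = []
        for a, b in combinations(labels, 2):
            sa, sb = samples[a], samples[b]
            diff = float(sa.mean() - sb.mean())
            se = math.sqrt(mse * (1 / len(sa) + 1 / len(sb)))
            t = diff / se if se > 0 else 0.0
            p_unc = 2 * sps.t.sf(abs(t), df_within)
            rows.append((a, b, diff, se, t, min(1.0, p_unc * ncomp)))
        result.posthoc = pd.DataFrame(
            rows, columns=["group_a", "group_b", "mean_diff", "se", "t", "p_bonf"]
        )
    return result
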