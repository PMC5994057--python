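"""Downstream inference on fitted components.

A fitted decomposition yields, per data type and component, a weight over
every feature.  This module turns those weights into biology: top-|weight|
feature selection, enrichment of selected features against annotation
categories (Fisher's exact test for feature-set enrichment, binomial test
for truth-set screening and chromosome enrichment), the two sensitivity
summaries SE(max)/SE(all) used to score recovery of a gold-standard CpG
set, the quantile rule that calls a feature's effect cell-type independent
or cell-type specific, iterative kurtosis-thresholded feature selection,
and association of sample-mode mixing columns with phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tica import TICAModel, excess_kurtosis, project_mode1

__all__ = [
    "FeatureAnnotation",
    "EnrichmentResult",
    "select_top_features",
    "fisher_enrichment",
    "binomial_enrichment",
    "SensitivityResult",
    "sensitivity_measures",
    "classify_specificity",
    "iterative_kurtosis_selection",
    "AssociationResult",
    "associate_phenotype",
]


@dataclass
class FeatureAnnotation:
    """Feature annotation: ids, optional chromosome labels and named
    category sets (e.g. a gold-standard mQTL list); category sets must be
    subsets of the feature universe."""

    feature_ids: list[str]
    chromosome: dict[str, str] | None = None
    category_sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        universe = set(self.feature_ids)
        if len(universe) != len(self.feature_ids):
            raise ValueError("duplicate feature ids in annotation")
        for name, members in self.category_sets.items():
            extra = set(members) - universe
            if extra:
                raise ValueError(
                    f"category {name!r} contains {len(extra)} ids outside the "
                    f"feature universe (e.g. {sorted(extra)[:3]})"
                )

    def chromosome_fraction(self, chrom: str) -> float:
        if not self.chromosome:
            raise ValueError("no chromosome labels in annotation")
        labels = [self.chromosome.get(f) for f in self.feature_ids]
        return sum(1 for c in labels if c == chrom) / len(labels)


@dataclass
class EnrichmentResult:
    """A 2x2 enrichment test result (counts: in-set & selected, in-set not
    selected, selected not in-set, neither)."""

    counts: tuple[int, int, int, int]
    odds_ratio: float
    p_value: float
    test: str
    component: object = None
    selected: list = field(default_factory=list)


def select_top_features(weights: np.ndarray, k: int) -> list[int]:
    """Indices of the ``k`` largest absolute weights, in decreasing-|weight|
    order; ties broken by smaller index (deterministic)."""
    weights = np.asarray(weights, dtype=float)
    p = weights.shape[0]
    if not 1 <= k <= p:
        raise ValueError(f"k={k} out of range 1..{p}")
    order = np.lexsort((np.arange(p), -np.abs(weights)))
    return [int(i) for i in order[:k]]


def fisher_enrichment(
    selected: set, category: set, universe: set, component=None
) -> EnrichmentResult:
    """One-tailed (greater) Fisher's exact test of category enrichment among
    selected features.  OR = ad/bc with +inf when bc = 0; ``category ==
    universe`` gives p = 1 with an undefined (NaN) odds ratio."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    category = set(category)
    if not selected <= universe or not category <= universe:
        raise ValueError("selected and category must be subsets of the universe")
    a = len(selected & category)
    b = len(category - selected)
    c = len(selected - category)
    d = len(universe) - a - b - c
    if category == universe:
        return EnrichmentResult(
            (a, b, c, d), float("nan"), 1.0, "fisher", component, sorted(selected)
        )
    # hypergeometric upper tail: P(X >= a) with |category| successes in
    # |universe|, |selected| draws
    p = float(stats.hypergeom.sf(a - 1, len(universe), len(category), len(selected)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    if b * c == 0:
        orr = float("inf") if a * d > 0 else float("nan")
    else:
        orr = (a * d) / (b * c)
    return EnrichmentResult((a, b, c, d), orr, p, "fisher", component, sorted(selected))


def binomial_enrichment(k: int, x: int, q: float) -> float:
    """Upper-tail binomial p-value ``P(X >= x)`` for ``X ~ Binomial(k, q)``."""
    if not 0 < q < 1:
        raise ValueError(f"background fraction q={q} must lie in (0, 1)")
    if not 0 <= x <= k:
        raise ValueError(f"hits x={x} out of range 0..{k}")
    if x == 0:
        return 1.0
    return float(stats.binom.sf(x - 1, k, q))


@dataclass
class SensitivityResult:
    """SE(max)/SE(all) summary plus the per-(data type, component) table."""

    se_max: float
    se_all: float
    enriched: list[tuple[int, int]]  # (mode1 level, component) pairs
    table: pd.DataFrame
    bonferroni_alpha: float


def sensitivity_measures(
    model: TICAModel,
    truth: set,
    k: int | None = None,
    alpha: float = 0.05,
) -> SensitivityResult:
    """Sensitivity of a fitted model to recover a gold-standard feature set.

    The model is back-projected onto its original data-type axes.  Per
    (data type, component) the top ``k`` features by absolute weight are
    selected (``k`` defaults to ``|truth|``, matching the selection size to
    the number of true positives) and the sensitivity over ``truth``
    computed.  SE(max) is the best single-component sensitivity.  A
    component counts as enriched when its upper-tail binomial p-value beats
    the Bonferroni threshold ``alpha / (number of components tested)``;
    SE(all) is the sensitivity of the union of selections over enriched
    components (0 when none is enriched).
    """
    truth = set(truth)
    if not truth:
        raise ValueError("empty truth set")
    proj = project_mode1(model)
    ids = proj.feature_ids
    id_arr = np.asarray(ids)
    missing = truth - set(ids)
    if missing:
        raise ValueError(
            f"{len(missing)} truth ids absent from the model's features "
            f"(e.g. {sorted(missing)[:3]})"
        )
    p1, d2, p = proj.shape
    k = len(truth) if k is None else k
    q = len(truth) / p
    n_tested = p1 * d2
    thresh = alpha / n_tested
    rows = []
    enriched: list[tuple[int, int]] = []
    union: set = set()
    for t in range(p1):
        for j in range(d2):
            sel_idx = select_top_features(proj.values[t, j], k)
            sel_ids = set(id_arr[sel_idx])
            hits = len(sel_ids & truth)
            se = hits / len(truth)
            pval = binomial_enrichment(k, hits, q)
            is_enr = pval < thresh
            if is_enr:
                enriched.append((t, j))
                union |= sel_ids
            rows.append(
                {
                    "mode1_index": t,
                    "component": j,
                    "k": k,
                    "hits": hits,
                    "se": se,
                    "p_binomial": pval,
                    "enriched": is_enr,
                }
            )
    table = pd.DataFrame(rows)
    se_max = float(table["se"].max())
    se_all = len(union & truth) / len(truth) if enriched else 0.0
    return SensitivityResult(se_max, float(se_all), enriched, table, thresh)


def classify_specificity(
    model: TICAModel,
    features: set,
    component: int,
    top_quantile: float = 0.90,
    low_quantile: float = 0.50,
) -> pd.DataFrame:
    """Call features cell-type independent or cell-type specific.

    On the back-projected weights of one component, per data-type level the
    90th and 50th percentiles of |weight| are computed (linear
    interpolation).  A feature is *independent* when its |weight| reaches
    the top decile in every level; *specific* when it is strictly below the
    median in exactly one or two levels while reaching the top decile in at
    least one; anything else is *unclassified* (reported, never dropped).
    Calls are invariant to positive rescaling of any level's weights.
    """
    proj = project_mode1(model)
    p1, d2, p = proj.shape
    if p1 < 2:
        raise ValueError("specificity requires at least two mode-1 levels")
    if not 0 <= component < d2:
        raise ValueError(f"component {component} out of range 0..{d2 - 1}")
    ids = list(proj.feature_ids)
    index = {f: i for i, f in enumerate(ids)}
    missing = set(features) - set(ids)
    if missing:
        raise ValueError(f"unknown feature ids: {sorted(missing)[:3]}")
    absw = np.abs(proj.values[:, component, :])  # (p1, p)
    hi = np.percentile(absw, 100 * top_quantile, axis=1)
    lo = np.percentile(absw, 100 * low_quantile, axis=1)
    rows = []
    for f in sorted(features):
        w = absw[:, index[f]]
        in_top = w >= hi
        below_med = w < lo
        if in_top.all():
            call = "independent"
        elif 1 <= below_med.sum() <= 2 and in_top.any():
            call = "specific"
        else:
            call = "unclassified"
        rows.append(
            {
                "feature_id": f,
                "call": call,
                "n_top_decile": int(in_top.sum()),
                "n_below_median": int(below_med.sum()),
            }
        )
    return pd.DataFrame(rows)


def iterative_kurtosis_selection(
    weights: np.ndarray, kurt_floor: float = 1.0, max_removed: int = 500
) -> list[int]:
    """Iteratively select the features driving a heavy-tailed component.

    The largest-|weight| feature is removed and the excess kurtosis of the
    remaining weights recomputed, until kurtosis drops below ``kurt_floor``
    or ``max_removed`` features have been removed (the cap is inclusive: at
    most ``max_removed`` are ever returned).  Returns removed features in
    removal order; an initial kurtosis already below the floor yields an
    empty selection.
    """
    weights = np.asarray(weights, dtype=float)
    p = weights.shape[0]
    if p <= max_removed:
        raise ValueError(f"need more than max_removed={max_removed} features, got {p}")
    mask = np.ones(p, dtype=bool)
    removed: list[int] = []
    absw = np.abs(weights)
    while len(removed) < max_removed:
        if excess_kurtosis(weights[mask]) < kurt_floor:
            break
        live = np.flatnonzero(mask)
        top = live[np.argmax(absw[live])]
        mask[top] = False
        removed.append(int(top))
    return removed


@dataclass
class AssociationResult:
    statistic: float
    p_value: float
    test: str
    significant: bool
    alpha: float


def associate_phenotype(
    mixing_column: np.ndarray,
    phenotype: np.ndarray,
    kind: str = "auto",
    bonferroni: int = 1,
    alpha: float = 0.05,
) -> AssociationResult:
    """Associate one sample-mode mixing column with a phenotype.

    Continuous or ordinal phenotypes are tested by ordinary least-squares
    regression (two-sided t-test on the slope); two-group phenotypes by a
    two-sided Wilcoxon rank sum test (exact when the smaller group has at
    most 20 samples and there are no ties, normal approximation with tie
    correction otherwise).  The significance flag applies a Bonferroni
    divisor to ``alpha`` (e.g. the number of components tested).
    """
    y = np.asarray(mixing_column, dtype=float)
    x = np.asarray(phenotype)
    if y.shape[0] != x.shape[0]:
        raise ValueError("mixing column and phenotype lengths differ")
    levels = np.unique(x)
    if levels.size < 2:
        raise ValueError("phenotype is constant")
    if kind == "auto":
        kind = "two-group" if levels.size == 2 else "continuous"
    if kind == "two-group":
        if levels.size != 2:
            raise ValueError("two-group test requires exactly two phenotype levels")
        g1 = y[x == levels[0]]
        g2 = y[x == levels[1]]
        ties = np.unique(y).size < y.size
        method = "exact" if (min(len(g1), len(g2)) <= 20 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon-rank-sum"
    elif kind == "continuous":
        xf = x.astype(float)
        if np.ptp(xf) == 0:
            raise ValueError("phenotype is constant")
        res = stats.linregress(xf, y)
        stat, p = float(res.slope / res.stderr) if res.stderr > 0 else np.inf, float(
            res.pvalue
        )
        if not np.isfinite(stat):
            p = 0.0
        test = "ols-slope-t"
    else:
        raise ValueError(f"unknown kind {kind!r}")
    threshold = alpha / bonferroni
    return AssociationResult(stat, p, test, p < threshold, threshold)
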