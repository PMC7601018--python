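"""Feature reduction and the two feature-scoring routes.

Reduction keeps a feature iff it is "present" (value >= minimum intensity)
in at least a percentage-threshold fraction of either class.  Scoring ranks
features by a tie-corrected two-sided Mann-Whitney U test with
Benjamini-Hochberg FDR adjustment, and independently by mean decrease in
Gini impurity from a seeded random forest trained on the full dataset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from mccims.alignment import FeatureMatrix
from mccims.errors import ValidationError
from mccims.io_formats import LabelTable

logger = logging.getLogger(__name__)

SIGNIFICANCE_CUTOFF = 0.05
DEFAULT_PCT_THRESHOLD = 50.0
EXACT_MWU_MAX_N = 8

__all__ = [
    "ReductionParams",
    "FeatureScore",
    "reduce_features",
    "mwu_pvalues",
    "bh_fdr",
    "gini_importance",
    "score_features",
    "select_top",
    "SIGNIFICANCE_CUTOFF",
]


@dataclass(frozen=True)
class ReductionParams:
    min_intensity: float = 0.0
    pct_threshold: float = DEFAULT_PCT_THRESHOLD

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_threshold <= 100.0):
            raise ValidationError("pct_threshold must be in [0, 100]")
        if self.min_intensity < 0:
            raise ValidationError("min_intensity must be >= 0")


@dataclass
class FeatureScore:
    peak_id: str
    p_value: float
    q_value: float
    gini_decrease: float
    rank_mwu: int
    rank_gini: int


def _class_masks(fm: FeatureMatrix, labels: LabelTable) -> tuple[str, str, np.ndarray, np.ndarray]:
    sub = labels.subset(fm.sample_ids)
    neg, pos = sub.require_binary()
    y = np.array([sub[s] for s in fm.sample_ids])
    return neg, pos, y == neg, y == pos


def reduce_features(
    fm: FeatureMatrix, labels: LabelTable, params: ReductionParams
) -> FeatureMatrix:
    """Drop features that are not conserved within either class.

    Presence = value >= ``min_intensity``; a feature is kept iff its
    presence fraction is >= ``pct_threshold``% within class A or within
    class B.  Sub-threshold values in surviving columns are kept as-is;
    the mask affects the presence test only.  Column order is preserved.
    """
    _, _, mask_a, mask_b = _class_masks(fm, labels)
    present = fm.values >= params.min_intensity
    frac = params.pct_threshold / 100.0
    keep = (present[mask_a].mean(axis=0) >= frac) | (present[mask_b].mean(axis=0) >= frac)
    kept_ids = [p for p, k in zip(fm.peak_ids, keep) if k]
    if not kept_ids:
        warnings.warn("feature reduction removed every feature")
    logger.info(
        "feature reduction: %d -> %d columns (min_intensity=%g, pct=%g)",
        len(fm.peak_ids), len(kept_ids), params.min_intensity, params.pct_threshold,
    )
    return fm.select_columns(kept_ids)


def mwu_pvalues(fm: FeatureMatrix, labels: LabelTable) -> np.ndarray:
    """Two-sided Mann-Whitney U p-value per feature.

    Exact distribution when both groups have <= 8 samples and the column is
    tie-free; tie-corrected normal approximation otherwise.
    """
    _, _, mask_a, mask_b = _class_masks(fm, labels)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValidationError("each class needs at least one sample")
    pvals = np.empty(len(fm.peak_ids))
    for j in range(len(fm.peak_ids)):
        a, b = fm.values[mask_a, j], fm.values[mask_b, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[j] = 1.0
            continue
        tie_free = np.unique(np.concatenate([a, b])).size == n_a + n_b
        method = "exact" if (max(n_a, n_b) <= EXACT_MWU_MAX_N and tie_free) else "asymptotic"
        pvals[j] = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    return np.clip(pvals, 0.0, 1.0)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def gini_importance(
    fm: FeatureMatrix,
    labels: LabelTable,
    n_trees: int = 500,
    seed: int = 42,
) -> np.ndarray:
    """Mean decrease in Gini impurity from a seeded forest on the full data.

    Importances are normalized to sum to 1 (all-zero when the forest never
    splits).  Reproducible given the seed.
    """
    from sklearn.ensemble import RandomForestClassifier

    sub = labels.subset(fm.sample_ids)
    counts = sub.class_counts()
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValidationError("gini importance needs >= 2 samples in each of 2 classes")
    y = np.array([sub[s] for s in fm.sample_ids])
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(fm.values, y)
    return forest.feature_importances_


def score_features(
    fm: FeatureMatrix,
    labels: LabelTable,
    n_trees: int = 500,
    seed: int = 42,
) -> list[FeatureScore]:
    """Compute both scoring routes and dense ranks for every feature."""
    p = mwu_pvalues(fm, labels)
    q = bh_fdr(p)
    g = gini_importance(fm, labels, n_trees=n_trees, seed=seed)
    ids = fm.peak_ids
    mwu_order = sorted(range(len(ids)), key=lambda j: (q[j], -g[j], ids[j]))
    gini_order = sorted(range(len(ids)), key=lambda j: (-g[j], q[j], ids[j]))
    rank_mwu = {j: r + 1 for r, j in enumerate(mwu_order)}
    rank_gini = {j: r + 1 for r, j in enumerate(gini_order)}
    return [
        FeatureScore(
            peak_id=ids[j],
            p_value=float(p[j]),
            q_value=float(q[j]),
            gini_decrease=float(g[j]),
            rank_mwu=rank_mwu[j],
            rank_gini=rank_gini[j],
        )
        for j in range(len(ids))
    ]


def select_top(scores: list[FeatureScore], n: int = 10, by: str = "gini") -> list[str]:
    """Top-n peak ids by descending Gini decrease or ascending q-value.

    Ties break by the other criterion, then by peak id, so the selection is
    deterministic.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if by == "gini":
        key = lambda s: (-s.gini_decrease, s.q_value, s.peak_id)
    elif by == "mwu":
        key = lambda s: (s.q_value, -s.gini_decrease, s.peak_id)
    else:
        raise ValidationError(f"unknown ranking criterion {by!r}")
    ordered = sorted(scores, key=key)
    if n > len(ordered):
        warnings.warn(f"requested top {n} of only {len(ordered)} features; returning all")
    return [s.peak_id for s in ordered[:n]]
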