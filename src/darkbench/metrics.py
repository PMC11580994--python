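"""Accuracy and community-structure metrics for profile evaluation.

Set metrics (precision/recall/F1, intersection-over-union) compare which
taxa two profiles contain; Bray-Curtis compares their abundances; Mantel
and Spearman-of-inverse-Simpson compare whole-dataset beta and alpha
diversity structure; the unknown-calibration slope measures how well a
method's estimated unknown abundance tracks the true uncharacterized
abundance (1.0 = perfectly calibrated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix

from .errors import UndefinedMetricError, ValidationError
from .postprocess import RankProfile

_NORM_TOL = 1e-6


def _entries(profile) -> Mapping:
    return profile.entries if isinstance(profile, RankProfile) else profile


def precision_recall_f1(assigned, truth) -> tuple[float, float, float]:
    """Taxon-set precision, recall and F1 of an assigned profile.

    F1 is the harmonic mean of precision and recall, 0 when both are 0.
    """
    a_set, t_set = set(_entries(assigned)), set(_entries(truth))
    if not t_set:
        raise ValidationError("truth set is empty")
    if not a_set:
        return 0.0, 0.0, 0.0
    hits = len(a_set & t_set)
    precision = hits / len(a_set)
    recall = hits / len(t_set)
    f1 = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return precision, recall, f1


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: half the L1 distance over the key union."""
    x_map, y_map = _entries(x), _entries(y)
    for name, m in (("x", x_map), ("y", y_map)):
        total = sum(m.values())
        if abs(total - 1.0) > _NORM_TOL:
            raise ValidationError(f"{name} sums to {total}, expected 1")
    keys = set(x_map) | set(y_map)
    return 0.5 * sum(abs(x_map.get(k, 0.0) - y_map.get(k, 0.0)) for k in keys)


def iou(a, b) -> float:
    """Intersection over union (Jaccard index) of two taxon sets."""
    a_set, b_set = set(_entries(a) if not isinstance(a, (set, frozenset)) else a), set(
        _entries(b) if not isinstance(b, (set, frozenset)) else b
    )
    if not a_set and not b_set:
        raise ValidationError("both sets are empty")
    return len(a_set & b_set) / len(a_set | b_set)


def diversity(profile, index: str = "inverse_simpson") -> float:
    """Alpha diversity of a normalized profile.

    ``inverse_simpson`` is 1/Σp² (effective species number); ``shannon`` is
    −Σ p ln p.
    """
    values = np.array(list(_entries(profile).values()), dtype=float)
    if values.size == 0:
        raise ValidationError("empty profile")
    if abs(values.sum() - 1.0) > _NORM_TOL:
        raise ValidationError("profile must be normalized")
    if index == "inverse_simpson":
        return float(1.0 / np.sum(values**2))
    if index == "shannon":
        positive = values[values > 0]
        return float(-np.sum(positive * np.log(positive)))
    raise ValidationError(f"unknown diversity index {index!r}")


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x_arr, y_arr = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.size < 3:
        raise ValidationError("need equal-length vectors of length >= 3")
    if np.ptp(x_arr) == 0 or np.ptp(y_arr) == 0:
        raise UndefinedMetricError("spearman undefined for a constant vector")
    rho = stats.spearmanr(x_arr, y_arr).statistic
    return float(rho)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices.

    r is the Pearson correlation of the upper triangles; the one-sided
    p-value is (1 + #{permuted r >= observed}) / (1 + n_perm) under
    simultaneous row/column permutation of *d2*.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValidationError("distance matrices cover different samples")
    if len(d1.ids) < 4:
        raise ValidationError("mantel needs at least 4 samples")
    d2 = d2.filter(d1.ids)
    m1, m2 = d1.data, d2.data
    iu = np.triu_indices(m1.shape[0], k=1)
    v1, v2 = m1[iu], m2[iu]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise UndefinedMetricError("mantel undefined for constant distances")
    observed = float(np.corrcoef(v1, v2)[0, 1])
    if n_perm <= 0:
        return observed, float("nan")
    rng = np.random.default_rng() if rng is None else rng
    n = m1.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        permuted = m2[np.ix_(perm, perm)][iu]
        if np.corrcoef(v1, permuted)[0, 1] >= observed:
            count += 1
    return observed, (1 + count) / (1 + n_perm)


def unknown_calibration_slope(
    true_unknown: Sequence[float], estimated_unknown: Sequence[float]
) -> tuple[float, float]:
    """OLS slope and intercept of estimated unknown mass on true unknown mass."""
    x = np.asarray(true_unknown, dtype=float)
    y = np.asarray(estimated_unknown, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("need equal-length vectors of length >= 2")
    if np.any((x < 0) | (x > 1)) or np.any((y < 0) | (y > 1)):
        raise ValidationError("unknown fractions must lie in [0, 1]")
    if np.ptp(x) == 0:
        raise UndefinedMetricError("slope undefined for constant true vector")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept)


def bray_curtis_matrix(profiles: Mapping[str, RankProfile]) -> DistanceMatrix:
    """All-versus-all Bray-Curtis dissimilarity matrix over samples."""
    ids = sorted(profiles)
    n = len(ids)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            data[i, j] = data[j, i] = bray_curtis(profiles[ids[i]], profiles[ids[j]])
    return DistanceMatrix(data, ids)


@dataclass
class EvaluationReport:
    """Per-rank accuracy and per-dataset community-structure metrics."""

    per_rank: pd.DataFrame  # columns: sample, rank, metric, value
    dataset: pd.DataFrame  # columns: metric, value

    def to_tidy(self, dataset: str = "dataset", method: str = "method") -> pd.DataFrame:
        frame = self.per_rank.copy()
        frame.insert(0, "dataset", dataset)
        frame.insert(1, "method", method)
        extra = self.dataset.copy()
        extra.insert(0, "dataset", dataset)
        extra.insert(1, "method", method)
        extra["sample"] = pd.NA
        extra["rank"] = pd.NA
        return pd.concat([frame, extra], ignore_index=True)[
            ["dataset", "method", "sample", "rank", "metric", "value"]
        ]


def evaluate_rank_pair(assigned: RankProfile, truth: RankProfile) -> dict[str, float]:
    """All per-rank accuracy metrics for one (assigned, truth) pair."""
    precision, recall, f1 = precision_recall_f1(assigned, truth)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "bray_curtis": bray_curtis(assigned, truth),
        "iou": iou(assigned, truth),
    }
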