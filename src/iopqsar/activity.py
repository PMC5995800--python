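"""Hypotensive potency scale and k-means IOP activity classing.

Hypotensive potency is summarized by ED20, the dose lowering systemic
arterial pressure by 20%, and by an ordinal Index derived from it on a
fixed mg/kg scale:

====================  =====
ED20 (mg/kg)          Index
====================  =====
ed20 <= 4.0             3
4.0 < ed20 <= 10.0      2
10.0 < ed20 <= 25.0     1
ed20 > 25.0             0
====================  =====

Interval boundaries are left-open/right-closed; the reference drug
bendazole (18.8 mg/kg) scores Index 1.

The binary intraocular-pressure (IOP) activity class is obtained by
2-means clustering of a compounds x 6 matrix of IOP-lowering indicators.
Columns are z-scored first, the best of ``restarts`` seeded random
initializations by within-cluster sum of squares is kept, and the cluster
with the larger mean raw indicator value is labelled 1 (active).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

#: (upper bound in mg/kg, points); scanned in order, first bound that holds wins.
INDEX_SCALE = ((4.0, 3), (10.0, 2), (25.0, 1), (float("inf"), 0))


@dataclass
class ActivityProfile:
    """One compound's hypotensive predictors and (optional) IOP class."""

    code: str
    ed20_mg_kg: float
    index_points: int
    ed20_umol_kg: float
    level: int
    iop_cluster: int | None = None

    def check(self) -> None:
        if not (self.ed20_mg_kg > 0 and np.isfinite(self.ed20_mg_kg)):
            raise ValueError(f"{self.code}: ED20 must be positive and finite")
        expect = index_from_ed20(self.ed20_mg_kg)
        if self.index_points != expect:
            raise ValueError(
                f"{self.code}: Index {self.index_points} inconsistent with "
                f"ED20 {self.ed20_mg_kg} mg/kg (expected {expect})"
            )
        if self.level not in (0, 1, 2):
            raise ValueError(f"{self.code}: Level must be 0, 1 or 2")
        if self.iop_cluster not in (None, 0, 1):
            raise ValueError(f"{self.code}: IOP class must be binary")


def index_from_ed20(ed20: float) -> int:
    """Ordinal potency Index (0-3 points) from an ED20 dose in mg/kg."""
    if not (ed20 > 0 and np.isfinite(ed20)):
        raise ValueError(f"ED20 must be positive and finite, got {ed20}")
    for bound, points in INDEX_SCALE:
        if ed20 <= bound:
            return points
    raise AssertionError("unreachable")


def mgkg_to_umolkg(ed20: float, mw: float) -> float:
    """Convert a dose from mg/kg to umol/kg given a molecular weight in g/mol."""
    if not (ed20 > 0 and np.isfinite(ed20)):
        raise ValueError(f"ED20 must be positive and finite, got {ed20}")
    if not (mw > 0 and np.isfinite(mw)):
        raise ValueError(f"molecular weight must be positive and finite, got {mw}")
    return ed20 / mw * 1000.0


@dataclass
class ClusteringResult:
    labels: np.ndarray          # 1 = active, 0 = inactive
    centroids: np.ndarray       # (2, 6) in standardized coordinates
    inertia: float              # within-cluster sum of squares (standardized)
    column_means: np.ndarray
    column_sds: np.ndarray


def cluster_activity(
    iop: pd.DataFrame | np.ndarray,
    k: int = 2,
    seed: int = 0,
    restarts: int = 50,
) -> ClusteringResult:
    """Split compounds into active/inactive by k-means on 6 IOP indicators.

    Lloyd's algorithm on z-scored columns, best of ``restarts`` random
    initializations by within-cluster sum of squares; deterministic given
    ``seed``.  Row order does not change the partition.  Raises on fewer
    than ``k`` distinct rows (all-identical input included).
    """
    X = np.asarray(iop, dtype=float)
    if X.ndim != 2:
        raise ValueError("IOP matrix must be 2-dimensional")
    if not np.all(np.isfinite(X)):
        raise ValueError("IOP matrix contains non-finite values")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"need at least {k} distinct rows, all rows coincide")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(Z)
    raw_labels = km.labels_
    # orient: cluster with larger mean raw IOP-lowering value is "active" (1)
    means = [X[raw_labels == c].mean() for c in range(k)]
    active_cluster = int(np.argmax(means))
    labels = (raw_labels == active_cluster).astype(int)
    # row 0 = inactive centroid, row 1 = active centroid
    centroids = km.cluster_centers_[[1 - active_cluster, active_cluster]]
    return ClusteringResult(
        labels=labels,
        centroids=centroids,
        inertia=float(km.inertia_),
        column_means=mu,
        column_sds=sd,
    )
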