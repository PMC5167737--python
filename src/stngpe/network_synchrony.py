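"""Whole-network synchrony via PCA component counting.

The synchrony index is the number of principal components needed to
capture a fixed fraction (default 80%) of the variance across the slow
variables of all STN cells: 1 for perfectly coordinated activity, up to
the population size for independent activity.  PCA is performed on the
covariance of mean-centered, non-standardized columns (all cells share
one parameter scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["SynchronyScore", "pca_component_count", "classify_synchrony", "CATEGORIES"]

#: Component-count bins: 1-3 most synchronous ... 8-10 least synchronous.
CATEGORIES = (
    ("red", 1, 3),
    ("green", 4, 5),
    ("blue", 6, 7),
    ("black", 8, 10),
)


@dataclass
class SynchronyScore:
    component_count: int
    variance_fractions: np.ndarray  # descending, sums to 1
    category: str
    matched: bool | None = None  # filled in by the phase-pattern match, if run


def classify_synchrony(count: int, n_max: int = 10) -> str:
    """Map a component count to its synchrony category."""
    if not 1 <= count <= n_max:
        raise ValueError(f"component count {count} out of range 1..{n_max}")
    for name, lo, hi in CATEGORIES:
        if lo <= count <= hi:
            return name
    return CATEGORIES[-1][0]


def pca_component_count(x: np.ndarray, threshold: float = 0.8) -> SynchronyScore:
    """Smallest number of principal components reaching ``threshold`` variance.

    ``x`` is (samples x neurons); columns are mean-centered internally.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (samples >= 2, neurons) matrix")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if np.allclose(x.var(axis=0).sum(), 0.0):
        raise ValueError("zero total variance: degenerate input")
    pca = PCA(n_components=min(x.shape), svd_solver="full")
    pca.fit(x)
    frac = np.zeros(x.shape[1])
    frac[: pca.explained_variance_ratio_.size] = pca.explained_variance_ratio_
    count = int(np.searchsorted(np.cumsum(frac), threshold - 1e-12) + 1)
    count = min(count, x.shape[1])
    return SynchronyScore(
        component_count=count,
        variance_fractions=frac,
        category=classify_synchrony(count, n_max=x.shape[1]),
    )
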