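"""Group- and breed-level comparison of the cohort call set.

Given the binary presence/absence matrix this module computes, per label
(group or breed), the set of SVs carried by at least one member; exact
Venn-region counts over those sets; and a principal component analysis of
the mean-centred presence matrix, the standard view of population
structure from shared variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .popmerge import PresenceMatrix


def group_sets(matrix: PresenceMatrix, level: str = "group") -> dict[str, set[str]]:
    """SV id set per label: every SV with >= 1 carrier in that label."""
    labels = matrix.labels(level)
    out: dict[str, set[str]] = {}
    for label in sorted(labels.unique()):
        rows = matrix.matrix.loc[labels == label]
        present = rows.any(axis=0)
        out[label] = set(present.index[present])
    return out


@dataclass
class VennCounts:
    """Count of SVs present in exactly each nonempty subset of labels."""

    labels: tuple[str, ...]
    counts: dict[frozenset, int]

    def exactly(self, *labels: str) -> int:
        return self.counts.get(frozenset(labels), 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(1, len(self.labels) + 1):
            for combo in combinations(self.labels, r):
                key = frozenset(combo)
                rows.append({"members": "&".join(combo),
                             "count": self.counts.get(key, 0)})
        return pd.DataFrame(rows)


def venn_counts(sets: Mapping[str, set]) -> VennCounts:
    """Exact membership-pattern tally over >= 2 labelled sets."""
    if len(sets) < 2:
        raise ValueError("venn_counts needs at least two sets")
    labels = tuple(sorted(sets))
    counts: dict[frozenset, int] = {}
    universe = set().union(*sets.values())
    for item in universe:
        key = frozenset(l for l in labels if item in sets[l])
        counts[key] = counts.get(key, 0) + 1
    return VennCounts(labels, counts)


def specific_sets(sets: Mapping[str, set]) -> dict[str, set]:
    """Per label, the items found in that label and no other."""
    out = {}
    for label, s in sets.items():
        others = set().union(*(v for k, v in sets.items() if k != label)) \
            if len(sets) > 1 else set()
        out[label] = s - others
    return out


@dataclass
class PcaResult:
    coordinates: pd.DataFrame        # samples x components
    variance_explained: np.ndarray   # per component, in [0, 1]
    loadings: np.ndarray             # components x SVs

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def pca(matrix: PresenceMatrix, n_components: int = 2) -> PcaResult:
    """PCA of the presence/absence matrix by SVD of the centred matrix.

    Columns are mean-centred but not variance-scaled (standard for binary
    presence data).  Variance explained per component is the squared
    singular value over the total variance.  Sign convention: each
    component's largest-magnitude loading is made positive, so results are
    reproducible across runs and BLAS builds.  A constant matrix yields
    all-zero coordinates and zero variance, not an error.
    """
    X = matrix.matrix.to_numpy(dtype=float)
    n_samples, n_svs = X.shape
    if n_samples < 2 or n_svs < 1:
        raise ValueError("PCA needs >= 2 samples and >= 1 SV column")
    n_components = min(n_components, n_samples - 1, n_svs)

    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = (s ** 2).sum()

    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components]
    for k in range(n_components):
        pivot = np.argmax(np.abs(loadings[k]))
        if loadings[k, pivot] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    if total_var > 0:
        var_exp = (s[:n_components] ** 2) / total_var
    else:
        var_exp = np.zeros(n_components)
        scores = np.zeros_like(scores)

    coords = pd.DataFrame(scores, index=matrix.matrix.index,
                          columns=[f"PC{k + 1}" for k in range(n_components)])
    return PcaResult(coords, var_exp, loadings)
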