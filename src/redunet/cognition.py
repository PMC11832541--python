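"""Cognitive-domain PCA with line-distance elbow selection.

The 13 cognitive test variables are z-scored over complete cases and
decomposed by PCA.  The number of retained components is chosen by the
maximum-distance-to-chord elbow rule on the explained-variance scree, and
each retained component is labeled with the cognitive domain (episodic,
semantic, executive) holding the plurality of its strongest loadings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .synth import TEST_CATEGORIES


class ConstantColumnError(ValueError):
    """A cognitive variable has zero variance and cannot be z-scored."""


class AmbiguousDomainError(ValueError):
    """A component's top loadings tie between domains; label it manually."""


@dataclass(frozen=True)
class CognitiveComponents:
    """PCA decomposition of the cognitive battery.

    ``loadings`` is tests x components (orthonormal columns, each flipped so
    its largest-magnitude coefficient is positive); ``variance_fraction``
    holds all component fractions (summing to 1); ``scores`` are subject
    scores for all components; ``n_retained`` is the elbow choice and
    ``domain_labels`` tags the retained components.
    """

    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    scores: pd.DataFrame
    n_retained: int = 0
    domain_labels: tuple[str, ...] = ()

    @property
    def retained_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.n_retained]


def complete_cases(table: pd.DataFrame) -> pd.DataFrame:
    """Drop rows with any missing value (before z-scoring, so means and
    standard deviations are computed on the analyzed sample only)."""
    return table.dropna(axis=0, how="any")


def zscore_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, sample SD 1 (n-1 denominator)."""
    sd = table.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ConstantColumnError(f"constant column(s): {bad}")
    return (table - table.mean(axis=0)) / sd


def run_pca(table: pd.DataFrame) -> CognitiveComponents:
    """Full PCA of a z-scored test table (all components).

    Components are ordered by explained variance.  Sign convention: each
    loading column is flipped so its largest-|loading| coefficient is
    positive (signs carry no statistical meaning).
    """
    x = table.to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than variables ({p})")
    pca = PCA(n_components=p)
    raw_scores = pca.fit_transform(x)
    loadings = pca.components_.T  # p x p, orthonormal columns
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = raw_scores * flip
    comp_names = [f"PC{i + 1}" for i in range(p)]
    return CognitiveComponents(
        loadings=pd.DataFrame(loadings, index=table.columns, columns=comp_names),
        variance_fraction=pca.explained_variance_ratio_.copy(),
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
    )


def find_elbow(curve: Sequence[float]) -> int:
    """1-based index of the scree point farthest from the first-last chord.

    Draws the chord from the first to the last observation in
    (index, value) coordinates and returns the observation maximizing the
    perpendicular distance to it; ties take the smallest index.
    """
    y = np.asarray(curve, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need at least 3 points to locate an elbow")
    x = np.arange(1.0, y.size + 1.0)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    # perpendicular distance from (x_i, y_i) to the chord
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    # ties (within floating-point noise) take the earliest point
    return int(np.argmax(dist >= dist.max() - 1e-12 * max(1.0, dist.max()))) + 1


def label_components(
    components: CognitiveComponents,
    n_retained: int,
    test_category_map: Mapping[str, str] | None = None,
) -> tuple[str, ...]:
    """Domain label for each retained component.

    Each component is labeled by the domain that primarily influences it:
    the domain whose own tests carry the highest mean |loading| on the
    component (normalizing by domain size keeps a 6-test domain comparable
    to a 3-test one, equivalent in spirit to asking which domain dominates
    the component's top loadings).  An exact tie between domains raises
    :class:`AmbiguousDomainError` so the label can be set manually.
    """
    cmap = dict(test_category_map or TEST_CATEGORIES)
    unmapped = [t for t in components.loadings.index if t not in cmap]
    if unmapped:
        raise KeyError(f"tests missing from category map: {unmapped}")
    domains = sorted(set(cmap.values()))
    labels = []
    for comp in components.loadings.columns[:n_retained]:
        col = components.loadings[comp].abs()
        votes = {
            d: col[[t for t in col.index if cmap[t] == d]].mean() for d in domains
        }
        best = max(votes.values())
        winners = [d for d, v in votes.items() if abs(v - best) < 1e-12]
        if len(winners) > 1:
            raise AmbiguousDomainError(
                f"{comp}: domains {winners} tie at mean |loading| {best:.3f}"
            )
        labels.append(winners[0])
    return tuple(labels)


def analyze_cognition(
    table: pd.DataFrame,
    test_category_map: Mapping[str, str] | None = None,
) -> CognitiveComponents:
    """Complete-case filter, z-score, PCA, elbow selection, domain labels.

    ``table`` holds one row per subject and one column per test (an index
    or ``subject_id`` column identifies subjects).  The elbow is located on
    the explained-variance percentage scree.
    """
    if "subject_id" in table.columns:
        table = table.set_index("subject_id")
    table = complete_cases(table)
    z = zscore_columns(table)
    comps = run_pca(z)
    n_retained = find_elbow(100.0 * comps.variance_fraction)
    labels = label_components(comps, n_retained, test_category_map)
    return CognitiveComponents(
        loadings=comps.loadings,
        variance_fraction=comps.variance_fraction,
        scores=comps.scores,
        n_retained=n_retained,
        domain_labels=labels,
    )
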