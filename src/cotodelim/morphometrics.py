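"""Mixed-trait morphometrics: Gower distance, UPGMA, PCA, diagnosability.

Quantitative and integer-coded qualitative traits are combined with
Gower's coefficient (range-normalized absolute differences averaged
with mismatch indicators), clustered by average linkage, and ordinated
by correlation-matrix PCA. The delimitation framework's morphological
criterion is the number of *discontinuous* traits between two taxa: a
quantitative trait whose observed ranges do not overlap, or a
qualitative trait whose observed state sets are disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import QUALITATIVE, QUANTITATIVE, TraitTable

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with labelled rows."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        if (self.matrix < -1e-12).any():
            raise ValueError("negative distances")

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


def gower_matrix(T: TraitTable) -> DistanceMatrix:
    """Gower distance over mixed traits with pairwise deletion.

    Per pair of units, each trait observed in both contributes
    ``|x_i - x_j| / range`` (quantitative; a zero-range trait
    contributes 0) or a 0/1 mismatch indicator (qualitative); the
    distance is the mean over shared observed traits. A pair sharing no
    observed trait is an error.
    """
    units = T.units
    n = len(units)
    if n < 2:
        raise ValueError("need at least 2 units")
    vals = T.values.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    if not obs.any(axis=0).all():
        t = T.values.columns[~obs.any(axis=0)][0]
        raise ValueError(f"trait {t!r} has no observed value")
    contrib = np.zeros((n, n, len(T.traits)))
    shared = np.zeros((n, n), dtype=int)
    for t_idx, trait in enumerate(T.traits):
        col = vals[:, t_idx]
        both = obs[:, t_idx][:, None] & obs[:, t_idx][None, :]
        diff = np.abs(col[:, None] - col[None, :])
        if trait.kind == QUANTITATIVE:
            rng = np.nanmax(col) - np.nanmin(col)
            c = diff / rng if rng > 0 else np.zeros_like(diff)
        else:
            c = (diff > 0).astype(float)
        contrib[:, :, t_idx] = np.where(both, c, 0.0)
        shared += both.astype(int)
    np.fill_diagonal(shared, len(T.traits))
    if (shared == 0).any():
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"units {units[i]!r} and {units[j]!r} share no observed trait")
    d = contrib.sum(axis=2) / shared
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(units), d)


class Dendrogram:
    """Ultrametric average-linkage tree with merge heights.

    Heights are half the between-cluster average distance, so two units
    at distance ``d`` merge at height ``d/2`` and cophenetic distances
    reproduce the linkage scale.
    """

    def __init__(self, labels: list[str], linkage: np.ndarray):
        self.labels = list(labels)
        self.linkage = linkage

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2] / 2.0

    def cophenetic(self) -> DistanceMatrix:
        cond = hierarchy.cophenet(self.linkage)
        return DistanceMatrix(self.labels, squareform(cond, checks=False))

    def cut(self, n_clusters: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=n_clusters,
                                  criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_h: float) -> str:
            h = node.dist / 2.0
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_h:g}"
            left = rec(node.left, h)
            right = rec(node.right, h)
            return f"({left},{right}):{parent_h - h:g}"

        root_h = tree.dist / 2.0
        return f"({rec(tree.left, root_h)},{rec(tree.right, root_h)});"


def upgma_cluster(D: DistanceMatrix) -> Dendrogram:
    """Agglomerative average-linkage (UPGMA) clustering."""
    Z = hierarchy.linkage(D.condensed(), method="average")
    return Dendrogram(D.labels, Z)


def trait_pca(T: TraitTable) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """PCA of the trait correlation matrix (qualitative traits as coded
    integers, all columns standardized).

    Returns (scores, variance fractions, trait contributions); the
    contribution of trait t to PC k is its squared loading as a percent,
    summing to 100 per PC. Constant traits are excluded with a warning.
    """
    vals = T.values
    sd = vals.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = list(vals.columns[~keep])
    if dropped:
        log.warning("excluding constant trait(s) from PCA: %s", dropped)
    vals = vals.loc[:, keep]
    if vals.shape[1] == 0:
        raise ValueError("no varying traits")
    if vals.isna().any().any():
        vals = vals.fillna(vals.mean(axis=0))
    X = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    X = X.to_numpy()
    corr = (X.T @ X) / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    fractions = eigval / eigval.sum()
    pcs = [f"PC{i + 1}" for i in range(len(eigval))]
    scores = pd.DataFrame(X @ eigvec, index=T.values.index, columns=pcs)
    contributions = pd.DataFrame(eigvec ** 2 * 100.0,
                                 index=vals.columns, columns=pcs)
    return scores, fractions, contributions


@dataclass
class TraitVerdict:
    trait: str
    discontinuous: bool
    detail: str


def count_diagnostic_traits(T: TraitTable, taxon_a: list[str],
                            taxon_b: list[str], gap_fraction: float = 0.0,
                            min_traits: int = 2
                            ) -> tuple[int, bool, list[TraitVerdict]]:
    """Count traits with discontinuous observed distributions between
    two unit sets.

    A quantitative trait is discontinuous iff the observed [min, max]
    intervals are disjoint (optionally by more than ``gap_fraction`` of
    the trait's overall range); a qualitative trait iff the observed
    state sets are disjoint. Traits observed on only one side are
    excluded (logged). Returns (count, count >= min_traits, verdicts).
    """
    ia = T.values.index.isin(taxon_a)
    ib = T.values.index.isin(taxon_b)
    if not ia.any() or not ib.any():
        raise ValueError("both unit sets must be non-empty in the table")
    verdicts: list[TraitVerdict] = []
    count = 0
    for trait in T.traits:
        col = T.values[trait.name]
        a = col[ia].dropna()
        b = col[ib].dropna()
        if a.empty or b.empty:
            log.info("trait %s observed on one side only; excluded",
                     trait.name)
            continue
        if trait.kind == QUANTITATIVE:
            rng = col.max() - col.min()
            gap = gap_fraction * rng
            disc = (a.min() > b.max() + gap) or (b.min() > a.max() + gap)
            detail = (f"[{a.min():g},{a.max():g}] vs "
                      f"[{b.min():g},{b.max():g}]")
        else:
            sa, sb = set(a.astype(int)), set(b.astype(int))
            disc = sa.isdisjoint(sb)
            detail = f"{sorted(sa)} vs {sorted(sb)}"
        verdicts.append(TraitVerdict(trait.name, disc, detail))
        count += int(disc)
    return count, count >= min_traits, verdicts
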