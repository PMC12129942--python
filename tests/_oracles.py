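"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately naive (nested loops, exhaustive
enumeration, a second tree library) and shares no code with the
package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np

MISSING = -9


# ---------------------------------------------------------------- filtering

def site_filter_oracle(dosages: np.ndarray, max_missing: float,
                       min_mac: int, min_maf: float) -> list[int]:
    """Per-site re-check with explicit loops."""
    n, m = dosages.shape
    keep = []
    for j in range(m):
        col = [int(x) for x in dosages[:, j]]
        obs = [x for x in col if x != MISSING]
        miss_frac = 1 - len(obs) / n
        if miss_frac > max_missing:
            continue
        alt = sum(obs)
        ref = 2 * len(obs) - alt
        mac = min(alt, ref)
        if mac < min_mac:
            continue
        maf = mac / (2 * len(obs)) if obs else 0.0
        if maf < min_maf:
            continue
        keep.append(j)
    return keep


def pearson_r2(x: list[float], y: list[float]) -> float:
    pairs = [(a, b) for a, b in zip(x, y)
             if a != MISSING and b != MISSING]
    if len(pairs) < 2:
        return 0.0
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    mx = sum(xs) / len(xs)
    my = sum(ys) / len(ys)
    sxx = sum((a - mx) ** 2 for a in xs)
    syy = sum((b - my) ** 2 for b in ys)
    sxy = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    if sxx == 0 or syy == 0:
        return 0.0
    return (sxy * sxy) / (sxx * syy)


def ld_prune_oracle(dosages: np.ndarray, window: int, step: int,
                    r2_max: float) -> list[int]:
    """Quadratic windowed greedy pruning with the same tie rule."""
    m = dosages.shape[1]
    keep = [True] * m
    cols = [list(dosages[:, j]) for j in range(m)]
    start = 0
    while True:
        stop = min(start + window, m)
        while True:
            live = [j for j in range(start, stop) if keep[j]]
            best = 0.0
            for a, b in itertools.combinations(live, 2):
                r2 = pearson_r2(cols[a], cols[b])
                if r2 > best:
                    best = r2
            if best <= r2_max:
                break
            drop = -1
            for a, b in itertools.combinations(live, 2):
                if pearson_r2(cols[a], cols[b]) >= best - 1e-12:
                    drop = max(drop, max(a, b))
            keep[drop] = False
        if stop >= m:
            break
        start += step
    return [j for j in range(m) if keep[j]]


# ---------------------------------------------------------------- trees

def dendropy_sides(newick: str) -> set[frozenset]:
    """All internal bipartition sides via an independent traversal."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    sides = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(below) <= len(leaves) - 2:
            sides.add(below)
            sides.add(leaves - below)
    return sides


def monophyly_oracle(newick: str, target: set) -> bool:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    target = frozenset(target)
    # pendant edges are bipartitions too: a single leaf, or all but one,
    # is trivially one side of the bipartition induced by that edge
    if len(target) <= 1 or len(leaves - target) <= 1:
        return True
    return target in dendropy_sides(newick) or \
        (leaves - target) in dendropy_sides(newick)


def min_containing_side_oracle(newick: str, inside: set,
                               outside: set) -> frozenset | None:
    """Smallest bipartition side containing ``inside``, avoiding
    ``outside``; None when no side qualifies."""
    candidates = [s for s in dendropy_sides(newick)
                  if frozenset(inside) <= s and not (s & frozenset(outside))]
    # pendant sides too
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    for leaf in leaves:
        for s in (frozenset([leaf]), leaves - {leaf}):
            if frozenset(inside) <= s and not (s & frozenset(outside)):
                candidates.append(s)
    if not candidates:
        return None
    return min(candidates, key=lambda s: (len(s), sorted(s)))


def nj_oracle_sides(labels: list[str], matrix: np.ndarray
                    ) -> set[frozenset]:
    """Neighbor joining via dendropy as an independent implementation."""
    import io as _io

    pdm_csv = "," + ",".join(labels) + "\n"
    for i, lab in enumerate(labels):
        pdm_csv += lab + "," + ",".join(str(matrix[i, j])
                                        for j in range(len(labels))) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=_io.StringIO(pdm_csv), delimiter=",")
    tree = pdm.nj_tree()
    newick = tree.as_string(schema="newick")
    return dendropy_sides(newick)


def upgma_oracle(labels: list[str], matrix: np.ndarray
                 ) -> list[tuple[frozenset, float]]:
    """Naive UPGMA; returns (cluster, merge height) per merge."""
    clusters = [frozenset([l]) for l in labels]
    d = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d[frozenset([clusters[i], clusters[j]])] = matrix[i, j]
    merges = []
    while len(clusters) > 1:
        pair = min(d, key=lambda k: d[k])
        dist = d[pair]
        a, b = tuple(pair)
        new = a | b
        merges.append((new, dist / 2.0))
        clusters = [c for c in clusters if c not in (a, b)]
        for c in clusters:
            da = d.pop(frozenset([a, c]))
            db = d.pop(frozenset([b, c]))
            d[frozenset([new, c])] = (len(a) * da + len(b) * db) \
                / (len(a) + len(b))
        del d[pair]
        clusters.append(new)
    return merges


# ---------------------------------------------------------------- matching

def best_label_permutation(corr: np.ndarray) -> tuple[tuple[int, ...], float]:
    """Exhaustive search over column permutations maximizing the trace."""
    k_ref, k_other = corr.shape
    best, best_score = None, -math.inf
    for perm in itertools.permutations(range(k_other), k_ref):
        score = sum(corr[i, perm[i]] for i in range(k_ref))
        if score > best_score:
            best, best_score = perm, score
    return best, best_score


def best_clade_correspondence(conf: np.ndarray) -> int:
    """Max concordant count over exhaustive label assignments."""
    n_nuc, n_pla = conf.shape
    best = -1
    r = min(n_nuc, n_pla)
    for rows in itertools.permutations(range(n_nuc), r):
        for cols in itertools.permutations(range(n_pla), r):
            score = sum(conf[i, j] for i, j in zip(rows, cols))
            best = max(best, score)
    return best


def diagnostic_count_oracle(values, kinds, units_a, units_b) -> int:
    """Brute-force per-trait interval/state check.

    ``values`` is a pandas DataFrame, ``kinds`` maps trait -> kind.
    """
    count = 0
    for trait in values.columns:
        a = values.loc[values.index.isin(units_a), trait].dropna()
        b = values.loc[values.index.isin(units_b), trait].dropna()
        if a.empty or b.empty:
            continue
        if kinds[trait] == "quantitative":
            disjoint = a.min() > b.max() or b.min() > a.max()
        else:
            disjoint = not (set(a.astype(int)) & set(b.astype(int)))
        count += int(disjoint)
    return count
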