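"""Tree building, support-thresholded monophyly, backbone clades, and
cytonuclear discordance.

Monophyly is assessed in the bipartition (unrooted) sense: a leaf set
is monophyletic iff it, or its complement, is one side of some edge of
the tree, and it *passes* only when the stem edge's SH-aLRT and UFboot
supports clear their thresholds (absent support fails closed).
Discordance between a nuclear and a plastid backbone-clade labelling is
counted under the label correspondence that maximizes the number of
concordant populations (an optimal assignment on the confusion matrix),
so clade names never need to match across trees.

A distance-based neighbor-joining builder with site-resampling
bootstrap is included so synthetic scenarios run end to end; it writes
the bootstrap percentage into both support slots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datatypes import MISSING, CladeMap, GenotypeMatrix, SampleMap
from .morphometrics import DistanceMatrix
from .trees import SupportTree, parse_support_tree

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# neighbor joining

def nj_tree(D: DistanceMatrix) -> SupportTree:
    """Standard neighbor joining; negative branch lengths clamped to 0.

    Supports are absent on every edge; attach them with
    :func:`bootstrap_supports` when genotypes are available.
    """
    if len(D.labels) < 3:
        raise ValueError("need at least 3 units")
    if not np.isfinite(D.matrix).all():
        raise ValueError("non-finite distances")
    d = D.matrix.astype(float).copy()
    nodes = [f"{lab}" for lab in D.labels]
    n = len(nodes)
    while n > 3:
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = (f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})")
        dk = (d[i, :] + d[j, :] - d[i, j]) / 2.0
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep],
                       dk[keep][None, :]])
        d = np.hstack([d, np.append(dk[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        n -= 1
    la = max((d[0, 1] + d[0, 2] - d[1, 2]) / 2.0, 0.0)
    lb = max((d[0, 1] + d[1, 2] - d[0, 2]) / 2.0, 0.0)
    lc = max((d[0, 2] + d[1, 2] - d[0, 1]) / 2.0, 0.0)
    newick = (f"({nodes[0]}:{la:.10g},{nodes[1]}:{lb:.10g},"
              f"{nodes[2]}:{lc:.10g});")
    return parse_support_tree(newick)


def genotype_distance(G: GenotypeMatrix,
                      site_index: np.ndarray | None = None
                      ) -> DistanceMatrix:
    """Mean absolute dosage difference / 2 over pairwise-complete sites."""
    d = np.where(G.dosages == MISSING, np.nan, G.dosages).astype(float)
    if site_index is not None:
        d = d[:, site_index]
    n = d.shape[0]
    obs = ~np.isnan(d)
    filled = np.where(obs, d, 0.0)
    # |a-b| for dosages in {0,1,2}: use (a-b)^2 and |a-b| identities
    gram = filled @ filled.T
    sq = (filled ** 2) @ obs.T.astype(float)
    counts = obs.astype(float) @ obs.T.astype(float)
    sqdiff = sq + sq.T - 2 * gram
    absdiff = np.zeros_like(sqdiff)
    # exact |a-b| needs a loop only over the 1-vs-(0,2) case; with
    # dosages, |a-b| = (a-b)^2 unless |a-b| == 2 where (a-b)^2 == 4.
    two = np.zeros_like(sqdiff)
    hi = (d == 2).astype(float)
    lo = (d == 0).astype(float)
    hi = np.where(obs, hi, 0.0)
    lo = np.where(obs, lo, 0.0)
    two = hi @ lo.T + lo @ hi.T
    absdiff = sqdiff - 2 * two
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(counts > 0, absdiff / (2.0 * counts), 0.0)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(list(G.samples), dist)


def _canonical_sides(tree: SupportTree) -> set[frozenset]:
    """Internal bipartitions as canonical frozensets (side not holding
    the alphabetically first leaf)."""
    leaves = tree.leaf_labels
    anchor = min(leaves)
    out = set()
    for side in tree.bipartition_sides():
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        canon = side if anchor not in side else leaves - side
        out.add(canon)
    return out


def bootstrap_supports(G: GenotypeMatrix, n_reps: int = 100,
                       seed: int = 0) -> SupportTree:
    """NJ tree over samples with site-resampling bootstrap percentages.

    Each internal bipartition of the point tree is annotated with the
    percentage of replicates recovering it; the value fills both the
    SH-aLRT and UFboot slots (a documented limitation: SH-aLRT is not
    simulated).
    """
    if G.n_samples < 4:
        raise ValueError("need at least 4 samples")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    point = nj_tree(genotype_distance(G))
    counts: dict[frozenset, int] = {s: 0 for s in _canonical_sides(point)}
    for _ in range(n_reps):
        idx = rng.integers(0, G.n_sites, size=G.n_sites)
        rep = nj_tree(genotype_distance(G, site_index=idx))
        for side in _canonical_sides(rep):
            if side in counts:
                counts[side] += 1
    leaves = point.leaf_labels
    anchor = min(leaves)
    sides = point.bipartition_sides()
    for side, node in sides.items():
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        canon = side if anchor not in side else leaves - side
        pct = 100.0 * counts[canon] / n_reps
        node.sh_alrt = pct
        node.ufboot = pct
    return point


# ---------------------------------------------------------------------
# monophyly

@dataclass
class MonophylyResult:
    """Bipartition-sense monophyly of a target leaf set with the stem
    edge's support pair."""

    target: frozenset
    is_monophyletic: bool
    sh_alrt: float | None
    ufboot: float | None
    passes_thresholds: bool
    supports_waived: bool = False


def assess_monophyly(T: SupportTree, leaves, sh_min: float = 80.0,
                     uf_min: float = 95.0,
                     waive_singletons: bool = True) -> MonophylyResult:
    """Test whether ``leaves`` form one side of some bipartition of
    ``T`` and whether the stem supports clear the thresholds.

    Singleton targets (and the degenerate full-leaf-set target) are
    monophyletic with absent stem supports; they pass only when
    ``waive_singletons`` is set (the default, matching the treatment of
    single-population taxa).
    """
    target = frozenset(leaves)
    all_leaves = T.leaf_labels
    unknown = target - all_leaves
    if unknown:
        raise ValueError(f"unknown leaf {sorted(unknown)[0]!r}")
    if not target:
        raise ValueError("empty target set")
    if len(target) == 1 or target == all_leaves:
        return MonophylyResult(target, True, None, None,
                               bool(waive_singletons),
                               supports_waived=True)
    sides = T.bipartition_sides()
    # the same unrooted edge may be represented by both the target side
    # and its complement (children of a bifurcating root): prefer
    # whichever carries the support annotation
    node = sides.get(target)
    comp_node = sides.get(all_leaves - target)
    if node is None and comp_node is None:
        return MonophylyResult(target, False, None, None, False)
    if node is None or (node.sh_alrt is None and node.ufboot is None):
        if comp_node is not None and (comp_node.sh_alrt is not None
                                      or comp_node.ufboot is not None):
            node = comp_node
        elif node is None:
            node = comp_node
    sh, uf = node.sh_alrt, node.ufboot
    passes = (sh is not None and uf is not None
              and sh >= sh_min and uf >= uf_min)
    return MonophylyResult(target, True, sh, uf, passes)


# ---------------------------------------------------------------------
# backbone clades

def assign_backbone_clades(T: SupportTree,
                           seeds: dict[str, set]) -> CladeMap:
    """Label leaves by backbone clade from exemplar leaf sets.

    Each clade is the smallest bipartition side containing every
    exemplar of its label and none of any other; leaves outside all
    chosen sides stay unassigned.
    """
    labels = list(seeds)
    exemplars = {lab: frozenset(s) for lab, s in seeds.items()}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if exemplars[a] & exemplars[b]:
                raise ValueError(f"exemplar sets of {a!r} and {b!r} overlap")
    leaves = T.leaf_labels
    for lab, ex in exemplars.items():
        missing = ex - leaves
        if missing:
            raise ValueError(
                f"exemplar {sorted(missing)[0]!r} of {lab!r} not in tree")
    all_sides: set[frozenset] = set()
    for side in T.bipartition_sides():
        if 0 < len(side) < len(leaves):
            all_sides.add(side)
            all_sides.add(leaves - side)
    chosen: dict[str, frozenset] = {}
    for lab in labels:
        others = frozenset().union(*(exemplars[o] for o in labels
                                     if o != lab)) if len(labels) > 1 \
            else frozenset()
        candidates = [s for s in all_sides
                      if exemplars[lab] <= s and not (s & others)]
        if not candidates:
            raise ValueError(
                f"exemplars of {lab!r} are not separable from "
                f"{sorted(set(labels) - {lab})} on any bipartition side")
        chosen[lab] = min(candidates, key=lambda s: (len(s), sorted(s)))
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if chosen[a] & chosen[b]:
                raise ValueError(
                    f"backbone sides for {a!r} and {b!r} overlap: "
                    f"{sorted(chosen[a] & chosen[b])[:5]}")
    assignments: dict[str, str] = {}
    for lab in labels:
        for leaf in chosen[lab]:
            assignments[leaf] = lab
    return CladeMap(assignments)


# ---------------------------------------------------------------------
# cytonuclear discordance

@dataclass
class DiscordanceReport:
    """Per-population concordance between nuclear and plastid backbone
    clades under the agreement-maximizing label correspondence."""

    correspondence: dict[str, str]
    flags: dict[str, bool]  # population -> discordant?
    discordant_species: list[str] = field(default_factory=list)

    @property
    def n_discordant_populations(self) -> int:
        return sum(self.flags.values())

    @property
    def n_discordant_species(self) -> int:
        return len(self.discordant_species)

    def to_tsv(self) -> str:
        lines = ["population\tdiscordant"]
        lines += [f"{p}\t{int(f)}" for p, f in sorted(self.flags.items())]
        return "\n".join(lines) + "\n"


def detect_cytonuclear_discordance(nuclear: CladeMap, plastid: CladeMap,
                                   M: SampleMap) -> DiscordanceReport:
    """Count populations whose plastid clade conflicts with their
    nuclear clade.

    The nuclear -> plastid clade correspondence is the optimal
    assignment on the label confusion matrix; a population is
    discordant iff its plastid label differs from the image of its
    nuclear label (nuclear labels left without an image are discordant
    throughout). A species is discordant iff at least one of its
    populations is.
    """
    common = [p for p in nuclear.assignments if p in plastid.assignments]
    dropped = (set(nuclear.assignments) | set(plastid.assignments)) \
        - set(common)
    if dropped:
        log.info("populations excluded from discordance (unassigned in "
                 "one map): %s", sorted(dropped))
    if not common:
        raise ValueError("no population assigned in both clade maps")
    nuc_labels = sorted({nuclear.assignments[p] for p in common})
    pla_labels = sorted({plastid.assignments[p] for p in common})
    conf = np.zeros((len(nuc_labels), len(pla_labels)))
    for p in common:
        i = nuc_labels.index(nuclear.assignments[p])
        j = pla_labels.index(plastid.assignments[p])
        conf[i, j] += 1
    rows, cols = linear_sum_assignment(-conf)
    image = {nuc_labels[i]: pla_labels[j] for i, j in zip(rows, cols)}
    flags = {}
    for p in common:
        img = image.get(nuclear.assignments[p])
        flags[p] = (img is None) or (plastid.assignments[p] != img)
    taxon_of = M.taxon_of_population()
    species = sorted({taxon_of[p] for p, f in flags.items()
                      if f and p in taxon_of})
    return DiscordanceReport(image, flags, species)
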