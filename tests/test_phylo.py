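"""NJ, bootstrap supports, monophyly, backbone clades, discordance."""

import random

import numpy as np
import pytest

from cotodelim.datatypes import CladeMap, SampleMap
from cotodelim.morphometrics import DistanceMatrix, upgma_cluster
from cotodelim.phylo import (assess_monophyly, assign_backbone_clades,
                             bootstrap_supports,
                             detect_cytonuclear_discordance,
                             genotype_distance, nj_tree)
from cotodelim.trees import parse_support_tree, random_topology_newick

from _oracles import (best_clade_correspondence, dendropy_sides,
                      min_containing_side_oracle, monophyly_oracle,
                      nj_oracle_sides)


def patristic(tree):
    """Leaf-to-leaf path lengths from a SupportTree."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])


class TestNjTree:
    def test_recovers_additive_tree_exactly(self):
        # ((A:1,B:2):1,(C:1,D:1)) -> AB=3 AC=3 AD=3 BC=4 BD=4 CD=2
        m = np.array([[0, 3, 3, 3], [3, 0, 4, 4],
                      [3, 4, 0, 2], [3, 4, 2, 0]], float)
        t = nj_tree(DistanceMatrix(list("ABCD"), m))
        sides = {frozenset(s) for s in t.bipartition_sides()}
        assert frozenset("AB") in sides or frozenset("CD") in sides
        d = patristic(t)
        for (a, b), exp in {("A", "B"): 3, ("A", "C"): 3, ("A", "D"): 3,
                            ("B", "C"): 4, ("B", "D"): 4,
                            ("C", "D"): 2}.items():
            assert abs(d(a, b) - exp) < 1e-9

    def test_three_taxa_give_unique_star(self):
        m = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        t = nj_tree(DistanceMatrix(list("ABC"), m))
        assert t.leaf_labels == frozenset("ABC")
        assert t.internal_sides() == {}

    def test_matches_dendropy_on_random_matrices(self, rng):
        for _ in range(5):
            n = 7
            x = rng.uniform(0, 1, (n, 5))
            m = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
            labels = [f"t{i}" for i in range(n)]
            ours = nj_tree(DistanceMatrix(labels, m))
            our_sides = {s if f"t0" not in s else ours.leaf_labels - s
                         for s in ours.internal_sides()}
            oracle = nj_oracle_sides(labels, m)
            leaves = frozenset(labels)
            oracle = {s if "t0" not in s else leaves - s for s in oracle}
            assert our_sides == oracle

    def test_ultrametric_input_matches_upgma_topology(self, rng):
        for rep in range(20):
            n = 6
            x = rng.uniform(0, 1, (n, 3))
            raw = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
            labels = [f"t{i}" for i in range(n)]
            dend = upgma_cluster(DistanceMatrix(labels, raw))
            um = dend.cophenetic().matrix  # ultrametric by construction
            t = nj_tree(DistanceMatrix(labels, um))
            nj_sides = {s if "t0" not in s else t.leaf_labels - s
                        for s in t.internal_sides()}
            up_sides = dendropy_sides(dend.to_newick())
            leaves = frozenset(labels)
            up_sides = {s if "t0" not in s else leaves - s
                        for s in up_sides}
            assert nj_sides <= up_sides

    def test_non_finite_distances_are_error(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            nj_tree(DistanceMatrix(list("ABC"), m))


class TestBootstrapSupports:
    def _two_group_matrix(self, genotype_factory, rng, n=5, sites=300):
        a = rng.binomial(2, 0.95, (n, sites))
        b = rng.binomial(2, 0.05, (n, sites))
        return genotype_factory(np.vstack([a, b]))

    def test_deep_split_gets_high_support(self, genotype_factory, rng):
        G = self._two_group_matrix(genotype_factory, rng)
        t = bootstrap_supports(G, n_reps=200, seed=3)
        stem = frozenset(G.samples[:5])
        sh, uf = t.support_of_side(stem)
        assert sh == uf and uf >= 95.0

    def test_single_replicate_supports_are_binary(self, genotype_factory,
                                                  rng):
        G = self._two_group_matrix(genotype_factory, rng)
        t = bootstrap_supports(G, n_reps=1, seed=4)
        vals = {n.ufboot for n in t.internal_sides().values()
                if n.ufboot is not None}
        assert vals <= {0.0, 100.0}

    def test_fixed_seed_reproduces_supports_bitwise(self, genotype_factory,
                                                    rng):
        G = self._two_group_matrix(genotype_factory, rng)
        t1 = bootstrap_supports(G, n_reps=50, seed=9)
        t2 = bootstrap_supports(G, n_reps=50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_fewer_than_four_samples_is_error(self, genotype_factory, rng):
        G = genotype_factory(rng.integers(0, 3, (3, 20)))
        with pytest.raises(ValueError, match="4 samples"):
            bootstrap_supports(G)


class TestAssessMonophyly:
    TREE = "((g1,g2)99.8/100,(x,y));"

    def test_supported_clade_passes_thresholds(self):
        t = parse_support_tree(self.TREE)
        r = assess_monophyly(t, {"g1", "g2"})
        assert r.is_monophyletic and r.passes_thresholds
        assert (r.sh_alrt, r.ufboot) == (99.8, 100.0)

    def test_scattered_target_is_not_monophyletic(self):
        t = parse_support_tree(self.TREE)
        r = assess_monophyly(t, {"g1", "x"})
        assert not r.is_monophyletic and not r.passes_thresholds

    def test_complement_side_counts_as_monophyletic(self):
        t = parse_support_tree(self.TREE)
        r = assess_monophyly(t, {"x", "y"})
        assert r.is_monophyletic
        assert (r.sh_alrt, r.ufboot) == (99.8, 100.0)

    def test_low_support_is_monophyletic_but_failing(self):
        t = parse_support_tree("((g1,g2)75/90,(x,y));")
        r = assess_monophyly(t, {"g1", "g2"})
        assert r.is_monophyletic and not r.passes_thresholds

    def test_absent_support_fails_closed(self):
        t = parse_support_tree("((g1,g2),(x,y));")
        r = assess_monophyly(t, {"g1", "g2"})
        assert r.is_monophyletic and not r.passes_thresholds

    def test_singleton_passes_only_when_waived(self):
        t = parse_support_tree(self.TREE)
        assert assess_monophyly(t, {"g1"}).passes_thresholds
        strict = assess_monophyly(t, {"g1"}, waive_singletons=False)
        assert strict.is_monophyletic and not strict.passes_thresholds

    def test_unknown_leaf_is_error(self):
        t = parse_support_tree(self.TREE)
        with pytest.raises(ValueError, match="zzz"):
            assess_monophyly(t, {"zzz"})

    def test_matches_exhaustive_bipartition_oracle(self):
        r = random.Random(99)
        for _ in range(200):
            n = r.randint(4, 10)
            labels = [f"t{i}" for i in range(n)]
            newick = random_topology_newick(labels, r)
            t = parse_support_tree(newick)
            k = r.randint(1, n - 1)
            target = set(r.sample(labels, k))
            got = assess_monophyly(t, target).is_monophyletic
            assert got == monophyly_oracle(newick, target)


class TestAssignBackboneClades:
    def test_caterpillar_blocks(self):
        newick = "((((a1,a2),a3),((b1,b2),b3)));"
        t = parse_support_tree(newick)
        cm = assign_backbone_clades(t, {"A": {"a1", "a2"},
                                        "B": {"b1", "b2"}})
        assert cm.assignments == {"a1": "A", "a2": "A",
                                  "b1": "B", "b2": "B"}

    def test_inseparable_exemplars_error(self):
        t = parse_support_tree("((a,b),(c,d));")
        with pytest.raises(ValueError, match="separable"):
            assign_backbone_clades(t, {"X": {"a", "c"}, "Y": {"b", "d"}})

    def test_overlapping_exemplar_sets_error(self):
        t = parse_support_tree("((a,b),(c,d));")
        with pytest.raises(ValueError, match="overlap"):
            assign_backbone_clades(t, {"X": {"a"}, "Y": {"a", "c"}})

    def test_matches_minimal_side_oracle_on_random_trees(self):
        r = random.Random(5)
        for _ in range(30):
            labels = [f"t{i}" for i in range(8)]
            newick = random_topology_newick(labels, r)
            t = parse_support_tree(newick)
            ex_a = set(r.sample(labels, 2))
            ex_b = set(r.sample([l for l in labels if l not in ex_a], 2))
            side_a = min_containing_side_oracle(newick, ex_a, ex_b)
            side_b = min_containing_side_oracle(newick, ex_b, ex_a)
            try:
                cm = assign_backbone_clades(t, {"A": ex_a, "B": ex_b})
            except ValueError:
                assert side_a is None or side_b is None \
                    or (side_a & side_b)
                continue
            got_a = {l for l, lab in cm.assignments.items() if lab == "A"}
            got_b = {l for l, lab in cm.assignments.items() if lab == "B"}
            assert got_a == side_a and got_b == side_b


class TestDiscordance:
    def _map(self, pairs):
        return CladeMap(dict(pairs))

    def _samples(self, pops):
        return SampleMap.from_records(
            [(f"s_{p}", p, f"sp_{p.rstrip('0123456789')}", "species")
             for p in pops])

    def test_identical_maps_have_zero_discordance(self):
        nuc = self._map({"p1": "NA", "p2": "NB", "p3": "NC"})
        pla = self._map({"p1": "PA", "p2": "PB", "p3": "PC"})
        M = self._samples(["p1", "p2", "p3"])
        rep = detect_cytonuclear_discordance(nuc, pla, M)
        assert rep.n_discordant_populations == 0

    def test_single_conflicting_population_flagged(self):
        nuc = self._map({"a1": "NA", "a2": "NA", "b1": "NB", "b2": "NB"})
        pla = self._map({"a1": "PA", "a2": "PA", "b1": "PA", "b2": "PB"})
        M = self._samples(["a1", "a2", "b1", "b2"])
        rep = detect_cytonuclear_discordance(nuc, pla, M)
        assert rep.correspondence == {"NA": "PA", "NB": "PB"}
        assert rep.flags["b1"] and rep.n_discordant_populations == 1

    def test_species_count_bounded_by_population_count(self):
        nuc = self._map({"a1": "NA", "a2": "NA", "b1": "NB"})
        pla = self._map({"a1": "PB", "a2": "PB", "b1": "PA"})
        M = SampleMap.from_records(
            [("s1", "a1", "spA", "species"),
             ("s2", "a2", "spA", "species"),
             ("s3", "b1", "spB", "species")])
        rep = detect_cytonuclear_discordance(nuc, pla, M)
        assert rep.n_discordant_species <= rep.n_discordant_populations

    def test_matches_exhaustive_assignment_on_random_maps(self, rng):
        for _ in range(20):
            pops = [f"p{i}" for i in range(12)]
            nuc = self._map({p: f"N{rng.integers(0, 3)}" for p in pops})
            pla = self._map({p: f"P{rng.integers(0, 3)}" for p in pops})
            M = self._samples(pops)
            rep = detect_cytonuclear_discordance(nuc, pla, M)
            nl = sorted({v for v in nuc.assignments.values()})
            pl = sorted({v for v in pla.assignments.values()})
            conf = np.zeros((len(nl), len(pl)))
            for p in pops:
                conf[nl.index(nuc.assignments[p]),
                     pl.index(pla.assignments[p])] += 1
            best = best_clade_correspondence(conf)
            assert rep.n_discordant_populations == len(pops) - best

    def test_relabeling_either_map_preserves_counts(self, rng):
        pops = [f"p{i}" for i in range(10)]
        nuc = self._map({p: f"N{rng.integers(0, 3)}" for p in pops})
        pla = self._map({p: f"P{rng.integers(0, 3)}" for p in pops})
        M = self._samples(pops)
        base = detect_cytonuclear_discordance(nuc, pla, M)
        relabel = {"N0": "X2", "N1": "X0", "N2": "X1"}
        nuc2 = self._map({p: relabel[c] for p, c in
                          nuc.assignments.items()})
        rep2 = detect_cytonuclear_discordance(nuc2, pla, M)
        assert rep2.n_discordant_populations == \
            base.n_discordant_populations

    def test_empty_overlap_is_error(self):
        M = self._samples(["p1", "p2"])
        with pytest.raises(ValueError, match="no population"):
            detect_cytonuclear_discordance(self._map({"p1": "NA"}),
                                           self._map({"p2": "PA"}), M)
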