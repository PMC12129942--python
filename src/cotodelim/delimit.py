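"""The hierarchical species-delimitation decision cascade.

Evidence per taxon: nuclear monophyly with branch-support thresholds
and single-gene-pool ancestry are the primary criterion; morphological
diagnosability (>= 2 discontinuous traits against every taxon sharing
its gene pool) and plastid-lineage concordance are secondary. The
ordered rules:

1. PURE ancestry + supported monophyly + diagnosable against every
   shared-pool partner -> VALID;
2. PURE or near-pure ancestry, sharing a pool with a partner it cannot
   be diagnosed from, and junior to that partner -> SYNONYM_CANDIDATE;
3. near-pure (SUBTHRESHOLD window) + supported monophyly + diagnosable
   -> VALID_BY_OVERRIDE (the reusable form of the documented
   ~70 %-purity exception);
4. ADMIXED + cytonuclear discordance + (non-monophyletic or
   morphologically intermediate with a parent candidate) -> HYBRID;
5. otherwise UNRESOLVED.

Plastid discordance is recorded for every taxon but is only *required*
evidence on the hybrid path: a pure, monophyletic, diagnosable taxon
stays VALID even when its plastid was captured elsewhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .ancestry import (ADMIXED, PURE, SUBTHRESHOLD, AncestryMatrix,
                       PurityCall, classify_taxa)
from .datatypes import (INFRASPECIFIC, SPECIES, CladeMap, GenotypeMatrix,
                        SampleMap, TraitTable)
from .morphometrics import count_diagnostic_traits
from .phylo import (DiscordanceReport, MonophylyResult, SupportTree,
                    assess_monophyly, assign_backbone_clades,
                    bootstrap_supports, detect_cytonuclear_discordance)

log = logging.getLogger(__name__)

VALID = "VALID"
VALID_BY_OVERRIDE = "VALID_BY_OVERRIDE"
HYBRID = "HYBRID"
SYNONYM_CANDIDATE = "SYNONYM_CANDIDATE"
UNRESOLVED = "UNRESOLVED"


@dataclass
class DelimitConfig:
    """All cascade thresholds in one place."""

    pure_threshold: float = 0.95
    override_floor: float = 0.70
    minor_threshold: float = 0.05
    sh_min: float = 80.0
    uf_min: float = 95.0
    min_traits: int = 2
    gap_fraction: float = 0.0
    waive_singletons: bool = True
    enable_override: bool = True
    #: explicit nomenclatural seniority: maps frozenset({a, b}) -> senior
    seniority: dict = field(default_factory=dict)

    def is_senior(self, taxon: str, partner: str,
                  ranks: dict[str, str]) -> bool:
        """Is ``taxon`` the senior name of the (taxon, partner) pair?

        Rank decides first (a species outranks an infraspecific taxon),
        then the explicit seniority mapping, then lexicographic order
        (earlier name senior) as a deterministic fallback — priority
        proper is nomenclature, not genomics, hence configurable.
        """
        ra = ranks.get(taxon, SPECIES)
        rb = ranks.get(partner, SPECIES)
        if ra != rb:
            return ra == SPECIES
        senior = self.seniority.get(frozenset((taxon, partner)))
        if senior is not None:
            return senior == taxon
        return taxon < partner


@dataclass
class DelimitationRecord:
    """Per-taxon evidence bundle and verdict."""

    taxon: str
    rank: str
    monophyly: MonophylyResult | None
    purity: PurityCall
    diagnosability: dict[str, int]
    plastid_concordant: bool | None
    status: str
    evidence: list[str]

    def to_dict(self) -> dict:
        mono = self.monophyly
        return {
            "taxon": self.taxon,
            "rank": self.rank,
            "status": self.status,
            "purity_class": self.purity.purity_class,
            "q_star": round(self.purity.q_star, 4),
            "dominant_pool": self.purity.dominant_pool,
            "contributing_pools": self.purity.contributing_pools,
            "monophyletic": None if mono is None else mono.is_monophyletic,
            "monophyly_passes": None if mono is None
            else mono.passes_thresholds,
            "stem_supports": None if mono is None
            else [mono.sh_alrt, mono.ufboot],
            "diagnosability": self.diagnosability,
            "plastid_concordant": self.plastid_concordant,
            "evidence": self.evidence,
        }


def evaluate_taxon(taxon: str, rank: str, mono: MonophylyResult,
                   purity: PurityCall, diag: dict[str, int],
                   plastid_concordant: bool | None,
                   shared_pool_partners: list[str],
                   parent_candidates: list[str],
                   config: DelimitConfig,
                   ranks: dict[str, str] | None = None
                   ) -> DelimitationRecord:
    """Apply the ordered rule cascade to one taxon's evidence bundle."""
    ranks = ranks or {}
    if mono is None:
        raise ValueError(f"missing monophyly evidence for {taxon!r}")
    if purity is None:
        raise ValueError(f"missing purity evidence for {taxon!r}")
    for p in shared_pool_partners + parent_candidates:
        if p not in diag:
            raise ValueError(
                f"missing diagnosability evidence for {taxon!r} vs {p!r}")
    trail: list[str] = [
        f"purity={purity.purity_class} (q*={purity.q_star:.3f})",
        f"monophyly={'pass' if mono.passes_thresholds else 'fail'}"
        f" (monophyletic={mono.is_monophyletic})",
    ]
    if plastid_concordant is not None:
        trail.append(f"plastid_concordant={plastid_concordant}")

    def diagnosable_against_all() -> tuple[bool, list[str]]:
        absorbed = []
        for p in shared_pool_partners:
            if diag[p] >= config.min_traits:
                continue
            if config.is_senior(taxon, p, ranks):
                absorbed.append(p)
            else:
                return False, absorbed
        return True, absorbed

    status = UNRESOLVED
    ok, absorbed = diagnosable_against_all()
    junior_conflicts = [p for p in shared_pool_partners
                        if diag[p] < config.min_traits
                        and not config.is_senior(taxon, p, ranks)]
    if purity.purity_class == PURE and mono.passes_thresholds and ok:
        status = VALID
        trail.append("rule1: pure + supported monophyly + diagnosable "
                     "-> VALID")
        for p in absorbed:
            trail.append(f"rule1: shared-pool junior {p} not diagnosable; "
                         f"absorbed as synonym")
    elif (purity.purity_class in (PURE, SUBTHRESHOLD)
          and junior_conflicts):
        status = SYNONYM_CANDIDATE
        senior = junior_conflicts[0]
        trail.append(f"rule2: shares pool {purity.dominant_pool} with "
                     f"{senior} and < {config.min_traits} discontinuous "
                     f"traits -> SYNONYM_CANDIDATE (senior: {senior})")
    elif (config.enable_override
          and purity.purity_class == SUBTHRESHOLD
          and mono.passes_thresholds and ok):
        status = VALID_BY_OVERRIDE
        trail.append("rule3: subthreshold purity overridden by supported "
                     "monophyly + diagnosability -> VALID_BY_OVERRIDE")
    elif purity.purity_class == ADMIXED and plastid_concordant is False:
        intermediate = [p for p in parent_candidates
                        if diag[p] < config.min_traits]
        if not mono.is_monophyletic or intermediate:
            status = HYBRID
            why = ("non-monophyletic" if not mono.is_monophyletic
                   else f"morphologically intermediate with "
                        f"{intermediate[0]}")
            trail.append(f"rule4: admixed + cytonuclear discordance + "
                         f"{why} -> HYBRID")
    if status == UNRESOLVED:
        trail.append("rule5: no rule fired -> UNRESOLVED")
    return DelimitationRecord(taxon, rank, mono, purity, diag,
                              plastid_concordant, status, trail)


@dataclass
class DelimitationSummary:
    valid_species: int
    admixed_species: int
    hybrid_species: int
    synonym_species: int
    unresolved_species: int
    gene_pools_among_valid: int
    n_species: int


class DelimitationReport:
    """Results object of a full delimitation run."""

    def __init__(self, records: dict[str, DelimitationRecord],
                 discordance: DiscordanceReport | None,
                 config: DelimitConfig):
        self.records = records
        self.discordance = discordance
        self.config = config

    def species_records(self) -> list[DelimitationRecord]:
        return [r for r in self.records.values() if r.rank == SPECIES]

    def taxa_with_status(self, *statuses: str) -> list[str]:
        return [r.taxon for r in self.records.values()
                if r.status in statuses]

    @property
    def summary_counts(self) -> DelimitationSummary:
        sp = self.species_records()
        valid = [r for r in sp if r.status in (VALID, VALID_BY_OVERRIDE)]
        pools = {r.purity.dominant_pool for r in self.records.values()
                 if r.status in (VALID, VALID_BY_OVERRIDE)}
        return DelimitationSummary(
            valid_species=len(valid),
            admixed_species=sum(r.purity.purity_class == ADMIXED
                                for r in sp),
            hybrid_species=sum(r.status == HYBRID for r in sp),
            synonym_species=sum(r.status == SYNONYM_CANDIDATE for r in sp),
            unresolved_species=sum(r.status == UNRESOLVED for r in sp),
            gene_pools_among_valid=len(pools),
            n_species=len(sp),
        )

    def summary(self) -> str:
        c = self.summary_counts
        lines = [
            "Species delimitation report",
            f"  species-rank taxa: {c.n_species}",
            f"  valid species (incl. override): {c.valid_species}",
            f"  admixed species: {c.admixed_species}",
            f"  distinct gene pools among valid taxa: "
            f"{c.gene_pools_among_valid}",
            f"  hybrid: {c.hybrid_species}   synonym candidates: "
            f"{c.synonym_species}   unresolved: {c.unresolved_species}",
        ]
        if self.discordance is not None:
            lines.append(
                f"  cytonuclear discordance: "
                f"{self.discordance.n_discordant_populations} populations / "
                f"{self.discordance.n_discordant_species} species")
        lines.append("")
        lines.append(f"  {'taxon':<34}{'status':<20}{'class':<14}q*")
        for r in self.records.values():
            lines.append(f"  {r.taxon:<34}{r.status:<20}"
                         f"{r.purity.purity_class:<14}"
                         f"{r.purity.q_star:.2f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({t: r.to_dict() for t, r in self.records.items()},
                          indent=2)

    def to_tsv(self) -> str:
        lines = ["taxon\trank\tstatus\tpurity_class\tq_star\tdominant_pool"
                 "\tmonophyly_passes\tplastid_concordant"]
        for r in self.records.values():
            mono = "" if r.monophyly is None \
                else int(r.monophyly.passes_thresholds)
            pc = "" if r.plastid_concordant is None \
                else int(r.plastid_concordant)
            lines.append(f"{r.taxon}\t{r.rank}\t{r.status}\t"
                         f"{r.purity.purity_class}\t{r.purity.q_star:.4f}\t"
                         f"{r.purity.dominant_pool}\t{mono}\t{pc}")
        return "\n".join(lines) + "\n"


def _tip_sets(tree: SupportTree, M: SampleMap) -> dict[str, list[str]]:
    """Tree tips per taxon; tips may be sample ids or population ids."""
    tips = tree.leaf_labels
    samples = set(M.table["sample"])
    pops = set(M.table["population"])
    if tips <= samples:
        return {t: [s for s in M.samples_of_taxon(t) if s in tips]
                for t in M.taxa}
    if tips <= pops:
        return {t: [p for p in M.populations_of_taxon(t) if p in tips]
                for t in M.taxa}
    raise ValueError("tree tips are neither all sample ids nor all "
                     "population ids")


def _trait_units(traits: TraitTable, M: SampleMap) -> dict[str, list[str]]:
    units = set(traits.units)
    if units <= set(M.taxa):
        return {t: [t] for t in M.taxa if t in units}
    if units <= set(M.populations):
        return {t: [p for p in M.populations_of_taxon(t) if p in units]
                for t in M.taxa}
    raise ValueError("trait-table units are neither taxa nor populations")


def population_clades_from_tree(tree: SupportTree, seeds: dict[str, set],
                                M: SampleMap) -> CladeMap:
    """Backbone clades per population from a tree over samples or
    populations.

    Sample-level labels are lifted to populations by majority;
    populations whose tips fall outside every backbone side inherit the
    label of the nearest assigned tip (patristic distance), so taxa of
    intermediate placement still receive the clade they nest closest
    to.
    """
    leaf_map = assign_backbone_clades(tree, seeds)
    tips = tree.leaf_labels
    by_pop: dict[str, list[str]] = {}
    if tips <= set(M.table["sample"]):
        pop_of = dict(zip(M.table["sample"], M.table["population"]))
    else:
        pop_of = {p: p for p in M.populations}
    for tip in tips:
        pop = pop_of.get(tip)
        if pop is not None:
            by_pop.setdefault(pop, []).append(tip)
    pdm = None
    assignments: dict[str, str] = {}
    for pop, members in by_pop.items():
        labels = [leaf_map.assignments.get(t) for t in members]
        labels = [l for l in labels if l is not None]
        if labels:
            assignments[pop] = max(sorted(set(labels)), key=labels.count)
            continue
        if pdm is None:
            pdm = tree.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.tree.taxon_namespace}
        best, best_d = None, float("inf")
        for t in members:
            for other, lab in leaf_map.assignments.items():
                dist = pdm.patristic_distance(taxa[t], taxa[other])
                if dist < best_d:
                    best, best_d = lab, dist
        assignments[pop] = best
    return CladeMap(assignments)


def run_delimitation(Q: AncestryMatrix, M: SampleMap,
                     traits: TraitTable, config: DelimitConfig | None = None,
                     nuclear_tree: SupportTree | None = None,
                     nuclear_clades: CladeMap | None = None,
                     plastid_clades: CladeMap | None = None,
                     nuclear_clade_seeds: dict[str, set] | None = None
                     ) -> DelimitationReport:
    """Evaluate every taxon of a study against the full cascade.

    The nuclear tree provides monophyly; clade maps (given directly or
    derived from the tree via exemplar seeds) provide the cytonuclear
    comparison; the trait table provides diagnosability. All evidence
    must come from one ancestry run (one K).
    """
    config = config or DelimitConfig()
    if nuclear_tree is None:
        raise ValueError("nuclear tree is required")
    calls = classify_taxa(Q, M, pure_threshold=config.pure_threshold,
                          override_floor=config.override_floor,
                          minor_threshold=config.minor_threshold)
    ranks = M.rank_of_taxon()
    tip_sets = _tip_sets(nuclear_tree, M)
    trait_units = _trait_units(traits, M)

    if nuclear_clades is None and nuclear_clade_seeds is not None:
        nuclear_clades = population_clades_from_tree(
            nuclear_tree, nuclear_clade_seeds, M)
    discordance = None
    pop_flags: dict[str, bool] = {}
    if nuclear_clades is not None and plastid_clades is not None:
        discordance = detect_cytonuclear_discordance(
            nuclear_clades, plastid_clades, M)
        pop_flags = discordance.flags

    # shared-pool partnerships and hybrid parent candidates
    dominant_taxon: dict[int, list[str]] = {}
    for t, c in calls.items():
        if not c.is_admixed:
            dominant_taxon.setdefault(c.dominant_pool, []).append(t)

    records: dict[str, DelimitationRecord] = {}
    for taxon, call in calls.items():
        partners = [t for t in dominant_taxon.get(call.dominant_pool, [])
                    if t != taxon] if not call.is_admixed else []
        # infraspecific taxa never threaten their parent species: drop
        # them from the partner list of species-rank taxa
        if ranks.get(taxon) == SPECIES:
            partners = [p for p in partners
                        if ranks.get(p) != INFRASPECIFIC]
        parents: list[str] = []
        if call.is_admixed:
            for pool in call.contributing_pools:
                parents.extend(t for t in dominant_taxon.get(pool, [])
                               if t != taxon)
        tips = tip_sets.get(taxon, [])
        if tips:
            mono = assess_monophyly(nuclear_tree, tips,
                                    sh_min=config.sh_min,
                                    uf_min=config.uf_min,
                                    waive_singletons=config.waive_singletons)
        else:
            mono = MonophylyResult(frozenset(), False, None, None, False)
            log.warning("taxon %s has no tips in the nuclear tree", taxon)
        diag: dict[str, int] = {}
        for p in dict.fromkeys(partners + parents):
            ua = trait_units.get(taxon, [])
            ub = trait_units.get(p, [])
            if not ua or not ub:
                raise ValueError(
                    f"missing trait observations for pair "
                    f"({taxon!r}, {p!r})")
            n, _, _ = count_diagnostic_traits(
                traits, ua, ub, gap_fraction=config.gap_fraction,
                min_traits=config.min_traits)
            diag[p] = n
        pops = M.populations_of_taxon(taxon)
        flagged = [pop_flags[p] for p in pops if p in pop_flags]
        concordant = (not any(flagged)) if flagged else None
        records[taxon] = evaluate_taxon(
            taxon, ranks.get(taxon, SPECIES), mono, call, diag,
            concordant, partners, parents, config, ranks)
    return DelimitationReport(records, discordance, config)


def rebuild_without_hybrids(report: DelimitationReport, G: GenotypeMatrix,
                            M: SampleMap, n_reps: int = 100,
                            seed: int = 0
                            ) -> tuple[SupportTree, SampleMap]:
    """Rebuild the nuclear tree after dropping admixed and hybrid taxa.

    Removes every taxon whose purity class is ADMIXED or whose status
    is HYBRID (subthreshold override taxa are retained) and rebuilds an
    NJ + bootstrap tree over the remaining samples.
    """
    drop = {r.taxon for r in report.records.values()
            if r.status == HYBRID or r.purity.purity_class == ADMIXED}
    keep_taxa = [t for t in M.taxa if t not in drop]
    M_kept = M.restrict_to_taxa(keep_taxa)
    if len(M_kept.populations) < 4:
        raise ValueError("fewer than 4 populations retained")
    samples = [s for s in G.samples
               if s in set(M_kept.table["sample"])]
    G_kept = G.take_samples(samples)
    tree = bootstrap_supports(G_kept, n_reps=n_reps, seed=seed)
    return tree, M_kept
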